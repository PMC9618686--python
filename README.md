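# metgxe

Multi-environment trial (MET) analysis of cassava processed-product traits —
gari and fufu conversion rates, processing losses, and root yields — for
breeding programmes that must separate genetics from environment before
selecting clones.

Cassava roots are mostly consumed after processing, and the fraction of fresh
root weight recovered as gari or fufu (the *conversion rate*) varies among
genotypes and across location-year environments. Deciding which clones to
advance requires variance components and heritability across trials,
genotype-by-environment interaction (GEI) modelling, and stability analysis.
`metgxe` implements that whole workflow as a library plus a thin CLI, together
with a synthetic MET generator that emulates a two-set uniform-yield-trial
series (62 advanced clones + 5 shared checks in 8 environments, alpha-lattice
layout with 2 replications) so that every estimator can be validated against
known truth.

## Models

**Trait derivation.** From plot records: gari% = 100·gari weight / starting
root weight (likewise fufu%, peel loss%, fiber%); FYLD (t/ha) =
RTWT / (plants harvested × 0.8 m²) × 10; DYLD = FYLD·DM/100; product yields =
FYLD × conversion/100.

**Variance components (REML).** The across-environment linear mixed model

    y = Xβ + Z_g u_g + Z_E u_E + Z_{r(E)} u_r + Z_{gE} u_gE + ε,   u_c ~ N(0, σ²_c I)

with genotype, environment, replication-within-environment and GEI random,
and row/column trends (nested in trial set × environment) fixed. Fitted by
REML on the mixed-model equations (EM warm start, quasi-Newton polish,
analytic gradients); variance components get standard errors from the
observed information and one-sided z-tests.

**Heritability.** Entry-mean `H² = σ²_g / (σ²_g + σ²_gE/e + σ²_ε/(e·r))` and
Cullis `H² = 1 − v̄_Δ / (2σ²_g)`, where `v̄_Δ` is the mean variance of a
difference between genotype BLUPs taken from the inverse mixed-model
equations.

**Deregression.** `DRBLUP = BLUP / reliability`, reliability `= 1 − PEV/σ²_g`;
cross-trait Pearson correlations of DRBLUPs with t-tests.

**GEI models** on the genotype × environment table of per-environment BLUEs:
Finlay–Wilkinson regression `y_ij = μ + G_i + E_j + b_i E_j + e_ij` (two-step
estimator, slopes centred on 1), AMMI (SVD of the double-centred interaction,
IPCA scores with Gollob df), and GGE (SVD of the environment-centred table,
symmetric-scaling biplot coordinates, which-won-where hull flags). All three
partition the same total sum of squares.

**Stability.** Wricke ecovalence `W_i = Σ_j (x_ij − x̄_i· − x̄_·j + x̄_··)²`
(ΣW_i equals the interaction SS exactly) and the geometric adaptability index
`GAI_i = (Π_j x_ij)^{1/E}`, with ranking and the "above the population mean
and stable" selection rule.

## Worked example

```python
import metgxe as m

cfg, corr = m.cassava_uyt_config(seed=42)      # 67 genotypes x 8 envs x 2 reps
pheno, truth = m.simulate_met(cfg, corr)

res = m.METMixedModel(pheno, "gari_pct").fit()
print(res.summary())
```

```
Variance components (REML)
==============================================================
term                        estimate        se       z       p
genotype                     0.94702    0.2262    4.19   0.000
environment                  1.90961    1.1024    1.73   0.042
rep:environment              0.21709    0.1288    1.69   0.046
genotype:environment         1.34682    0.1996    6.75   0.000
residual                     2.71703    0.1666   16.31   0.000
--------------------------------------------------------------
REML log-likelihood -1379.7274   iterations 30   converged True

H2_standard = 0.7369  (e=8, r=2)
H2_Cullis   = 0.7304
```

Genotype and GEI variance are both significant (one-sided z-tests), and the
entry-mean heritability of ~0.74 says selection on across-trial means is
worthwhile. Continuing to stability:

```python
tw = m.complete_table(m.two_way_means(pheno, "gari_pct"))
stab = m.rank_and_select(m.stability_table(tw), rule="gai_top_k", k=5)
print(stab[stab.selected].round(3).to_string())
```

```
             mean      Wi  Wi_pct_gei     GAI  Wi_rank  GAI_rank  selected
genotype
G11        22.305  19.843       1.543  22.259       42         2      True
G25        22.232   6.572       0.511  22.191        5         3      True
G32        23.324  16.582       1.290  23.225       33         1      True
G58        21.950  17.936       1.395  21.827       37         5      True
TMS000070  21.950  13.362       1.039  21.872       22         4      True
```

The five GAI-selected clones all sit above the population mean; `Wi_rank`
shows that high adaptability (GAI) and static stability (Wi) need not agree —
only G25 is also near the top of the ecovalence ranking.

The same workflow is scriptable:

```bash
metgxe simulate --seed 1 --raw --out pheno.csv --truth truth.json
metgxe fit --pheno pheno.csv --trait gari_pct --out-prefix gari
metgxe gxe --pheno pheno.csv --trait gari_pct --models fw,ammi,gge --out gxe/
metgxe stability --pheno pheno.csv --trait gari_pct --top 5 --out stab.csv
metgxe run --config full.yaml --out results/    # whole pipeline, reproducible
```

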