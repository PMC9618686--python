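# Methods

## The statistical model

All estimation rests on one linear mixed model class,

    y = Xβ + Σ_c Z_c u_c + ε,   u_c ~ N(0, σ²_c I_{q_c}),   ε ~ N(0, σ²_ε I),

with independent, identically distributed levels inside every random term
(no pedigree or genomic covariance — genotypes are exchangeable labels).
Two configurations of this class cover the workflow:

* **Across-environment analysis** (variance components, BLUPs,
  heritability): genotype, environment, replication-within-environment and
  genotype×environment random; intercept plus row- and column-position
  trends fixed.
* **Per-environment adjusted means** (BLUEs for the GEI models): genotype
  fixed (full indicator coding, no intercept, so coefficients are adjusted
  genotype means), replication and row/column-within-set random.

Rows and columns enter the fixed part as *standardised linear trends nested
within set × environment*, not as factors. Factor coding of plot positions
across eight environments is not identifiable in general (and aliases under
missingness), while the spatial signal the design records is a smooth
within-trial trend; the generator produces exactly such trends. Aliased
fixed columns are detected by pivoted QR and reported by name.

## REML estimation

The REML log-likelihood is evaluated through Henderson's mixed-model
equations (MME): with W = [X, Z] and C the MME coefficient matrix,

    −2 l_R = n log σ²_ε + Σ_c q_c log σ²_c + log|C| + y'Py + const,

needing one Cholesky factorisation of C per evaluation. The analytic
gradient follows from the inverse-MME diagonal blocks. Optimisation is:

1. **EM warm start** (default 15 iterations) — boundary-safe and
   monotone in the likelihood (the iteration trace is exposed and tested);
2. **L-BFGS-B polish** with the analytic gradient, variances bounded below
   by 10⁻¹² on the unit-variance working scale (the response is
   standardised internally for conditioning and results rescaled);
3. **Damped Newton refinement** using a numerical Hessian of the analytic
   gradient. Line searches in step 2 routinely stall once objective
   changes drop under float resolution; with curvatures of order 10² or
   more, a relative gradient of 10⁻⁵ (the acceptance threshold) bounds the
   parameter error by roughly 10⁻⁷, far inside every tolerance used
   downstream.

Components shrinking below 10⁻⁸ of the phenotypic variance are **pinned at
exactly zero** — an explicit, reportable state (their standard errors are
missing, not fabricated) — and excluded from a final re-polish. Standard
errors come from the observed information (numerical Hessian at the
optimum); z-tests for variance components are one-sided, the appropriate
choice for boundary-constrained parameters. Percent variance explained is
each component over the sum of all components including the residual.

BLUPs, their prediction-error variances (PEV) and the full PEV block of the
genotype effects are read off the inverse MME at the optimum. The Cullis
heritability uses the exact mean pairwise-difference variance

    v̄_Δ = mean_{i≠j} Var(û_i − û_j) = 2 (n·tr M − 1'M1) / (n(n−1)),

with M the genotype PEV block; the common approximation 2·mean(PEV) is
available as an option (`method="approx"`) and agrees to ~10⁻³ on balanced
data. Deregression divides each BLUP by its reliability 1 − PEV/σ²_g;
genotypes at or below the reliability floor (default 0.1) get a missing
DRBLUP with a logged count.

Entry-mean heritability uses e = number of environments observed and r =
the median number of plots per genotype × environment × set (2 in the
emulated design; checks appear in both trial sets and therefore have four
plots per environment, which the median deliberately ignores).

## Per-trial heritability

Within a single environment, genotypic and interaction variance are
confounded: the within-trial "genetic" variance estimates σ²_g + σ²_gE, so
the expected within-trial Cullis value is (σ²_g + σ²_gE)/(σ²_g + σ²_gE +
σ²_ε/r), not σ²_g/(σ²_g + σ²_gE + σ²_ε/r). The tests assert the former.
Environments that fail to converge are reported missing, never raised.

## Two-way table, completion, scaling

Adjusted means are computed per environment rather than from one joint fit:
the GEI models need a genotype × environment cell table, and a joint
genotype-fixed fit returns only main-effect BLUEs. Missing cells (genotype
absent from an environment) are counted and flagged. Completion fits the
additive two-way model **by least squares on observed cells only** and then
EM-iterates a single multiplicative (rank-1 SVD) term, missing residuals
starting at zero. Fitting the additive part on observed cells is what makes
purely additive data impute exactly; estimating it from the completed
matrix lets the rank-1 term chase its own imputations on isolated missing
cells. Tables missing a whole row/column, or more than 20% of cells, are
refused.

Scaling standardises all cells to mean 0, SD 1 (ddof = 1), and is applied
**only before Finlay–Wilkinson regression** (to make sensitivities and MS
deviations comparable across traits). Stability indices always run on the
unscaled table: GAI is a geometric mean and is meaningless on centred data.

## GEI models

* **Finlay–Wilkinson** uses the two-step estimator: environmental index
  Ê_j = column mean − grand mean, then per-genotype OLS of the row on Ê.
  On a complete, equally weighted table this coincides with alternating
  least squares; slopes average exactly 1, and the interaction SS splits
  exactly into slope heterogeneity + deviation SS. MS deviation is
  RSS/(E−2), so at least three environments are required.
* **AMMI** double-centres the table and takes its SVD. Scores use the
  symmetric convention u√λ / v√λ for both modes, so the Gram matrix of
  score vectors is diag(λ). IPCA degrees of freedom follow Gollob,
  (g−1)+(e−1)−(2k−1); the F-tests against the interaction residual are
  reported but approximate by construction.
* **GGE** removes only the environment means before the SVD; PC shares of
  G+GE, environment-vector cosines in the PC1–PC2 plane, and
  which-won-where hull membership (scipy ConvexHull against a brute-force
  per-environment argmax) are reported.

SVD orientation is made deterministic by forcing the largest-magnitude
genotype loading of each component positive; nearly equal singular values
trigger a rotation-indeterminacy warning. Ranking ties anywhere break by
genotype label (stable mergesort), so ranks are always a permutation of
1..n.

Wricke's ecovalence is reported as the squared-deviation form (ΣW_i equals
the interaction SS, and a %-of-GEI column makes that visible); GAI is
computed in log space to avoid overflow on yield-scale products, and
genotypes with any non-positive cell get a missing GAI with a warning.

## The synthetic generator

Each trait is simulated as

    y = μ + g_i + E_j + (b_i − 1)E_j + ge_ij + rep_{k(j)} + spatial + ε,

genetic values drawn jointly across traits from a user-specified genetic
correlation matrix (slightly indefinite input is repaired by eigenvalue
clipping; input beyond the repair tolerance is rejected), FW sensitivities
b_i ~ N(1, sd²) entering multiplicatively on the environment effect so that
the marginal regression of a genotype on the environment mean has slope b_i
in expectation, and cell-level interaction ge_ij independent of the slope
term. The incomplete-block structure of an alpha-lattice is approximated by
random row/column linear trends per set × environment — the analysis models
use row/column trends, not block effects, so this is the matching
data-generating process. All randomness derives from one master seed via
named substreams; identical configurations give byte-identical tables.

The design emulates the two-set uniform-yield-trial series: 62 advanced
clones split over two 36-entry sets that share 5 checks (67 unique
genotypes, 72 entries), 8 location-year environments, 2 replications,
1152 plots. The `cassava_uyt` preset sets trait means at the reported
population means (gari% 19.23, fufu% 19.68, DM 36.94%, FYLD 33.03 t/ha)
and variance components that put the entry-mean heritability of the
conversion rates near 0.7 with the environment near 45% of phenotypic
variance; genetic correlations tie DM to gari% (0.80), DM to fufu% (0.82)
and gari% to fufu% (0.84) while fresh root yield is essentially
uncorrelated with the conversion rates. Within-trial spatial variance
magnitudes are not observable from published summaries; the preset uses a
small trend SD (0.3 on the trait scale) as a documented assumption, and a
5% plot missingness rate.

**What the generator does not emulate:** spatial autocorrelation beyond
linear trends, non-Gaussian trait distributions, cross-trait correlation of
*non-genetic* effects (interaction and plot error are independent across
traits), heterogeneous error variances across environments, and missingness
that is informative rather than completely at random. Tests passing on this
generator therefore validate the estimators under the stated model, not the
full messiness of field data.

## Recovery experiments and problem sizes

* Variance-component recovery: 100 replicate METs at the emulated scale
  (67×8×2, σ²_g=1, σ²_gE=0.5, σ²_ε=2). Mean estimates recover truth within
  a few percent; the mean entry-mean H² sits on the closed form
  1/(1 + 0.5/8 + 2/16) ≈ 0.842.
* FW slope recovery uses sensitivity SD 0.3 with environment-effect SD 5:
  the slope-estimation error variance is (σ²_gE + σ²_ε/r̄)/ΣÊ², so a wide
  environmental range is what makes slopes estimable at all; with 8
  environments of SD 2 the error variance equals the signal and no
  estimator could reach correlation 0.9.
* Large-population experiments (deregression slope, correlation recovery)
  use 505 genotypes in one set and fit the **entry-mean model** (genotype
  and environment random on cell means) — with a balanced design this
  carries the same genotype information as the plot-level fit at a
  fraction of the random-effect dimension. Regressing DRBLUPs on true
  genetic values has slope 1 (BLUPs have slope = mean reliability; that is
  the shrinkage deregression removes).
* Cross-trait DRBLUP correlations attenuate by the mean reliability,
  r_obs ≈ r_g·r̄, because non-genetic effects are independent across traits
  in the generator. The correlation-recovery experiment therefore uses
  high-reliability settings (σ²_gE=0.2, σ²_ε=0.8, r̄≈0.93), where the
  attenuated expectation ≈ 0.74 for a genetic correlation of 0.8; with the
  base settings (r̄≈0.84) the expectation would be ≈ 0.67. Estimated
  correlations should be read as lower bounds on the genetic correlation
  whenever reliability is materially below 1.

## Numerical conventions

* Missing data: one sentinel (NaN) everywhere; rows with missing response
  are dropped explicitly at design construction; derivations with missing
  parents propagate missingness and never raise.
* Convergence: relative component change < 10⁻⁸ in EM, L-BFGS-B
  ftol 10⁻¹⁴ / gtol 10⁻¹⁰, Newton relative-gradient 10⁻⁵.
* Table completion: iterate to max imputation change < 10⁻⁸, cap 500.
* CSV output: ≥ 10 significant digits (`%.12g`), fixed column order —
  pipeline reruns with the same config and seed are byte-identical.
* Degenerate inputs: zero-variance tables cannot be scaled; a recorded
  product weight with zero starting root weight is a data error; duplicate
  (genotype, environment, rep, set) keys are a data error naming the key.

## Known limitations

* Identity covariance among genotypes only; no kinship, no spatial
  autocorrelation models beyond fixed trends.
* Gollob F-tests for IPCAs are anti-conservative; treat them as screening.
* The per-environment BLUE step assumes enough replication within each
  environment to separate design effects; single-rep environments fall
  back to raw means for the affected terms.
* GAI requires strictly positive cell values and is undefined otherwise.
* Environment labels are opaque strings; reconciling location-year naming
  schemes is the user's responsibility.
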