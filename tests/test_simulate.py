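"""Synthetic MET generator: design validity, determinism, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from metgxe.pheno import ConfigError
from metgxe.simulate import (GeneticCorrelation, SimConfig, TraitSpec,
                             TruthRecord, make_design, cassava_uyt_config,
                             simulate_met)
from metgxe.gxe import two_way_means, FinlayWilkinson, complete_table

from conftest import recovery_config


class TestDesign:
    def test_two_sets_sharing_checks_give_67_genotypes(self):
        cfg = SimConfig(traits=[TraitSpec("y", mu=0, var_g=1)], seed=0)
        d = make_design(cfg)
        assert d.df["genotype"].nunique() == 67
        sets = cfg.sets
        assert len(sets) == 2
        shared = set(sets["setA"]) & set(sets["setB"])
        assert len(shared) == 5          # checks planted in both sets
        assert all(len(v) == 36 for v in sets.values())

    def test_plot_count_by_enumeration(self):
        # 36 entries x 2 sets x 2 reps x 8 environments = 1152 plots
        d = make_design(SimConfig(traits=[TraitSpec("y", mu=0, var_g=1)], seed=0))
        assert len(d.df) == 1152

    def test_plot_key_unique_and_no_grid_collisions(self):
        d = make_design(SimConfig(traits=[TraitSpec("y", mu=0, var_g=1)], seed=0))
        assert not d.df.duplicated(["genotype", "environment", "rep", "set"]).any()
        assert not d.df.duplicated(["environment", "set", "rep", "row", "col"]).any()

    def test_grid_overflow_raises(self):
        cfg = SimConfig(traits=[TraitSpec("y", mu=0, var_g=1)], grid=(5, 5), seed=0)
        with pytest.raises(ConfigError, match="grid"):
            make_design(cfg)


class TestSimulate:
    def test_same_seed_identical(self):
        cfg = recovery_config(seed=11)
        t1, _ = simulate_met(cfg)
        t2, _ = simulate_met(recovery_config(seed=11))
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_different_seed_differs(self):
        t1, _ = simulate_met(recovery_config(seed=1))
        t2, _ = simulate_met(recovery_config(seed=2))
        assert not t1.df["y"].equals(t2.df["y"])

    def test_no_interaction_limit_is_exactly_additive(self):
        cfg = SimConfig(traits=[TraitSpec("y", mu=10, var_g=1.0,
                                          env_effect_sd=2.0)], seed=5)
        table, truth = simulate_met(cfg)
        cells = table.df.pivot_table(index="genotype", columns="environment",
                                     values="y", aggfunc="mean").to_numpy()
        dc = cells - cells.mean(1, keepdims=True) - cells.mean(0, keepdims=True) \
            + cells.mean()
        assert np.abs(dc).max() < 1e-9

    def test_all_variances_zero_gives_constant(self):
        cfg = SimConfig(traits=[TraitSpec("y", mu=7.5, var_g=0.0)], seed=2)
        table, _ = simulate_met(cfg)
        assert np.allclose(table.df["y"], 7.5)

    def test_truth_matches_observed_effects(self):
        cfg = recovery_config(seed=4)
        table, truth = simulate_met(cfg)
        # reconstruct one plot from the truth record
        r = table.df.iloc[0]
        spec = cfg.traits[0]
        g = truth.genetic_values.loc[r.genotype, "y"]
        E = truth.env_effects.loc[r.environment, "y"]
        b = truth.slopes.loc[r.genotype, "y"]
        ge = truth.ge_effects["y"].loc[r.genotype, r.environment]
        rep = truth.rep_effects["y"]
        rep = rep[(rep.environment == r.environment) & (rep.rep == r.rep)]["effect"].iloc[0]
        resid = r.y - (spec.mu + g + E + (b - 1) * E + ge + rep)
        assert abs(resid) < 5 * np.sqrt(spec.var_e)  # only noise remains

    def test_missingness_rate(self):
        cfg = recovery_config(seed=9, missing_rate=0.1)
        table, _ = simulate_met(cfg)
        frac = table.df["y"].isna().mean()
        assert 0.05 < frac < 0.15

    def test_truth_roundtrips_through_json(self, tmp_path):
        _, truth = simulate_met(recovery_config(seed=1))
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = TruthRecord.from_json(p)
        pd.testing.assert_frame_equal(truth.genetic_values, back.genetic_values)
        pd.testing.assert_frame_equal(truth.ge_effects["y"], back.ge_effects["y"])


class TestStatisticalStructure:
    def test_genetic_variance_calibration(self):
        """Mean sample variance of genetic values over 200 draws at n=500
        stays within 3 standard errors of the requested variance."""
        var_g = 1.7
        cfg0 = SimConfig(n_genotypes=505, n_sets=1, grid=(23, 23),
                         environments=["E1", "E2"], n_reps=1,
                         traits=[TraitSpec("y", mu=0, var_g=var_g)], seed=0)
        n = 505
        vars_ = []
        for s in range(200):
            cfg = SimConfig(n_genotypes=505, n_sets=1, grid=(23, 23),
                            environments=["E1", "E2"], n_reps=1,
                            traits=[TraitSpec("y", mu=0, var_g=var_g)], seed=s)
            _, truth = simulate_met(cfg)
            vars_.append(truth.genetic_values["y"].var(ddof=1))
        mean_v = np.mean(vars_)
        se = var_g * np.sqrt(2.0 / (n - 1)) / np.sqrt(200)
        assert abs(mean_v - var_g) < 3 * se

    def test_cross_trait_genetic_correlation(self):
        traits = [TraitSpec("a", mu=0, var_g=1.0), TraitSpec("b", mu=0, var_g=2.0)]
        corr = GeneticCorrelation({("a", "b"): 0.6})
        rs = []
        for s in range(20):
            cfg = SimConfig(n_genotypes=505, n_sets=1, grid=(23, 23),
                            environments=["E1", "E2"], n_reps=1,
                            traits=traits, seed=s)
            _, truth = simulate_met(cfg, corr)
            g = truth.genetic_values
            rs.append(np.corrcoef(g["a"], g["b"])[0, 1])
        assert abs(np.mean(rs) - 0.6) < 0.05

    def test_fw_slope_recovery_from_generated_table(self):
        """FW slopes estimated from the simulated MET correlate > 0.9 with
        the generating sensitivities (67 genotypes, 8 environments)."""
        cfg = recovery_config(seed=21, sensitivity_sd=0.3, env_effect_sd=5.0)
        table, truth = simulate_met(cfg)
        tw = complete_table(two_way_means(table, "y"))
        fw = FinlayWilkinson(tw).fit()
        est = fw.genotype_stats["sensitivity"].reindex(truth.slopes.index)
        r = np.corrcoef(est, truth.slopes["y"])[0, 1]
        assert r > 0.9


class TestCorrelationRepair:
    def test_psd_repair_and_rejection(self):
        # mildly inconsistent triple: repairable
        c = GeneticCorrelation({("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.65})
        R = c.matrix(["a", "b", "c"])
        assert np.linalg.eigvalsh(R).min() >= -1e-12
        assert np.allclose(np.diag(R), 1.0)
        # wildly inconsistent: rejected
        bad = GeneticCorrelation({("a", "b"): 0.95, ("a", "c"): 0.95,
                                  ("b", "c"): -0.95})
        with pytest.raises(ConfigError, match="not PSD"):
            bad.matrix(["a", "b", "c"])

    def test_uyt_preset_is_valid(self):
        cfg, corr = cassava_uyt_config(seed=0)
        R = corr.matrix([t.name for t in cfg.traits])
        assert np.linalg.eigvalsh(R).min() > 0
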