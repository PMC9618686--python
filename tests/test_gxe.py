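"""Two-way BLUE table construction and the FW / AMMI / GGE models."""

import numpy as np
import pandas as pd
import pytest

from metgxe.gxe import (AMMI, GGE, FinlayWilkinson, TwoWayTable,
                        complete_table, partition_tss, scale_table,
                        two_way_means)
from metgxe.pheno import PhenoTable
from metgxe.simulate import SimConfig, TraitSpec, simulate_met

from conftest import recovery_config


def random_table(seed=0, g=67, e=8, interaction=1.0):
    rng = np.random.default_rng(seed)
    X = (10 + rng.normal(0, 1.5, (g, 1)) + rng.normal(0, 2.0, (1, e))
         + rng.normal(0, interaction, (g, e)))
    return TwoWayTable(pd.DataFrame(X, index=[f"g{i:02d}" for i in range(g)],
                                    columns=[f"E{j}" for j in range(e)]))


def additive_table(g=10, e=6, seed=1):
    rng = np.random.default_rng(seed)
    X = 5 + rng.normal(0, 1, (g, 1)) + rng.normal(0, 2, (1, e)) + np.zeros((g, e))
    return TwoWayTable(pd.DataFrame(X, index=[f"g{i}" for i in range(g)],
                                    columns=[f"E{j}" for j in range(e)]))


class TestTwoWayMeans:
    def test_noiseless_additive_cells_exact(self, additive_met):
        table, truth = additive_met
        tw = two_way_means(table, "y")
        for gname in tw.genotypes[:10]:
            for ename in tw.environments:
                expect = (10.0 + truth.genetic_values.loc[gname, "y"]
                          + truth.env_effects.loc[ename, "y"])
                assert tw.data.loc[gname, ename] == pytest.approx(expect, abs=1e-8)

    def test_balanced_no_design_effects_equal_cell_means(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(6):
            for j in range(3):
                for k in (1, 2):
                    rows.append((f"g{i}", f"E{j}", k, "S1",
                                 rng.normal(10 + i - j, 1.0)))
        df = pd.DataFrame(rows, columns=["genotype", "environment", "rep",
                                         "set", "y"])
        tw = two_way_means(PhenoTable(df), "y")
        cell = df.pivot_table(index="genotype", columns="environment",
                              values="y", aggfunc="mean")
        assert np.allclose(tw.data.to_numpy(), cell.to_numpy(), atol=1e-8)

    def test_absent_genotype_gives_flagged_cell(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(5):
            for j in range(3):
                for k in (1, 2):
                    if i == 0 and j == 2:
                        continue
                    rows.append((f"g{i}", f"E{j}", k, "S1", rng.normal(10, 1)))
        df = pd.DataFrame(rows, columns=["genotype", "environment", "rep",
                                         "set", "y"])
        with pytest.warns(UserWarning, match="1 genotype-environment cell"):
            tw = two_way_means(PhenoTable(df), "y")
        assert tw.n_missing == 1
        assert np.isnan(tw.data.loc["g0", "E2"])


class TestCompleteTable:
    def test_identity_on_complete(self):
        t = random_table()
        out = complete_table(t)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_additive_oracle_imputation(self):
        t = additive_table()
        full = t.data.copy()
        t.data.iloc[0, 0] = np.nan
        t.data.iloc[3, 2] = np.nan
        t.data.iloc[7, 5] = np.nan
        out = complete_table(t)
        for i, j in [(0, 0), (3, 2), (7, 5)]:
            assert out.data.iloc[i, j] == pytest.approx(full.iloc[i, j], abs=1e-6)
            assert out.imputed.iloc[i, j]

    def test_whole_column_missing_is_error(self):
        t = additive_table()
        t.data.iloc[:, 1] = np.nan
        with pytest.raises(ValueError, match="whole genotype row or environment"):
            complete_table(t)

    def test_excess_missing_is_error(self):
        t = random_table(g=10, e=6)
        t.data.iloc[:5, :3] = np.nan
        with pytest.raises(ValueError, match="missing exceeds"):
            complete_table(t)


class TestScaleTable:
    def test_mean_zero_sd_one(self):
        s = scale_table(random_table())
        assert abs(np.mean(s.values)) < 1e-12
        assert np.std(s.values, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        s1 = scale_table(random_table())
        s2 = scale_table(s1)
        assert np.allclose(s1.values, s2.values, atol=1e-12)

    def test_zero_variance_rejected(self):
        t = TwoWayTable(pd.DataFrame(np.full((3, 3), 2.0)))
        with pytest.raises(ValueError, match="zero variance"):
            scale_table(t)

    def test_fw_slopes_invariant_msdev_rescaled(self):
        t = random_table(seed=3)
        raw = FinlayWilkinson(t).fit()
        sc = FinlayWilkinson(scale_table(t)).fit()
        assert np.allclose(raw.genotype_stats["sensitivity"],
                           sc.genotype_stats["sensitivity"], atol=1e-10)
        var = np.var(t.values, ddof=1)
        assert np.allclose(raw.genotype_stats["ms_deviation"] / var,
                           sc.genotype_stats["ms_deviation"], atol=1e-10)


class TestFinlayWilkinson:
    def test_average_genotype_has_unit_slope_zero_deviation(self):
        t = random_table(seed=4, g=12, e=6)
        # row 0 = mean of the other rows, hence exactly the column means
        t.data.iloc[0] = t.data.iloc[1:].mean(0)
        fw = FinlayWilkinson(t).fit()
        assert fw.genotype_stats["sensitivity"].iloc[0] == pytest.approx(1.0)
        assert fw.genotype_stats["ms_deviation"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_additive_null_slopes_one_msdev_zero(self):
        fw = FinlayWilkinson(additive_table()).fit()
        assert np.allclose(fw.genotype_stats["sensitivity"], 1.0, atol=1e-12)
        assert np.allclose(fw.genotype_stats["ms_deviation"], 0.0, atol=1e-12)

    def test_mean_slope_is_one(self):
        fw = FinlayWilkinson(random_table(seed=9)).fit()
        assert fw.genotype_stats["sensitivity"].mean() == pytest.approx(1.0)

    def test_interaction_ss_splits_into_sensitivity_plus_residual(self):
        t = random_table(seed=12)
        fw = FinlayWilkinson(t).fit()
        an = fw.anova.set_index("term")
        assert (an.loc["sensitivity", "ss"] + an.loc["residual", "ss"]
                == pytest.approx(t.interaction_ss(), rel=1e-10))

    def test_invariant_to_shift_and_positive_scale(self):
        t = random_table(seed=6)
        b0 = FinlayWilkinson(t).fit().genotype_stats["sensitivity"]
        shifted = TwoWayTable(t.data + 7.3)
        scaled = TwoWayTable(t.data * 2.6)
        assert np.allclose(FinlayWilkinson(shifted).fit()
                           .genotype_stats["sensitivity"], b0, atol=1e-10)
        assert np.allclose(FinlayWilkinson(scaled).fit()
                           .genotype_stats["sensitivity"], b0, atol=1e-10)

    def test_too_few_environments_rejected(self):
        t = TwoWayTable(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.raises(ValueError, match=">= 3 environments"):
            FinlayWilkinson(t)


class TestAMMI:
    def test_energy_conservation(self):
        t = random_table(seed=8)
        am = AMMI(t).fit()
        assert np.sum(am.singular_values ** 2) == pytest.approx(
            t.interaction_ss(), rel=1e-10)

    def test_rank_one_interaction_on_ipca1(self):
        t = additive_table(g=12, e=6)
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 6)
        a -= a.mean()
        b -= b.mean()
        t = TwoWayTable(t.data + np.outer(a, b))
        am = AMMI(t).fit()
        assert am.pct_interaction().iloc[0] == pytest.approx(100.0, abs=1e-8)

    def test_score_orthogonality(self):
        # symmetric scaling: scores are u * sqrt(lambda), so the Gram matrix
        # of the score vectors is diag(lambda) with zero off-diagonals
        am = AMMI(random_table(seed=10)).fit()
        G = am.genotype_scores.to_numpy()
        gram = G.T @ G
        lam = am.singular_values
        assert np.allclose(gram, np.diag(lam), atol=1e-8 * lam[0])

    def test_gollob_df_sum_to_interaction_df(self):
        g, e = 67, 8
        am = AMMI(random_table(seed=2, g=g, e=e)).fit()
        an = am.anova.set_index("term")
        ipca_df = an.loc[an.index.str.startswith("IPCA"), "df"].sum()
        assert ipca_df + an.loc["residual", "df"] == (g - 1) * (e - 1)

    def test_k_max_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            AMMI(random_table(g=10, e=4), k_max=9)

    def test_matches_fw_interaction_partition(self):
        t = random_table(seed=14)
        am = AMMI(t).fit()
        fw = FinlayWilkinson(t).fit()
        fa = fw.anova.set_index("term")
        assert am.interaction_ss == pytest.approx(
            fa.loc["sensitivity", "ss"] + fa.loc["residual", "ss"], rel=1e-10)
        # identical genotype and environment SS across the two models
        aa = am.anova.set_index("term")
        assert aa.loc["genotype", "ss"] == pytest.approx(fa.loc["genotype", "ss"])
        assert aa.loc["environment", "ss"] == pytest.approx(fa.loc["environment", "ss"])


class TestGGE:
    def test_null_g_plus_ge(self):
        e_eff = np.array([1.0, -2.0, 0.5, 0.5])
        X = np.tile(5 + e_eff, (6, 1))  # only environment effects
        gg = GGE(TwoWayTable(pd.DataFrame(X))).fit()
        assert np.allclose(gg.singular_values, 0.0, atol=1e-10)

    def test_energy_conservation(self):
        t = random_table(seed=5)
        gg = GGE(t).fit()
        X = t.values
        cc = X - X.mean(0, keepdims=True)
        assert np.sum(gg.singular_values ** 2) == pytest.approx(
            (cc ** 2).sum(), rel=1e-10)

    def test_gge_ss_equals_ammi_genotype_plus_interaction(self):
        t = random_table(seed=16)
        gg = GGE(t).fit()
        am = AMMI(t).fit()
        aa = am.anova.set_index("term")
        assert gg.gge_ss == pytest.approx(
            aa.loc["genotype", "ss"] + am.interaction_ss, rel=1e-10)

    def test_full_rank_reconstruction(self):
        t = random_table(seed=17, g=9, e=5)
        gg = GGE(t).fit()
        rec = gg.genotype_coords.to_numpy() @ gg.env_coords.to_numpy().T
        assert np.allclose(rec, gg.centered.to_numpy(), atol=1e-8)

    def test_winners_on_hull_with_crossover_gei(self):
        """With strong crossover interaction the per-environment winning
        genotype sits on the PC1-PC2 polygon hull for >= 90% of environments
        (brute-force argmax comparison)."""
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(23 + seed)
            g, e = 67, 8
            E = rng.normal(0, 2, e)
            slopes = 1 + rng.normal(0, 0.45, g)
            X = (20 + rng.normal(0, 1.0, (g, 1)) + E[None, :]
                 + np.outer(slopes - 1, E) + rng.normal(0, 0.35, (g, e)))
            gg = GGE(TwoWayTable(pd.DataFrame(
                X, index=[f"g{i:02d}" for i in range(g)],
                columns=[f"E{j}" for j in range(e)]))).fit()
            hits.extend(gg.which_won_where()["winner_on_hull"].tolist())
        assert np.mean(hits) >= 0.9


class TestPartitionTSS:
    @pytest.mark.parametrize("model", ["fw", "ammi", "gge"])
    def test_percentages_sum_to_100(self, model):
        t = random_table(seed=19)
        fit = {"fw": lambda: FinlayWilkinson(t).fit(),
               "ammi": lambda: AMMI(t).fit(),
               "gge": lambda: GGE(t).fit()}[model]()
        part = partition_tss(fit)
        assert part["pct_tss"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_additive_table_has_zero_interaction_share(self):
        t = additive_table()
        part = AMMI(t).fit().tss_partition().set_index("term")
        ipca = part.loc[part.index.str.startswith("IPCA"), "pct_tss"]
        assert np.allclose(ipca, 0.0, atol=1e-8)
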