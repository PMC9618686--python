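"""Genotype-by-environment interaction models on a two-way BLUE table.

The exchange object is :class:`TwoWayTable`, a genotype x environment matrix
of adjusted means (BLUEs) produced by :func:`two_way_means`, which fits
genotype as a fixed effect within each environment with replication and
row/column-within-set as random design terms.  Three classical GEI models
operate on the (completed, optionally scaled) table:

* :class:`FinlayWilkinson` — per-genotype regression on the environmental
  index (two-step estimator: index = environment mean deviation), reporting
  sensitivity slopes, mean-square deviations, and an ANOVA splitting the
  interaction into slope heterogeneity + residual;
* :class:`AMMI` — additive main effects plus SVD of the double-centred
  interaction, with interaction principal component axes (IPCAs), Gollob
  degrees of freedom, and symmetric score scaling;
* :class:`GGE` — SVD of the environment-centred table (genotype main effect
  + interaction together), symmetric-scaling biplot coordinates, environment
  vector angles and which-won-where hull membership.

All three partition the same total sum of squares; AMMI and FW report
identical genotype/environment/interaction SS, and the FW sensitivity +
residual SS equals the AMMI interaction SS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .pheno import ConfigError, PhenoTable
from .reml import VarianceComponentModel
from .mixed import build_design

__all__ = [
    "TwoWayTable",
    "two_way_means",
    "complete_table",
    "scale_table",
    "FinlayWilkinson",
    "AMMI",
    "GGE",
    "partition_tss",
]


class TwoWayTable:
    """Genotype x environment matrix of adjusted means.

    ``data`` rows are genotypes, columns environments.  ``imputed`` flags
    cells filled by :func:`complete_table`.
    """

    def __init__(self, data: pd.DataFrame, imputed: pd.DataFrame | None = None):
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("two-way table needs >= 2 genotypes and >= 2 environments")
        self.data = data.astype(float)
        self.imputed = (imputed.astype(bool) if imputed is not None
                        else pd.DataFrame(False, index=data.index, columns=data.columns))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def genotypes(self) -> list:
        return list(self.data.index)

    @property
    def environments(self) -> list:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def double_centered(self) -> np.ndarray:
        """Interaction residuals x_ij - rowmean_i - colmean_j + grand."""
        X = self.values
        return X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True) + X.mean()

    def interaction_ss(self) -> float:
        return float((self.double_centered() ** 2).sum())

    def copy(self) -> "TwoWayTable":
        return TwoWayTable(self.data.copy(), self.imputed.copy())


# ----------------------------------------------------------------------
def two_way_means(pheno: PhenoTable, trait: str) -> TwoWayTable:
    """Per-environment genotype BLUEs assembled into a two-way table.

    Within each environment, genotype enters as a fixed effect (full
    indicator coding, no intercept, so the coefficients are the adjusted
    genotype means) with replication, row-within-set and column-within-set
    as random terms where they have at least two levels.  Genotypes absent
    from an environment yield missing cells, which are counted and logged.
    """
    df = pheno.df if isinstance(pheno, PhenoTable) else pheno
    if trait not in df.columns:
        raise ConfigError(f"trait '{trait}' not in table")
    envs = sorted(df.loc[df[trait].notna(), "environment"].unique())
    if len(envs) < 2:
        raise ValueError(f"trait '{trait}' present in < 2 environments")
    genos = sorted(df["genotype"].unique())

    out = pd.DataFrame(np.nan, index=genos, columns=envs)
    for env in envs:
        sub = df[(df["environment"] == env) & df[trait].notna()].reset_index(drop=True)
        Zg = pd.get_dummies(pd.Categorical(sub["genotype"]), dtype=float)
        present = sorted(Zg.columns)
        X = Zg[present].to_numpy()
        random = []
        if sub["rep"].nunique() > 1:
            random.append("rep")
        if "row" in sub.columns and sub["row"].notna().all():
            if (sub["set"].astype(str) + ":" + sub["row"].astype(str)).nunique() > 1:
                random.append("row:set")
            if (sub["set"].astype(str) + ":" + sub["col"].astype(str)).nunique() > 1:
                random.append("col:set")
        if random:
            _, _, _, Z, lev, _ = build_design(sub, trait, fixed=("intercept",),
                                              random=tuple(random))
            core = VarianceComponentModel(sub[trait].to_numpy(dtype=float), X, Z,
                                          exog_names=present, vc_levels=lev)
            blues = core.fit(compute_se=False).fe_params
        else:
            beta, *_ = np.linalg.lstsq(X, sub[trait].to_numpy(dtype=float), rcond=None)
            blues = pd.Series(beta, index=present)
        out.loc[blues.index, env] = blues.to_numpy()

    n_miss = int(out.isna().sum().sum())
    if n_miss:
        warnings.warn(f"{n_miss} genotype-environment cell(s) missing in the "
                      f"two-way table for '{trait}'", UserWarning)
    return TwoWayTable(out)


def complete_table(t: TwoWayTable, max_missing_frac: float = 0.2,
                   tol: float = 1e-8, max_iter: int = 500) -> TwoWayTable:
    """Impute missing cells by iterated additive fit + rank-1 SVD residual.

    Missing cells start at their additive (row + column - grand) expectation
    and are refined with the leading multiplicative interaction term until
    the imputations change by less than ``tol``.  Refuses tables with a
    fully missing row/column or more than ``max_missing_frac`` missing.
    """
    if t.is_complete():
        return t.copy()
    X = t.values.copy()
    mask = np.isnan(X)
    if mask.all(0).any() or mask.all(1).any():
        raise ValueError("a whole genotype row or environment column is missing; "
                         "filter it out before completion")
    frac = mask.mean()
    if frac > max_missing_frac:
        raise ValueError(f"{frac:.0%} of cells missing exceeds "
                         f"{max_missing_frac:.0%}; filter genotypes/traits first")

    # additive fit by least squares on the observed cells only (unbalanced
    # two-way without interaction), so purely additive data are imputed
    # exactly and the multiplicative term never chases its own imputations
    g, e = X.shape
    obs = ~mask
    rows_i, cols_j = np.nonzero(obs)
    A = np.zeros((obs.sum(), 1 + (g - 1) + (e - 1)))
    A[:, 0] = 1.0
    for k, (i, j) in enumerate(zip(rows_i, cols_j)):
        if i > 0:
            A[k, i] = 1.0
        if j > 0:
            A[k, g - 1 + j] = 1.0
    beta, *_ = np.linalg.lstsq(A, X[obs], rcond=None)
    add = np.full((g, e), beta[0])
    add[1:, :] += beta[1:g][:, None]
    add[:, 1:] += beta[g:][None, :]

    # EM for the leading multiplicative term: missing residuals start at 0
    X[mask] = add[mask]
    for _ in range(max_iter):
        R = X - add
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        fill = add + s[0] * np.outer(U[:, 0], Vt[0])
        delta = np.max(np.abs(fill[mask] - X[mask]))
        X[mask] = fill[mask]
        if delta < tol:
            break

    data = pd.DataFrame(X, index=t.data.index, columns=t.data.columns)
    imputed = t.imputed | pd.DataFrame(mask, index=t.data.index,
                                       columns=t.data.columns)
    return TwoWayTable(data, imputed)


def scale_table(t: TwoWayTable) -> TwoWayTable:
    """Standardise the whole table to mean 0, SD 1 over all cells.

    This is the pre-processing used before Finlay-Wilkinson regression so
    that sensitivities and MS deviations are comparable across traits on
    different scales.  SDs use ddof=1.  A zero-variance table is an error.
    """
    X = t.values
    mu = np.nanmean(X)
    sd = np.nanstd(X, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("table has zero variance; cannot scale")
    return TwoWayTable((t.data - mu) / sd, t.imputed.copy())


# ----------------------------------------------------------------------
def _require_complete(t: TwoWayTable, who: str):
    if not t.is_complete():
        raise ValueError(f"{who} requires a complete table; "
                         f"run complete_table() first ({t.n_missing} missing)")


def _fix_svd_signs(U, s, Vt):
    """Deterministic SVD orientation: dominant genotype loading positive."""
    for k in range(len(s)):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1
            Vt[k, :] *= -1
    return U, Vt


def _warn_degenerate(s):
    s = np.asarray(s)
    if len(s) > 1 and s[0] > 0:
        tied = (np.abs(np.diff(s)) <= 1e-9 * s[0]) & (s[1:] > 1e-6 * s[0])
        if tied.any():
            warnings.warn("nearly equal singular values: component scores are "
                          "rotation-indeterminate within the tied subspace",
                          UserWarning)


class FinlayWilkinson:
    """Finlay-Wilkinson joint regression on a complete two-way table."""

    def __init__(self, table: TwoWayTable):
        _require_complete(table, "Finlay-Wilkinson")
        if table.data.shape[1] < 3:
            raise ValueError("Finlay-Wilkinson slopes need >= 3 environments")
        self.table = table

    def fit(self) -> "FWResults":
        X = self.table.values
        g, e = X.shape
        grand = X.mean()
        gmean = X.mean(1)
        env_index = X.mean(0) - grand          # environmental index E_j
        Se = float((env_index ** 2).sum())

        centered = X - gmean[:, None]
        slopes = centered @ env_index / Se      # b_i, ~1 for average response
        fitted = gmean[:, None] + np.outer(slopes, env_index)
        resid = X - fitted
        rss = (resid ** 2).sum(1)
        msdev = rss / (e - 2)

        ss_gen = e * float(((gmean - grand) ** 2).sum())
        ss_env = g * Se
        ss_sens = float(((slopes - 1.0) ** 2).sum()) * Se
        ss_resid = float(rss.sum())
        ss_int = self.table.interaction_ss()
        tss = float(((X - grand) ** 2).sum())

        df_g, df_e, df_s = g - 1, e - 1, g - 1
        df_r = (g - 1) * (e - 2)
        anova = _anova_frame(
            [("genotype", df_g, ss_gen), ("environment", df_e, ss_env),
             ("sensitivity", df_s, ss_sens), ("residual", df_r, ss_resid)],
            resid_term="residual",
        )
        stats_df = pd.DataFrame({
            "mean": X.mean(1), "sensitivity": slopes, "ms_deviation": msdev,
        }, index=self.table.data.index)
        return FWResults(self, grand, pd.Series(env_index, index=self.table.data.columns),
                         stats_df, anova, tss, ss_int)


class FWResults:
    """FW fit: per-genotype sensitivities and the joint-regression ANOVA."""

    def __init__(self, model, grand_mean, env_index, genotype_stats, anova,
                 tss, interaction_ss):
        self.model = model
        self.grand_mean = grand_mean
        self.env_index = env_index
        self.genotype_stats = genotype_stats
        self.anova = anova
        self.tss = tss
        self.interaction_ss = interaction_ss

    @property
    def slope_variance(self) -> float:
        return float(self.genotype_stats["sensitivity"].var(ddof=1))

    @property
    def slope_median(self) -> float:
        return float(self.genotype_stats["sensitivity"].median())

    @property
    def msdev_variance(self) -> float:
        return float(self.genotype_stats["ms_deviation"].var(ddof=1))

    @property
    def msdev_median(self) -> float:
        return float(self.genotype_stats["ms_deviation"].median())

    def tss_partition(self) -> pd.DataFrame:
        return _partition(self.anova, self.tss)


def _anova_frame(rows, resid_term):
    df = pd.DataFrame(rows, columns=["term", "df", "ss"])
    df["ms"] = df["ss"] / df["df"].replace(0, np.nan)
    ms_r = df.loc[df["term"] == resid_term, "ms"].iloc[0]
    df_r = df.loc[df["term"] == resid_term, "df"].iloc[0]
    F, p = [], []
    for _, r in df.iterrows():
        if r["term"] == resid_term or not np.isfinite(ms_r) or ms_r <= 0 or df_r <= 0:
            F.append(np.nan)
            p.append(np.nan)
        else:
            f = r["ms"] / ms_r
            F.append(f)
            p.append(stats.f.sf(f, r["df"], df_r))
    df["F"] = F
    df["pvalue"] = p
    return df


def _partition(anova, tss):
    out = anova[["term", "ss"]].copy()
    out["pct_tss"] = 100.0 * out["ss"] / tss
    return out


# ----------------------------------------------------------------------
class AMMI:
    """Additive main effects and multiplicative interaction model.

    The double-centred interaction is decomposed by SVD into IPCAs; scores
    use the symmetric convention (both modes scaled by sqrt of the singular
    value).  IPCA significance uses Gollob degrees of freedom
    ``(g-1) + (e-1) - (2k-1)`` and is approximate.
    """

    def __init__(self, table: TwoWayTable, k_max: int | None = None):
        _require_complete(table, "AMMI")
        self.table = table
        g, e = table.data.shape
        k_full = min(g, e) - 1
        if k_max is None:
            k_max = k_full
        elif k_max > k_full:
            warnings.warn(f"k_max={k_max} exceeds interaction rank {k_full}; "
                          "truncated", UserWarning)
            k_max = k_full
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        self.k_max = k_max

    def fit(self) -> "AMMIResults":
        X = self.table.values
        g, e = X.shape
        grand = X.mean()
        geff = X.mean(1) - grand
        eeff = X.mean(0) - grand
        Z = X - grand - geff[:, None] - eeff[None, :]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        k_full = min(g, e) - 1
        U, s, Vt = U[:, :k_full], s[:k_full], Vt[:k_full]
        U, Vt = _fix_svd_signs(U, s, Vt)
        _warn_degenerate(s)

        rs = np.sqrt(s)
        gscores = pd.DataFrame(U * rs, index=self.table.data.index,
                               columns=[f"IPCA{k+1}" for k in range(k_full)])
        escores = pd.DataFrame(Vt.T * rs, index=self.table.data.columns,
                               columns=gscores.columns)

        ss_gen = e * float((geff ** 2).sum())
        ss_env = g * float((eeff ** 2).sum())
        ss_int = float((Z ** 2).sum())
        lam2 = s ** 2
        tss = float(((X - grand) ** 2).sum())

        rows = [("genotype", g - 1, ss_gen), ("environment", e - 1, ss_env)]
        used_df = 0
        for k in range(self.k_max):
            dfk = (g - 1) + (e - 1) - (2 * (k + 1) - 1)
            rows.append((f"IPCA{k+1}", dfk, float(lam2[k])))
            used_df += dfk
        resid_ss = float(lam2[self.k_max:].sum())
        resid_df = (g - 1) * (e - 1) - used_df
        rows.append(("residual", resid_df, resid_ss))
        anova = _anova_frame(rows, resid_term="residual")
        return AMMIResults(self, grand,
                           pd.Series(geff, index=self.table.data.index),
                           pd.Series(eeff, index=self.table.data.columns),
                           s, gscores, escores, anova, tss, ss_int)


class AMMIResults:
    def __init__(self, model, grand_mean, genotype_effects, env_effects,
                 singular_values, genotype_scores, env_scores, anova, tss,
                 interaction_ss):
        self.model = model
        self.grand_mean = grand_mean
        self.genotype_effects = genotype_effects
        self.env_effects = env_effects
        self.singular_values = singular_values
        self.genotype_scores = genotype_scores
        self.env_scores = env_scores
        self.anova = anova
        self.tss = tss
        self.interaction_ss = interaction_ss

    def pct_interaction(self) -> pd.Series:
        """Percent of interaction SS captured by each IPCA."""
        lam2 = self.singular_values ** 2
        return pd.Series(100.0 * lam2 / lam2.sum(),
                         index=self.genotype_scores.columns)

    def tss_partition(self) -> pd.DataFrame:
        return _partition(self.anova, self.tss)


# ----------------------------------------------------------------------
class GGE:
    """Genotype main effect + GEI model (environment-centred SVD)."""

    def __init__(self, table: TwoWayTable):
        _require_complete(table, "GGE")
        self.table = table

    def fit(self) -> "GGEResults":
        X = self.table.values
        g, e = X.shape
        grand = X.mean()
        colm = X.mean(0)
        centered = X - colm[None, :]
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        k = min(g - 1, e)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        U, Vt = _fix_svd_signs(U, s, Vt)
        _warn_degenerate(s)

        rs = np.sqrt(s)
        cols = [f"PC{j+1}" for j in range(k)]
        gcoord = pd.DataFrame(U * rs, index=self.table.data.index, columns=cols)
        ecoord = pd.DataFrame(Vt.T * rs, index=self.table.data.columns, columns=cols)

        lam2 = s ** 2
        ss_gge = float(lam2.sum())
        ss_env = g * float(((colm - grand) ** 2).sum())
        tss = ss_env + ss_gge  # == sum((X - grand)^2)
        return GGEResults(self, grand, s, gcoord, ecoord, ss_env, ss_gge, tss,
                          pd.DataFrame(centered, index=self.table.data.index,
                                       columns=self.table.data.columns))


class GGEResults:
    def __init__(self, model, grand_mean, singular_values, genotype_coords,
                 env_coords, env_ss, gge_ss, tss, centered):
        self.model = model
        self.grand_mean = grand_mean
        self.singular_values = singular_values
        self.genotype_coords = genotype_coords
        self.env_coords = env_coords
        self.env_ss = env_ss
        self.gge_ss = gge_ss
        self.tss = tss
        self.centered = centered

    @property
    def pct_gge(self) -> pd.Series:
        """Percent of G+GE sum of squares captured by each PC."""
        lam2 = self.singular_values ** 2
        return pd.Series(100.0 * lam2 / lam2.sum(), index=self.genotype_coords.columns)

    def env_cosines(self) -> pd.DataFrame:
        """Cosine of angles between environment vectors in the PC1-PC2 plane.

        Environments with small angles rank genotypes similarly; this is the
        environment-correlation reading of the biplot vector view.
        """
        V = self.env_coords[["PC1", "PC2"]].to_numpy()
        norm = np.linalg.norm(V, axis=1, keepdims=True)
        C = (V / norm) @ (V / norm).T
        return pd.DataFrame(C, index=self.env_coords.index, columns=self.env_coords.index)

    def which_won_where(self) -> pd.DataFrame:
        """Per environment: the winning genotype and its PC1-PC2 hull status."""
        tab = self.model.table.data
        winners = tab.idxmax(0)
        pts = self.genotype_coords[["PC1", "PC2"]].to_numpy()
        try:
            hull = set(np.asarray(ConvexHull(pts).vertices).tolist())
        except QhullError:  # degenerate (collinear) score cloud
            hull = set(range(len(pts)))
        gidx = {g: i for i, g in enumerate(self.genotype_coords.index)}
        return pd.DataFrame({
            "environment": tab.columns,
            "winner": winners.to_numpy(),
            "winner_on_hull": [gidx[w] in hull for w in winners],
        })

    def tss_partition(self) -> pd.DataFrame:
        lam2 = self.singular_values ** 2
        rows = [("environment", self.env_ss),
                ("PC1", float(lam2[0])),
                ("PC2", float(lam2[1]) if len(lam2) > 1 else 0.0),
                ("residual", float(lam2[2:].sum()))]
        out = pd.DataFrame(rows, columns=["term", "ss"])
        out["pct_tss"] = 100.0 * out["ss"] / self.tss
        return out


def partition_tss(fit) -> pd.DataFrame:
    """Percent of total sum of squares per model term (sums to 100)."""
    if hasattr(fit, "tss_partition"):
        return fit.tss_partition()
    raise TypeError(f"no TSS partition for {type(fit).__name__}")
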