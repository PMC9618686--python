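"""Random-genotype mixed-model analysis of a multi-environment trial.

:class:`METMixedModel` fits, by REML, the across-environment model with
genotype, environment, replication-within-environment and genotype-by-
environment interaction as random effects, and trial-design covariates (row
and column trends nested within trial set and environment) as fixed effects.
Its :class:`METResults` expose variance components with one-sided z-tests,
percent variance explained, genotype BLUPs with prediction-error variances
and reliabilities, deregressed BLUPs, and both broad-sense heritability
estimators:

* ``H2_standard = s2g / (s2g + s2ge/e + s2e/(e*r))`` on an entry-mean basis,
  with ``e`` environments and ``r`` replicates per environment;
* ``H2_Cullis = 1 - vbar_delta / (2 s2g)`` where ``vbar_delta`` is the mean
  variance of pairwise BLUP differences, read off the inverse mixed-model
  equations (robust to unbalancedness).

Row/column positions enter as standardised linear trends nested within
set-by-environment rather than as factors: the cross-environment factor
coding is not identifiable in general and the within-trial spatial signal is
a smooth trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pheno import ConfigError, PhenoTable
from .reml import VarianceComponentModel, VCResults, ConvergenceError

__all__ = [
    "ModelSpec",
    "METMixedModel",
    "METResults",
    "build_design",
    "h2_standard",
    "h2_cullis",
    "deregress",
    "per_trial_h2",
]

DEFAULT_FIXED = ("intercept", "row_trend", "col_trend")
DEFAULT_RANDOM = ("genotype", "environment", "rep:environment", "genotype:environment")


@dataclass
class ModelSpec:
    """Terms of the mixed model for one response trait."""

    response: str
    fixed: tuple = DEFAULT_FIXED
    random: tuple = DEFAULT_RANDOM

    def __post_init__(self):
        both = set(self.fixed) & set(self.random)
        if both:
            raise ConfigError(f"terms in both fixed and random: {sorted(both)}")


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(labels.astype(str))
    cats = sorted(cat.categories)
    cat = cat.reorder_categories(cats)
    Z = pd.get_dummies(cat, dtype=float).to_numpy()
    return Z, cats


def _nested_trend(sub: pd.DataFrame, var: str) -> tuple[np.ndarray, list]:
    """Standardised linear trend of `var`, one column per (environment, set)."""
    cols, names = [], []
    for (env, s), idx in sorted(sub.groupby(["environment", "set"]).groups.items()):
        x = sub.loc[idx, var].to_numpy(dtype=float)
        sd = np.std(x)
        if sd == 0 or np.isnan(sd):
            continue
        col = np.zeros(len(sub))
        col[sub.index.get_indexer(idx)] = (x - x.mean()) / sd
        cols.append(col)
        names.append(f"{var}@{env}/{s}")
    if not cols:
        return np.empty((len(sub), 0)), []
    return np.column_stack(cols), names


def build_design(df: pd.DataFrame, response: str, fixed=DEFAULT_FIXED,
                 random=DEFAULT_RANDOM):
    """Build (y, X, X names, Z dict, level dict) for one response trait.

    Rows with a missing response are dropped (explicitly, never silently:
    the count is available from the returned index length).
    """
    if response not in df.columns:
        raise ConfigError(f"response trait '{response}' not in table")
    sub = df[df[response].notna()].reset_index(drop=True)
    if not len(sub):
        raise ValueError(f"no non-missing observations for '{response}'")
    y = sub[response].to_numpy(dtype=float)

    X_parts, X_names = [], []
    for term in fixed:
        if term == "intercept":
            X_parts.append(np.ones((len(sub), 1)))
            X_names.append("intercept")
        elif term in ("row_trend", "col_trend"):
            var = "row" if term == "row_trend" else "col"
            if var not in sub.columns:
                continue
            Xt, names = _nested_trend(sub, var)
            X_parts.append(Xt)
            X_names.extend(names)
        elif term in sub.columns and pd.api.types.is_numeric_dtype(sub[term]):
            X_parts.append(sub[term].to_numpy(dtype=float)[:, None])
            X_names.append(term)
        else:
            raise ConfigError(f"unknown fixed term '{term}'")
    X = np.hstack(X_parts)

    Z, levels = {}, {}
    for term in random:
        if term == "genotype":
            lab = sub["genotype"]
        elif term == "environment":
            lab = sub["environment"]
        elif term == "rep":
            lab = "rep" + sub["rep"].astype(str)
        elif term == "rep:environment":
            lab = sub["environment"] + ":rep" + sub["rep"].astype(str)
        elif term == "genotype:environment":
            lab = sub["genotype"] + ":" + sub["environment"]
        elif term == "row:set":
            lab = sub["set"] + ":row" + sub["row"].astype(int).astype(str)
        elif term == "col:set":
            lab = sub["set"] + ":col" + sub["col"].astype(int).astype(str)
        else:
            raise ConfigError(f"unknown random term '{term}'")
        Z[term], levels[term] = _dummies(lab)
    return y, X, X_names, Z, levels, sub


# ----------------------------------------------------------------------
def h2_standard(var_g: float, var_ge: float, var_e: float,
                e: int, r: int) -> float:
    """Entry-mean broad-sense heritability.

    ``H2 = s2g / (s2g + s2ge/e + s2e/(e*r))`` with ``e`` environments and
    ``r`` replicates per environment.  Returns NaN (with a warning) when all
    components are zero.
    """
    if e < 1 or r < 1:
        raise ValueError("e and r must be >= 1")
    denom = var_g + var_ge / e + var_e / (e * r)
    if denom == 0:
        warnings.warn("all variance components are zero; H2 undefined", UserWarning)
        return np.nan
    return var_g / denom


def h2_cullis(var_g: float, vbar_delta: float) -> float:
    """Cullis heritability ``1 - vbar_delta / (2 s2g)``.

    ``vbar_delta`` is the mean variance of a difference between two genotype
    BLUPs.  Returns NaN with a warning when the genetic variance is zero.
    """
    if var_g <= 0:
        warnings.warn("genetic variance is zero; H2_Cullis undefined", UserWarning)
        return np.nan
    return 1.0 - vbar_delta / (2.0 * var_g)


def deregress(predictions: pd.DataFrame, var_g: float,
              reliability_floor: float = 0.1) -> pd.DataFrame:
    """Deregress genotype BLUPs: ``DRBLUP = BLUP / reliability``.

    ``reliability = 1 - PEV / s2g``.  Genotypes at or below the reliability
    floor get a missing DRBLUP (their count is reported via a warning); the
    sign of the BLUP is preserved and |DRBLUP| >= |BLUP| always.
    """
    if var_g <= 0:
        raise ValueError("var_g must be > 0 to deregress")
    out = predictions.copy()
    out["reliability"] = 1.0 - out["pev"] / var_g
    ok = out["reliability"] > reliability_floor
    out["drblup"] = np.where(ok, out["blup"] / out["reliability"], np.nan)
    n_floor = int((~ok).sum())
    if n_floor:
        warnings.warn(f"{n_floor} genotype(s) at reliability <= "
                      f"{reliability_floor}; DRBLUP set missing", UserWarning)
    return out


# ----------------------------------------------------------------------
class METMixedModel:
    """Across-environment random-genotype mixed model for one trait."""

    def __init__(self, pheno: PhenoTable | pd.DataFrame, response: str,
                 fixed=DEFAULT_FIXED, random=DEFAULT_RANDOM):
        df = pheno.df if isinstance(pheno, PhenoTable) else pheno
        self.spec = ModelSpec(response, tuple(fixed), tuple(random))
        y, X, xn, Z, lev, sub = build_design(df, response, fixed, random)
        self.data = sub
        if "genotype" in Z:
            n_geno = Z["genotype"].shape[1]
            if len(y) < n_geno:
                raise ValueError("fewer observations than genotypes")
        self._core = VarianceComponentModel(y, X, Z, exog_names=xn, vc_levels=lev)

    @classmethod
    def from_pheno(cls, pheno, trait, spec: ModelSpec | None = None):
        if spec is None:
            return cls(pheno, trait)
        return cls(pheno, spec.response, spec.fixed, spec.random)

    def fit(self, **kwargs) -> "METResults":
        return METResults(self, self._core.fit(**kwargs))


class METResults:
    """Results wrapper: variance components, BLUPs, heritabilities."""

    def __init__(self, model: METMixedModel, vcres: VCResults):
        self.model = model
        self.vc = vcres
        self.converged = vcres.converged
        self.llf = vcres.llf
        self.n_iter = vcres.n_iter

    @property
    def params(self) -> dict:
        return dict(self.vc.params)

    @property
    def varcomp(self) -> pd.DataFrame:
        return self.vc.varcomp_frame()

    @property
    def pct_explained(self) -> pd.Series:
        return self.vc.pct_explained

    # ------------------------------------------------------------------
    @property
    def n_environments(self) -> int:
        return self.model.data["environment"].nunique()

    @property
    def n_reps(self) -> int:
        counts = self.model.data.groupby(
            ["genotype", "environment", "set"], observed=True
        ).size()
        return int(round(float(counts.median())))

    def predictions(self, reliability_floor: float = 0.1) -> pd.DataFrame:
        """Per-genotype BLUP, PEV, reliability and deregressed BLUP."""
        pred = self.vc.ranef("genotype").copy()
        pred.index.name = "genotype"
        var_g = self.params.get("genotype", 0.0)
        if var_g <= 0:
            pred["reliability"] = np.nan
            pred["drblup"] = np.nan
            return pred
        return deregress(pred, var_g, reliability_floor)

    def h2_standard(self, e: int | None = None, r: int | None = None) -> float:
        return h2_standard(
            self.params.get("genotype", 0.0),
            self.params.get("genotype:environment", 0.0),
            self.params.get("residual", 0.0),
            e if e is not None else self.n_environments,
            r if r is not None else self.n_reps,
        )

    def h2_cullis(self, method: str = "exact") -> float:
        var_g = self.params.get("genotype", 0.0)
        if var_g <= 0:
            warnings.warn("genetic variance pinned at zero; H2_Cullis undefined",
                          UserWarning)
            return np.nan
        return h2_cullis(var_g, self.vc.vbar_delta("genotype", method=method))

    def summary(self) -> str:
        lines = [self.vc.summary(), ""]
        h2s = self.h2_standard()
        h2c = self.h2_cullis() if self.params.get("genotype", 0) > 0 else np.nan
        lines.append(f"H2_standard = {h2s:.4f}  (e={self.n_environments}, "
                     f"r={self.n_reps})")
        if np.isfinite(h2c):
            lines.append(f"H2_Cullis   = {h2c:.4f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
def per_trial_h2(pheno: PhenoTable, trait: str,
                 fixed=("intercept", "row_trend", "col_trend"),
                 random=("genotype", "rep")) -> pd.DataFrame:
    """Within-trial Cullis heritability, one row per environment.

    Fits a genotype-random model with replication random and row/column
    trends fixed inside each environment.  Environments whose fit fails to
    converge (or lacks replication) are reported with missing values rather
    than raised.
    """
    df = pheno.df if isinstance(pheno, PhenoTable) else pheno
    rows = []
    for env in sorted(df["environment"].unique()):
        sub = df[df["environment"] == env]
        h2 = var_g = np.nan
        ok = False
        try:
            res = METMixedModel(sub, trait, fixed=fixed, random=random).fit(
                compute_se=False)
            var_g = res.params.get("genotype", 0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h2 = res.h2_cullis()
            ok = res.converged
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            pass
        rows.append((env, h2, var_g, ok))
    return pd.DataFrame(rows, columns=["environment", "h2_cullis",
                                       "var_g", "converged"])
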