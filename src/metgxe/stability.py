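"""Stability indices and the above-mean + stable selection rule.

Two complementary measures over the unscaled genotype x environment table:

* Wricke's ecovalence ``Wi`` — a genotype's contribution to the interaction
  sum of squares, the row sum of squared double-centred residuals
  ``sum_j (x_ij - rowmean_i - colmean_j + grand)^2``.  A *static* measure:
  low Wi (near 0) means the genotype tracks the environmental mean.  The
  ecovalences sum exactly to the interaction SS.
* Geometric adaptability index ``GAI`` — the geometric mean of a genotype's
  performance across environments, ``(prod_j x_ij)^(1/E)``; a *dynamic*
  adaptability measure, high GAI desired.  Defined only for all-positive
  rows (computed in log space); by AM-GM it never exceeds the arithmetic
  row mean.

Both operate on original trait units — GAI is meaningless on mean-centred
or standardised data, so only the Finlay-Wilkinson model consumes the scaled
table, never the stability indices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gxe import TwoWayTable, _require_complete

__all__ = ["wricke", "gai", "stability_table", "rank_and_select"]


def wricke(t: TwoWayTable) -> pd.DataFrame:
    """Wricke's ecovalence per genotype (``Wi`` column, plus % of GEI SS)."""
    _require_complete(t, "Wricke ecovalence")
    D = t.double_centered()
    wi = (D ** 2).sum(1)
    ss_int = wi.sum()
    return pd.DataFrame({
        "mean": t.values.mean(1),
        "Wi": wi,
        "Wi_pct_gei": 100.0 * wi / ss_int if ss_int > 0 else 0.0,
    }, index=t.data.index)


def gai(t: TwoWayTable) -> pd.DataFrame:
    """Geometric adaptability index per genotype (log-space product)."""
    _require_complete(t, "GAI")
    X = t.values
    ok = (X > 0).all(1)
    vals = np.full(len(X), np.nan)
    with np.errstate(invalid="ignore"):
        vals[ok] = np.exp(np.log(X[ok]).mean(1))
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} genotype(s) with non-positive cells; "
                      "GAI set missing", UserWarning)
    return pd.DataFrame({"mean": X.mean(1), "GAI": vals}, index=t.data.index)


def _rank(values: pd.Series, ascending: bool) -> pd.Series:
    """Dense 1..n ranking; ties (and NaN, ranked last) broken by label."""
    df = pd.DataFrame({"v": values})
    df["nan"] = df["v"].isna()
    df["key"] = df["v"] if ascending else -df["v"]
    df["label"] = df.index.astype(str)
    order = df.sort_values(["nan", "key", "label"], kind="mergesort").index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.reindex(values.index)


def stability_table(t: TwoWayTable) -> pd.DataFrame:
    """Combined stability table: mean, Wi (+rank), GAI (+rank) per genotype.

    ``Wi_rank`` ascends (1 = most stable); ``GAI_rank`` descends (1 = best
    adaptability).  Ranks are a permutation of 1..n with label tie-breaks.
    """
    w = wricke(t)
    g = gai(t)
    out = pd.DataFrame({
        "mean": w["mean"],
        "Wi": w["Wi"],
        "Wi_pct_gei": w["Wi_pct_gei"],
        "GAI": g["GAI"],
    }, index=t.data.index)
    out["Wi_rank"] = _rank(out["Wi"], ascending=True)
    out["GAI_rank"] = _rank(out["GAI"], ascending=False)
    out.index.name = "genotype"
    return out


def rank_and_select(s: pd.DataFrame, rule: str = "gai_top_k", k: int = 5,
                    above_mean: bool = True) -> pd.DataFrame:
    """Apply the top-k selection rule, optionally requiring above-mean yield.

    ``rule`` is ``"wi_top_k"`` (most stable) or ``"gai_top_k"`` (best
    adaptability).  Selection candidates must simultaneously be stable/
    adapted and above the population mean when ``above_mean`` is set.  The
    overlap between the Wi and GAI top-k sets is stored in
    ``result.attrs["topk_overlap"]``.
    """
    if rule not in ("wi_top_k", "gai_top_k"):
        raise ValueError(f"unknown selection rule '{rule}'")
    col = "Wi_rank" if rule == "wi_top_k" else "GAI_rank"
    if col not in s.columns:
        raise ValueError(f"column '{col}' missing; run stability_table first")
    out = s.copy()
    n = len(out)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} genotypes; clamped", UserWarning)
        k = n
    out["selected"] = out[col] <= k
    if above_mean:
        out["selected"] &= out["mean"] > out["mean"].mean()

    wi_top = set(out.index[out["Wi_rank"] <= k]) if "Wi_rank" in out else set()
    gai_top = set(out.index[out["GAI_rank"] <= k]) if "GAI_rank" in out else set()
    out.attrs["topk_overlap"] = sorted(wi_top & gai_top)
    return out
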