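"""Cross-trait correlation of deregressed BLUPs and the full pipeline runner.

:func:`run_pipeline` chains the whole analysis — simulate or ingest, derive
processed-product traits, fit the random-genotype mixed model per trait,
heritabilities, deregressed BLUPs, cross-trait correlations, per-environment
BLUEs, Finlay-Wilkinson / AMMI / GGE, and stability indices — into one
reproducible run that writes CSV tables, a Markdown summary, and a manifest
(config hash, seed, input digests, stage timings).  Reruns with the same
config and seed produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pheno import ConfigError, PhenoTable, derive_traits, read_pheno, write_table
from .simulate import cassava_uyt_config, simulate_met
from .mixed import METMixedModel, per_trial_h2
from .gxe import (AMMI, GGE, FinlayWilkinson, complete_table, scale_table,
                  two_way_means)
from .stability import rank_and_select, stability_table

__all__ = ["correlate_drblups", "run_pipeline", "PipelineError", "CorrMatrix"]

logger = logging.getLogger("metgxe")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


class CorrMatrix:
    """Pairwise-complete Pearson correlations of deregressed BLUPs.

    Attributes ``r``, ``n``, ``t``, ``p`` and ``p_bonferroni`` are trait x
    trait DataFrames; p-values are two-sided from the t distribution with
    n - 2 degrees of freedom, uncorrected (a Bonferroni column is provided
    separately).  Pairs with fewer than ``min_n`` common genotypes are
    reported missing.
    """

    def __init__(self, r, n, t, p, p_bonf):
        self.r, self.n, self.t, self.p, self.p_bonferroni = r, n, t, p, p_bonf

    def to_frame(self) -> pd.DataFrame:
        rows = []
        traits = list(self.r.index)
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                rows.append((a, b, self.r.loc[a, b], int(self.n.loc[a, b]),
                             self.t.loc[a, b], self.p.loc[a, b],
                             self.p_bonferroni.loc[a, b]))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "n",
                                           "t", "pvalue", "pvalue_bonferroni"])


def correlate_drblups(drblups: dict[str, pd.Series], min_n: int = 3) -> CorrMatrix:
    """Pairwise-complete Pearson correlation across traits' DRBLUPs."""
    traits = list(drblups)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    t = pd.DataFrame(np.nan, index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    for i, a in enumerate(traits):
        n.loc[a, a] = int(drblups[a].notna().sum())
        for b in traits[i + 1:]:
            xa, xb = drblups[a].align(drblups[b], join="inner")
            ok = xa.notna() & xb.notna()
            m = int(ok.sum())
            n.loc[a, b] = n.loc[b, a] = m
            if m < min_n:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rr = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
            r.loc[a, b] = r.loc[b, a] = rr
            if abs(rr) < 1.0:
                tt = rr * np.sqrt((m - 2) / (1 - rr ** 2))
            else:
                tt = np.inf * np.sign(rr)
            from scipy import stats as _st
            pp = 2 * _st.t.sf(abs(tt), m - 2)
            t.loc[a, b] = t.loc[b, a] = tt
            p.loc[a, b] = p.loc[b, a] = pp
    n_tests = k * (k - 1) / 2
    p_bonf = (p * n_tests).clip(upper=1.0)
    return CorrMatrix(r, n, t, p, p_bonf)


# ----------------------------------------------------------------------
_KNOWN_KEYS = {"seed", "simulate", "input", "traits", "derive", "spacing_m2",
               "net_plot_plants", "gxe_models", "stability", "deregress"}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if ("simulate" in config) == ("input" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'input'")
    return config


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df, path):
    write_table(df.reset_index() if df.index.name else df, path)


def run_pipeline(config, out_dir) -> dict:
    """Run the full MET analysis; returns the manifest dictionary.

    ``config`` is a YAML path or dict.  Outputs (CSV tables, ``summary.md``,
    ``manifest.json``) are written under ``out_dir``; any stage error raises
    :class:`PipelineError` naming the stage, leaving prior outputs intact.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "software_version": __version__,
        "input_digests": {},
        "timings_s": {},
        "warnings": [],
        "outputs": [],
    }
    caught: list[str] = []

    def stage(name):
        class _Stage:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s", name)
                self_.wctx = warnings.catch_warnings(record=True)
                self_.wlist = self_.wctx.__enter__()
                warnings.simplefilter("always")
                return self_

            def __exit__(self_, exc_type, exc, tb):
                self_.wctx.__exit__(None, None, None)
                for w in self_.wlist:
                    caught.append(f"{name}: {w.message}")
                manifest["timings_s"][name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False
        return _Stage()

    # ---------------- ingest or simulate -------------------------------
    with stage("ingest"):
        if "simulate" in cfg:
            sim = dict(cfg["simulate"] or {})
            preset = sim.pop("preset", "cassava_uyt")
            if preset != "cassava_uyt":
                raise ConfigError(f"unknown simulation preset '{preset}'")
            simcfg, corr = cassava_uyt_config(seed=seed, **sim)
            available = {t.name for t in simcfg.traits} | {
                "DYLD", "gari_yield", "fufu_yield"}
            _check_traits(cfg, available)
            pheno, truth = simulate_met(simcfg, corr)
            truth.to_json(out / "truth.json")
        else:
            inp = cfg["input"]
            pheno = read_pheno(inp["pheno"], dialect=inp.get("dialect"))
            truth = None
            manifest["input_digests"][str(inp["pheno"])] = _hash_file(inp["pheno"])
            _check_traits(cfg, set(pheno.traits) | set(
                ("FYLD", "DYLD", "gari_pct", "fufu_pct", "peel_loss_pct",
                 "fiber_pct", "gari_yield", "fufu_yield")))

    with stage("derive"):
        if cfg.get("derive", True):
            pheno = derive_traits(pheno, spacing_m2=cfg.get("spacing_m2", 0.8),
                                  net_plot_plants=cfg.get("net_plot_plants", 20))
        write_table(pheno, out / "pheno.csv")
        traits = cfg.get("traits") or pheno.traits
        missing = [t for t in traits if t not in pheno.traits]
        if missing:
            raise ConfigError(f"traits not present after derivation: {missing}")

    # ---------------- mixed models per trait ---------------------------
    results, h2_rows, drblups = {}, [], {}
    floor = float((cfg.get("deregress") or {}).get("reliability_floor", 0.1))
    with stage("mixed_model"):
        for trait in traits:
            res = METMixedModel(pheno, trait).fit()
            results[trait] = res
            vc = res.varcomp
            vc.insert(0, "trait", trait)
            _write(vc, out / f"varcomp_{trait}.csv")
            pred = res.predictions(reliability_floor=floor)
            _write(pred.reset_index(), out / f"predictions_{trait}.csv")
            drblups[trait] = pred["drblup"]
            h2_rows.append((trait, "overall", "standard", res.h2_standard()))
            h2_rows.append((trait, "overall", "cullis", res.h2_cullis()))

    with stage("per_trial_h2"):
        for trait in traits:
            per = per_trial_h2(pheno, trait)
            for _, r in per.iterrows():
                h2_rows.append((trait, r["environment"], "cullis", r["h2_cullis"]))
        h2df = pd.DataFrame(h2_rows, columns=["trait", "scope", "method", "value"])
        _write(h2df, out / "heritability.csv")

    with stage("correlations"):
        corrm = correlate_drblups(drblups)
        _write(corrm.to_frame(), out / "correlations.csv")

    # ---------------- GEI models ---------------------------------------
    gxe_models = [m.lower() for m in cfg.get("gxe_models", ["fw", "ammi", "gge"])]
    stab_cfg = cfg.get("stability") or {}
    with stage("gxe"):
        for trait in traits:
            tw = complete_table(two_way_means(pheno, trait))
            _write(tw.data.rename_axis("genotype").reset_index(),
                   out / f"two_way_{trait}.csv")
            coords = []
            if "fw" in gxe_models:
                fw = FinlayWilkinson(scale_table(tw)).fit()
                _write(fw.genotype_stats.rename_axis("genotype").reset_index(),
                       out / f"fw_{trait}.csv")
                _write(fw.tss_partition(), out / f"fw_tss_{trait}.csv")
            if "ammi" in gxe_models:
                am = AMMI(tw).fit()
                _write(am.anova, out / f"ammi_anova_{trait}.csv")
                _write(am.tss_partition(), out / f"ammi_tss_{trait}.csv")
                for mode, sc in (("genotype", am.genotype_scores),
                                 ("environment", am.env_scores)):
                    for lab, row in sc.iterrows():
                        coords.append(("ammi", mode, lab, row.iloc[0],
                                       row.iloc[1] if len(row) > 1 else 0.0))
            if "gge" in gxe_models:
                gg = GGE(tw).fit()
                _write(gg.tss_partition(), out / f"gge_tss_{trait}.csv")
                _write(gg.which_won_where(), out / f"gge_winners_{trait}.csv")
                for mode, sc in (("genotype", gg.genotype_coords),
                                 ("environment", gg.env_coords)):
                    for lab, row in sc.iterrows():
                        coords.append(("gge", mode, lab, row["PC1"],
                                       row.get("PC2", 0.0)))
            if coords:
                _write(pd.DataFrame(coords, columns=["model", "mode", "label",
                                                     "PC1", "PC2"]),
                       out / f"biplot_coords_{trait}.csv")

            stab = stability_table(tw)
            stab = rank_and_select(stab, rule=stab_cfg.get("rule", "gai_top_k"),
                                   k=int(stab_cfg.get("top_k", 5)),
                                   above_mean=bool(stab_cfg.get("above_mean", True)))
            _write(stab.reset_index(), out / f"stability_{trait}.csv")

    with stage("summary"):
        manifest["warnings"] = caught
        _write_summary(out, traits, results, h2df, corrm, seed)
        for f in sorted(out.glob("*.csv")):
            manifest["outputs"].append({"file": f.name, "sha256": _hash_file(f)})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _check_traits(cfg, available):
    """Fail fast on unknown analysis traits, before any computation."""
    for t in cfg.get("traits") or []:
        if t not in available:
            raise ConfigError(f"unknown trait '{t}'; available: {sorted(available)}")


def _write_summary(out, traits, results, h2df, corrm, seed):
    lines = ["# MET analysis summary", "",
             f"Seed {seed}; traits analysed: {', '.join(traits)}.", "",
             "## Variance components and heritability", ""]
    for trait in traits:
        res = results[trait]
        lines.append(f"### {trait}")
        lines.append("```")
        lines.append(res.summary())
        lines.append("```")
        lines.append("")
    lines.append("## DRBLUP correlations (upper triangle)")
    lines.append("")
    lines.append("```")
    lines.append(corrm.r.round(3).to_string())
    lines.append("```")
    (out / "summary.md").write_text("\n".join(lines))
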