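"""Synthetic multi-environment trial (MET) generator.

Emulates the structure of a uniform-yield-trial series: 67 genotypes
(62 advanced clones + 5 checks shared between two overlapping 36-entry trial
sets) evaluated in 8 location-year environments under an alpha-lattice-like
layout with 2 replications and recorded row/column positions.

The phenotype model for each trait is

    y_ijkr = mu + g_i + E_j + (b_i - 1) E_j + ge_ij + rep_k(j)
             + spatial(row, col) + eps

with genetic values ``g_i`` drawn jointly across traits from a specified
genetic correlation matrix, per-genotype environmental sensitivities ``b_i``
(Finlay-Wilkinson slopes) centred on 1, cell-level interaction ``ge_ij`` over
and above the slope term, replication effects nested in environments, and a
linear row/column trend per trial set standing in for incomplete-block
effects.  A :class:`TruthRecord` stores every drawn effect for
parameter-recovery testing.

All randomness derives from one master seed through named substreams, so the
same configuration always yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pheno import ConfigError, PhenoTable

__all__ = [
    "TraitSpec",
    "SimConfig",
    "GeneticCorrelation",
    "TruthRecord",
    "make_design",
    "simulate_met",
    "cassava_uyt_config",
]

# named substream ids: every source of randomness has its own child stream
_STREAMS = {
    "design": 0, "genetic": 1, "slopes": 2, "env": 3, "ge": 4,
    "rep": 5, "spatial": 6, "noise": 7, "missing": 8,
}


def _rng(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), _STREAMS[name], int(extra)))
    )


# ----------------------------------------------------------------------
@dataclass
class TraitSpec:
    """Variance structure of one simulated trait.

    Parameters are on the trait's own measurement scale (e.g. percentage
    points for conversion rates, t/ha for yields): ``var_g`` genotypic
    variance, ``var_ge`` residual (non-regression) interaction variance,
    ``var_rep_env`` replication-within-environment variance, ``var_e`` plot
    residual variance, ``env_effect_sd`` the SD of environment main effects,
    ``sensitivity_sd`` the spread of Finlay-Wilkinson slopes around 1,
    ``spatial_sd`` the SD of each (row, column) linear trend component within
    a trial set, and ``missing_rate`` the per-plot probability that the trait
    value is unrecorded.
    """

    name: str
    mu: float
    var_g: float
    var_ge: float = 0.0
    var_rep_env: float = 0.0
    var_e: float = 0.0
    env_effect_sd: float = 0.0
    sensitivity_sd: float = 0.0
    spatial_sd: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        for f_ in ("var_g", "var_ge", "var_rep_env", "var_e",
                   "env_effect_sd", "sensitivity_sd", "spatial_sd"):
            v = getattr(self, f_)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"trait '{self.name}': {f_} must be finite and >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"trait '{self.name}': missing_rate must be in [0, 1)")


#: Default environment labels: four Nigerian locations over 2017-2019
#: (Ago-Owu, Ibadan, Ikenne, Ubiaja), eight location-year combinations.
DEFAULT_ENVIRONMENTS = ["AG17", "AG18", "AG19", "IB18", "IB19", "IK17", "IK19", "UB19"]

DEFAULT_CHECKS = ["TMS30572", "TMEB419", "TMS000070", "TMS980581", "TMS982101"]


@dataclass
class SimConfig:
    """Design and trait configuration of a simulated MET."""

    n_genotypes: int = 67
    n_checks: int = 5
    environments: list = field(default_factory=lambda: list(DEFAULT_ENVIRONMENTS))
    n_reps: int = 2
    n_sets: int = 2
    grid: tuple = (6, 6)            # rows x cols available per set and rep
    traits: list = field(default_factory=list)
    seed: int = 0
    emit_raw: bool = False          # also write back raw weights/counts

    def __post_init__(self):
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.n_sets < 1:
            raise ConfigError("n_sets must be >= 1")
        if self.n_checks >= self.n_genotypes:
            raise ConfigError("n_checks must be < n_genotypes")
        n_adv = self.n_genotypes - self.n_checks
        if self.n_sets > 1 and n_adv % self.n_sets:
            raise ConfigError("advanced genotypes must divide evenly into sets")

    # ------------------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        n_adv = self.n_genotypes - self.n_checks
        adv = [f"G{i + 1:02d}" for i in range(n_adv)]
        checks = list(DEFAULT_CHECKS[: self.n_checks])
        checks += [f"CHK{i + 1}" for i in range(len(checks), self.n_checks)]
        return adv + checks

    @property
    def sets(self) -> dict[str, list[str]]:
        """Trial sets: advanced clones split across sets, checks in all."""
        g = self.genotypes
        n_adv = self.n_genotypes - self.n_checks
        adv, checks = g[:n_adv], g[n_adv:]
        per = n_adv // self.n_sets
        out = {}
        for s in range(self.n_sets):
            label = f"set{chr(ord('A') + s)}"
            out[label] = adv[s * per:(s + 1) * per] + checks
        return out


class GeneticCorrelation:
    """Genetic correlation structure across simulated traits.

    Built from a mapping of unordered trait pairs to correlations; assembled
    into a symmetric matrix with unit diagonal.  Slightly indefinite user
    input is repaired by clipping negative eigenvalues at zero and rescaling
    to a correlation matrix; input beyond ``repair_tol`` is rejected.
    """

    def __init__(self, pairs: dict | None = None, repair_tol: float = 0.1):
        self.pairs = {}
        for (a, b), r in (pairs or {}).items():
            if not -1 <= r <= 1:
                raise ConfigError(f"correlation for ({a}, {b}) outside [-1, 1]")
            self.pairs[frozenset((a, b))] = float(r)
        self.repair_tol = repair_tol

    def matrix(self, traits: list[str]) -> np.ndarray:
        t = list(traits)
        n = len(t)
        R = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r = self.pairs.get(frozenset((t[i], t[j])), 0.0)
                R[i, j] = R[j, i] = r
        w, V = np.linalg.eigh(R)
        if w.min() < -self.repair_tol:
            raise ConfigError(
                f"correlation matrix is not PSD (min eigenvalue {w.min():.3f})"
            )
        if w.min() < 0:
            w = np.clip(w, 0.0, None)
            R = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            np.fill_diagonal(R, 1.0)
        return R


@dataclass
class TruthRecord:
    """All latent effects behind one simulated table (recovery oracle)."""

    seed: int
    genotypes: list
    environments: list
    variance_components: dict            # trait -> dict of spec values
    genetic_values: pd.DataFrame         # genotype x trait
    slopes: pd.DataFrame                 # genotype x trait (FW b_i)
    env_effects: pd.DataFrame            # environment x trait
    ge_effects: dict                     # trait -> DataFrame genotype x environment
    rep_effects: dict                    # trait -> DataFrame (environment, rep)
    correlation: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "genotypes": list(self.genotypes),
            "environments": list(self.environments),
            "variance_components": self.variance_components,
            "genetic_values": self.genetic_values.to_dict(orient="split"),
            "slopes": self.slopes.to_dict(orient="split"),
            "env_effects": self.env_effects.to_dict(orient="split"),
            "ge_effects": {k: v.to_dict(orient="split") for k, v in self.ge_effects.items()},
            "rep_effects": {k: v.to_dict(orient="split") for k, v in self.rep_effects.items()},
            "correlation": None if self.correlation is None
            else self.correlation.to_dict(orient="split"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)

        def _df(spl):
            return pd.DataFrame(spl["data"], index=spl["index"], columns=spl["columns"])

        return cls(
            seed=d["seed"], genotypes=d["genotypes"], environments=d["environments"],
            variance_components=d["variance_components"],
            genetic_values=_df(d["genetic_values"]), slopes=_df(d["slopes"]),
            env_effects=_df(d["env_effects"]),
            ge_effects={k: _df(v) for k, v in d["ge_effects"].items()},
            rep_effects={k: _df(v) for k, v in d["rep_effects"].items()},
            correlation=None if d["correlation"] is None else _df(d["correlation"]),
        )


# ----------------------------------------------------------------------
def make_design(config: SimConfig) -> PhenoTable:
    """Field-design skeleton: one row per plot, no phenotypes.

    Every genotype appears once per (set, rep) in every environment; checks
    appear in all sets.  Within a replicate of a set, genotypes are laid on
    the row x column grid by a seeded random permutation (an alpha-lattice
    randomisation stand-in), so no (row, col) cell is used twice.
    """
    rows_per, cols_per = config.grid
    sets = config.sets
    cap = rows_per * cols_per
    need = max(len(v) for v in sets.values())
    if cap < need:
        raise ConfigError(f"grid {config.grid} holds {cap} plots; set needs {need}")

    rng = _rng(config.seed, "design")
    recs = []
    for env in config.environments:
        for set_id, members in sets.items():
            for rep in range(1, config.n_reps + 1):
                perm = rng.permutation(len(members))
                for pos, gi in enumerate(perm):
                    recs.append(
                        (members[gi], str(env), rep, set_id,
                         pos // cols_per + 1, pos % cols_per + 1)
                    )
    df = pd.DataFrame(recs, columns=["genotype", "environment", "rep", "set", "row", "col"])
    return PhenoTable(df)


def simulate_met(config: SimConfig,
                 correlations: GeneticCorrelation | None = None
                 ) -> tuple[PhenoTable, TruthRecord]:
    """Simulate plot-level phenotypes for every trait in ``config.traits``.

    Returns the phenotype table and the :class:`TruthRecord` holding the
    drawn genetic values, slopes, environment/interaction/replication effects
    and the variance components used.
    """
    if not config.traits:
        raise ConfigError("config.traits is empty")
    corr = correlations or GeneticCorrelation()
    trait_names = [t.name for t in config.traits]
    R = corr.matrix(trait_names)

    design = make_design(config)
    df = design.df.copy()
    genos = config.genotypes
    envs = [str(e) for e in config.environments]
    gi = df["genotype"].map({g: k for k, g in enumerate(genos)}).to_numpy()
    ej = df["environment"].map({e: k for k, e in enumerate(envs)}).to_numpy()

    # joint genetic values across traits: Z L' scaled by per-trait sd
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    z = _rng(config.seed, "genetic").standard_normal((len(genos), len(R)))
    gmat = z @ L.T
    gmat = gmat * np.array([np.sqrt(t.var_g) for t in config.traits])

    truth_vc, ge_all, rep_all = {}, {}, {}
    slopes = np.empty((len(genos), len(config.traits)))
    envmat = np.empty((len(envs), len(config.traits)))

    for k, spec in enumerate(config.traits):
        slopes[:, k] = 1.0 + _rng(config.seed, "slopes", k).standard_normal(len(genos)) \
            * spec.sensitivity_sd
        envmat[:, k] = _rng(config.seed, "env", k).standard_normal(len(envs)) \
            * spec.env_effect_sd
        ge = _rng(config.seed, "ge", k).standard_normal((len(genos), len(envs))) \
            * np.sqrt(spec.var_ge)
        ge_all[spec.name] = pd.DataFrame(ge, index=genos, columns=envs)

        reps = _rng(config.seed, "rep", k).standard_normal((len(envs), config.n_reps)) \
            * np.sqrt(spec.var_rep_env)
        rep_all[spec.name] = pd.DataFrame(
            [(envs[a], r + 1, reps[a, r]) for a in range(len(envs))
             for r in range(config.n_reps)],
            columns=["environment", "rep", "effect"],
        )

        # spatial linear trends per (environment, set): standardised row/col
        rs = _rng(config.seed, "spatial", k)
        trend = np.zeros(len(df))
        for (env, set_id), idx in df.groupby(["environment", "set"]).groups.items():
            a_r, a_c = rs.standard_normal(2) * spec.spatial_sd
            sub = df.loc[idx]
            for coef, colname in ((a_r, "row"), (a_c, "col")):
                x = sub[colname].to_numpy(dtype=float)
                sd = x.std()
                if sd > 0:
                    trend[np.asarray(idx)] += coef * (x - x.mean()) / sd

        eps = _rng(config.seed, "noise", k).standard_normal(len(df)) * np.sqrt(spec.var_e)

        rep_effect = reps[ej, df["rep"].to_numpy() - 1]
        y = (spec.mu + gmat[gi, k] + envmat[ej, k]
             + (slopes[gi, k] - 1.0) * envmat[ej, k]
             + ge[gi, ej] + rep_effect + trend + eps)

        if spec.missing_rate > 0:
            miss = _rng(config.seed, "missing", k).random(len(df)) < spec.missing_rate
            y = np.where(miss, np.nan, y)
        df[spec.name] = y
        truth_vc[spec.name] = {
            "mu": spec.mu, "var_g": spec.var_g, "var_ge": spec.var_ge,
            "var_rep_env": spec.var_rep_env, "var_e": spec.var_e,
            "env_effect_sd": spec.env_effect_sd,
            "sensitivity_sd": spec.sensitivity_sd, "spatial_sd": spec.spatial_sd,
            "missing_rate": spec.missing_rate,
        }

    if config.emit_raw:
        _emit_raw(df)

    registry = {t.name: {"units": "", "derivation": "raw"}
                for t in config.traits if t.name in df.columns}
    table = PhenoTable(df, registry, validate=False)
    truth = TruthRecord(
        seed=config.seed, genotypes=genos, environments=envs,
        variance_components=truth_vc,
        genetic_values=pd.DataFrame(gmat, index=genos, columns=trait_names),
        slopes=pd.DataFrame(slopes, index=genos, columns=trait_names),
        env_effects=pd.DataFrame(envmat, index=envs, columns=trait_names),
        ge_effects=ge_all, rep_effects=rep_all,
        correlation=pd.DataFrame(R, index=trait_names, columns=trait_names),
    )
    return table, truth


def _emit_raw(df: pd.DataFrame) -> None:
    """Back-fill raw plot measures consistent with the simulated traits.

    Processing starts from 20 kg of roots per plot; the net plot is 20 plants
    at 0.8 m² spacing, so RTWT (kg/plot) = FYLD * 20 * 0.8 / 10.
    """
    df["n_plants_harvested"] = 20
    if "FYLD" in df.columns:
        df["RTWT"] = np.clip(df["FYLD"] * 20 * 0.8 / 10.0, 0.1, None)
        del df["FYLD"]
    for pct, (prod, start) in (
        ("gari_pct", ("gari_weight", "starting_root_weight_gari")),
        ("fufu_pct", ("fufu_weight", "starting_root_weight_fufu")),
    ):
        if pct in df.columns:
            df[start] = 20.0
            df[prod] = np.clip(df[pct], 0.1, None) / 100.0 * 20.0
            df.loc[df[pct].isna(), [prod]] = np.nan
            del df[pct]


# ----------------------------------------------------------------------
def cassava_uyt_config(seed: int = 0, emit_raw: bool = False,
                      missing_rate: float = 0.05,
                      ) -> tuple[SimConfig, GeneticCorrelation]:
    """Preset emulating the study conditions of the gari/fufu MET.

    67 genotypes (62 advanced + 5 checks), 8 environments, 2 reps, two trial
    sets.  Trait means follow the reported population means (gari% 19.23,
    fufu% 19.68, DM 36.94%, FYLD 33.03 t/ha).  Variance components target an
    entry-mean heritability around 0.7 for the conversion rates with the
    environment contributing roughly 45% of phenotypic variance; strong
    genetic correlations tie DM to both conversion rates (0.80-0.84) while
    fresh root yield is essentially uncorrelated with them.
    """
    traits = [
        TraitSpec("DM", mu=36.94, var_g=1.15, var_ge=1.5, var_rep_env=0.15,
                  var_e=2.8, env_effect_sd=1.8, sensitivity_sd=0.1,
                  spatial_sd=0.3, missing_rate=missing_rate),
        TraitSpec("gari_pct", mu=19.23, var_g=0.80, var_ge=1.10, var_rep_env=0.18,
                  var_e=2.9, env_effect_sd=2.0, sensitivity_sd=0.2,
                  spatial_sd=0.3, missing_rate=missing_rate),
        TraitSpec("fufu_pct", mu=19.68, var_g=0.85, var_ge=0.80, var_rep_env=0.18,
                  var_e=2.9, env_effect_sd=1.8, sensitivity_sd=0.25,
                  spatial_sd=0.3, missing_rate=missing_rate),
        TraitSpec("FYLD", mu=33.03, var_g=8.0, var_ge=10.0, var_rep_env=1.5,
                  var_e=30.0, env_effect_sd=6.0, sensitivity_sd=0.2,
                  spatial_sd=1.0, missing_rate=missing_rate),
    ]
    corr = GeneticCorrelation({
        ("DM", "gari_pct"): 0.80,
        ("DM", "fufu_pct"): 0.82,
        ("gari_pct", "fufu_pct"): 0.84,
        ("DM", "FYLD"): -0.05,
        ("gari_pct", "FYLD"): -0.10,
        ("fufu_pct", "FYLD"): -0.10,
    })
    cfg = SimConfig(traits=traits, seed=seed, emit_raw=emit_raw)
    return cfg, corr
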