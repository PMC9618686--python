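"""Shared fixtures: small synthetic MET datasets and helper constructors."""

import numpy as np
import pandas as pd
import pytest

from metgxe.simulate import SimConfig, TraitSpec, simulate_met


def recovery_config(seed, **overrides):
    """One-trait MET at study scale (67 genotypes, 8 envs, 2 reps) with
    variance components sigma_g^2=1, sigma_ge^2=0.5, sigma_e^2=2."""
    kw = dict(mu=20.0, var_g=1.0, var_ge=0.5, var_rep_env=0.2, var_e=2.0,
              env_effect_sd=2.0)
    kw.update(overrides)
    return SimConfig(traits=[TraitSpec("y", **kw)], seed=seed)


def big_population_config(seed, traits=None, correlations=None,
                          n_genotypes=505):
    """Large-population config (default 500 advanced + 5 checks, one set)
    used for deregression and genetic-correlation recovery experiments."""
    if traits is None:
        traits = [TraitSpec("y", mu=20.0, var_g=1.0, var_ge=0.5,
                            var_rep_env=0.2, var_e=2.0, env_effect_sd=2.0)]
    return SimConfig(n_genotypes=n_genotypes, n_sets=1, grid=(23, 23),
                     traits=traits, seed=seed)


def entry_means(pheno, trait):
    """Genotype x environment cell means as a long DataFrame (rep collapsed)."""
    df = pheno.df
    cells = (df.groupby(["genotype", "environment"], as_index=False)[trait]
             .mean())
    cells["rep"] = 1
    cells["set"] = "S1"
    return cells


@pytest.fixture(scope="session")
def small_met():
    """67 x 8 x 2 MET with known truth, moderate noise, no missingness."""
    cfg = recovery_config(seed=7)
    return simulate_met(cfg)


@pytest.fixture(scope="session")
def additive_met():
    """Purely additive, noise-free MET: y = mu + g + E exactly."""
    cfg = SimConfig(traits=[TraitSpec("y", mu=10.0, var_g=1.0,
                                      env_effect_sd=2.0)], seed=3)
    return simulate_met(cfg)


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "pheno.csv"
    path.write_text(
        "genotype,environment,rep,set,RTWT,DM\n"
        "G1,E1,1,A,30,40\n"
        "G1,E1,2,A,34,41\n"
        "G2,E1,1,A,28,38\n"
        "G2,E1,2,A,31,39\n"
    )
    return path
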