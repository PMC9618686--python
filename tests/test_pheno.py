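"""Phenotype table I/O and trait derivation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgxe.pheno import (ConfigError, DataError, PhenoTable, derive_traits,
                          read_pheno, write_table)


def _plot_df(**traits):
    base = {"genotype": ["G1"], "environment": ["E1"], "rep": [1], "set": ["A"]}
    base.update({k: [v] for k, v in traits.items()})
    return pd.DataFrame(base)


class TestReadPheno:
    def test_row_count_preserved(self, tiny_csv):
        t = read_pheno(tiny_csv)
        assert t.n_records == 4
        assert set(t.traits) == {"RTWT", "DM"}

    def test_blank_cell_becomes_missing_with_warning(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("genotype,environment,rep,RTWT\nG1,E1,1,\nG1,E1,2,30\n")
        with pytest.warns(UserWarning, match="1 blank or unparseable"):
            t = read_pheno(p)
        assert t.n_records == 2
        assert t.df["RTWT"].isna().sum() == 1
        assert t.n_unparseable == 1

    def test_duplicate_key_is_data_error(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("genotype,environment,rep,set,RTWT\n"
                     "G1,E1,1,setA,30\nG1,E1,1,setA,31\n")
        with pytest.raises(DataError, match="duplicate plot key"):
            read_pheno(p)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("genotype,rep,RTWT\nG1,1,30\n")
        with pytest.raises(ConfigError, match="environment"):
            read_pheno(p)

    def test_dialect_resolves_alternative_headers(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("accession_name,studyName,replicate,root_wt\nG1,IK19,1,30\n")
        t = read_pheno(p, dialect={"root_wt": "RTWT"})
        assert list(t.df["environment"]) == ["IK19"]
        assert "RTWT" in t.traits

    def test_roundtrip(self, tiny_csv, tmp_path):
        t = read_pheno(tiny_csv)
        out = tmp_path / "out.csv"
        write_table(t, out)
        t2 = read_pheno(out)
        assert t.equals(t2)


class TestInvariantValidation:
    @pytest.mark.parametrize("traits,msg", [
        (dict(RTWT=-1.0), "negative weight"),
        (dict(DM=120.0), "DM"),
        (dict(HI=1.5), "HI"),
        (dict(RTSZ=4.0), "RTSZ"),
    ])
    def test_range_violations_raise(self, traits, msg):
        with pytest.raises(DataError, match=msg):
            PhenoTable(_plot_df(**traits))


class TestDeriveTraits:
    def test_conversion_rates_and_yields(self):
        df = _plot_df(RTWT=32.0, DM=40.0, n_plants_harvested=20,
                      gari_weight=4.0, starting_root_weight_gari=20.0,
                      fufu_weight=4.4, starting_root_weight_fufu=20.0,
                      peel_weight=4.2, dried_fiber_weight=0.9)
        t = derive_traits(PhenoTable(df))
        r = t.df.iloc[0]
        assert r["gari_pct"] == pytest.approx(20.0)
        assert r["fufu_pct"] == pytest.approx(22.0)
        assert r["peel_loss_pct"] == pytest.approx(21.0)
        assert r["fiber_pct"] == pytest.approx(4.5)
        # 32 kg over 20 plants x 0.8 m2 = 2 kg/m2 = 20 t/ha
        assert r["FYLD"] == pytest.approx(20.0)
        assert r["DYLD"] == pytest.approx(8.0)
        assert r["gari_yield"] == pytest.approx(4.0)

    def test_missing_parent_propagates_not_raises(self):
        df = _plot_df(gari_weight=np.nan, starting_root_weight_gari=20.0)
        t = derive_traits(PhenoTable(df))
        assert np.isnan(t.df["gari_pct"].iloc[0])

    def test_zero_starting_weight_with_product_is_error(self):
        df = _plot_df(gari_weight=4.0, starting_root_weight_gari=0.0)
        with pytest.raises(DataError, match="starting_root_weight_gari = 0"):
            derive_traits(PhenoTable(df))

    def test_idempotent(self):
        df = _plot_df(RTWT=32.0, DM=40.0, n_plants_harvested=20,
                      gari_weight=4.0, starting_root_weight_gari=20.0)
        once = derive_traits(PhenoTable(df))
        twice = derive_traits(once)
        assert once.equals(twice)

    def test_registry_marks_derivation(self):
        df = _plot_df(gari_weight=4.0, starting_root_weight_gari=20.0)
        t = derive_traits(PhenoTable(df))
        assert t.trait_registry["gari_pct"]["derivation"] == "derived"
        assert t.trait_registry["gari_weight"]["derivation"] == "raw"

    @given(rtwt=st.floats(0.1, 200), dm=st.floats(5, 60),
           gari_w=st.floats(0.01, 8), plants=st.integers(1, 25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_yield_consistency_properties(self, rtwt, dm, gari_w, plants):
        """gari_yield <= FYLD (conversion <= 100%) and FYLD == DYLD/(DM/100)."""
        df = _plot_df(RTWT=rtwt, DM=dm, n_plants_harvested=plants,
                      gari_weight=gari_w, starting_root_weight_gari=20.0)
        r = derive_traits(PhenoTable(df)).df.iloc[0]
        assert r["gari_yield"] <= r["FYLD"] + 1e-12
        assert r["FYLD"] == pytest.approx(r["DYLD"] / (dm / 100.0), abs=1e-9)


class TestWriteTable:
    def test_empty_table_writes_header_only(self, tmp_path):
        out = tmp_path / "e.csv"
        write_table(pd.DataFrame(columns=["genotype", "mean", "Wi"]), out)
        lines = out.read_text().strip().splitlines()
        assert lines == ["genotype,mean,Wi"]

    def test_float_precision_at_least_10_digits(self, tmp_path):
        out = tmp_path / "f.csv"
        x = 1.2345678901234
        write_table(pd.DataFrame({"v": [x]}), out)
        back = pd.read_csv(out)["v"].iloc[0]
        assert back == pytest.approx(x, abs=1e-10)
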