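"""Plot-level phenotype tables for multi-environment cassava trials.

The universal exchange object is :class:`PhenoTable`, a thin wrapper around a
long-format :class:`pandas.DataFrame` with one row per plot and one column per
trait.  Plots are keyed by (genotype, environment, rep, set); environments are
location-year codes such as ``"IK19"``.  Missing values are represented by a
single sentinel (NaN) and are never silently dropped.

Raw plot measurements (root weight, processing weights, dry matter, ...) are
turned into the processed-product and yield traits — gari and fufu conversion
rates, peel loss, fiber content, fresh/dry root yield and product yields — by
:func:`derive_traits`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PhenoTable",
    "DataError",
    "ConfigError",
    "DEFAULT_DIALECT",
    "KEY_COLS",
    "read_pheno",
    "derive_traits",
    "write_table",
]


class DataError(ValueError):
    """Raised when input data violate a structural invariant."""


class ConfigError(ValueError):
    """Raised when a configuration (dialect, simulation, pipeline) is invalid."""


#: Columns that uniquely key a plot record.
KEY_COLS = ["genotype", "environment", "rep", "set"]

#: Non-trait columns describing the field layout.
DESIGN_COLS = ["row", "col", "n_plants_harvested"]

#: Default column-name dialect.  Maps common file headers (cassavabase-style
#: ontology labels and frequent shorthands) onto canonical column names.
DEFAULT_DIALECT = {
    "genotype": "genotype",
    "accession_name": "genotype",
    "germplasmname": "genotype",
    "clone": "genotype",
    "environment": "environment",
    "env": "environment",
    "studyname": "environment",
    "trial": "environment",
    "rep": "rep",
    "replicate": "rep",
    "replication": "rep",
    "rep_number": "rep",
    "set": "set",
    "set_name": "set",
    "trial_set": "set",
    "row": "row",
    "row_number": "row",
    "col": "col",
    "column": "col",
    "col_number": "col",
    "n_plants_harvested": "n_plants_harvested",
    "plant_stands_harvested": "n_plants_harvested",
}

# weight-like raw traits that must be non-negative
_WEIGHT_TRAITS = (
    "RTWT",
    "gari_weight",
    "fufu_weight",
    "peel_weight",
    "dried_fiber_weight",
    "starting_root_weight_gari",
    "starting_root_weight_fufu",
)

#: (product weight, starting weight) pairs used for conversion rates.
_PRODUCT_PAIRS = {
    "gari_pct": ("gari_weight", "starting_root_weight_gari"),
    "fufu_pct": ("fufu_weight", "starting_root_weight_fufu"),
    "peel_loss_pct": ("peel_weight", "starting_root_weight_gari"),
    "fiber_pct": ("dried_fiber_weight", "starting_root_weight_fufu"),
}

#: Derived trait -> (units, parents).
DERIVED_TRAITS = {
    "gari_pct": ("%", ("gari_weight", "starting_root_weight_gari")),
    "fufu_pct": ("%", ("fufu_weight", "starting_root_weight_fufu")),
    "peel_loss_pct": ("%", ("peel_weight", "starting_root_weight_gari")),
    "fiber_pct": ("%", ("dried_fiber_weight", "starting_root_weight_fufu")),
    "FYLD": ("t/ha", ("RTWT", "n_plants_harvested")),
    "DYLD": ("t/ha", ("RTWT", "n_plants_harvested", "DM")),
    "gari_yield": ("t/ha", ("RTWT", "n_plants_harvested", "gari_weight", "starting_root_weight_gari")),
    "fufu_yield": ("t/ha", ("RTWT", "n_plants_harvested", "fufu_weight", "starting_root_weight_fufu")),
}


class PhenoTable:
    """Long-format plot-level phenotype table.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per plot.  Must contain the key columns ``genotype``,
        ``environment``, ``rep`` and ``set``; any numeric non-key, non-design
        column is treated as a trait.
    trait_registry : dict, optional
        Mapping trait name -> ``{"units": str, "derivation": "raw"|"derived"}``.
        Unregistered trait columns are registered as raw with unknown units.
    validate : bool
        Check key uniqueness and basic range invariants.
    """

    def __init__(self, df: pd.DataFrame, trait_registry: dict | None = None,
                 validate: bool = True):
        df = df.copy()
        for c in ("genotype", "environment"):
            if c not in df.columns:
                raise ConfigError(f"mandatory column '{c}' missing")
            df[c] = df[c].astype(str)
        if "rep" not in df.columns:
            raise ConfigError("mandatory column 'rep' missing")
        df["rep"] = pd.to_numeric(df["rep"]).astype(int)
        if "set" not in df.columns:
            df["set"] = "S1"
        df["set"] = df["set"].astype(str)
        order = KEY_COLS + [c for c in df.columns if c not in KEY_COLS]
        self.df = df[order].reset_index(drop=True)

        self.trait_registry: dict[str, dict] = dict(trait_registry or {})
        for c in self.traits:
            self.trait_registry.setdefault(c, {"units": "", "derivation": "raw"})

        if validate:
            self._validate()

    # ------------------------------------------------------------------
    @property
    def traits(self) -> list[str]:
        out = []
        for c in self.df.columns:
            if c in KEY_COLS or c in DESIGN_COLS:
                continue
            if pd.api.types.is_numeric_dtype(self.df[c]):
                out.append(c)
        return out

    @property
    def n_records(self) -> int:
        return len(self.df)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)

    def _validate(self) -> None:
        dup = self.df.duplicated(KEY_COLS)
        if dup.any():
            key = tuple(self.df.loc[dup.idxmax(), KEY_COLS])
            raise DataError(f"duplicate plot key {key}")
        if "rep" in self.df and (self.df["rep"] < 1).any():
            raise DataError("replication numbers must be >= 1")
        for c in _WEIGHT_TRAITS:
            if c in self.df.columns and (self.df[c].dropna() < 0).any():
                raise DataError(f"negative weight in column '{c}'")
        if "DM" in self.df.columns:
            dm = self.df["DM"].dropna()
            if ((dm <= 0) | (dm > 100)).any():
                raise DataError("DM must lie in (0, 100]")
        if "HI" in self.df.columns:
            hi = self.df["HI"].dropna()
            if ((hi < 0) | (hi > 1)).any():
                raise DataError("HI must lie in [0, 1]")
        if "RTSZ" in self.df.columns:
            sz = self.df["RTSZ"].dropna()
            if (~sz.isin([3, 5, 7])).any():
                raise DataError("RTSZ must be one of {3, 5, 7}")

    # ------------------------------------------------------------------
    def copy(self) -> "PhenoTable":
        return PhenoTable(self.df, dict(self.trait_registry), validate=False)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()

    def equals(self, other: "PhenoTable") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if pd.api.types.is_numeric_dtype(a[c]):
                x = a[c].to_numpy(dtype=float)
                y = pd.to_numeric(b[c]).to_numpy(dtype=float)
                if not np.allclose(x, y, equal_nan=True, atol=1e-12, rtol=1e-9):
                    return False
            elif not a[c].astype(str).equals(b[c].astype(str)):
                return False
        return True


# ----------------------------------------------------------------------
def _normalise_dialect(dialect: dict | None) -> dict:
    d = {k.lower(): v for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        d.update({k.lower(): v for k, v in dialect.items()})
    return d


def read_pheno(path, dialect: dict | None = None) -> PhenoTable:
    """Read a long-format phenotype CSV.

    Column names are resolved through a *dialect* map (file header ->
    canonical name); unmapped columns are kept verbatim as trait columns.
    Unparseable or blank trait cells become missing values; their count is
    reported via a single :class:`UserWarning`.
    """
    d = _normalise_dialect(dialect)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [d.get(str(c).strip().lower(), str(c).strip()) for c in raw.columns]
    for c in ("genotype", "environment", "rep"):
        if c not in raw.columns:
            raise ConfigError(
                f"mandatory column '{c}' not resolvable from header "
                f"{list(raw.columns)}; extend the dialect map"
            )

    df = pd.DataFrame()
    for c in ("genotype", "environment"):
        df[c] = raw[c].str.strip()
    try:
        df["rep"] = pd.to_numeric(raw["rep"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise DataError(f"replication column is not integer: {exc}") from None
    df["set"] = raw["set"].str.strip() if "set" in raw.columns else "S1"

    n_bad = 0
    for c in raw.columns:
        if c in KEY_COLS:
            continue
        vals = raw[c].str.strip()
        num = pd.to_numeric(vals.replace("", np.nan), errors="coerce")
        n_bad += int(num.isna().sum())
        df[c] = num
    if n_bad:
        warnings.warn(f"{n_bad} blank or unparseable cell(s) set to missing",
                      UserWarning, stacklevel=2)
    table = PhenoTable(df)
    table.n_unparseable = n_bad
    return table


def derive_traits(table: PhenoTable, spacing_m2: float = 0.8,
                  net_plot_plants: int = 20) -> PhenoTable:
    """Derive processed-product and yield traits from raw plot measures.

    Adds, where the parent raw traits exist:

    * ``gari_pct``  = 100 * gari_weight / starting_root_weight_gari
    * ``fufu_pct``  = 100 * fufu_weight / starting_root_weight_fufu
    * ``peel_loss_pct`` = 100 * peel_weight / starting root weight
    * ``fiber_pct`` = 100 * dried_fiber_weight / starting_root_weight_fufu
    * ``FYLD`` (t/ha) = RTWT_kg / (n_plants_harvested * spacing_m2) * 10
    * ``DYLD`` = FYLD * DM / 100
    * ``gari_yield`` = FYLD * gari_pct / 100, ``fufu_yield`` likewise

    The yield conversion follows from kg per occupied area: each harvested
    plant occupies ``spacing_m2`` m², and 1 kg/m² = 10 t/ha.  Derivations with
    any missing parent propagate missingness and never raise; recomputation is
    idempotent.  A recorded product weight with a zero starting weight is a
    data error.
    """
    out = table.copy()
    df = out.df

    for trait, (prod, start) in _PRODUCT_PAIRS.items():
        if prod in df.columns and start in df.columns:
            bad = (df[start] == 0) & (df[prod] > 0)
            if bad.any():
                i = int(bad.idxmax())
                raise DataError(
                    f"plot {tuple(df.loc[i, KEY_COLS])}: {prod} > 0 but {start} = 0"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                val = 100.0 * df[prod] / df[start]
            df[trait] = val.where(df[start] > 0)
            out.trait_registry[trait] = {"units": "%", "derivation": "derived"}

    if "RTWT" in df.columns and "n_plants_harvested" in df.columns:
        plants = df["n_plants_harvested"].where(df["n_plants_harvested"] > 0)
        df["FYLD"] = df["RTWT"] / (plants * spacing_m2) * 10.0
        out.trait_registry["FYLD"] = {"units": "t/ha", "derivation": "derived"}
    if "FYLD" in df.columns and "DM" in df.columns:
        df["DYLD"] = df["FYLD"] * df["DM"] / 100.0
        out.trait_registry["DYLD"] = {"units": "t/ha", "derivation": "derived"}
    for y, pct in (("gari_yield", "gari_pct"), ("fufu_yield", "fufu_pct")):
        if "FYLD" in df.columns and pct in df.columns:
            df[y] = df["FYLD"] * df[pct] / 100.0
            out.trait_registry[y] = {"units": "t/ha", "derivation": "derived"}

    out.df = df
    return out


def write_table(obj, path) -> None:
    """Write any tabular result to CSV with >= 10 significant digits.

    Accepts a :class:`PhenoTable`, a DataFrame, a Series, or any object with a
    ``to_frame`` method.  Column order is preserved; the file round-trips
    through :func:`read_pheno` / :func:`pandas.read_csv`.
    """
    if isinstance(obj, PhenoTable):
        frame = obj.df
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    elif isinstance(obj, pd.Series):
        frame = obj.to_frame()
    elif hasattr(obj, "to_frame"):
        frame = obj.to_frame()
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__} as a table")
    frame.to_csv(path, index=False, float_format="%.12g")
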