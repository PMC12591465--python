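"""Readers and writers for the tabular survey formats.

Two CSV dialects are understood:

* **site tables** — one row per sampling site with coordinates, basin,
  environmental covariates and the measured eDNA concentration (copies/L);
* **plate tables** — one row per qPCR well/channel with the well role
  (sample / standard / ntc / positive / field_blank), the Cq value (empty or
  "ND"/"Undetermined" meaning non-detect), the nominal standard concentration
  (copies/µl, standards only) and the site / water-replicate linkage.

Both are returned as pandas DataFrames with canonical lower-case column
names; header matching is case-insensitive with configurable aliases.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

SITE_COLUMNS = [
    "site_id",
    "latitude",
    "longitude",
    "basin",
    "water_temperature",
    "secchi_depth",
    "water_depth",
    "tds",
    "tsm",
    "chl_a",
    "edna_concentration",
]

#: default header aliases (canonical name -> accepted spellings, normalised)
SITE_ALIASES: dict[str, tuple[str, ...]] = {
    "site_id": ("site_id", "site", "id", "sampling_site", "station"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon", "long"),
    "basin": ("basin",),
    "water_temperature": (
        "water_temperature", "water_temp", "temperature", "temp",
        "water_temperature_c",
    ),
    "secchi_depth": ("secchi_depth", "secchi", "secchi_depth_m"),
    "water_depth": ("water_depth", "depth", "water_depth_m"),
    "tds": ("tds", "tds_mg_l", "total_dissolved_solids"),
    "tsm": ("tsm", "tsm_mg_l", "total_suspended_materials"),
    "chl_a": ("chl_a", "chla", "chl", "chlorophyll_a", "chl_a_ug_l"),
    "edna_concentration": (
        "edna_concentration", "edna", "concentration", "copies_per_l",
        "edna_copies_l", "edna_concentration_copies_l",
    ),
}

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "target",
    "cq",
    "nominal_copies_per_ul",
    "site_id",
    "water_rep",
]

VALID_ROLES = frozenset({"sample", "standard", "ntc", "positive", "field_blank"})
VALID_TARGETS = frozenset({"assay", "ipc"})

_NONDETECT_TOKENS = frozenset({"", "nd", "na", "nan", "undetermined", "none", "-"})


def _normalise(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(name).strip().lower()).strip("_")


def _map_columns(
    columns, aliases: dict[str, tuple[str, ...]]
) -> dict[str, str]:
    """Map raw header names onto canonical names via the alias table."""
    lookup = {}
    for canon, alts in aliases.items():
        for alt in alts:
            lookup.setdefault(_normalise(alt), canon)
    mapping = {}
    for col in columns:
        canon = lookup.get(_normalise(col))
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    return mapping


def read_site_table(
    path: str | Path, aliases: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Read a site table CSV into canonical columns.

    ``site_id`` and ``edna_concentration`` are mandatory; every other column
    is optional and missing cells become NaN. Zero concentrations are
    preserved as exact zeros (they are the non-detect sites).

    Raises
    ------
    ValueError
        On a missing mandatory column, a duplicated site_id, or a negative
        concentration (reported with its row number).
    """
    raw = pd.read_csv(path)
    mapping = _map_columns(raw.columns, aliases or SITE_ALIASES)
    df = raw.rename(columns=mapping)
    for mandatory in ("site_id", "edna_concentration"):
        if mandatory not in df.columns:
            raise ValueError(f"site table is missing mandatory column '{mandatory}'")
    df = df[[c for c in SITE_COLUMNS if c in df.columns]].copy()
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicated site_id '{dup}' in site table")
    conc = pd.to_numeric(df["edna_concentration"], errors="coerce")
    if conc.isna().any():
        row = int(np.where(conc.isna())[0][0]) + 2  # +2: header + 1-based
        raise ValueError(f"non-numeric eDNA concentration at row {row}")
    if (conc < 0).any():
        row = int(np.where(conc < 0)[0][0]) + 2
        raise ValueError(f"negative eDNA concentration at row {row}")
    df["edna_concentration"] = conc.astype(float)
    for col in df.columns:
        if col not in ("site_id", "basin", "edna_concentration"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.reset_index(drop=True)


def _parse_cq(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    token = str(value).strip().lower()
    if token in _NONDETECT_TOKENS:
        return np.nan
    return float(value)


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate CSV into canonical columns.

    Cq is parsed as a float with NaN marking non-detect wells. Raises
    ``ValueError`` for unknown role values or standards without a nominal
    concentration.
    """
    raw = pd.read_csv(raw_path := path)
    mapping = {c: _normalise(c) for c in raw.columns}
    df = raw.rename(columns=mapping)
    missing = {"well", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"plate table {raw_path} missing columns {sorted(missing)}")
    df["role"] = df["role"].astype(str).str.strip().str.lower()
    bad = set(df["role"]) - VALID_ROLES
    if bad:
        raise ValueError(f"unknown well role(s) {sorted(bad)}; expected {sorted(VALID_ROLES)}")
    if "target" in df.columns:
        df["target"] = df["target"].astype(str).str.strip().str.lower()
        bad_t = set(df["target"]) - VALID_TARGETS
        if bad_t:
            raise ValueError(f"unknown target channel(s) {sorted(bad_t)}")
    else:
        df["target"] = "assay"
    df["cq"] = df["cq"].map(_parse_cq) if "cq" in df.columns else np.nan
    for col in PLATE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "nominal_copies_per_ul" else pd.NA
    df["nominal_copies_per_ul"] = pd.to_numeric(
        df["nominal_copies_per_ul"], errors="coerce"
    )
    standards = df["role"] == "standard"
    if (standards & (df["target"] == "assay") & df["nominal_copies_per_ul"].isna()).any():
        raise ValueError("standard well without a nominal concentration (copies/µl)")
    if "plate_id" in mapping.values():
        df["plate_id"] = df["plate_id"].astype(str)
    else:
        df["plate_id"] = Path(path).stem
    return df[PLATE_COLUMNS].reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 CSV with '.' decimals (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
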