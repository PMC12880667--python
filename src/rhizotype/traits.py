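"""Derived root/shoot traits and genotype-level aggregation.

Derived quantities, computed per plant from the raw image/biomass columns:

- specific root length  SRL = total root length / root dry mass  [m g-1]
- root mass fraction    RMF = root mass / (root mass + shoot mass)
- lateral root length   LRL = length in diameter classes 2 + 3   [mm]
- lateral root fraction LRF = LRL / total root length
- total biomass         root mass + shoot mass                   [g]
- root-to-shoot ratio   root mass / shoot mass

Raw lengths are assumed to be in millimetres (the scanner-software
convention); SRL converts to metres per gram.  Rows with missing or zero
denominators yield missing derived values, never errors.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import ID_COLUMNS

__all__ = [
    "DERIVED_TRAITS",
    "REQUIRED_RAW_COLUMNS",
    "derive_traits",
    "genotype_means",
]

REQUIRED_RAW_COLUMNS = [
    "total_root_length",
    "root_length_diam2",
    "root_length_diam3",
    "root_dry_biomass",
    "shoot_dry_biomass",
]

DERIVED_TRAITS = [
    "specific_root_length",
    "root_mass_fraction",
    "lateral_root_length",
    "lateral_root_fraction",
    "total_biomass",
    "root_to_shoot_ratio",
]

_MM_PER_M = 1000.0


def _safe_div(num: pd.Series, den: pd.Series) -> pd.Series:
    den = den.where(den != 0)
    return num / den


def derive_traits(
    table: pd.DataFrame,
    length_unit: str = "mm",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Append the derived trait columns to a per-plant table.

    ``column_map`` renames raw export headers (e.g. RhizoVision Explorer's)
    to the canonical names in :data:`REQUIRED_RAW_COLUMNS` before deriving.
    Idempotent: derived columns are recomputed from raw columns each call.
    """
    if length_unit not in ("mm", "m"):
        raise ValueError("length_unit must be 'mm' or 'm'")
    out = table.copy()
    if column_map:
        out = out.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_RAW_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"missing required raw columns: {missing}")

    to_m = 1.0 if length_unit == "m" else 1.0 / _MM_PER_M
    trl, rm, sm = out["total_root_length"], out["root_dry_biomass"], out["shoot_dry_biomass"]
    out["specific_root_length"] = _safe_div(trl * to_m, rm)
    out["total_biomass"] = rm + sm
    out["root_mass_fraction"] = _safe_div(rm, rm + sm)
    out["root_to_shoot_ratio"] = _safe_div(rm, sm)
    out["lateral_root_length"] = out["root_length_diam2"] + out["root_length_diam3"]
    out["lateral_root_fraction"] = _safe_div(out["lateral_root_length"], trl)
    return out


def genotype_means(
    table: pd.DataFrame,
    traits: Sequence[str] | None = None,
    by_block: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype x trait matrix of means plus the per-cell sample sizes.

    Plants flagged culled are excluded.  By default plants are pooled across
    blocks (robust to unequal culling); ``by_block=True`` instead averages
    block means.  Cells with zero surviving observations are missing (n=0).
    """
    if table.empty:
        raise ValueError("empty table")
    if traits is None:
        traits = [c for c in table.columns if c not in ID_COLUMNS]
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValueError(f"traits not in table: {missing}")
    data = table
    if "culled" in table.columns:
        data = table.loc[~table["culled"].astype(bool)]
    sub = data[["genotype", "block"] + list(traits)]
    n = sub.groupby("genotype")[list(traits)].count()
    if by_block:
        block_means = sub.groupby(["genotype", "block"])[list(traits)].mean()
        means = block_means.groupby("genotype").mean()
    else:
        means = sub.groupby("genotype")[list(traits)].mean()
    return means, n
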