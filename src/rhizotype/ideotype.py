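"""Root-shoot quadrant ideotype classification from percentile ranks.

Each genotype is ranked per trait on a 0-100 percentile scale
(``100 * rank / n`` with average ranks for ties, so ranks are invariant to
monotone rescaling of the trait).  A genotype whose percentile exceeds the
threshold (default 50) on *every* designated root trait has a BIG root
system; at or below on every root trait, SMALL; otherwise MIXED — and
likewise for the shoot traits.  The combinations map to quadrants:

    I   big root,  big shoot       II  big root,  small shoot
    III small root, small shoot    IV  small root, big shoot

A genotype MIXED on either side is UNASSIGNED and receives a nearest-group
resemblance: the quadrant supported by the majority of its per-trait
big/small indicators, with per-side ties broken by the mean signed distance
of that side's percentiles from the threshold.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUADRANTS",
    "DEFAULT_ROOT_TRAITS",
    "DEFAULT_SHOOT_TRAITS",
    "FIVE_TRAIT_SHOOT_SET",
    "percentile_ranks",
    "assign_quadrants",
    "nearest_group",
]

QUADRANTS = ["I", "II", "III", "IV", "UNASSIGNED"]

#: Six-trait classification set (methods convention): three root, three shoot.
DEFAULT_ROOT_TRAITS = ["root_dry_biomass", "total_root_length", "root_convex_area"]
DEFAULT_SHOOT_TRAITS = ["shoot_dry_biomass", "shoot_convex_area", "shoot_height"]
#: Five-trait variant (results convention) drops shoot height.
FIVE_TRAIT_SHOOT_SET = ["shoot_dry_biomass", "shoot_convex_area"]


def percentile_ranks(
    matrix: pd.DataFrame, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-trait percentile ranks in (0, 100]: 100 * rank / n, average ties.

    Missing values stay missing; n counts the non-missing genotypes for that
    trait.  All-missing traits are excluded with a warning.
    """
    if traits is None:
        traits = list(matrix.columns)
    traits = list(traits)
    missing_cols = [t for t in traits if t not in matrix.columns]
    if missing_cols:
        raise ValueError(f"traits not in matrix: {missing_cols}")
    out = {}
    for t in traits:
        x = matrix[t].to_numpy(float)
        ok = np.isfinite(x)
        if ok.sum() < 2:
            warnings.warn(f"trait {t!r} has <2 non-missing values; excluded", stacklevel=2)
            continue
        pct = np.full(len(x), np.nan)
        pct[ok] = 100.0 * stats.rankdata(x[ok], method="average") / ok.sum()
        out[t] = pct
    return pd.DataFrame(out, index=matrix.index)


def _side_status(pct_row: pd.Series, traits: Sequence[str], threshold: float) -> str:
    vals = pct_row[list(traits)]
    if vals.isna().any():
        return "MIXED"
    if (vals > threshold).all():
        return "BIG"
    if (vals <= threshold).all():
        return "SMALL"
    return "MIXED"


_QUADRANT_OF = {
    ("BIG", "BIG"): "I",
    ("BIG", "SMALL"): "II",
    ("SMALL", "SMALL"): "III",
    ("SMALL", "BIG"): "IV",
}


def _majority_side(pct_row: pd.Series, traits: Sequence[str], threshold: float) -> str:
    """BIG/SMALL vote over one side's traits, mean-distance tie-break."""
    vals = pct_row[list(traits)].dropna()
    if vals.empty:
        return "SMALL"
    big = int((vals > threshold).sum())
    small = len(vals) - big
    if big != small:
        return "BIG" if big > small else "SMALL"
    return "BIG" if float(vals.mean()) > threshold else "SMALL"


def nearest_group(
    pct_row: pd.Series,
    root_traits: Sequence[str],
    shoot_traits: Sequence[str],
    threshold: float = 50.0,
) -> str:
    """Quadrant an unassigned genotype most resembles."""
    root = _majority_side(pct_row, root_traits, threshold)
    shoot = _majority_side(pct_row, shoot_traits, threshold)
    return _QUADRANT_OF[(root, shoot)]


def assign_quadrants(
    percentiles: pd.DataFrame,
    root_traits: Sequence[str] = DEFAULT_ROOT_TRAITS,
    shoot_traits: Sequence[str] = DEFAULT_SHOOT_TRAITS,
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-genotype quadrant assignment from a percentile table.

    Returns a DataFrame indexed by genotype with columns root_status,
    shoot_status, quadrant, resembles (NONE unless UNASSIGNED) and
    missing_data (True when any classification trait is missing).
    """
    root_traits, shoot_traits = list(root_traits), list(shoot_traits)
    if not root_traits or not shoot_traits:
        raise ValueError("root_traits and shoot_traits must be nonempty")
    overlap = set(root_traits) & set(shoot_traits)
    if overlap:
        raise ValueError(f"root and shoot trait sets overlap: {sorted(overlap)}")
    all_traits = root_traits + shoot_traits
    absent = [t for t in all_traits if t not in percentiles.columns]
    if absent:
        raise ValueError(f"classification traits missing from percentile table: {absent}")

    rows = []
    for gid, row in percentiles.iterrows():
        root = _side_status(row, root_traits, threshold)
        shoot = _side_status(row, shoot_traits, threshold)
        quadrant = _QUADRANT_OF.get((root, shoot), "UNASSIGNED")
        resembles = (
            nearest_group(row, root_traits, shoot_traits, threshold)
            if quadrant == "UNASSIGNED"
            else "NONE"
        )
        rows.append(
            {
                "genotype": gid,
                "root_status": root,
                "shoot_status": shoot,
                "quadrant": quadrant,
                "resembles": resembles,
                "missing_data": bool(row[all_traits].isna().any()),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
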