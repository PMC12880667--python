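"""Culling sensitivity check: drop heavily culled plots, re-analyze, compare.

Male culling leaves plots with unequal plant counts; plots that lost four or
more plants are dominated by one or two survivors and extra growing space.
The check removes such plots entirely, re-runs the per-trait genotype tests
and heritability, and reports which traits changed significance status,
the per-trait Spearman correlation of genotype rankings before/after, and
the per-trait H2 shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SensitivityReport",
    "filter_culled_plots",
    "compare_significance",
    "truncated_poisson_exclusion_probability",
]


@dataclass
class SensitivityReport:
    excluded_plot_fraction: float
    traits_lost_significance: list[str]
    traits_gained_significance: list[str]
    traits_stable_significant: list[str]
    traits_stable_nonsignificant: list[str]
    ranking_correlation: pd.Series | None = None  # Spearman rho per trait
    heritability_shift: pd.Series | None = None  # filtered H2 - full H2

    def status(self) -> pd.DataFrame:
        rows = (
            [(t, "lost") for t in self.traits_lost_significance]
            + [(t, "gained") for t in self.traits_gained_significance]
            + [(t, "stable-significant") for t in self.traits_stable_significant]
            + [(t, "stable-nonsignificant") for t in self.traits_stable_nonsignificant]
        )
        return pd.DataFrame(rows, columns=["trait", "status"]).set_index("trait")


def filter_culled_plots(
    table: pd.DataFrame, culled_counts: pd.DataFrame, threshold: int = 4
) -> tuple[pd.DataFrame, float]:
    """Remove whole plots whose culled count is >= threshold.

    ``culled_counts`` has columns genotype, block, culled_count (the
    simulator's truth table or a user-supplied per-plot count file).
    Returns the filtered table and the excluded-plot fraction.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    for col in ("genotype", "block", "culled_count"):
        if col not in culled_counts.columns:
            raise ValueError(f"culled_counts missing column {col!r}")
    bad = culled_counts.loc[culled_counts["culled_count"] >= threshold, ["genotype", "block"]]
    fraction = len(bad) / len(culled_counts) if len(culled_counts) else 0.0
    if bad.empty:
        return table.copy(), fraction
    bad_keys = set(map(tuple, bad.to_numpy()))
    mask = [
        (g, b) not in bad_keys for g, b in zip(table["genotype"], table["block"])
    ]
    return table.loc[mask].reset_index(drop=True), fraction


def compare_significance(
    full_results: pd.DataFrame,
    filtered_results: pd.DataFrame,
    alpha: float = 0.05,
    full_means: pd.DataFrame | None = None,
    filtered_means: pd.DataFrame | None = None,
) -> SensitivityReport:
    """Classify each trait's genotype-effect significance change.

    Both inputs are heritability tables (columns trait, p_value, H2) over the
    same trait list; genotype-mean matrices, when given, add per-trait
    Spearman ranking correlations.
    """
    full = full_results.set_index("trait")
    filt = filtered_results.set_index("trait")
    diff = set(full.index).symmetric_difference(filt.index)
    if diff:
        raise ValueError(f"trait lists differ: {sorted(diff)}")
    lost, gained, stable_sig, stable_ns = [], [], [], []
    for t in full.index:
        sig_full = full.loc[t, "p_value"] < alpha
        sig_filt = filt.loc[t, "p_value"] < alpha
        if sig_full and not sig_filt:
            lost.append(t)
        elif not sig_full and sig_filt:
            gained.append(t)
        elif sig_full:
            stable_sig.append(t)
        else:
            stable_ns.append(t)

    rho = None
    if full_means is not None and filtered_means is not None:
        shared = full_means.index.intersection(filtered_means.index)
        vals = {}
        for t in full.index:
            if t in full_means.columns and t in filtered_means.columns:
                x = full_means.loc[shared, t]
                y = filtered_means.loc[shared, t]
                ok = x.notna() & y.notna()
                if ok.sum() >= 3:
                    vals[t] = float(stats.spearmanr(x[ok], y[ok]).statistic)
        rho = pd.Series(vals, name="spearman_rho")

    dh2 = None
    if "H2" in full.columns and "H2" in filt.columns:
        dh2 = (filt["H2"] - full["H2"]).rename("delta_H2")

    excluded = float(full_results.attrs.get("excluded_plot_fraction", np.nan))
    return SensitivityReport(
        excluded_plot_fraction=excluded,
        traits_lost_significance=lost,
        traits_gained_significance=gained,
        traits_stable_significant=stable_sig,
        traits_stable_nonsignificant=stable_ns,
        ranking_correlation=rho,
        heritability_shift=dh2,
    )


def truncated_poisson_exclusion_probability(
    rate: float, n_plants_per_plot: int, threshold: int = 4
) -> float:
    """P(min(Poisson(rate), n_plants-1) >= threshold) — the expected
    excluded-plot fraction under the simulator's culling model."""
    cap = n_plants_per_plot - 1
    if threshold > cap:
        return 0.0
    # min(X, cap) >= threshold  <=>  X >= threshold (threshold <= cap)
    return float(stats.poisson.sf(threshold - 1, rate))
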