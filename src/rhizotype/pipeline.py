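"""End-to-end pipeline: simulate/load -> derive -> analyze -> report.

Stage order: trait derivation; per-trait genotype ANOVA, variance components
and broad-sense heritability; pairwise trait correlations on genotype means;
quadrant ideotype classification; PCA + K-means with bootstrap Jaccard
stability and quadrant concordance; and, when per-plot culling counts are
available, the heavy-culling sensitivity re-analysis.  All stage outputs are
delimited text plus one machine-readable JSON run summary; identical config
and seed give an identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    SimulationConfig,
    apply_culling,
    default_trial_config,
    read_trial_csv,
    simulate_trial,
    true_heritability,
    write_ground_truth,
    write_trial_csv,
)
from .traits import DERIVED_TRAITS, derive_traits, genotype_means
from .variance import heritability_table
from .correlation import bivariate_regression, correlation_matrix
from .ideotype import (
    DEFAULT_ROOT_TRAITS,
    DEFAULT_SHOOT_TRAITS,
    assign_quadrants,
    percentile_ranks,
)
from .clustering import bootstrap_jaccard, concordance, standardize_and_pca
from .sensitivity import compare_significance, filter_culled_plots

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("rhizotype")


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "csv"
    trial_csv: str | None = None
    culled_counts_csv: str | None = None
    out_dir: str = "rhizotype_out"
    seed: int = 0
    # analysis
    analysis_traits: list[str] | None = None  # None -> all trait columns
    alpha: float = 0.05
    vc_method: str = "REML"
    vc_scale: str = "plot_means"
    # classification
    root_traits: list[str] = field(default_factory=lambda: list(DEFAULT_ROOT_TRAITS))
    shoot_traits: list[str] = field(default_factory=lambda: list(DEFAULT_SHOOT_TRAITS))
    quadrant_threshold: float = 50.0
    # clustering
    k_list: list[int] = field(default_factory=lambda: [3, 4])
    n_boot: int = 100
    n_starts: int = 25
    # sensitivity
    culling_threshold: int = 4
    # synthetic mode
    culling_rate: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv":
            if not self.trial_csv or not Path(self.trial_csv).exists():
                raise FileNotFoundError(f"trial_csv not found: {self.trial_csv}")
            if self.culled_counts_csv and not Path(self.culled_counts_csv).exists():
                raise FileNotFoundError(
                    f"culled_counts_csv not found: {self.culled_counts_csv}"
                )


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage %-14s rows in=%d out=%d", name, n_in, n_out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle under ``out_dir``.

    Returns the run summary (also written as run_summary.json).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    # --- input ---------------------------------------------------------
    counts = None
    if config.mode == "synthetic":
        sim = default_trial_config(seed=config.seed, culling_rate=config.culling_rate)
        raw = simulate_trial(sim)
        table, counts = apply_culling(raw, sim.culling_rate, sim)
        write_trial_csv(table, out / "trial.csv")
        counts.to_csv(out / "culled_counts.csv", index=False)
        write_ground_truth(sim, out / "ground_truth.csv")
        summary["stages"]["simulate"] = {
            "rows_before_culling": len(raw),
            "rows_after_culling": len(table),
            "true_H2": true_heritability(sim).round(6).to_dict(),
        }
    else:
        table = read_trial_csv(config.trial_csv)
        if config.culled_counts_csv:
            counts = pd.read_csv(config.culled_counts_csv)
        summary["stages"]["load"] = {"rows": len(table)}

    # --- derive --------------------------------------------------------
    derived = derive_traits(table)
    derived.to_csv(out / "derived.csv", index=False)
    _stage("derive", len(table), len(derived))

    id_cols = {"genotype", "block", "plant", "culled"}
    traits = config.analysis_traits or [c for c in derived.columns if c not in id_cols]
    summary["stages"]["derive"] = {"n_traits": len(traits), "derived": DERIVED_TRAITS}

    # --- variance / heritability --------------------------------------
    herit = heritability_table(derived, traits, method=config.vc_method, scale=config.vc_scale)
    herit.to_csv(out / "heritability.csv", index=False)
    n_sig = int((herit["p_value"] < config.alpha).sum())
    _stage("heritability", len(derived), len(herit))
    summary["stages"]["heritability"] = {
        "n_traits": len(herit),
        "n_significant": n_sig,
        "H2": dict(zip(herit["trait"], herit["H2"].round(6))),
    }

    # --- genotype means and correlations ------------------------------
    means, nobs = genotype_means(derived, traits)
    means.to_csv(out / "genotype_means.csv")
    corr = correlation_matrix(means, traits)
    corr.R.round(6).to_csv(out / "correlation_R.csv")
    corr.P.to_csv(out / "correlation_P.csv")
    corr.N.to_csv(out / "correlation_N.csv")
    _stage("correlate", len(means), len(traits))
    reg = bivariate_regression("root_dry_biomass", "shoot_dry_biomass", means)
    summary["stages"]["correlate"] = {
        "n_genotypes": len(means),
        "r_root_shoot_biomass": round(
            float(corr.R.loc["root_dry_biomass", "shoot_dry_biomass"]), 6
        ),
        "regression_root_vs_shoot": {
            "slope": round(reg.slope, 6),
            "intercept": round(reg.intercept, 6),
            "r": round(reg.r, 6),
        },
    }

    # --- ideotype classification --------------------------------------
    class_traits = config.root_traits + config.shoot_traits
    pct = percentile_ranks(means, class_traits)
    quads = assign_quadrants(
        pct, config.root_traits, config.shoot_traits, config.quadrant_threshold
    )
    pd.concat([pct.round(3), quads], axis=1).to_csv(out / "quadrants.csv")
    qcounts = quads["quadrant"].value_counts().to_dict()
    _stage("classify", len(means), len(quads))
    summary["stages"]["classify"] = {
        "root_traits": config.root_traits,
        "shoot_traits": config.shoot_traits,
        "threshold": config.quadrant_threshold,
        "quadrant_counts": {q: int(qcounts.get(q, 0)) for q in ["I", "II", "III", "IV", "UNASSIGNED"]},
    }

    # --- clustering and stability --------------------------------------
    pca = standardize_and_pca(means, traits)
    pca.scores.round(6).to_csv(out / "pca_scores.csv")
    cluster_summary = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for k in config.k_list:
        stab = bootstrap_jaccard(
            pca.scores,
            k,
            B=config.n_boot,
            n_starts=config.n_starts,
            seed=int(rng.integers(2**31)),
        )
        stab.labels.to_csv(out / f"clusters_k{k}.csv")
        ctab, ari = concordance(stab.labels, quads["quadrant"])
        ctab.to_csv(out / f"concordance_k{k}.csv")
        cluster_summary[f"k={k}"] = {
            "jaccard": [round(float(j), 4) for j in stab.jaccard],
            "dissolved": stab.dissolved.tolist(),
            "ari_vs_quadrants": round(ari, 6),
        }
    summary["stages"]["cluster"] = {
        "variance_explained": [round(float(v), 6) for v in pca.variance_explained[:5]],
        **cluster_summary,
    }

    # --- sensitivity ----------------------------------------------------
    if counts is not None:
        filtered, fraction = filter_culled_plots(derived, counts, config.culling_threshold)
        herit_f = heritability_table(
            filtered, traits, method=config.vc_method, scale=config.vc_scale
        )
        means_f, _ = genotype_means(filtered, traits)
        report = compare_significance(
            herit, herit_f, config.alpha, full_means=means, filtered_means=means_f
        )
        report.excluded_plot_fraction = fraction
        herit_f.to_csv(out / "heritability_filtered.csv", index=False)
        report.status().to_csv(out / "sensitivity_status.csv")
        _stage("sensitivity", len(derived), len(filtered))
        summary["stages"]["sensitivity"] = {
            "excluded_plot_fraction": round(fraction, 6),
            "lost": report.traits_lost_significance,
            "gained": report.traits_gained_significance,
            "median_ranking_rho": (
                round(float(report.ranking_correlation.median()), 6)
                if report.ranking_correlation is not None
                else None
            ),
        }

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
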