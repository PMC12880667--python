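"""Synthetic randomized-block phenotyping trials with known ground truth.

Simulates a multi-trait genotype panel grown in a randomized complete block
design, the setting of a greenhouse root/shoot phenomics trial: ``n_genotypes``
genotypes x ``n_blocks`` replicate blocks x ``n_plants_per_plot`` plants per
plot.  Each trait follows the additive model

    y[trait, ijk] = mu_t + g_i[t] + b_j[t] + e_ijk[t]

where the genotype effect vectors ``g_i`` are drawn from a multivariate normal
with covariance ``diag(sqrt(sigma2_g)) @ C_g @ diag(sqrt(sigma2_g))`` for a
genetic correlation matrix ``C_g``, block effects are independent univariate
normals, and plant-level residuals are multivariate normal across traits
(correlated residuals model the within-plant environmental coupling of root
and shoot size; see the residual_correlation field).

A dioecious crop adds a complication: male plants are culled after sex
expression, removing on average a couple of plants per plot and leaving
unequal stand sizes.  :func:`apply_culling` models this with a truncated
Poisson count per plot, capped so at least one plant survives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_trial",
    "apply_culling",
    "true_heritability",
    "sigma2_e_for_h2",
    "default_trial_config",
    "write_trial_csv",
    "read_trial_csv",
    "write_ground_truth",
    "ID_COLUMNS",
]

#: Identifier columns of the standard trial table, in order.
ID_COLUMNS = ["genotype", "block", "plant", "culled"]

_PSD_TOL = 1e-8


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated randomized-block trial.

    Variances are on the plant level; ``genetic_correlation`` must be a
    symmetric positive-semidefinite matrix with unit diagonal over
    ``trait_names``.  ``residual_correlation=None`` (default) reuses the
    genetic correlation structure for plant-level residuals; pass an identity
    matrix for trait-independent noise.
    """

    n_genotypes: int
    n_blocks: int
    n_plants_per_plot: int
    trait_names: Sequence[str]
    trait_means: Sequence[float]
    sigma2_g: Sequence[float]
    sigma2_b: Sequence[float]
    sigma2_e: Sequence[float]
    genetic_correlation: np.ndarray | None = None
    residual_correlation: np.ndarray | None = None
    culling_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.trait_names)
        if self.genetic_correlation is None:
            self.genetic_correlation = np.eye(p)
        self.genetic_correlation = np.asarray(self.genetic_correlation, float)
        for name in ("trait_means", "sigma2_g", "sigma2_b", "sigma2_e"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (p,):
                raise ValueError(f"{name} must have one entry per trait ({p})")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2 (heritability divides by r)")
        if self.n_plants_per_plot < 1:
            raise ValueError("n_plants_per_plot must be >= 1")
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        for name in ("sigma2_g", "sigma2_b", "sigma2_e"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.culling_rate < 0:
            raise ValueError("culling_rate must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        _check_correlation(self.genetic_correlation, len(self.trait_names), "genetic_correlation")
        if self.residual_correlation is not None:
            self.residual_correlation = np.asarray(self.residual_correlation, float)
            _check_correlation(
                self.residual_correlation, len(self.trait_names), "residual_correlation"
            )

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _check_correlation(C: np.ndarray, p: int, name: str) -> None:
    if C.shape != (p, p):
        raise ValueError(f"{name} must be {p}x{p}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -_PSD_TOL:
        raise ValueError(
            f"{name} is not positive semidefinite (min eigenvalue {eigmin:.3g})"
        )


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix for sampling (eigen-based)."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Draw one trial table under ``config``; deterministic given the seed.

    Returns a DataFrame with columns genotype, block, plant, culled and one
    column per trait; row count = n_genotypes * n_blocks * n_plants_per_plot.
    Culling is *not* applied here — see :func:`apply_culling`.
    """
    config.validate()
    G, B, P, T = (
        config.n_genotypes,
        config.n_blocks,
        config.n_plants_per_plot,
        config.n_traits,
    )
    # Independent substreams so that e.g. re-running culling with a different
    # rate leaves the simulated effects untouched.
    ss = np.random.SeedSequence(config.seed)
    ss_g, ss_b, ss_e, _ss_cull, ss_miss = ss.spawn(5)

    sd_g = np.sqrt(config.sigma2_g)
    Lg = _mvn_factor(config.genetic_correlation)
    g_eff = np.random.default_rng(ss_g).standard_normal((G, T)) @ Lg.T * sd_g

    b_eff = np.random.default_rng(ss_b).standard_normal((B, T)) * np.sqrt(config.sigma2_b)

    C_e = (
        config.genetic_correlation
        if config.residual_correlation is None
        else config.residual_correlation
    )
    Le = _mvn_factor(C_e)
    resid = np.random.default_rng(ss_e).standard_normal((G * B * P, T)) @ Le.T * np.sqrt(
        config.sigma2_e
    )

    gi, bj, pk = np.meshgrid(np.arange(G), np.arange(B), np.arange(P), indexing="ij")
    gi, bj, pk = gi.ravel(), bj.ravel(), pk.ravel()
    values = config.trait_means + g_eff[gi] + b_eff[bj] + resid

    if config.missing_rate > 0:
        mask = np.random.default_rng(ss_miss).random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    out = pd.DataFrame(
        {
            "genotype": [f"G{i + 1:03d}" for i in gi],
            "block": [f"B{j + 1}" for j in bj],
            "plant": pk + 1,
            "culled": False,
        }
    )
    out[list(config.trait_names)] = values
    return out


def _culling_stream(seed_or_config) -> np.random.Generator:
    if isinstance(seed_or_config, SimulationConfig):
        return np.random.default_rng(np.random.SeedSequence(seed_or_config.seed).spawn(5)[3])
    return np.random.default_rng(seed_or_config)


def apply_culling(
    table: pd.DataFrame,
    culling_rate: float,
    seed: int | SimulationConfig = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove male plants at random from each genotype x block plot.

    The number removed per plot is ``min(Poisson(culling_rate), n_plants - 1)``
    so at least one plant always survives.  Passing the
    :class:`SimulationConfig` as ``seed`` uses its dedicated culling
    substream.

    Returns ``(surviving table, counts)`` where counts has columns genotype,
    block, culled_count — the per-plot tally consumed by the sensitivity
    analysis.
    """
    if culling_rate < 0:
        raise ValueError("culling_rate must be >= 0")
    rng = _culling_stream(seed)
    keep = np.ones(len(table), dtype=bool)
    records = []
    for (g, b), idx in table.groupby(["genotype", "block"], sort=True).indices.items():
        n = len(idx)
        k = 0
        if culling_rate > 0:
            k = min(int(rng.poisson(culling_rate)), n - 1)
            if k > 0:
                culled_idx = rng.choice(idx, size=k, replace=False)
                keep[culled_idx] = False
        records.append({"genotype": g, "block": b, "culled_count": k})
    counts = pd.DataFrame.from_records(records)
    survivors = table.loc[keep].reset_index(drop=True)
    return survivors, counts


def sigma2_e_for_h2(
    h2: float, sigma2_g: float, n_blocks: int, n_plants_per_plot: int
) -> float:
    """Plant-level residual variance giving broad-sense heritability ``h2``.

    Uses the plot-mean convention H2 = s2g / (s2g + s2e_plot / r) with
    s2e_plot = s2e_plant / n_plants_per_plot.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    return n_plants_per_plot * n_blocks * sigma2_g * (1.0 / h2 - 1.0)


def true_heritability(config: SimulationConfig) -> pd.Series:
    """Per-trait H2 implied by the config (plot-mean residual convention)."""
    s2e_plot = config.sigma2_e / config.n_plants_per_plot
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = config.sigma2_g / (config.sigma2_g + s2e_plot / config.n_blocks)
    return pd.Series(h2, index=list(config.trait_names), name="H2")


# --- default trial emulating the hemp panel study conditions ----------------

#: (mean, genetic CV, H2, factor loading) per raw trait.  Lengths mm, masses
#: g, areas mm^2.  Loadings define a one-factor "plant size" correlation
#: structure (guaranteed PSD); root and shoot biomass load at 0.95 each so
#: their genetic correlation is ~0.9.  H2 values follow the reported
#: heritabilities for this kind of panel (root length 0.63, shoot biomass
#: 0.77, ...); unreported ones sit in the same moderate range.
_DEFAULT_TRAITS: dict[str, tuple[float, float, float, float]] = {
    "total_root_length": (25000.0, 0.25, 0.63, 0.85),
    "root_length_diam2": (8000.0, 0.25, 0.60, 0.80),
    "root_length_diam3": (4000.0, 0.25, 0.55, 0.75),
    "root_dry_biomass": (0.50, 0.30, 0.70, 0.95),
    "shoot_dry_biomass": (5.0, 0.30, 0.77, 0.95),
    "root_convex_area": (150000.0, 0.25, 0.64, 0.80),
    "shoot_convex_area": (200000.0, 0.25, 0.66, 0.85),
    "shoot_height": (900.0, 0.15, 0.50, 0.70),
    "root_max_depth": (600.0, 0.15, 0.55, 0.60),
    "root_crown_width": (300.0, 0.20, 0.45, 0.60),
    "lower_root_area": (30000.0, 0.30, 0.51, 0.65),
    "avg_root_diameter": (0.50, 0.10, 0.50, -0.30),
    "shoot_width_depth_ratio": (0.40, 0.20, 0.45, -0.20),
}


def default_trial_config(seed: int = 0, culling_rate: float = 2.0) -> SimulationConfig:
    """Config emulating the study design: 46 genotypes x 3 blocks x 5 plants,
    ~2 plants culled per plot, one-factor size-driven trait correlations."""
    names = list(_DEFAULT_TRAITS)
    means = np.array([v[0] for v in _DEFAULT_TRAITS.values()])
    cvs = np.array([v[1] for v in _DEFAULT_TRAITS.values()])
    h2s = np.array([v[2] for v in _DEFAULT_TRAITS.values()])
    lam = np.array([v[3] for v in _DEFAULT_TRAITS.values()])

    C = np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)

    s2g = (cvs * means) ** 2
    n_blocks, n_plants = 3, 5
    s2e = np.array(
        [sigma2_e_for_h2(h, g, n_blocks, n_plants) for h, g in zip(h2s, s2g)]
    )
    s2b = 0.25 * s2g  # block heterogeneity, not stated by the study; modest
    return SimulationConfig(
        n_genotypes=46,
        n_blocks=n_blocks,
        n_plants_per_plot=n_plants,
        trait_names=names,
        trait_means=means,
        sigma2_g=s2g,
        sigma2_b=s2b,
        sigma2_e=s2e,
        genetic_correlation=C,
        culling_rate=culling_rate,
        seed=seed,
    )


# --- trial CSV dialect ------------------------------------------------------


def write_trial_csv(table: pd.DataFrame, path) -> None:
    """Write the standard trial CSV (genotype, block, plant, culled, traits)."""
    cols = ID_COLUMNS + [c for c in table.columns if c not in ID_COLUMNS]
    table[cols].to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial CSV missing identifier columns: {missing}")
    table["culled"] = table["culled"].astype(bool)
    return table


def write_ground_truth(config: SimulationConfig, path) -> None:
    """Companion ground-truth table: per-trait variance components and H2."""
    truth = pd.DataFrame(
        {
            "trait": list(config.trait_names),
            "sigma2_g": config.sigma2_g,
            "sigma2_b": config.sigma2_b,
            "sigma2_e": config.sigma2_e,
            "H2": true_heritability(config).to_numpy(),
        }
    )
    truth.to_csv(path, index=False)
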