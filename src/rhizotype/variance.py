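"""Genotype-effect tests, variance components and broad-sense heritability.

The design is genotype x replicate block.  Two model fits serve two purposes:

1. *Significance*: an F-test of the genotype effect with genotype fixed and
   block controlled, on plant-level data (nested least-squares models;
   denominator df = N - G - B + 1, exact for balanced designs).
2. *Heritability*: genotype and block as random effects to obtain variance
   components, by REML (default) or by the balanced expected-mean-squares
   (EMS) closed form, then

       H2 = sigma2_g / (sigma2_g + sigma2_e / r)

   with r the number of replicate blocks.  By default components are
   estimated on genotype-by-block *plot means*, so the residual is plot-level
   and r divides it exactly once — the precision of a genotype mean over r
   blocks.  ``scale="plants"`` fits plant-level data instead (then sigma2_e
   is the plant residual and the same formula yields a different, stricter
   convention; the components carry their scale so results are unambiguous).

Negative EMS solutions are truncated to zero and flagged.  REML maximizes the
restricted likelihood of the two-way crossed random model directly (L-BFGS-B
on log-variances with analytic gradients, warm-started at the EMS solution);
on balanced data it reproduces the EMS closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "AnovaResult",
    "HeritabilityResult",
    "plot_means",
    "fit_genotype_anova",
    "estimate_variance_components",
    "broad_sense_heritability",
    "heritability_table",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    r: int
    method: str  # "REML" or "EMS"
    scale: str = "plot_means"  # or "plants"
    truncated: bool = False

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_b", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (truncate negative estimates)")


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    F_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    H2: float
    components: VarianceComponents


def _clean(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    data = table
    if "culled" in table.columns:
        data = table.loc[~table["culled"].astype(bool)]
    data = data.loc[np.isfinite(data[trait])]
    return data


def plot_means(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Genotype x block plot means for one trait (culled plants excluded)."""
    data = _clean(table, trait)
    pm = data.groupby(["genotype", "block"], sort=True)[trait].mean().reset_index()
    return pm


# --- genotype F-test --------------------------------------------------------


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_genotype_anova(table: pd.DataFrame, trait: str) -> AnovaResult:
    """F-test for the genotype effect controlling for block (plant level).

    Compares the additive genotype+block least-squares fit against the
    block-only fit; identical to the mixed-model F with a between-within df
    approximation, and exact for balanced data.
    """
    data = _clean(table, trait)
    g_codes, g_levels = pd.factorize(data["genotype"], sort=True)
    b_codes, b_levels = pd.factorize(data["block"], sort=True)
    G, B, N = len(g_levels), len(b_levels), len(data)
    if G < 2 or B < 2:
        raise ValueError("need >= 2 genotypes and >= 2 blocks")
    y = data[trait].to_numpy(float)

    Zg = np.zeros((N, G - 1))
    Zg[np.arange(N)[g_codes > 0], g_codes[g_codes > 0] - 1] = 1.0
    Zb = np.zeros((N, B - 1))
    Zb[np.arange(N)[b_codes > 0], b_codes[b_codes > 0] - 1] = 1.0
    ones = np.ones((N, 1))

    rss_full = _rss(np.hstack([ones, Zg, Zb]), y)
    rss_red = _rss(np.hstack([ones, Zb]), y)
    df_num = G - 1
    df_den = N - G - B + 1
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")

    tss = float(np.var(y) * N)
    tol = 1e-12 * max(tss, 1.0)
    if rss_full <= tol and rss_red - rss_full <= tol:
        # constant trait: degenerate fit
        return AnovaResult(trait, 0.0, df_num, df_den, float("nan"))
    F = max(rss_red - rss_full, 0.0) / df_num / (rss_full / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(trait, float(F), df_num, df_den, p)


# --- variance components ----------------------------------------------------


def _design(data: pd.DataFrame, trait: str, scale: str):
    """Response vector and genotype/block index codes on the requested scale."""
    if scale == "plot_means":
        pm = data.groupby(["genotype", "block"], sort=True)[trait].mean().reset_index()
        y = pm[trait].to_numpy(float)
        g = pd.factorize(pm["genotype"], sort=True)[0]
        b = pd.factorize(pm["block"], sort=True)[0]
        n_per_plot = 1.0
    elif scale == "plants":
        y = data[trait].to_numpy(float)
        g = pd.factorize(data["genotype"], sort=True)[0]
        b = pd.factorize(data["block"], sort=True)[0]
        sizes = data.groupby(["genotype", "block"]).size().to_numpy(float)
        n_per_plot = stats.hmean(sizes)  # harmonic mean plot size
    else:
        raise ValueError("scale must be 'plot_means' or 'plants'")
    return y, g, b, n_per_plot


def _ems_components(y, g, b, n_per_plot: float):
    """Balanced-design expected-mean-squares (method-of-moments) solution.

    On plot means: sig2_g = (MS_G - MS_E)/r, sig2_b = (MS_B - MS_E)/G with
    MS_E the additive-model residual.  On plant level the genotype divisor is
    r * n_per_plot (harmonic-mean plot size if unbalanced).
    """
    G = int(g.max()) + 1
    B = int(b.max()) + 1
    N = len(y)
    grand = y.mean()
    gm = np.array([y[g == i].mean() for i in range(G)])
    bm = np.array([y[b == j].mean() for j in range(B)])
    ng = np.array([(g == i).sum() for i in range(G)], float)
    nb = np.array([(b == j).sum() for j in range(B)], float)
    ss_g = float(ng @ (gm - grand) ** 2)
    ss_b = float(nb @ (bm - grand) ** 2)
    # residual from the additive fixed-effects fit
    Zg = np.zeros((N, G - 1))
    Zg[np.arange(N)[g > 0], g[g > 0] - 1] = 1.0
    Zb = np.zeros((N, B - 1))
    Zb[np.arange(N)[b > 0], b[b > 0] - 1] = 1.0
    ss_e = _rss(np.hstack([np.ones((N, 1)), Zg, Zb]), y)
    df_e = N - G - B + 1
    ms_g = ss_g / (G - 1)
    ms_b = ss_b / (B - 1)
    ms_e = ss_e / df_e
    k_g = B * n_per_plot  # replicates per genotype mean
    k_b = G * n_per_plot
    s2g = (ms_g - ms_e) / k_g
    s2b = (ms_b - ms_e) / k_b
    return s2g, s2b, ms_e


def _reml_neg2ll_and_grad(theta, y, Zg, Zb, X):
    s2g, s2b, s2e = np.exp(theta)
    n = len(y)
    V = s2g * (Zg @ Zg.T) + s2b * (Zb @ Zb.T) + s2e * np.eye(n)
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    P = Vinv - XtVinv.T @ np.linalg.solve(XtVinvX, XtVinv)
    Py = P @ y
    neg2ll = logdetV + logdetX + float(y @ Py)
    grads = []
    for Z in (Zg, Zb, None):
        if Z is None:
            PV = P
            VPy = Py
        else:
            PZ = P @ Z
            PV = PZ @ Z.T
            VPy = Z @ (Z.T @ Py)
        d = np.trace(PV) - float(Py @ VPy)
        grads.append(d)
    grad = np.array(grads) * np.exp(theta)  # chain rule for log-variances
    return neg2ll, grad


def _reml_components(y, g, b):
    G = int(g.max()) + 1
    B = int(b.max()) + 1
    n = len(y)
    Zg = np.zeros((n, G))
    Zg[np.arange(n), g] = 1.0
    Zb = np.zeros((n, B))
    Zb[np.arange(n), b] = 1.0
    X = np.ones((n, 1))
    vy = float(np.var(y))
    if vy == 0:
        return 0.0, 0.0, 0.0
    floor = 1e-10 * vy
    # EMS warm start: standard method-of-moments initialization for REML
    s2g0, s2b0, s2e0 = _ems_components(y, g, b, 1.0)
    x0 = np.log(np.clip([s2g0, s2b0, s2e0], max(1e-4 * vy, floor * 10), None))
    bounds = [(np.log(floor), np.log(1e4 * vy + floor))] * 3
    res = optimize.minimize(
        _reml_neg2ll_and_grad,
        x0,
        args=(y, Zg, Zb, X),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    s2 = np.exp(res.x)
    s2[s2 <= 10 * floor] = 0.0  # boundary solutions are zero components
    return float(s2[0]), float(s2[1]), float(s2[2])


def estimate_variance_components(
    table: pd.DataFrame,
    trait: str,
    method: str = "REML",
    scale: str = "plot_means",
) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_b, sigma2_e) for one trait.

    ``method="REML"`` fits genotype and block as random effects by restricted
    maximum likelihood; ``method="EMS"`` uses the balanced expected-mean-
    squares closed form (with a warning and harmonic-mean plot sizes when the
    data are unbalanced).  Negative EMS solutions truncate to 0 and are
    flagged.
    """
    method = method.upper()
    if method not in ("REML", "EMS"):
        raise ValueError("method must be 'REML' or 'EMS'")
    data = _clean(table, trait)
    y, g, b, n_per_plot = _design(data, trait, scale)
    r = int(b.max()) + 1
    if int(g.max()) + 1 < 2 or r < 2:
        raise ValueError("need >= 2 genotypes and >= 2 blocks")

    if method == "EMS":
        if scale == "plants":
            sizes = data.groupby(["genotype", "block"]).size()
            if sizes.nunique() > 1:
                warnings.warn(
                    "unbalanced plot sizes: EMS uses harmonic-mean plot size",
                    stacklevel=2,
                )
        s2g, s2b, s2e = _ems_components(y, g, b, n_per_plot if scale == "plants" else 1.0)
        truncated = s2g < 0 or s2b < 0
        return VarianceComponents(
            max(s2g, 0.0), max(s2b, 0.0), max(s2e, 0.0), r, "EMS", scale, truncated
        )
    s2g, s2b, s2e = _reml_components(y, g, b)
    return VarianceComponents(s2g, s2b, s2e, r, "REML", scale, False)


def broad_sense_heritability(
    components: VarianceComponents, trait: str = ""
) -> HeritabilityResult:
    """H2 = sigma2_g / (sigma2_g + sigma2_e / r); missing when 0/0."""
    denom = components.sigma2_g + components.sigma2_e / components.r
    h2 = float("nan") if denom == 0 else components.sigma2_g / denom
    return HeritabilityResult(trait, h2, components)


def heritability_table(
    table: pd.DataFrame,
    traits: Sequence[str],
    method: str = "REML",
    scale: str = "plot_means",
) -> pd.DataFrame:
    """Per-trait ANOVA + variance components + H2 as one results table."""
    rows = []
    for trait in traits:
        an = fit_genotype_anova(table, trait)
        vc = estimate_variance_components(table, trait, method=method, scale=scale)
        h2 = broad_sense_heritability(vc, trait)
        rows.append(
            {
                "trait": trait,
                "F": an.F_statistic,
                "df_num": an.df_numerator,
                "df_den": an.df_denominator,
                "p_value": an.p_value,
                "sigma2_g": vc.sigma2_g,
                "sigma2_b": vc.sigma2_b,
                "sigma2_e": vc.sigma2_e,
                "r": vc.r,
                "H2": h2.H2,
                "method": vc.method,
                "scale": vc.scale,
                "truncated": vc.truncated,
            }
        )
    return pd.DataFrame(rows)
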