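"""Pairwise Pearson correlations with significance, and bivariate OLS fits.

Correlations are computed on pairwise-complete observations (each pair uses
exactly the rows where both traits are present); p-values come from the
t transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom,
two-sided.  By convention the input is the genotype-mean matrix (n = number
of genotypes); plant-level tables work identically and the level is up to
the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "RegressionResult", "correlation_matrix", "bivariate_regression"]

MIN_PAIRS = 3


@dataclass
class CorrelationResult:
    traits: list[str]
    R: pd.DataFrame  # Pearson coefficients
    P: pd.DataFrame  # two-sided p-values (diagonal 0)
    N: pd.DataFrame  # pairwise-complete sample sizes


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def _pearson_p(r: float, n: int) -> float:
    if n < MIN_PAIRS or not np.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlation_matrix(
    matrix: pd.DataFrame, traits: Sequence[str] | None = None
) -> CorrelationResult:
    """Symmetric Pearson R, p-value and sample-size matrices over traits.

    Zero-variance traits get missing correlations (with a warning); pairs
    with fewer than three complete observations are missing.
    """
    if traits is None:
        traits = [c for c in matrix.columns if np.issubdtype(matrix[c].dtype, np.number)]
    traits = list(traits)
    missing = [t for t in traits if t not in matrix.columns]
    if missing:
        raise ValueError(f"traits not in matrix: {missing}")
    X = matrix[traits].to_numpy(float)
    p = len(traits)
    R = np.full((p, p), np.nan)
    P = np.full((p, p), np.nan)
    N = np.zeros((p, p), int)
    for i in range(p):
        for j in range(i, p):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(ok.sum())
            N[i, j] = N[j, i] = n
            if n < MIN_PAIRS:
                continue
            xi, xj = X[ok, i], X[ok, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                if i == j and np.ptp(xi) == 0:
                    warnings.warn(f"trait {traits[i]!r} has zero variance", stacklevel=2)
                continue
            if i == j:
                R[i, i], P[i, i] = 1.0, 0.0
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = _pearson_p(r, n)
    idx = pd.Index(traits, name="trait")
    return CorrelationResult(
        traits,
        pd.DataFrame(R, index=idx, columns=traits),
        pd.DataFrame(P, index=idx, columns=traits),
        pd.DataFrame(N, index=idx, columns=traits),
    )


def bivariate_regression(
    x_trait: str, y_trait: str, matrix: pd.DataFrame
) -> RegressionResult:
    """OLS of y on x over complete pairs; r matches the correlation matrix."""
    for t in (x_trait, y_trait):
        if t not in matrix.columns:
            raise ValueError(f"trait {t!r} not in matrix")
    x = matrix[x_trait].to_numpy(float)
    y = matrix[y_trait].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    if np.ptp(x[ok]) == 0:
        raise ValueError(f"trait {x_trait!r} has zero variance")
    fit = stats.linregress(x[ok], y[ok])
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue), n
    )
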