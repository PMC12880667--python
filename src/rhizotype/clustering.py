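"""PCA, K-means, bootstrap Jaccard cluster stability, and concordance.

The genotype-mean trait matrix is z-scored column-wise, decomposed by PCA,
and clustered with K-means (best of ``n_starts`` initializations).  By
default K-means runs on the full set of PCA scores, which is an orthogonal
rotation of the z-scored data and therefore yields the same partition as
clustering the scaled matrix directly.

Cluster robustness is assessed clusterwise by bootstrap Jaccard stability:
for each bootstrap resample (drawn with replacement) the data are
re-clustered from scratch, and each original cluster is matched to the
bootstrap cluster with which it shares the largest Jaccard coefficient
J(A, B) = |A n B| / |A u B|, computed over the points present in the
resample.  The per-cluster stability is the mean of these maxima over
resamples; values near 1 indicate a robust cluster, values below 0.5 count
as "dissolved" in that resample.  Agreement between the K-means partition
and the quadrant ideotype groups is summarized by a contingency table and
the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "PCAResult",
    "ClusterStabilityResult",
    "standardize_and_pca",
    "kmeans_cluster",
    "bootstrap_jaccard",
    "concordance",
]

DISSOLUTION_THRESHOLD = 0.5


@dataclass
class PCAResult:
    scores: pd.DataFrame  # genotypes x components
    loadings: pd.DataFrame  # traits x components
    variance_explained: np.ndarray  # fraction per component, nonincreasing
    dropped_genotypes: list
    dropped_traits: list


@dataclass
class ClusterStabilityResult:
    k: int
    labels: pd.Series  # genotype -> cluster id
    jaccard: np.ndarray  # per-cluster mean bootstrap Jaccard
    dissolved: np.ndarray  # per-cluster dissolution counts (max J < 0.5)
    n_boot: int


def standardize_and_pca(
    matrix: pd.DataFrame, traits: Sequence[str] | None = None
) -> PCAResult:
    """Column-wise z-scores followed by a full PCA.

    Genotypes with any missing cell are dropped (and reported), as are
    constant traits.  Deterministic up to component sign.
    """
    if traits is None:
        traits = list(matrix.columns)
    traits = list(traits)
    absent = [t for t in traits if t not in matrix.columns]
    if absent:
        raise ValueError(f"traits not in matrix: {absent}")
    X = matrix[traits]
    all_missing = [t for t in traits if X[t].isna().all()]
    if all_missing:
        raise ValueError(f"all-missing traits: {all_missing}")
    keep_rows = X.notna().all(axis=1)
    dropped_genotypes = list(X.index[~keep_rows])
    if dropped_genotypes:
        warnings.warn(
            f"dropping {len(dropped_genotypes)} genotypes with missing cells",
            stacklevel=2,
        )
    X = X.loc[keep_rows]
    stds = X.std(ddof=0)
    dropped_traits = list(stds.index[stds == 0])
    if dropped_traits:
        warnings.warn(f"dropping constant traits: {dropped_traits}", stacklevel=2)
        X = X.drop(columns=dropped_traits)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 genotypes and >= 2 non-constant traits")
    Z = (X - X.mean()) / X.std(ddof=0)
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=Z.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=Z.columns, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
        dropped_genotypes=dropped_genotypes,
        dropped_traits=dropped_traits,
    )


def kmeans_cluster(
    X: np.ndarray | pd.DataFrame, k: int, n_starts: int = 25, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Best-of-``n_starts`` K-means: labels and within-cluster sum of squares."""
    arr = np.asarray(X, float)
    if k < 1 or k > len(arr):
        raise ValueError(f"k={k} invalid for {len(arr)} points")
    if k > len(np.unique(arr, axis=0)):
        raise ValueError("k exceeds the number of distinct points")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(arr)
    return labels, float(km.inertia_)


def _jaccard_max(original: np.ndarray, boot_labels: np.ndarray, present: np.ndarray) -> float:
    """Max Jaccard of one original cluster against all bootstrap clusters,
    both restricted to the points present in the resample."""
    A = set(np.flatnonzero(original)) & set(present)
    if not A:
        return float("nan")
    best = 0.0
    for c in np.unique(boot_labels):
        Bc = set(present[boot_labels == c])
        inter = len(A & Bc)
        union = len(A | Bc)
        if union and inter / union > best:
            best = inter / union
    return best


def bootstrap_jaccard(
    X: np.ndarray | pd.DataFrame,
    k: int,
    B: int = 100,
    n_starts: int = 25,
    seed: int = 0,
) -> ClusterStabilityResult:
    """Clusterwise bootstrap Jaccard stability of a K-means partition.

    Each resample is re-clustered with fresh random starts (the original
    solution is never reused as initialization).  Per cluster: the mean over
    resamples of the maximum Jaccard overlap with any bootstrap cluster,
    plus a count of resamples where that maximum fell below 0.5 (cluster
    "dissolved").
    """
    if B < 20:
        raise ValueError("B must be >= 20")
    arr = np.asarray(X, float)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(arr))
    n = len(arr)
    rng = np.random.default_rng(seed)
    labels, _ = kmeans_cluster(arr, k, n_starts=n_starts, seed=int(rng.integers(2**31)))

    sums = np.zeros(k)
    counts = np.zeros(k, int)
    dissolved = np.zeros(k, int)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        present = np.unique(idx)
        boot_seed = int(rng.integers(2**31))
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=boot_seed)
        boot_fit = km.fit(arr[idx])
        # label each distinct resampled point by its cluster assignment
        present_labels = km.predict(arr[present])
        for c in range(k):
            j = _jaccard_max(labels == c, present_labels, present)
            if np.isfinite(j):
                sums[c] += j
                counts[c] += 1
                if j < DISSOLUTION_THRESHOLD:
                    dissolved[c] += 1
    with np.errstate(invalid="ignore"):
        stability = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(dissolved > B / 2):
        warnings.warn(
            f"cluster(s) dissolved in >50% of resamples: {np.flatnonzero(dissolved > B / 2)}",
            stacklevel=2,
        )
    return ClusterStabilityResult(
        k=k,
        labels=pd.Series(labels, index=index, name="cluster"),
        jaccard=stability,
        dissolved=dissolved,
        n_boot=B,
    )


def concordance(
    cluster_labels: pd.Series, quadrant_labels: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index between two labelings.

    Both labelings must cover a shared genotype set; only the intersection
    is compared.
    """
    shared = cluster_labels.index.intersection(quadrant_labels.index)
    if len(shared) == 0:
        raise ValueError("no shared genotypes between labelings")
    a = cluster_labels.loc[shared]
    b = quadrant_labels.loc[shared]
    table = pd.crosstab(a, b)
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    return table, ari
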