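"""Data-driven K-means parcellation with subset-reproducibility validation.

Voxel (or vertex) time series are standardized and clustered with K-means;
reproducibility is assessed by splitting the data into disjoint subsets,
parcellating each, matching clusters one-to-one by maximum overlap
(Hungarian assignment) and averaging the per-cluster Dice coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = ["ParcellationResult", "kmeans_parcellate", "matched_dice", "subset_reproducibility"]


@dataclass
class ParcellationResult:
    """K-means labeling of voxels: labels in [0, k), inertia, seed."""

    labels: np.ndarray
    k: int
    inertia: float
    seed: int
    excluded: np.ndarray | None = None  # indices of zero-variance voxels, label -1


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (standardized rows, mask of valid rows)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[valid] = (X[valid] - mu[valid]) / sd[valid]
    return Xs, valid


def kmeans_parcellate(
    voxel_series: np.ndarray, k: int, n_init: int = 10, seed: int = 0,
    refine_to: int | None = None,
) -> ParcellationResult:
    """Cluster voxel time series into k parcels.

    Each voxel series is z-scored before clustering; the best of ``n_init``
    restarts by inertia is kept and the result is deterministic under a fixed
    seed. Constant (zero-variance) voxels are excluded with a warning and
    labeled -1.

    ``refine_to`` optionally runs a second clustering stage within each of
    the k networks, subdividing them into a total of ``refine_to`` parcels
    (region-level refinement of the network-level solution).
    """
    X = np.asarray(voxel_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("voxel_series must be 2-D (voxels x time)")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    Xs, valid = _standardize_rows(X)
    n_valid = int(valid.sum())
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} zero-variance voxel(s)", RuntimeWarning
        )
    if n_valid < k:
        raise ValueError(f"only {n_valid} usable voxels for k={k}")

    if n_valid == k:
        # degenerate: each voxel its own cluster
        labels = np.full(X.shape[0], -1, dtype=int)
        labels[valid] = np.arange(k)
        return ParcellationResult(labels, k, 0.0, seed, np.flatnonzero(~valid))

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    fit_labels = km.fit_predict(Xs[valid])
    labels = np.full(X.shape[0], -1, dtype=int)
    labels[valid] = fit_labels
    inertia = float(km.inertia_)

    if refine_to is not None:
        if refine_to < k:
            raise ValueError("refine_to must be >= k")
        labels = _refine_within_networks(Xs, labels, k, refine_to, seed)
        inertia = float("nan")  # inertia of the two-stage labeling is not comparable
        k = refine_to
    return ParcellationResult(labels, k, inertia, seed, np.flatnonzero(~valid))


def _refine_within_networks(
    Xs: np.ndarray, labels: np.ndarray, k: int, total: int, seed: int
) -> np.ndarray:
    """Subdivide each network into sub-parcels, proportionally to size."""
    sizes = np.array([(labels == c).sum() for c in range(k)])
    sub_k = np.maximum(1, np.round(total * sizes / sizes.sum()).astype(int))
    while sub_k.sum() > total:
        sub_k[np.argmax(sub_k)] -= 1
    while sub_k.sum() < total:
        sub_k[np.argmax(sizes / sub_k)] += 1
    out = np.full(labels.shape, -1, dtype=int)
    offset = 0
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if sub_k[c] == 1 or len(idx) <= sub_k[c]:
            out[idx] = offset + (np.arange(len(idx)) % sub_k[c])
        else:
            km = KMeans(n_clusters=int(sub_k[c]), n_init=5, random_state=seed + c)
            out[idx] = offset + km.fit_predict(Xs[idx])
        offset += int(sub_k[c])
    return out


def matched_dice(labelsA: np.ndarray, labelsB: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-cluster Dice after optimal one-to-one cluster matching.

    Clusters of the two labelings are matched by maximizing total overlap
    (bipartite assignment), then Dice_c = 2|A∩B|/(|A|+|B|) per matched pair.
    Returns (per-cluster Dice in A's matched order, mean Dice). Voxels
    labeled -1 (excluded) are ignored.
    """
    a = np.asarray(labelsA)
    b = np.asarray(labelsB)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same voxel universe")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    ka, kb = len(np.unique(a)), len(np.unique(b))
    if ka != kb:
        raise ValueError(f"cluster counts differ: {ka} vs {kb}")
    cats_a = np.unique(a)
    cats_b = np.unique(b)
    overlap = np.zeros((ka, kb))
    for ia, ca in enumerate(cats_a):
        for ib, cb in enumerate(cats_b):
            overlap[ia, ib] = np.sum((a == ca) & (b == cb))
    row, col = linear_sum_assignment(-overlap)
    dice = np.zeros(ka)
    for ia, ib in zip(row, col):
        na = np.sum(a == cats_a[ia])
        nb = np.sum(b == cats_b[ib])
        dice[ia] = 2.0 * overlap[ia, ib] / (na + nb)
    return dice, float(dice.mean())


def subset_reproducibility(
    voxel_series: np.ndarray,
    k: int,
    n_subsets: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> float:
    """Mean pairwise matched Dice of parcellations over disjoint data subsets.

    The timepoint axis is split into ``n_subsets`` contiguous blocks (when a
    3-D subjects x voxels x time array is given, the split is by subjects
    instead); each subset is parcellated independently and all subset pairs
    are compared with :func:`matched_dice`.
    """
    X = np.asarray(voxel_series, dtype=float)
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if X.ndim == 3:
        if X.shape[0] < n_subsets:
            raise ValueError(f"{X.shape[0]} subjects cannot form {n_subsets} subsets")
        groups = np.array_split(np.arange(X.shape[0]), n_subsets)
        subsets = [np.concatenate([X[i] for i in g], axis=1) for g in groups]
    elif X.ndim == 2:
        if X.shape[1] < 2 * n_subsets:
            raise ValueError(
                f"{X.shape[1]} timepoints are too few to split into {n_subsets} subsets"
            )
        blocks = np.array_split(np.arange(X.shape[1]), n_subsets)
        subsets = [X[:, b] for b in blocks]
    else:
        raise ValueError("voxel_series must be 2-D or 3-D")
    labelings = [
        kmeans_parcellate(S, k, n_init=n_init, seed=seed + i).labels
        for i, S in enumerate(subsets)
    ]
    dices = [matched_dice(la, lb)[1] for la, lb in combinations(labelings, 2)]
    return float(np.mean(dices))
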