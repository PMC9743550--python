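"""Distances, KD-tree data compression, deterministic seeding, and K-means.

K-means initialisation is fully deterministic: the data are first compressed
by a KD-tree (median splits on the widest-spread dimension until leaves hold
at most a configured fraction of the observations); each leaf becomes a
weighted "box" represented by its centroid. The first seed is the box
centroid sitting at a given percentile of the weighted distance distribution
from the global centroid; the second repeats the procedure from the first
seed; seeds three and up take the box at the percentile of the Euclidean
orthogonal distance to the affine subspace spanned by the seeds already
chosen. The subsequent Lloyd iterations use the configured metric
(correlation distance by default — 1 minus Pearson correlation, insensitive
to multiplicative intensity scaling) with arithmetic-mean centroid updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import LabelVector

log = logging.getLogger(__name__)

#: shapes (rows_a, rows_b) of every pairwise-distance evaluation, recorded so
#: large runs can be audited for accidental O(n^2) work
PAIRWISE_SHAPE_LOG: list[tuple[int, int]] = []

#: distance assigned from a constant (zero-variance) vector to anything else
#: under the correlation metric, where Pearson correlation is undefined
CONSTANT_VECTOR_DISTANCE = 2.0


class DegenerateVectorError(ValueError):
    """Raised for correlation distance on a constant vector."""


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus the Pearson correlation of two vectors; range [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("correlation distance needs vectors of length >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise DegenerateVectorError("correlation undefined for a constant vector")
    return float(1.0 - (ac @ bc) / (na * nb))


def _center_normalise(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centre and L2-normalise; flag zero-variance rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return xc / norms[:, None], degenerate


def pairwise_distances(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """All pairwise distances between rows of ``a`` and rows of ``b``.

    Under the correlation metric, rows with zero variance are maximally
    dissimilar (distance 2) from everything.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    PAIRWISE_SHAPE_LOG.append((a.shape[0], b.shape[0]))
    if metric == "euclidean":
        return cdist(a, b, "euclidean")
    if metric == "correlation":
        an, a_bad = _center_normalise(a)
        bn, b_bad = _center_normalise(b)
        d = 1.0 - an @ bn.T
        if a_bad.any():
            d[a_bad, :] = CONSTANT_VECTOR_DISTANCE
        if b_bad.any():
            d[:, b_bad] = CONSTANT_VECTOR_DISTANCE
        return np.clip(d, 0.0, 2.0)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class BoxSummary:
    """KD-tree leaves summarised as weighted boxes of observations."""

    centroids: np.ndarray
    weights: np.ndarray
    member_index: list[np.ndarray]

    @property
    def n_boxes(self) -> int:
        return self.centroids.shape[0]


@dataclass
class SeedSet:
    """Deterministically chosen initial centroids."""

    seeds: np.ndarray
    source_boxes: list[int]
    percentile: float

    @property
    def k(self) -> int:
        return self.seeds.shape[0]


@dataclass
class SplitResult:
    """Outcome of one K-means run."""

    labels: LabelVector
    centroids: np.ndarray
    k: int
    n_iter: int
    dunn: float | None = None


def kdtree_compress(m: np.ndarray, leaf_fraction: float) -> BoxSummary:
    """Compress observations into KD-tree leaf boxes.

    The tree splits on the dimension with the widest value range, at the
    median (stable argsort halves, so ties are deterministic), until a leaf
    holds at most ``ceil(leaf_fraction * n_obs)`` observations.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("matrix must be non-empty and 2-D")
    n_obs = m.shape[0]
    if not 0 < leaf_fraction <= 1:
        raise ValueError("leaf_fraction must be in (0, 1]")
    capacity = max(1, int(np.ceil(leaf_fraction * n_obs)))
    leaves: list[np.ndarray] = []
    stack = [np.arange(n_obs)]
    while stack:
        idx = stack.pop()
        if idx.size <= capacity:
            leaves.append(np.sort(idx))
            continue
        sub = m[idx]
        spread = sub.max(axis=0) - sub.min(axis=0)
        dim = int(np.argmax(spread))
        if spread[dim] == 0:  # all points identical: cannot separate further
            leaves.append(np.sort(idx))
            continue
        order = np.argsort(sub[:, dim], kind="stable")
        half = idx.size // 2
        stack.append(idx[order[half:]])
        stack.append(idx[order[:half]])
    leaves.sort(key=lambda ix: int(ix[0]))
    centroids = np.vstack([m[ix].mean(axis=0) for ix in leaves])
    weights = np.array([ix.size for ix in leaves], dtype=int)
    return BoxSummary(centroids=centroids, weights=weights, member_index=leaves)


def _weighted_percentile_box(
    distances: np.ndarray, weights: np.ndarray, percentile: float, eligible: np.ndarray
) -> int:
    """Box index at the given percentile of the weighted distance CDF.

    Nearest-rank rule on the distance-ascending order; ties in distance are
    broken by the lower box index.
    """
    idx = np.flatnonzero(eligible)
    order = idx[np.lexsort((idx, distances[idx]))]
    cum = np.cumsum(weights[order])
    target = percentile / 100.0 * cum[-1]
    pos = int(np.searchsorted(cum, target, side="left"))
    pos = min(pos, order.size - 1)
    return int(order[pos])


def _subspace_distances(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Euclidean orthogonal distance from each point to the affine hull of seeds."""
    origin = seeds[0]
    basis = (seeds[1:] - origin).T  # (n_feat, j-1)
    q, r = np.linalg.qr(basis)
    # drop numerically null directions
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(np.diag(r)).max(initial=0.0))
    q = q[:, keep]
    rel = points - origin
    proj = rel @ q @ q.T
    return np.linalg.norm(rel - proj, axis=1)


def select_seeds(
    boxes: BoxSummary, k: int, percentile: float, metric: str
) -> SeedSet:
    """Pick ``k`` deterministic seeds from box centroids (see module docs)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > boxes.n_boxes:
        raise ValueError(f"k={k} exceeds the number of boxes ({boxes.n_boxes})")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    total_w = boxes.weights.sum()
    global_centroid = (boxes.weights[:, None] * boxes.centroids).sum(axis=0) / total_w

    chosen: list[int] = []
    eligible = np.ones(boxes.n_boxes, dtype=bool)

    d1 = pairwise_distances(boxes.centroids, global_centroid[None, :], metric)[:, 0]
    first = _weighted_percentile_box(d1, boxes.weights, percentile, eligible)
    chosen.append(first)
    eligible[first] = False

    if k >= 2:
        d2 = pairwise_distances(
            boxes.centroids, boxes.centroids[first][None, :], metric
        )[:, 0]
        second = _weighted_percentile_box(d2, boxes.weights, percentile, eligible)
        chosen.append(second)
        eligible[second] = False

    while len(chosen) < k:
        seeds = boxes.centroids[chosen]
        d = _subspace_distances(boxes.centroids, seeds)
        if np.all(d[eligible] < 1e-12):
            # degenerate geometry (collinear boxes): fall back to the CDF of
            # the metric distance to the nearest already-chosen seed
            d = pairwise_distances(boxes.centroids, seeds, metric).min(axis=1)
            log.debug("collinear boxes; nearest-seed distance fallback for seed %d",
                      len(chosen) + 1)
        nxt = _weighted_percentile_box(d, boxes.weights, percentile, eligible)
        chosen.append(nxt)
        eligible[nxt] = False

    return SeedSet(
        seeds=boxes.centroids[chosen].copy(), source_boxes=chosen, percentile=percentile
    )


def kmeans(
    m: np.ndarray,
    seeds: SeedSet | np.ndarray,
    metric: str = "correlation",
    max_iter: int = 300,
) -> SplitResult:
    """Lloyd's K-means from the given seeds under the configured metric.

    Assignment is nearest-centroid under ``metric``; the update is the
    arithmetic mean of the members. Iteration stops when no label changes.
    An emptied cluster is re-seeded at the observation farthest from its own
    current centroid (at most k repairs per iteration).
    """
    m = np.asarray(m, dtype=float)
    centroids = seeds.seeds.copy() if isinstance(seeds, SeedSet) else np.asarray(seeds, float).copy()
    k = centroids.shape[0]
    if k == 1:
        labels = np.zeros(m.shape[0], dtype=int)
        return SplitResult(LabelVector(labels), m.mean(axis=0, keepdims=True), 1, 0)

    labels = np.argmin(pairwise_distances(m, centroids, metric), axis=1)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = m[members].mean(axis=0)
        d = pairwise_distances(m, centroids, metric)
        new_labels = np.argmin(d, axis=1)
        # empty-cluster repair: grab the observation farthest from its centroid
        repairs = 0
        for c in range(k):
            if not np.any(new_labels == c) and repairs < k:
                own = d[np.arange(m.shape[0]), new_labels]
                farthest = int(np.argmax(own))
                new_labels[farthest] = c
                centroids[c] = m[farthest]
                repairs += 1
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    for c in range(k):  # final consistency of centroids with labels
        members = labels == c
        if members.any():
            centroids[c] = m[members].mean(axis=0)
    return SplitResult(LabelVector(labels), centroids, k, n_iter)
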