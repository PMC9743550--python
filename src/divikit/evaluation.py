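"""Segmentation quality against annotated regions of interest.

Unsupervised clusters rarely align one-to-one with pathologist-drawn regions
(ROIs), so evaluation starts with a label-normalisation step: for every ROI,
clusters are sorted by the fraction of their area covered by the ROI and
greedily accumulated while the Dice coefficient of the union keeps
improving; clusters claimed by several ROIs are disambiguated by choosing
the assignment scenario with the highest adjusted Rand index against the ROI
labelling. On top of that the module provides the standard agreement scores
(adjusted Rand, multi-cluster Dice), the combination of the three quality
indices (adjusted Rand, Dice, relative spatial-structure score) into the two
overall-quality distances d(0,0,0) and d(1,1,1), and average-rank
aggregation across methods and criteria.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

log = logging.getLogger(__name__)

OTHER = "other"
#: cap on enumerated assignment scenarios in the Rand disambiguation stage
MAX_SCENARIOS = 100_000


@dataclass
class RoiAnnotation:
    """Observation → ROI name mapping with a priority order of ROIs."""

    roi_of: np.ndarray  # array of ROI names, one per observation
    roi_names: list[str]  # processing priority, e.g. tumour first

    def __post_init__(self) -> None:
        self.roi_of = np.asarray(self.roi_of, dtype=object)
        present = set(self.roi_of.tolist())
        missing = present - set(self.roi_names) - {OTHER}
        if missing:
            raise ValueError(f"ROIs present but not listed: {sorted(missing)}")


@dataclass
class QualityReport:
    """All quality indices of one segmentation."""

    adjusted_rand: float
    dice_per_roi: dict[str, float]
    relative_exims: float
    d000: float
    d111: float

    def to_dict(self) -> dict:
        return {
            "adjusted_rand": self.adjusted_rand,
            "dice_per_roi": self.dice_per_roi,
            "relative_exims": self.relative_exims,
            "d000": self.d000,
            "d111": self.d111,
        }


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two labelings."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))


def dice(selected: np.ndarray, roi_mask: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two boolean masks."""
    inter = int(np.sum(selected & roi_mask))
    size = int(selected.sum()) + int(roi_mask.sum())
    return 2.0 * inter / size if size else 0.0


def greedy_dice_selection(
    clusters: np.ndarray, roi_mask: np.ndarray
) -> tuple[list[int], float]:
    """Greedily pick the cluster set whose union best matches the ROI.

    Clusters are sorted by descending fraction of their area inside the ROI
    (ties by cluster id) and added one at a time; a cluster is kept iff it
    strictly increases the Dice coefficient of the union with the ROI.
    """
    clusters = np.asarray(clusters)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        return [], 0.0
    ids = np.unique(clusters)
    coverage = []
    for c in ids:
        member = clusters == c
        coverage.append(np.sum(member & roi_mask) / member.sum())
    order = sorted(range(ids.size), key=lambda i: (-coverage[i], ids[i]))
    selected: list[int] = []
    union = np.zeros_like(roi_mask)
    best = 0.0
    for i in order:
        candidate = union | (clusters == ids[i])
        score = dice(candidate, roi_mask)
        if score > best:
            best = score
            union = candidate
            selected.append(int(ids[i]))
    return sorted(selected), best


def normalize_labels(
    clusters: np.ndarray, rois: RoiAnnotation
) -> dict[int, str]:
    """Map every cluster to an ROI name (or ``"other"``).

    ROIs claim clusters via greedy Dice selection, in priority order.
    Clusters claimed once are final; clusters claimed by several ROIs are
    resolved by enumerating assignment scenarios and keeping the one whose
    induced labelling maximises the adjusted Rand index against the ROI
    labelling. Unclaimed clusters map to ``"other"``.
    """
    clusters = np.asarray(clusters)
    claims: dict[int, list[str]] = {}
    for roi in rois.roi_names:
        selected, _ = greedy_dice_selection(clusters, rois.roi_of == roi)
        for c in selected:
            claims.setdefault(c, []).append(roi)

    assignment: dict[int, str] = {}
    ambiguous: list[int] = []
    for c in np.unique(clusters):
        c = int(c)
        options = claims.get(c, [])
        if len(options) == 1:
            assignment[c] = options[0]
        elif len(options) == 0:
            assignment[c] = OTHER
        else:
            ambiguous.append(c)

    if ambiguous:
        option_lists = [claims[c] for c in ambiguous]
        n_scenarios = int(np.prod([len(o) for o in option_lists]))
        if n_scenarios > MAX_SCENARIOS:
            log.warning(
                "%d assignment scenarios exceed the cap (%d); "
                "resolving greedily in priority order", n_scenarios, MAX_SCENARIOS
            )
            for c in ambiguous:
                assignment[c] = claims[c][0]
        else:
            truth = rois.roi_of
            best_score = -np.inf
            best_combo = None
            for combo in itertools.product(*option_lists):
                trial = dict(assignment)
                trial.update(dict(zip(ambiguous, combo)))
                induced = np.array([trial[int(c)] for c in clusters], dtype=object)
                score = adjusted_rand(induced, truth)
                if score > best_score:
                    best_score = score
                    best_combo = combo
            assignment.update(dict(zip(ambiguous, best_combo)))
    return assignment


def overall_quality(ari: float, dice_value: float, exims: float) -> tuple[float, float]:
    """Combine the three indices into d(0,0,0) and d(1,1,1).

    ``d(0,0,0)`` is the Euclidean norm of the (ARI, Dice, relative
    structure-score) triplet — higher is better; ``d(1,1,1)`` is its
    Euclidean distance to the ideal point (1,1,1) — lower is better.
    Inputs are clipped to [0, 1].
    """
    v = np.clip([ari, dice_value, exims], 0.0, 1.0)
    d000 = float(np.sqrt(np.sum(v**2)))
    d111 = float(np.sqrt(np.sum((1.0 - v) ** 2)))
    return d000, d111


def quality_report(
    clusters: np.ndarray,
    rois: RoiAnnotation,
    relative_exims: float = 1.0,
    primary_roi: str | None = None,
) -> QualityReport:
    """Full evaluation of a segmentation against ROI annotations.

    The adjusted Rand index is computed between the normalised cluster
    labelling and the ROI labelling; the Dice index entering the overall
    quality is the multi-cluster Dice of the primary ROI (the first in
    priority order unless stated otherwise). The relative structure score is
    supplied externally, clipped to [0, 1].
    """
    clusters = np.asarray(clusters)
    assignment = normalize_labels(clusters, rois)
    induced = np.array([assignment[int(c)] for c in clusters], dtype=object)
    ari = adjusted_rand(induced, rois.roi_of)
    dice_per_roi = {
        roi: greedy_dice_selection(clusters, rois.roi_of == roi)[1]
        for roi in rois.roi_names
    }
    primary = primary_roi or rois.roi_names[0]
    exims = float(np.clip(relative_exims, 0.0, 1.0))
    d000, d111 = overall_quality(ari, dice_per_roi[primary], exims)
    return QualityReport(
        adjusted_rand=ari,
        dice_per_roi=dice_per_roi,
        relative_exims=exims,
        d000=d000,
        d111=d111,
    )


def rank_summary(
    scores: np.ndarray, higher_is_better: list[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-criterion average ranks (1 = best) and per-method rank sums.

    ``scores`` has one row per method and one column per criterion; ties
    share the mean of the tied rank positions.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be methods × criteria")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must not contain missing values")
    if len(higher_is_better) != scores.shape[1]:
        raise ValueError("one orientation flag per criterion required")
    ranks = np.empty_like(scores)
    for j, better_high in enumerate(higher_is_better):
        col = -scores[:, j] if better_high else scores[:, j]
        ranks[:, j] = rankdata(col, method="average")
    return ranks, ranks.sum(axis=1)
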