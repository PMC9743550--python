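"""Core data containers for segmentation of observations × features matrices.

The central object is :class:`AbundanceMatrix`: a dense nonnegative matrix of
peak/feature abundances, one row per observation (e.g. one mass spectrum per
pixel), one column per feature (e.g. one m/z peak), with optional integer
pixel coordinates for imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class AbundanceMatrix:
    """Dense nonnegative observations × features abundance matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_obs, n_feat)`` with nonnegative abundances.
    feature_ids
        Unique feature identifiers (strings or m/z values), one per column.
    obs_ids
        Unique observation identifiers, one per row.
    coords
        Optional integer pixel coordinates, shape ``(n_obs, d)`` with
        ``d`` in {2, 3}.
    """

    values: np.ndarray
    feature_ids: list[str]
    obs_ids: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_obs, n_feat = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if len(self.feature_ids) != n_feat:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_feat} columns"
            )
        if len(self.obs_ids) != n_obs:
            raise ValidationError(f"{len(self.obs_ids)} obs ids for {n_obs} rows")
        if len(set(self.feature_ids)) != n_feat:
            raise ValidationError("feature_ids are not unique")
        if len(set(self.obs_ids)) != n_obs:
            raise ValidationError("obs_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("abundances must be nonnegative")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=int)
            if self.coords.ndim != 2 or self.coords.shape[0] != n_obs:
                raise ValidationError("coords must have one row per observation")
            if self.coords.shape[1] not in (2, 3):
                raise ValidationError("coords must be 2-D or 3-D pixel indices")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_feat(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        same_coords = (self.coords is None) == (other.coords is None) and (
            self.coords is None or np.array_equal(self.coords, other.coords)
        )
        return (
            np.array_equal(self.values, other.values)
            and self.feature_ids == other.feature_ids
            and self.obs_ids == other.obs_ids
            and same_coords
        )


@dataclass
class LabelVector:
    """Cluster assignment per observation.

    Labels are canonicalised to consecutive nonnegative integers starting at
    zero; ``names`` optionally maps each label to a human-readable name.
    """

    labels: np.ndarray
    names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be nonnegative")

    def canonicalised(self) -> "LabelVector":
        """Remap labels to consecutive integers 0..k-1, keeping first-seen order."""
        uniq, inverse = np.unique(self.labels, return_inverse=True)
        names = None
        if self.names is not None:
            names = {new: self.names[old] for new, old in enumerate(uniq) if old in self.names}
        return LabelVector(labels=inverse, names=names)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def canonical_labels_by_size(labels: Sequence[int], tiebreak: Sequence[str]) -> np.ndarray:
    """Relabel clusters by decreasing size; ties broken by the given keys.

    ``tiebreak`` provides one sort key per original label value, aligned with
    ``sorted(set(labels))``.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    sizes = {u: int(np.sum(labels == u)) for u in uniq}
    keys = dict(zip(uniq.tolist(), tiebreak))
    order = sorted(uniq.tolist(), key=lambda u: (-sizes[u], keys[u]))
    remap = {u: i for i, u in enumerate(order)}
    return np.array([remap[u] for u in labels], dtype=int)
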