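"""Synthetic abundance matrices with planted hierarchical structure.

The generator emulates the gross statistical shape of peak-picked imaging
mass-spectrometry data: log-normal-like positive abundances, a planted
hierarchy of clusters where each split is driven by its own disjoint subset
of "informative" features (shifted in log space by a fixed effect size), and
a majority of noise features that share one global mean. It exists so that
the feature filters, the homogeneity test, the cluster-number selection and
the full recursion can be exercised end-to-end with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AbundanceMatrix


@dataclass
class HierarchyNode:
    """One node of the planted hierarchy.

    A leaf carries ``n_obs`` observations. An internal node lists its
    children and the number of informative features (and the log10 effect
    size) that drive its split.
    """

    n_obs: int = 0
    children: list["HierarchyNode"] = field(default_factory=list)
    n_informative: int = 0
    effect: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def total_obs(self) -> int:
        if self.is_leaf:
            return self.n_obs
        return sum(c.total_obs() for c in self.children)


@dataclass
class HierarchySpec:
    """Full description of a synthetic dataset."""

    tree: HierarchyNode
    n_noise_features: int
    base_log_mean: float = 2.0
    log_sd: float = 0.25
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Generated matrix plus the planted ground truth."""

    matrix: AbundanceMatrix
    labels_by_level: dict[int, np.ndarray]  # level -> per-observation label
    leaf_labels: np.ndarray
    informative_features: dict[str, list[str]]  # split path -> feature ids


def _count_informative(node: HierarchyNode) -> int:
    if node.is_leaf:
        return 0
    return node.n_informative + sum(_count_informative(c) for c in node.children)


def generate(spec: HierarchySpec) -> SyntheticDataset:
    """Generate a matrix with the planted hierarchy of ``spec``.

    Log10 abundances are ``base_log_mean`` plus the sum of the split shifts
    along the observation's path plus N(0, log_sd) noise; abundances are
    ``10**`` of that, hence strictly positive. Each internal split partitions
    its own disjoint set of informative features into one exclusive block per
    child; a child's observations are shifted by ``+effect`` on its block
    only. Siblings therefore differ by a contrastive up-regulation pattern
    (the geometry correlation distance responds to), and the deeper a split
    sits in the hierarchy the smaller the fraction of all observations its
    features are elevated in — so sub-split features carry less global
    variance than top-split features and only become dominant once the
    recursion has isolated their branch, the regime the local variance
    filter is designed for.
    """
    rng = np.random.default_rng(spec.seed)
    n_obs = spec.tree.total_obs()
    if n_obs < 1:
        raise ValueError("hierarchy must contain at least one observation")
    n_informative = _count_informative(spec.tree)
    n_feat = spec.n_noise_features + n_informative

    log_means = np.full((n_obs, n_feat), spec.base_log_mean)
    leaf_labels = np.zeros(n_obs, dtype=int)
    labels_by_level: dict[int, np.ndarray] = {}
    informative: dict[str, list[str]] = {}
    feature_ids = [f"f{j}" for j in range(n_feat)]

    next_feature = [0]
    next_leaf = [0]
    next_obs = [0]

    def plant(node: HierarchyNode, path: str, level: int) -> np.ndarray:
        """Returns the observation indices below this node."""
        if node.is_leaf:
            idx = np.arange(next_obs[0], next_obs[0] + node.n_obs)
            next_obs[0] += node.n_obs
            leaf_labels[idx] = next_leaf[0]
            next_leaf[0] += 1
            return idx
        feats = np.arange(next_feature[0], next_feature[0] + node.n_informative)
        next_feature[0] += node.n_informative
        if next_feature[0] > n_feat:
            raise ValueError("informative features exceed the feature budget")
        informative[path] = [feature_ids[j] for j in feats]
        blocks = np.array_split(feats, len(node.children))
        all_idx = []
        for j, (child, block) in enumerate(zip(node.children, blocks)):
            idx = plant(child, f"{path}.{j}", level + 1)
            log_means[np.ix_(idx, block)] += node.effect
            all_idx.append(idx)
        return np.concatenate(all_idx)

    plant(spec.tree, "0", 0)
    labels_by_level = _labels_by_level(spec.tree, n_obs)

    noise = rng.normal(0.0, spec.log_sd, size=(n_obs, n_feat))
    values = 10.0 ** (log_means + noise)
    obs_ids = [f"obs{i}" for i in range(n_obs)]
    side = int(np.ceil(np.sqrt(n_obs)))
    coords = np.column_stack([np.arange(n_obs) // side, np.arange(n_obs) % side])
    matrix = AbundanceMatrix(values, feature_ids, obs_ids, coords=coords)
    return SyntheticDataset(
        matrix=matrix,
        labels_by_level=labels_by_level,
        leaf_labels=leaf_labels,
        informative_features=informative,
    )


def _labels_by_level(tree: HierarchyNode, n_obs: int) -> dict[int, np.ndarray]:
    """Per-level labels where each distinct ancestor path is its own label."""
    paths: list[list[str]] = [[] for _ in range(n_obs)]
    cursor = [0]

    def walk(node: HierarchyNode, path: str) -> None:
        if node.is_leaf:
            for i in range(cursor[0], cursor[0] + node.n_obs):
                paths[i] = path
            cursor[0] += node.n_obs
            return
        for j, child in enumerate(node.children):
            walk(child, f"{path}.{j}")

    walk(tree, "0")
    max_depth = max(p.count(".") for p in paths)
    out: dict[int, np.ndarray] = {}
    for level in range(1, max_depth + 1):
        trunc = [".".join(p.split(".")[: level + 1]) for p in paths]
        uniq = sorted(set(trunc))
        lut = {u: i for i, u in enumerate(uniq)}
        out[level] = np.array([lut[t] for t in trunc], dtype=int)
    return out


def two_level_benchmark(
    n_obs: int = 5000,
    n_features: int = 500,
    informative_fraction: float = 0.05,
    effect: float = 1.0,
    seed: int = 0,
    log_sd: float = 0.25,
) -> SyntheticDataset:
    """Standard two-level benchmark: three top blobs, one split into two.

    ``informative_fraction`` of the features drive each split (disjoint
    blocks); the remaining features are pure noise. Observations divide
    evenly over the top blobs and the first top blob splits evenly in two,
    so the sub-split's features are elevated in half as many observations
    as the top-split's — a nested signature that only dominates once its
    branch has been isolated.
    """
    n_inf = max(1, int(round(informative_fraction * n_features)))
    n_noise = n_features - 2 * n_inf
    if n_noise < 0:
        raise ValueError("informative features exceed the feature budget")
    n_a = n_obs // 3
    n_b = n_obs // 3
    n_c = n_obs - n_a - n_b
    tree = HierarchyNode(
        children=[
            HierarchyNode(
                children=[
                    HierarchyNode(n_obs=n_a // 2),
                    HierarchyNode(n_obs=n_a - n_a // 2),
                ],
                n_informative=n_inf,
                effect=effect,
            ),
            HierarchyNode(n_obs=n_b),
            HierarchyNode(n_obs=n_c),
        ],
        n_informative=n_inf,
        effect=effect,
    )
    return generate(
        HierarchySpec(
            tree=tree, n_noise_features=n_noise, log_sd=log_sd, seed=seed
        )
    )


def generate_noise_floor(
    n_obs: int,
    n_feat: int,
    low_mode_fraction: float,
    seed: int = 0,
    separation: float = 3.0,
    low_log_mean: float = 0.0,
    log_sd: float = 0.25,
) -> tuple[AbundanceMatrix, np.ndarray]:
    """Matrix whose features split into a low "noise" and a high "signal" mode.

    Per-feature log10 means sit at ``low_log_mean`` (with probability
    ``low_mode_fraction``) or ``low_log_mean + separation``; observations add
    N(0, log_sd) noise. Returns the matrix and the boolean "is low mode"
    ground truth per feature, the fixture for the global abundance filter.
    """
    if not 0 <= low_mode_fraction < 1:
        raise ValueError("low_mode_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    is_low = rng.random(n_feat) < low_mode_fraction
    means = np.where(is_low, low_log_mean, low_log_mean + separation)
    values = 10.0 ** (means[None, :] + rng.normal(0.0, log_sd, size=(n_obs, n_feat)))
    matrix = AbundanceMatrix(
        values,
        [f"f{j}" for j in range(n_feat)],
        [f"obs{i}" for i in range(n_obs)],
    )
    return matrix, is_low
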