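"""The recursive divisive driver.

Starting from the full dataset, each node of the recursion:

1. stops if the region is too small to split (or small enough under the
   alternative large-volume stop rule);
2. re-derives its own informative feature subset by the local variance
   filter over the globally surviving feature pool;
3. runs the subsampled GAP homogeneity test in that local feature space and
   stops if the region is homogeneous;
4. otherwise sweeps candidate cluster numbers, splits with deterministic
   K-means, and recurses into every child.

The result is a tree whose leaves partition the observations and whose every
node records the locally informative features, the chosen number of clusters
and the reason the recursion stopped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DivikConfig
from .data import AbundanceMatrix, LabelVector, canonical_labels_by_size
from .gmm_filter import abundance_filter, variance_filter
from .model_selection import is_homogeneous, select_k

log = logging.getLogger(__name__)

STOP_REASONS = ("homogeneous", "too_small", "no_valid_split", "max_depth")


@dataclass
class DivikNode:
    """One region of the recursion: either a leaf or a split into children."""

    node_id: str
    obs_index: np.ndarray
    feature_mask: np.ndarray  # over the globally surviving feature pool
    k: int | None = None
    children: list["DivikNode"] = field(default_factory=list)
    stop_reason: str | None = None
    dunn: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class DivikTree:
    """Full segmentation result."""

    root: DivikNode
    config: DivikConfig
    global_abundance_mask: np.ndarray  # over the original features
    feature_ids: list[str]
    obs_ids: list[str]

    def leaves(self) -> list[DivikNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def find(self, node_id: str) -> DivikNode:
        for node in self.root.walk():
            if node.node_id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")


def divik_fit(m: AbundanceMatrix, cfg: DivikConfig) -> DivikTree:
    """Run the full divisive segmentation on an abundance matrix."""
    if m.n_obs < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(cfg.rng_seed)

    if cfg.apply_global_abundance_filter:
        g_filter = abundance_filter(
            m.values, max_components=cfg.max_gmm_components, rng_seed=cfg.rng_seed
        )
        global_mask = g_filter.mask
        log.info(
            "global abundance filter: kept %d/%d features (threshold=%s)",
            g_filter.n_kept, m.n_feat, g_filter.chosen_threshold,
        )
    else:
        global_mask = np.ones(m.n_feat, dtype=bool)
    pool = m.values[:, global_mask]
    n_pool = pool.shape[1]

    def build(node_id: str, obs_index: np.ndarray, depth: int) -> DivikNode:
        n = obs_index.size
        sub = pool[obs_index]

        def leaf(reason: str, mask: np.ndarray | None = None) -> DivikNode:
            log.info(
                "node %s depth=%d size=%d -> leaf (%s)", node_id, depth, n, reason
            )
            if mask is None:
                mask = np.ones(n_pool, dtype=bool)
            return DivikNode(node_id, obs_index, mask, stop_reason=reason)

        if n < cfg.min_cluster_size:
            return leaf("too_small")
        if cfg.max_leaf_size_stop is not None and n <= cfg.max_leaf_size_stop:
            return leaf("too_small")
        if depth >= cfg.max_depth:
            return leaf("max_depth")

        v_filter = variance_filter(
            sub,
            cfg.min_feature_fraction,
            max_components=cfg.max_gmm_components,
            rng_seed=cfg.rng_seed,
        )
        mask = v_filter.mask
        local = sub[:, mask]

        decision = is_homogeneous(local, cfg, rng)
        if decision.homogeneous:
            log.info(
                "node %s depth=%d size=%d n_features=%d -> homogeneous "
                "(%d/%d votes)",
                node_id, depth, n, int(mask.sum()),
                decision.votes_homogeneous, decision.n_votes,
            )
            return leaf("homogeneous", mask)

        selection = select_k(local, cfg, rng)
        if selection is None:
            return leaf("no_valid_split", mask)
        ksel, split = selection
        log.info(
            "node %s depth=%d size=%d n_features=%d -> split k=%d dunn=%.4f",
            node_id, depth, n, int(mask.sum()), ksel.best_k, split.dunn,
        )
        node = DivikNode(
            node_id, obs_index, mask, k=ksel.best_k, dunn=split.dunn
        )
        labels = split.labels.labels
        for c in range(ksel.best_k):  # depth-first, children by ascending label
            child_index = obs_index[labels == c]
            node.children.append(build(f"{node_id}.{c}", child_index, depth + 1))
        return node

    root = build("0", np.arange(m.n_obs), 0)
    return DivikTree(
        root=root,
        config=cfg,
        global_abundance_mask=global_mask,
        feature_ids=list(m.feature_ids),
        obs_ids=list(m.obs_ids),
    )


def flat_labels(tree: DivikTree, depth: int | None = None) -> LabelVector:
    """Flatten the tree into one label per observation.

    ``depth=None`` labels by leaf; ``depth=d`` labels by the ancestor at
    depth ``min(d, leaf depth)``. Labels are canonicalised by decreasing
    cluster size, ties broken by node id.
    """
    n_obs = len(tree.obs_ids)
    raw = np.empty(n_obs, dtype=object)

    def assign(node: DivikNode, level: int) -> None:
        if node.is_leaf or (depth is not None and level >= depth):
            raw[node.obs_index] = node.node_id
            return
        for child in node.children:
            assign(child, level + 1)

    assign(tree.root, 0)
    node_ids = sorted(set(raw.tolist()))
    id_to_int = {nid: i for i, nid in enumerate(node_ids)}
    numeric = np.array([id_to_int[v] for v in raw], dtype=int)
    canonical = canonical_labels_by_size(numeric, tiebreak=node_ids)
    names = {}
    for nid, i in id_to_int.items():
        new = int(canonical[numeric == i][0]) if np.any(numeric == i) else None
        if new is not None:
            names[new] = nid
    return LabelVector(labels=canonical, names=names)


def node_features(tree: DivikTree, node_id: str) -> list[str]:
    """Feature ids retained at a node (local mask composed with the global one)."""
    node = tree.find(node_id)
    pool_ids = [f for f, keep in zip(tree.feature_ids, tree.global_abundance_mask) if keep]
    return [f for f, keep in zip(pool_ids, node.feature_mask) if keep]
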