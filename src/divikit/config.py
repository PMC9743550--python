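"""Run configuration and the two published parameter presets."""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator


class DivikConfig(BaseModel):
    """All tunable parameters of a divisive segmentation run.

    Defaults follow the ``oscc`` preset: correlation distance, up to 10
    clusters per level, minimum cluster of 200 observations, at least 1% of
    the local feature pool retained, KD-tree leaves of 1% of the data,
    seeding at the 99th distance percentile, and quality indices estimated on
    ten subsamples of 1000 observations each.
    """

    distance: Literal["correlation", "euclidean"] = "correlation"
    max_k_per_level: int = Field(10, ge=2)
    min_cluster_size: int = Field(200, ge=2)
    min_feature_fraction: float = Field(0.01, gt=0.0, le=1.0)
    kdtree_leaf_fraction: float = Field(0.01, gt=0.0, le=1.0)
    seed_percentile: float = Field(99.0, gt=0.0, le=100.0)
    n_subsamples: int = Field(10, ge=1)
    subsample_size: int = Field(1000, ge=4)
    gap_n_reference: int = Field(10, ge=1)
    rng_seed: int = 0
    apply_global_abundance_filter: bool = True
    #: stop splitting clusters at or below this size (alternative stop rule
    #: used for very large volumes); None disables it
    max_leaf_size_stop: Optional[int] = None
    max_depth: int = Field(20, ge=1)
    max_gmm_components: int = Field(10, ge=1)
    kmeans_max_iter: int = Field(300, ge=1)

    @model_validator(mode="after")
    def _check_subsample(self) -> "DivikConfig":
        if self.subsample_size < 2 * self.max_k_per_level:
            raise ValueError(
                "subsample_size must be at least twice max_k_per_level"
            )
        return self


#: Published parameterisations: 2-D cancer-tissue data ("oscc") and the
#: large 3-D mouse kidney volume ("kidney3d").
PRESETS: dict[str, dict] = {
    "oscc": dict(
        distance="correlation",
        max_k_per_level=10,
        min_cluster_size=200,
        min_feature_fraction=0.01,
        kdtree_leaf_fraction=0.01,
        seed_percentile=99.0,
        n_subsamples=10,
        subsample_size=1000,
        gap_n_reference=10,
        apply_global_abundance_filter=True,
    ),
    "kidney3d": dict(
        distance="correlation",
        max_k_per_level=10,
        min_cluster_size=200,
        min_feature_fraction=0.005,
        kdtree_leaf_fraction=0.001,
        seed_percentile=95.0,
        n_subsamples=10,
        subsample_size=5000,
        gap_n_reference=10,
        apply_global_abundance_filter=True,
        max_leaf_size_stop=50_000,
    ),
}


def preset(name: str, **overrides) -> DivikConfig:
    """Return a named preset configuration, optionally overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return DivikConfig(**params)
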