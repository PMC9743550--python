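"""Data-driven feature filtering by 1-D Gaussian mixture decomposition.

For each feature (peak) a summary statistic is computed across the analysed
(sub)cluster: the mean abundance or the abundance variance, on a log10 scale.
The empirical distribution of that statistic over all features is decomposed
into a 1-D Gaussian mixture; the number of components is chosen by BIC.
Crossing points between adjacent weighted component densities act as
thresholds separating "noise" from "signal" features:

* the **abundance filter** (applied once, globally) drops every feature whose
  log mean abundance falls below the first (leftmost) crossing point;
* the **variance filter** (re-applied locally at every node of the divisive
  recursion) keeps only the features above the topmost crossing point,
  relaxing to the next threshold down until at least a configured fraction of
  the feature pool survives.

Components that attract less than 1% of the features under maximum-posterior
assignment are discarded as numerical artefacts before thresholds are
derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .data import AbundanceMatrix

log = logging.getLogger(__name__)

#: minimum share of points a mixture component must attract (by maximum
#: posterior) to be kept
MIN_COMPONENT_SHARE = 0.01
#: minimum number of finite statistics required to attempt an EM fit;
#: below this the filter degenerates to "keep everything finite"
MIN_POINTS_FOR_FIT = 10


class DegenerateInputError(ValueError):
    """Raised when the statistic vector carries no usable spread."""


@dataclass
class GaussianMixture1D:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_components: int
    bic: float
    component_shares: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.component_shares = np.asarray(self.component_shares, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by ascending mean")

    def density(self, x: np.ndarray) -> np.ndarray:
        """Weighted mixture density at ``x``."""
        x = np.asarray(x, dtype=float)
        comp = self.weights[:, None] * norm.pdf(
            x[None, :], self.means[:, None], self.sds[:, None]
        )
        return comp.sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_components": self.n_components,
            "bic": self.bic,
            "component_shares": self.component_shares.tolist(),
        }


@dataclass
class FeatureFilter:
    """Result of one filtering pass: statistic, fitted model, mask."""

    kind: Literal["abundance", "variance"]
    statistic: np.ndarray
    model: GaussianMixture1D
    thresholds: np.ndarray
    chosen_threshold: float | None
    mask: np.ndarray

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())


def log_feature_stats(
    m: AbundanceMatrix | np.ndarray, which: Literal["mean", "variance"]
) -> np.ndarray:
    """Per-feature log10 of the mean or variance of abundance.

    Features whose raw statistic is exactly zero (all-zero columns for the
    mean; constant columns for the variance) get a ``-inf`` sentinel: they
    are excluded from mixture fitting and always dropped by the mask.
    """
    values = m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, float)
    if which == "mean":
        stat = values.mean(axis=0)
    elif which == "variance":
        if values.shape[0] < 2:
            raise DegenerateInputError("variance requires at least 2 observations")
        stat = values.var(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown statistic {which!r}")
    with np.errstate(divide="ignore"):
        return np.where(stat > 0, np.log10(np.maximum(stat, np.finfo(float).tiny)), -np.inf)


def fit_gmm_1d(
    x: np.ndarray, max_components: int = 10, rng_seed: int = 0
) -> GaussianMixture1D:
    """Fit 1-D Gaussian mixtures for K = 1..max_components, pick K by BIC.

    EM uses k-means++ initialisation with 10 restarts, a log-likelihood
    tolerance of 1e-6 and a variance floor of ``1e-6 * var(x)``. Ties in BIC
    go to the smaller K. Components holding fewer than 1% of the points under
    maximum-posterior assignment are discarded and the remaining weights are
    renormalised.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateInputError("all values identical; mixture undefined")
    col = x[:, None]
    var = float(np.var(x))
    reg = max(1e-6 * var, 1e-12)
    best: GaussianMixture | None = None
    best_bic = np.inf
    k_cap = min(max_components, x.size - 1)
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            tol=1e-6,
            max_iter=1000,
            reg_covar=reg,
            init_params="k-means++",
            random_state=rng_seed,
        )
        try:
            gm.fit(col)
        except Exception:  # EM failure at this K: skip it
            continue
        bic = gm.bic(col)
        if bic < best_bic - 1e-12:  # strict improvement → smallest K wins ties
            best, best_bic = gm, bic
    if best is None:
        raise DegenerateInputError("no mixture size could be fitted")

    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    weights = best.weights_
    assign = best.predict(col)
    shares = np.bincount(assign, minlength=means.size) / x.size

    keep = shares >= MIN_COMPONENT_SHARE
    if not keep.any():
        keep = shares == shares.max()
    if not keep.all():
        log.debug("discarding %d component(s) with <1%% share", (~keep).sum())
    weights = weights[keep] / weights[keep].sum()
    means, sds, shares = means[keep], sds[keep], shares[keep]
    order = np.argsort(means, kind="stable")
    return GaussianMixture1D(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        n_components=int(keep.sum()),
        bic=float(best_bic),
        component_shares=shares[order] / shares.sum(),
    )


def crossing_thresholds(g: GaussianMixture1D) -> np.ndarray:
    """Equal-density crossing points between adjacent mixture components.

    For each adjacent pair (sorted by mean) the root of
    ``w_i N(x; mu_i, s_i) - w_j N(x; mu_j, s_j)`` strictly between the two
    means is located by Brent's method; if the difference does not change
    sign between the means (heavily overlapping or dominated components) the
    midpoint of the means is used as a fallback.
    """
    if g.n_components < 2:
        return np.array([])
    thresholds = []
    for i in range(g.n_components - 1):
        wi, mi, si = g.weights[i], g.means[i], g.sds[i]
        wj, mj, sj = g.weights[i + 1], g.means[i + 1], g.sds[i + 1]

        def diff(x: float) -> float:
            return wi * norm.pdf(x, mi, si) - wj * norm.pdf(x, mj, sj)

        lo, hi = mi, mj
        if hi - lo < 1e-12:
            thresholds.append(0.5 * (mi + mj))
            continue
        eps = 1e-9 * (hi - lo)
        a, b = lo + eps, hi - eps
        if diff(a) * diff(b) < 0:
            thresholds.append(float(brentq(diff, a, b, xtol=1e-12)))
        else:
            log.debug("no density crossing bracketed in (%g, %g); midpoint used", lo, hi)
            thresholds.append(0.5 * (mi + mj))
    return np.asarray(sorted(thresholds))


def _fit_on_finite(
    stat: np.ndarray, max_components: int, rng_seed: int
) -> tuple[GaussianMixture1D | None, np.ndarray]:
    """Fit the mixture on finite statistics; None when too few/degenerate."""
    finite = np.isfinite(stat)
    xs = stat[finite]
    if xs.size < MIN_POINTS_FOR_FIT or np.ptp(xs) == 0:
        return None, finite
    return fit_gmm_1d(xs, max_components=max_components, rng_seed=rng_seed), finite


def abundance_filter(
    m: AbundanceMatrix | np.ndarray,
    max_components: int = 10,
    rng_seed: int = 0,
) -> FeatureFilter:
    """Global noise filter on log mean abundance.

    Drops every feature below the first (leftmost) crossing point of the
    mixture fitted to the log10 mean abundances. A single-component model
    keeps all features (no threshold exists). All-zero features are always
    dropped.
    """
    stat = log_feature_stats(m, "mean")
    model, finite = _fit_on_finite(stat, max_components, rng_seed)
    if model is None:
        mask = finite.copy()
        model = _trivial_model(stat[finite])
        return FeatureFilter("abundance", stat, model, np.array([]), None, mask)
    thresholds = crossing_thresholds(model)
    if thresholds.size == 0:
        mask = finite.copy()
        chosen = None
    else:
        chosen = float(thresholds[0])
        mask = finite & (stat >= chosen)
    if not mask.any():  # never return an empty feature set
        mask = finite.copy()
        chosen = None
    return FeatureFilter("abundance", stat, model, thresholds, chosen, mask)


def variance_filter(
    m: AbundanceMatrix | np.ndarray,
    min_feature_fraction: float,
    max_components: int = 10,
    rng_seed: int = 0,
) -> FeatureFilter:
    """Local informative-feature filter on log abundance variance.

    Keeps the features above the topmost crossing point, provided at least
    ``ceil(min_feature_fraction * n_feat)`` features survive; otherwise the
    next threshold down is tried, and if no threshold satisfies the bound
    the top-variance features are kept directly up to that count. A
    single-component model keeps all (finite) features.
    """
    stat = log_feature_stats(m, "variance")
    n_feat = stat.size
    min_keep = int(np.ceil(min_feature_fraction * n_feat))
    model, finite = _fit_on_finite(stat, max_components, rng_seed)
    if model is None:
        mask = finite.copy() if finite.any() else np.ones(n_feat, bool)
        mdl = _trivial_model(stat[finite]) if finite.any() else _trivial_model(stat)
        return FeatureFilter("variance", stat, mdl, np.array([]), None, mask)
    thresholds = crossing_thresholds(model)
    chosen: float | None = None
    mask = finite.copy()
    for t in thresholds[::-1]:  # topmost threshold first, then relax downward
        candidate = finite & (stat >= t)
        if candidate.sum() >= min_keep:
            chosen = float(t)
            mask = candidate
            break
    else:
        if thresholds.size:  # no threshold keeps enough: top features by variance
            order = np.argsort(-stat, kind="stable")
            mask = np.zeros(n_feat, bool)
            mask[order[: min(min_keep, int(finite.sum()) or n_feat)]] = True
            mask &= finite
            if not mask.any():
                mask = finite.copy()
    if not mask.any():
        mask = finite.copy() if finite.any() else np.ones(n_feat, bool)
    return FeatureFilter("variance", stat, model, thresholds, chosen, mask)


def _trivial_model(x: np.ndarray) -> GaussianMixture1D:
    """One-component stand-in used when EM is not applicable."""
    x = np.asarray(x, dtype=float)
    mu = float(x.mean()) if x.size else 0.0
    sd = float(x.std()) if x.size and x.std() > 0 else 1.0
    return GaussianMixture1D(
        weights=np.array([1.0]),
        means=np.array([mu]),
        sds=np.array([sd]),
        n_components=1,
        bic=float("nan"),
        component_shares=np.array([1.0]),
    )
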