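"""Feature statistics, 1-D mixture fitting, crossing points, filters."""

import numpy as np
import pytest
from scipy.stats import norm

from divikit.data import AbundanceMatrix
from divikit.gmm_filter import (
    DegenerateInputError,
    GaussianMixture1D,
    abundance_filter,
    crossing_thresholds,
    fit_gmm_1d,
    log_feature_stats,
    variance_filter,
)
from divikit.synthetic import generate_noise_floor


def grid_scan_crossing(g: GaussianMixture1D, i: int, step: float = 1e-4) -> float:
    """Equal-density point between components i and i+1 by dense grid scan."""
    lo, hi = g.means[i], g.means[i + 1]
    xs = np.arange(lo, hi, step)
    di = g.weights[i] * norm.pdf(xs, g.means[i], g.sds[i])
    dj = g.weights[i + 1] * norm.pdf(xs, g.means[i + 1], g.sds[i + 1])
    sign = np.sign(di - dj)
    flips = np.flatnonzero(np.diff(sign) != 0)
    if flips.size == 0:
        return 0.5 * (lo + hi)
    return float(xs[flips[0]] + step / 2)


class TestLogFeatureStats:
    def test_mean_of_constant_column(self):
        m = np.full((3, 1), 10.0)
        assert log_feature_stats(m, "mean")[0] == pytest.approx(1.0)

    def test_zero_variance_gets_sentinel(self):
        m = np.full((3, 1), 10.0)
        assert log_feature_stats(m, "variance")[0] == -np.inf

    def test_variance_matches_two_pass_formula(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        # independent two-pass sample variance
        mean = col.sum() / col.size
        var = ((col - mean) ** 2).sum() / (col.size - 1)
        m = col[:, None]
        assert log_feature_stats(m, "variance")[0] == pytest.approx(np.log10(var))

    def test_variance_needs_two_observations(self):
        with pytest.raises(DegenerateInputError):
            log_feature_stats(np.ones((1, 3)), "variance")

    def test_all_zero_column_sentinel_for_mean(self):
        m = np.array([[0.0, 1.0], [0.0, 2.0]])
        stats = log_feature_stats(m, "mean")
        assert stats[0] == -np.inf and np.isfinite(stats[1])


class TestFitGmm1D:
    def test_single_normal_selects_one_component(self):
        x = np.random.default_rng(0).normal(5.0, 1.0, size=1000)
        g = fit_gmm_1d(x, max_components=5, rng_seed=0)
        assert g.n_components == 1
        assert g.means[0] == pytest.approx(5.0, abs=0.15)

    def test_well_separated_mixture_recovers_two_components(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0, 1, 500), rng.normal(10, 1, 500)]
        g = fit_gmm_1d(x, max_components=5, rng_seed=0)
        assert g.n_components == 2
        # oracle: quantile split at the midpoint
        low, high = x[x < 5], x[x >= 5]
        assert g.means[0] == pytest.approx(low.mean(), abs=0.2)
        assert g.means[1] == pytest.approx(high.mean(), abs=0.2)
        assert g.component_shares[0] == pytest.approx(0.5, abs=0.05)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_gmm_1d(np.full(100, 3.0), max_components=3, rng_seed=0)

    def test_tiny_components_are_discarded(self):
        # 2 outliers among 1000 points cannot form their own component
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 1, 998), np.array([50.0, 50.1])]
        g = fit_gmm_1d(x, max_components=5, rng_seed=0)
        assert np.all(g.component_shares >= 0.01 - 1e-12)
        assert g.weights.sum() == pytest.approx(1.0)

    def test_components_sorted_by_mean(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(8, 1, 400), rng.normal(0, 1, 400), rng.normal(-7, 1, 200)]
        g = fit_gmm_1d(x, max_components=6, rng_seed=0)
        assert np.all(np.diff(g.means) > 0)


class TestCrossingThresholds:
    def test_symmetric_pair_crosses_at_zero(self):
        g = GaussianMixture1D(
            weights=np.array([0.5, 0.5]),
            means=np.array([-1.0, 1.0]),
            sds=np.array([1.0, 1.0]),
            n_components=2,
            bic=0.0,
            component_shares=np.array([0.5, 0.5]),
        )
        assert crossing_thresholds(g)[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_component_has_no_thresholds(self):
        g = GaussianMixture1D(
            weights=np.array([1.0]), means=np.array([0.0]), sds=np.array([1.0]),
            n_components=1, bic=0.0, component_shares=np.array([1.0]),
        )
        assert crossing_thresholds(g).size == 0

    def test_asymmetric_pair_matches_grid_scan(self):
        g = GaussianMixture1D(
            weights=np.array([0.7, 0.3]),
            means=np.array([0.0, 5.0]),
            sds=np.array([1.0, 2.0]),
            n_components=2,
            bic=0.0,
            component_shares=np.array([0.7, 0.3]),
        )
        t = crossing_thresholds(g)[0]
        assert t == pytest.approx(grid_scan_crossing(g, 0), abs=1e-3)
        assert 0.0 < t < 5.0

    def test_random_mixtures_match_grid_scan_oracle(self):
        """Crossing solver vs dense grid scan on 100 random 2..4-component mixtures."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            means = np.sort(rng.uniform(-10, 10, k))
            while np.any(np.diff(means) < 1.0):  # keep components distinguishable
                means = np.sort(rng.uniform(-10, 10, k))
            g = GaussianMixture1D(
                weights=(w := rng.dirichlet(np.ones(k) * 5)),
                means=means,
                sds=rng.uniform(0.3, 1.5, k),
                n_components=k,
                bic=0.0,
                component_shares=w,
            )
            ts = crossing_thresholds(g)
            assert ts.size == k - 1
            assert np.all(np.diff(ts) > 0) or ts.size < 2
            for i, t in enumerate(ts):
                assert t == pytest.approx(grid_scan_crossing(g, i), abs=1e-3)
                assert g.means[i] < t < g.means[i + 1]


def _matrix(values: np.ndarray) -> AbundanceMatrix:
    n, p = values.shape
    return AbundanceMatrix(values, [f"f{j}" for j in range(p)], [f"o{i}" for i in range(n)])


class TestAbundanceFilter:
    def test_bimodal_features_split_at_crossing(self):
        m, is_low = generate_noise_floor(150, 800, 0.3, seed=3)
        f = abundance_filter(m.values, rng_seed=0)
        # planted-mode confusion counts
        low_removed = np.sum(~f.mask & is_low) / is_low.sum()
        high_removed = np.sum(~f.mask & ~is_low) / (~is_low).sum()
        assert low_removed >= 0.95
        assert high_removed <= 0.05
        # the mask must agree with a direct comparison against the threshold
        finite = np.isfinite(f.statistic)
        assert np.array_equal(f.mask, finite & (f.statistic >= f.chosen_threshold))

    def test_unimodal_statistics_keep_everything(self):
        rng = np.random.default_rng(4)
        values = 10 ** (2.0 + rng.normal(0, 0.2, size=(50, 200)))
        f = abundance_filter(values, rng_seed=0)
        assert f.mask.all()

    def test_all_zero_column_always_removed(self):
        rng = np.random.default_rng(5)
        values = 10 ** rng.normal(1, 0.3, size=(40, 30))
        values[:, 7] = 0.0
        f = abundance_filter(values, rng_seed=0)
        assert not f.mask[7]


class TestVarianceFilter:
    @staticmethod
    def _tiered_matrix(n_top: int, seed: int = 0) -> tuple[np.ndarray, int]:
        """1000 features: most low-variance, some mid, `n_top` high-variance."""
        rng = np.random.default_rng(seed)
        n_obs, n_feat = 120, 1000
        n_mid = 100
        sds = np.r_[
            np.full(n_feat - n_mid - n_top, 0.05),
            np.full(n_mid, 0.3),
            np.full(n_top, 2.0),
        ]
        values = 10 ** (2.0 + rng.normal(0, 1, size=(n_obs, n_feat)) * sds)
        return values, n_feat

    def test_topmost_component_too_small_falls_back_to_next_threshold(self):
        values, n_feat = self._tiered_matrix(n_top=5)
        f = variance_filter(values, min_feature_fraction=0.01, rng_seed=0)
        # 5 < ceil(0.01*1000) = 10, so the topmost threshold alone is not enough
        assert f.n_kept >= 10
        # explicit counting oracle: chosen threshold is the highest one
        # retaining at least 10 features
        finite = np.isfinite(f.statistic)
        for t in f.thresholds[::-1]:
            n_at = int(np.sum(finite & (f.statistic >= t)))
            if n_at >= 10:
                assert f.chosen_threshold == pytest.approx(t)
                assert f.n_kept == n_at
                break

    def test_large_top_component_uses_topmost_threshold(self):
        values, n_feat = self._tiered_matrix(n_top=100)
        f = variance_filter(values, min_feature_fraction=0.01, rng_seed=0)
        assert f.chosen_threshold == pytest.approx(f.thresholds[-1])
        finite = np.isfinite(f.statistic)
        assert f.n_kept == int(np.sum(finite & (f.statistic >= f.chosen_threshold)))

    def test_single_component_model_keeps_all(self):
        rng = np.random.default_rng(6)
        values = 10 ** (2.0 + rng.normal(0, 0.25, size=(60, 300)))
        f = variance_filter(values, min_feature_fraction=0.01, rng_seed=0)
        assert f.mask.all()

    def test_mask_respects_minimum_fraction(self):
        values, n_feat = self._tiered_matrix(n_top=5)
        for frac in (0.01, 0.05, 0.2):
            f = variance_filter(values, min_feature_fraction=frac, rng_seed=0)
            assert f.n_kept >= int(np.ceil(frac * n_feat))


class TestScaleConsistency:
    def test_global_rescaling_shifts_stats_and_preserves_masks(self):
        rng = np.random.default_rng(8)
        values = 10 ** (1.5 + rng.normal(0, 1, size=(80, 400)) * np.r_[
            np.full(360, 0.05), np.full(40, 1.0)
        ])
        c = 37.0
        s_mean = log_feature_stats(values, "mean")
        s_mean_scaled = log_feature_stats(values * c, "mean")
        assert np.allclose(s_mean_scaled, s_mean + np.log10(c))
        s_var = log_feature_stats(values, "variance")
        s_var_scaled = log_feature_stats(values * c, "variance")
        assert np.allclose(s_var_scaled, s_var + 2 * np.log10(c))
        f = variance_filter(values, 0.01, rng_seed=0)
        f_scaled = variance_filter(values * c, 0.01, rng_seed=0)
        assert np.array_equal(f.mask, f_scaled.mask)
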