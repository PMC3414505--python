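"""ISC statistic, circular-shift resampling null, and permutation p-values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iscval import (
    NullDistribution,
    isc_statistic,
    n_pairs,
    pairwise_corr,
    pvalues,
    resample_null,
)


def brute_force_isc(data: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit double loop over subject pairs."""
    n_sub, n_vox, _ = data.shape
    out = np.zeros(n_vox)
    for v in range(n_vox):
        acc = 0.0
        for i, j in itertools.combinations(range(n_sub), 2):
            acc += pairwise_corr(data[i, v], data[j, v])
        out[v] = acc / n_pairs(n_sub)
    return out


class TestPairwiseCorr:
    def test_self_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pairwise_corr(x, x) == pytest.approx(1.0)
        assert pairwise_corr(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        # direct evaluation of the covariance / sd formula
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pairwise_corr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_corr(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="3 samples"):
            pairwise_corr(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestISCStatistic:
    @pytest.mark.parametrize("n_sub,n_t", [(3, 10), (4, 7), (5, 20)])
    def test_matches_brute_force_loop(self, n_sub, n_t):
        rng = np.random.default_rng(n_sub * 100 + n_t)
        data = rng.standard_normal((n_sub, 6, n_t))
        np.testing.assert_allclose(
            isc_statistic(data), brute_force_isc(data), atol=1e-12
        )

    def test_identical_subjects_give_unity(self):
        series = np.random.default_rng(0).standard_normal(12)
        data = np.tile(series, (5, 3, 1))
        np.testing.assert_allclose(isc_statistic(data), 1.0, atol=1e-12)

    def test_zero_variance_voxel_marked_invalid(self):
        data = np.random.default_rng(1).standard_normal((3, 2, 10))
        data[1, 0, :] = 4.2
        out = isc_statistic(data)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 5, 15))
        shifted = data.copy()
        shifted[2] = 3.5 * shifted[2] - 7.0
        np.testing.assert_allclose(
            isc_statistic(shifted), isc_statistic(data), atol=1e-12
        )

    @given(perm_seed=st.integers(0, 100))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_subject_order_invariance(self, perm_seed):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 4, 12))
        perm = np.random.default_rng(perm_seed).permutation(5)
        np.testing.assert_allclose(
            isc_statistic(data[perm]), isc_statistic(data), atol=1e-12
        )

    def test_values_bounded(self, noise_cohort_ts):
        out = isc_statistic(noise_cohort_ts)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)


class TestResampleNull:
    def test_circular_shift_preserves_periodogram(self):
        x = np.random.default_rng(4).standard_normal(84)
        shifted = np.roll(x, 17)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(shifted)), np.abs(np.fft.rfft(x)), atol=1e-10
        )

    def test_determinism(self, noise_cohort_ts):
        a = resample_null(noise_cohort_ts, b=1000, seed=5)
        b = resample_null(noise_cohort_ts, b=1000, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_mean_near_zero(self, noise_cohort_ts):
        null = resample_null(noise_cohort_ts, b=10000, seed=6)
        assert abs(null.values.mean()) < 0.02
        assert np.all(np.diff(null.values) >= 0)

    def test_pvalues_uniform_under_pure_noise(self):
        from iscval.noise import pink_noise_matrix
        from scipy import stats

        root = np.random.SeedSequence(77)
        data = np.stack(
            [pink_noise_matrix(2000, 84, np.random.default_rng(s)) for s in root.spawn(10)]
        )
        iscmap = isc_statistic(data)
        null = resample_null(data, b=10000, seed=78)
        p = pvalues(iscmap, null)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_too_short_series_rejected(self):
        data = np.random.default_rng(7).standard_normal((3, 4, 18))
        with pytest.raises(ValueError, match="too short"):
            resample_null(data, b=1000, seed=0, min_shift=10)

    def test_minimum_realizations_enforced(self, noise_cohort_ts):
        with pytest.raises(ValueError, match="1000"):
            resample_null(noise_cohort_ts, b=500, seed=0)


class TestPValues:
    def test_add_one_floor_and_ceiling(self):
        null = NullDistribution(values=np.sort(np.linspace(-0.2, 0.2, 9999)))
        p = pvalues(np.array([0.5, -0.5]), null)
        assert p[0] == pytest.approx(1.0 / 10000)
        assert p[1] == pytest.approx(1.0)

    def test_empirical_quantile_oracle(self):
        rng = np.random.default_rng(8)
        null = NullDistribution(values=np.sort(rng.standard_normal(40000)))
        obs = np.quantile(null.values, 0.95)
        p = pvalues(np.array([obs]), null)
        assert p[0] == pytest.approx(0.05, abs=2.0 / np.sqrt(40000))

    def test_nan_propagates(self):
        null = NullDistribution(values=np.sort(np.linspace(-1, 1, 2000)))
        p = pvalues(np.array([np.nan, 0.0]), null)
        assert np.isnan(p[0]) and np.isfinite(p[1])


def test_pair_count_for_study_cohort():
    assert n_pairs(37) == 666
    assert n_pairs(37) == len(list(itertools.combinations(range(37), 2)))
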