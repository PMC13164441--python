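"""Histogram construction, entropy and the moment estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nccthist import (
    HistogramSpec,
    HUSample,
    build_histogram,
    entropy_bits,
    metric_set,
    pmf_entropy_bits,
    sample_kurtosis,
    sample_sd,
    sample_skewness,
)

from conftest import (
    discretized_gaussian_entropy_bits,
    naive_binning,
    naive_kurt_g2,
    naive_sd,
    naive_skew_g1,
)

SPEC = HistogramSpec()


class TestHistogramSpec:
    def test_default_bin_width_is_one_hu(self):
        assert SPEC.bin_width == 1.0
        assert SPEC.n_bins == 100
        assert SPEC.edges()[0] == -40 and SPEC.edges()[-1] == 60

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_bins": 1},
            {"hu_min": 60, "hu_max": -40},
            {"range_mode": "auto"},
            {"clip_policy": "wrap"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HistogramSpec(**kwargs)

    def test_dynamic_mode_pads_to_integer_hu(self):
        spec = HistogramSpec(range_mode="dynamic")
        edges = spec.edges(np.array([-3.2, 7.9]))
        assert edges[0] == -4.0 and edges[-1] == 8.0


class TestBuildHistogram:
    def test_one_value_per_bin_center(self):
        h = build_histogram(SPEC.centers(), SPEC)
        assert np.all(h.counts == 1)
        assert h.n_total == 100

    def test_clip_to_range_sends_outliers_to_edge_bins(self):
        h = build_histogram(np.array([-100.0, 70.0]), SPEC)
        assert h.counts[0] == 1 and h.counts[-1] == 1
        assert h.counts.sum() == 2

    def test_drop_policy_discards_outliers(self):
        spec = HistogramSpec(clip_policy="drop_out_of_range")
        h = build_histogram(np.array([-100.0, 5.0, 70.0]), spec)
        assert h.n_total == 1
        with pytest.raises(ValueError):
            build_histogram(np.array([-100.0]), spec)

    def test_matches_naive_binning_loop(self, rng):
        values = rng.normal(26.71, 5.16, size=10_000)
        h = build_histogram(values, SPEC)
        assert h.counts.tolist() == naive_binning(values.tolist(), h.edges.tolist())

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            build_histogram(np.array([]), SPEC)


class TestEntropy:
    def test_delta_distribution_has_zero_entropy(self):
        h = build_histogram(np.full(50, 30.0), SPEC)
        assert entropy_bits(h) == 0.0

    def test_uniform_hits_log2_of_bins(self):
        h = build_histogram(SPEC.centers(), SPEC)
        assert entropy_bits(h) == pytest.approx(math.log2(100), abs=1e-12)
        assert entropy_bits(h) == pytest.approx(6.6439, abs=1e-4)

    def test_entropy_bounds_on_random_samples(self, rng):
        for _ in range(25):
            v = rng.normal(rng.uniform(-30, 50), rng.uniform(0.1, 30), size=200)
            h = entropy_bits(build_histogram(v, SPEC))
            assert 0.0 <= h <= math.log2(100)

    def test_gaussian_plugin_approaches_discretized_pmf_entropy(self, rng):
        # moderate n here; the 1e6-pixel closed-form check runs with the
        # acceptance property suite
        sigma = 5.16
        v = rng.normal(26.71, sigma, size=200_000)
        h = entropy_bits(build_histogram(v, SPEC))
        oracle = discretized_gaussian_entropy_bits(sigma, mu=26.71)
        assert h == pytest.approx(oracle, abs=0.01)
        # and for sigma >> 1 HU the oracle matches the closed form
        assert oracle == pytest.approx(0.5 * math.log2(2 * math.pi * math.e * sigma**2), abs=0.01)

    def test_entropy_depends_only_on_histogram(self, rng):
        v = rng.normal(0, 5, 5000)
        h1 = entropy_bits(build_histogram(v, SPEC))
        h2 = entropy_bits(build_histogram(rng.permutation(v), SPEC))
        assert h1 == h2

    def test_monotone_in_sigma(self):
        sigmas = np.linspace(0.5, 15, 30)
        ents = [discretized_gaussian_entropy_bits(s) for s in sigmas]
        assert np.all(np.diff(ents) > 0)

    def test_miller_madow_correction_is_small_and_positive(self, rng):
        v = rng.normal(20, 5, size=500)
        h = build_histogram(v, SPEC)
        plain, corrected = entropy_bits(h), entropy_bits(h, miller_madow=True)
        assert 0 < corrected - plain < 0.1

    def test_zero_total_count_rejected(self):
        with pytest.raises(ValueError):
            entropy_bits(np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            pmf_entropy_bits(np.zeros(3))


class TestMoments:
    def test_sd_worked_example(self):
        assert sample_sd([2, 4, 4, 4, 5, 5, 7, 9]) == pytest.approx(2.1381, abs=1e-4)
        assert sample_sd([1, 1, 1, 1]) == 0.0

    def test_translation_invariance_of_sd(self, rng):
        x = rng.normal(0, 3, 100)
        assert sample_sd(x + 17.3) == pytest.approx(sample_sd(x), rel=1e-12)

    def test_symmetric_sample_has_zero_skewness(self):
        assert sample_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_skewness_sign_flips_under_negation(self):
        x = np.array([1.0, 1.0, 1.0, 10.0])
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x), rel=1e-12)

    def test_kurtosis_scale_invariance(self, rng):
        x = rng.normal(0, 1, 60)
        assert sample_kurtosis(3.7 * x) == pytest.approx(sample_kurtosis(x), rel=1e-9)
        assert sample_kurtosis(-2.0 * x) == pytest.approx(sample_kurtosis(x), rel=1e-9)

    def test_large_gaussian_sample_has_near_zero_excess_kurtosis(self, rng):
        x = rng.normal(0, 1, 400_000)
        assert sample_kurtosis(x) == pytest.approx(0.0, abs=0.05)

    def test_moments_match_brute_force_formulas(self, rng):
        """Bias-corrected SD/G1/G2 vs naive loop evaluation, 1e-12 relative."""
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.normal(rng.uniform(-10, 40), rng.uniform(0.5, 8), n).tolist()
            assert sample_sd(x) == pytest.approx(naive_sd(x), rel=1e-12)
            assert sample_skewness(x) == pytest.approx(naive_skew_g1(x), rel=1e-12)
            assert sample_kurtosis(x) == pytest.approx(naive_kurt_g2(x), rel=1e-12)

    def test_population_moment_mode(self, rng):
        x = rng.normal(0, 2, 40)
        import scipy.stats as sps

        assert sample_skewness(x, bias_corrected=False) == pytest.approx(
            sps.skew(x), rel=1e-12
        )

    @pytest.mark.parametrize(
        "func,bad",
        [
            (sample_sd, [1.0]),
            (sample_skewness, [1.0, 2.0]),
            (sample_skewness, [3.0, 3.0, 3.0]),
            (sample_kurtosis, [1.0, 2.0, 3.0]),
            (sample_kurtosis, [3.0, 3.0, 3.0, 3.0]),
        ],
    )
    def test_degenerate_inputs_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)


class TestMetricSet:
    def test_bundle_matches_components(self, rng):
        v = rng.normal(26.71, 5.16, 2000)
        ms = metric_set(v, SPEC)
        assert ms.sd == sample_sd(v)
        assert ms.entropy == entropy_bits(build_histogram(v, SPEC))
        assert ms.mean_hu == pytest.approx(np.mean(v))
        assert ms.n_pixels == 2000
        assert ms.metadata["entropy_base"] == 2

    def test_permutation_invariance(self, rng):
        v = rng.normal(30, 4, 500)
        a, b = metric_set(v, SPEC), metric_set(rng.permutation(v), SPEC)
        assert (a.sd, a.skewness, a.kurtosis, a.entropy) == pytest.approx(
            (b.sd, b.skewness, b.kurtosis, b.entropy), rel=1e-12
        )

    def test_degenerate_sample_takes_error_path(self):
        sample = HUSample(values=np.full(10, 30.0))
        assert entropy_bits(build_histogram(sample, SPEC)) == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            metric_set(sample, SPEC)

    def test_area_rule_enforced_when_requested(self):
        small = HUSample(values=np.arange(50.0), pixel_spacing=(1.0, 1.0))
        with pytest.raises(ValueError, match="mm"):
            metric_set(small, SPEC, enforce_area=True)
        ok = HUSample(values=np.arange(120.0), pixel_spacing=(1.0, 1.0))
        metric_set(ok, SPEC, enforce_area=True)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            HUSample(values=np.array([1.0, np.nan]))

    @given(
        st.lists(st.floats(-39.0, 59.0), min_size=8, max_size=60),
        st.floats(-5.0, 5.0),
    )
    def test_entropy_and_sd_invariants_hold(self, values, shift):
        v = np.asarray(values)
        if np.std(v) == 0:
            return
        h = entropy_bits(build_histogram(v, SPEC))
        assert 0.0 <= h <= math.log2(100)
        assert sample_sd(v + shift) == pytest.approx(sample_sd(v), rel=1e-9, abs=1e-9)
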