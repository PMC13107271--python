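import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielcorrect import (
    ActivityHistogram,
    TimeGrid,
    assign_bin,
    bin_probabilities_from_shape,
    histogram_from_times,
    overlap_delta,
    preset_shape,
    radians_to_hours,
    sample_times,
)


class TestTimeGrid:
    def test_default_is_hourly(self, grid):
        assert grid.n_bins == 24
        assert grid.bin_width == 1.0
        assert grid.edges[0] == 0.0 and grid.edges[-1] == 24.0

    @pytest.mark.parametrize("bad", [1, 0, -3, 2.5])
    def test_rejects_invalid_bin_counts(self, bad):
        with pytest.raises(ValueError):
            TimeGrid(bad)


class TestActivityHistogram:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            ActivityHistogram(np.array([0.5, -0.1, 0.6]))
        with pytest.raises(ValueError):
            ActivityHistogram(np.array([0.5, 0.4]))

    def test_probs_are_immutable(self):
        hist = ActivityHistogram(np.full(4, 0.25))
        with pytest.raises(ValueError):
            hist.probs[0] = 1.0


class TestRadiansToHours:
    @pytest.mark.parametrize(
        "angle,hour",
        [(math.pi, 12.0), (0.0, 0.0), (5 * math.pi / 2, 6.0), (3 * math.pi / 2, 18.0)],
    )
    def test_anchor_points(self, angle, hour):
        assert radians_to_hours(angle) == pytest.approx(hour, abs=1e-12)

    def test_negative_angles_wrap_into_day(self):
        assert radians_to_hours(-math.pi / 2) == pytest.approx(18.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            radians_to_hours(float("nan"))


class TestAssignBin:
    @pytest.mark.parametrize("hour,expected", [(0.0, 0), (23.999, 23), (24.0, 0), (6.5, 6)])
    def test_half_open_bins_with_midnight_wrap(self, hour, expected, grid):
        assert assign_bin(hour, grid) == expected

    def test_rejects_negative_hours(self, grid):
        with pytest.raises(ValueError):
            assign_bin(-0.5, grid)

    def test_quarter_circle_landmarks(self, grid):
        # quarter-turns land in bins 6, 12 and 18 on the hourly grid
        for angle, expected in [(math.pi / 2, 6), (math.pi, 12), (3 * math.pi / 2, 18)]:
            assert assign_bin(radians_to_hours(angle), grid) == expected


class TestHistogramFromTimes:
    def test_direct_counting(self, grid):
        hist = histogram_from_times([0.5, 0.6, 1.5], grid)
        assert hist.probs[0] == pytest.approx(2 / 3)
        assert hist.probs[1] == pytest.approx(1 / 3)
        assert hist.probs[2:].sum() == 0.0

    def test_uniform_sampling_gives_uniform_histogram(self, grid):
        times = np.arange(24) + 0.5
        hist = histogram_from_times(times, grid)
        np.testing.assert_allclose(hist.probs, 1 / 24)

    def test_permutation_invariance(self, grid, rng):
        times = rng.uniform(0, 24, size=200)
        h1 = histogram_from_times(times, grid)
        h2 = histogram_from_times(rng.permutation(times), grid)
        np.testing.assert_array_equal(h1.probs, h2.probs)

    def test_empty_input_rejected(self, grid):
        with pytest.raises(ValueError):
            histogram_from_times([], grid)

    def test_mode_bin_of_morning_peak(self, grid, unimodal, rng):
        times = sample_times(unimodal, 1000, rng)
        hist = histogram_from_times(times, grid)
        assert hist.probs.argmax() == 6  # peak at pi/2 rad = 06:00


class TestBinProbabilitiesFromShape:
    def test_flat_density_gives_equal_bins(self, grid):
        hist = bin_probabilities_from_shape(preset_shape("uniform_fp"), grid)
        np.testing.assert_allclose(hist.probs, 1 / 24, atol=1e-12)

    def test_normalization_for_all_presets(self, grid):
        for name in ("unimodal", "bimodal", "trimodal", "skewed_true", "night_fp"):
            hist = bin_probabilities_from_shape(preset_shape(name), grid)
            assert hist.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_morning_peak_symmetric_about_6h(self, grid, unimodal):
        hist = bin_probabilities_from_shape(unimodal, grid)
        assert set(np.argsort(hist.probs)[-2:]) == {5, 6}
        # density is symmetric about 06:00, so bins equidistant from it match
        np.testing.assert_allclose(hist.probs[5], hist.probs[6], rtol=1e-9)
        np.testing.assert_allclose(hist.probs[4], hist.probs[7], rtol=1e-9)

    def test_quadrature_matches_quadrature_oracle(self, grid, unimodal):
        # independent midpoint-rule oracle on a fine grid
        from scipy.stats import vonmises

        n_fine = 24 * 10_000
        edges = np.linspace(0, 2 * np.pi, n_fine + 1)
        mids = (edges[:-1] + edges[1:]) / 2
        dens = vonmises.pdf(mids, 8.0, loc=np.pi / 2)
        mass = dens * np.diff(edges)
        oracle = np.add.reduceat(mass, np.arange(0, n_fine, n_fine // 24))
        hist = bin_probabilities_from_shape(unimodal, grid)
        np.testing.assert_allclose(hist.probs, oracle / oracle.sum(), atol=1e-6)

    def test_matches_empirical_histogram_at_large_n(self, grid, rng):
        shape = preset_shape("bimodal")
        times = sample_times(shape, 1_000_000, rng)
        empirical = histogram_from_times(times, grid)
        exact = bin_probabilities_from_shape(shape, grid)
        assert np.abs(empirical.probs - exact.probs).max() < 0.005


class TestOverlapDelta:
    def test_identical_histograms_overlap_fully(self, rng):
        hist = ActivityHistogram(rng.dirichlet(np.ones(24)))
        assert overlap_delta(hist, hist) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_do_not_overlap(self):
        a = np.zeros(24); a[:12] = 1 / 12
        b = np.zeros(24); b[12:] = 1 / 12
        assert overlap_delta(ActivityHistogram(a), ActivityHistogram(b)) == 0.0

    def test_uniform_versus_point_mass(self):
        uniform = ActivityHistogram(np.full(24, 1 / 24))
        point = np.zeros(24); point[3] = 1.0
        assert overlap_delta(uniform, ActivityHistogram(point)) == pytest.approx(1 / 24)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            overlap_delta(
                ActivityHistogram(np.full(24, 1 / 24)),
                ActivityHistogram(np.full(12, 1 / 12)),
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_bounded_and_identity_only_at_equality(self, seed):
        rng = np.random.default_rng(seed)
        f1 = ActivityHistogram(rng.dirichlet(np.ones(24)))
        f2 = ActivityHistogram(rng.dirichlet(np.ones(24)))
        d12 = overlap_delta(f1, f2)
        assert d12 == overlap_delta(f2, f1)
        assert 0.0 <= d12 <= 1.0
        # distinct histograms overlap strictly less than fully
        assert d12 < 1.0
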