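"""Closed-form detection model: attenuation, optima, sensitivity laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryoslice import (
    DepthDistribution,
    EmptySliceError,
    IntensityMixture,
    OpticalParams,
    UndetectableCellError,
    corrected_count,
    discrete_optimal_thickness,
    distribution_sensitivity,
    expected_count,
    is_detected,
    mixture_sensitivity,
    optimal_intensity,
    optimal_thickness,
    pool_distributions,
    sensitivity_piecewise,
    surface_intensity,
)

triples = st.tuples(
    st.floats(0.11, 1e3),  # threshold
    st.floats(1.001, 1e4),  # intensity / threshold ratio
    st.floats(1.0, 5e3),  # attenuation
)


class TestSurfaceIntensity:
    def test_zero_depth_is_identity(self):
        assert surface_intensity(40, 314, 0) == 40

    @pytest.mark.parametrize(
        "intensity, mu, depth",
        [(30, 314, 35), (300, 332, 102.45)],
        ids=["stem-like", "red-microsphere"],
    )
    def test_decays_to_threshold_at_optimal_depth(self, intensity, mu, depth):
        # these depths are (close to) the optimal thickness for T = 10
        assert surface_intensity(intensity, mu, depth) == pytest.approx(10.0, abs=0.01)

    def test_strictly_decreasing_in_depth_and_attenuation(self):
        depths = np.linspace(0, 200, 50)
        vals = surface_intensity(87, 372, depths)
        assert np.all(np.diff(vals) < 0)
        mus = np.linspace(100, 500, 50)
        assert np.all(np.diff(surface_intensity(87, mus, 50.0)) < 0)

    @pytest.mark.parametrize("bad", [(-1, 314, 5), (30, 0, 5), (30, 314, -0.1)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            surface_intensity(*bad)


def test_detection_boundary_is_inclusive():
    assert is_detected(10, 10)
    assert not is_detected(9.999, 10)
    assert is_detected(15, 10)


class TestOptima:
    def test_printed_optimal_thicknesses(self, red_params, green_params, stem_params):
        assert optimal_thickness(red_params) == pytest.approx(102.45, abs=0.005)
        assert optimal_thickness(green_params) == pytest.approx(58.15, abs=0.005)
        assert optimal_thickness(stem_params) == pytest.approx(42.52, abs=0.005)

    def test_intensity_equal_to_threshold_gives_zero(self):
        assert optimal_thickness(OpticalParams(10, 314, 10)) == 0.0

    def test_undetectable_cells_raise(self):
        with pytest.raises(UndetectableCellError):
            optimal_thickness(OpticalParams(5, 314, 10))

    @pytest.mark.parametrize("mu, expected", [(214, 15.34), (314, 18.74), (414, 22.89)])
    def test_printed_optimal_intensities(self, mu, expected):
        assert optimal_intensity(10, mu, 20) == pytest.approx(expected, abs=0.005)

    def test_zero_thickness_returns_threshold(self):
        assert optimal_intensity(10, 314, 0) == 10

    @settings(max_examples=100, derandomize=True)
    @given(triples)
    def test_round_trip(self, triple):
        threshold, ratio, mu = triple
        intensity = threshold * ratio
        x_opt = optimal_thickness(OpticalParams(intensity, mu, threshold))
        assert optimal_intensity(threshold, mu, x_opt) == pytest.approx(intensity, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(triples, st.floats(1.01, 10))
    def test_monotonicity(self, triple, factor):
        threshold, ratio, mu = triple
        intensity = threshold * ratio
        base = optimal_thickness(OpticalParams(intensity, mu, threshold))
        assert optimal_thickness(OpticalParams(intensity * factor, mu, threshold)) > base
        assert optimal_thickness(OpticalParams(intensity, mu * factor, threshold)) < base
        if intensity / (threshold * factor) > 1:
            assert optimal_thickness(OpticalParams(intensity, mu, threshold * factor)) < base

    def test_discrete_optimum_counts_whole_depth_bins(self):
        # continuous optima 34.99, 51.26, 66.22, 44.15 um -> 35, 51, 66, 44 bins
        for intensity, bins in [(30, 35), (50, 51), (80, 66), (40, 44)]:
            params = OpticalParams(intensity, 314, 10)
            assert discrete_optimal_thickness(params) == bins


class TestSensitivity:
    def test_ideal_range_is_unity(self):
        assert sensitivity_piecewise(30, 35) == 1.0

    def test_undersampled_green_microspheres(self, green_params):
        x_opt = optimal_thickness(green_params)
        assert sensitivity_piecewise(100, x_opt) == pytest.approx(0.5815, abs=0.0005)

    def test_reciprocal_halving(self):
        assert sensitivity_piecewise(2 * 42.52, 42.52) == 0.5

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.1, 500), st.floats(1.01, 20))
    def test_loglog_identity_in_suboptimal_range(self, x_opt, factor):
        # log Sens = -log X + log X_opt, a -45 degree line
        x = x_opt * factor
        s = sensitivity_piecewise(x, x_opt)
        assert math.log(s) + math.log(x) - math.log(x_opt) == pytest.approx(0, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1, 200))
    def test_non_increasing_in_thickness(self, x_opt):
        xs = np.linspace(1, 400, 100)
        sens = [sensitivity_piecewise(x, x_opt) for x in xs]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


def test_expected_count_ceiling_and_cap():
    assert expected_count(20, 20, 7) == 7  # X = e resolves every cell
    assert expected_count(20, 40, 7) == 4  # ceil(3.5)
    assert expected_count(20, 10, 7) == 7  # oversampling capped at N


def test_corrected_count_inverts_sensitivity():
    assert corrected_count(58, 0.58) == pytest.approx(100)
    assert corrected_count(42, 1.0) == 42
    with pytest.raises(ZeroDivisionError):
        corrected_count(10, 0.0)
    with pytest.raises(ValueError):
        corrected_count(10, 1.5)


class TestMixture:
    def test_single_group_reduces_to_piecewise(self):
        mix = IntensityMixture(((30, 5),))
        x_opt = optimal_thickness(OpticalParams(30, 314, 10))
        for x in (20, 50, 120):
            assert mixture_sensitivity(mix, x, 314, 10) == pytest.approx(
                sensitivity_piecewise(x, x_opt)
            )

    def test_group_below_threshold_contributes_zero(self):
        assert mixture_sensitivity(IntensityMixture(((5, 10),)), 20, 314, 10) == 0.0

    def test_two_group_weighted_average(self):
        # equal groups at 30 and 80 gray: (34.99/66 + 1)/2
        mix = IntensityMixture(((30, 4), (80, 4)))
        assert mixture_sensitivity(mix, 66, 314, 10) == pytest.approx(0.765, abs=0.001)

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            IntensityMixture(())


class TestDepthDistribution:
    def test_uniform_density_reduces_to_piecewise(self):
        dist = DepthDistribution.uniform(100.0)
        for x_opt in (20.0, 58.15):
            assert distribution_sensitivity(dist, 100.0, x_opt) == pytest.approx(
                sensitivity_piecewise(100.0, x_opt), abs=1e-6
            )

    def test_mass_inside_optimum_gives_unity(self):
        grid = np.linspace(0, 100, 1001)
        density = np.where(grid <= 30, 1 / 30, 0.0)
        density /= np.trapezoid(density, grid)
        dist = DepthDistribution(grid, density)
        assert distribution_sensitivity(dist, 100, 40) == pytest.approx(1.0, abs=1e-3)

    def test_triangular_density_matches_refined_oracle(self):
        x, x_opt = 100.0, 42.0
        grid = np.linspace(0, x, 201)
        density = 2 * (1 - grid / x) / x
        dist = DepthDistribution(grid, density)
        # brute-force quadrature at 10x the grid resolution
        fine = np.linspace(0, x, 2001)
        pdf = 2 * (1 - fine / x) / x
        oracle = np.trapezoid(pdf[fine <= x_opt], fine[fine <= x_opt]) / np.trapezoid(pdf, fine)
        assert distribution_sensitivity(dist, x, x_opt) == pytest.approx(oracle, abs=1e-6)

    def test_empty_slice_rejected(self):
        grid = np.linspace(0, 200, 401)
        density = np.where(grid >= 150, 4 / 200, 0.0)
        density /= np.trapezoid(density, grid)
        with pytest.raises(EmptySliceError):
            distribution_sensitivity(DepthDistribution(grid, density), 100, 40)

    def test_density_must_normalise(self):
        grid = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            DepthDistribution(grid, np.full(11, 0.5))


class TestPooling:
    def test_identical_components_unchanged(self):
        dist = DepthDistribution.uniform(50.0)
        pooled = pool_distributions([(3, dist), (7, dist)])
        assert np.allclose(pooled.density, dist.density)

    def test_counts_become_weights(self):
        grid = np.linspace(0, 100, 1001)

        def bump(center):
            d = np.exp(-0.5 * ((grid - center) / 2.0) ** 2)
            return DepthDistribution(grid, d / np.trapezoid(d, grid))

        a, b = bump(20), bump(70)
        pooled = pool_distributions([(1, a), (3, b)])
        assert np.allclose(pooled.density, 0.25 * a.density + 0.75 * b.density)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            pool_distributions(
                [(1, DepthDistribution.uniform(50.0)), (1, DepthDistribution.uniform(60.0))]
            )
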