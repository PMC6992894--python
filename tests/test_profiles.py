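"""Profile extraction: plane means, masking, normalization, contour depths."""

import numpy as np
import pytest

from crpen import (
    DegenerateProfileError,
    DepthProfile,
    FiberMaskSet,
    InputError,
    NotYetPenetratedError,
    StackSeries,
    build_contours,
    contour_depth,
    fluorescence,
    masked_profile,
    mean_profile,
    normalize_profile,
    slope_at_level,
)
from crpen.exceptions import InsufficientDataError


def _series_from_planes(plane_values, z_step=1.0, surface_index=0, times=(10.0,)):
    """Build a single-time series whose planes are constant at the given values."""
    stack = np.repeat(
        np.asarray(plane_values, dtype=float)[:, None, None], 4, axis=1
    ).repeat(4, axis=2)
    return StackSeries(
        times=np.asarray(times), stacks=[stack], z_step=z_step, surface_index=surface_index
    )


class TestMeanProfile:
    def test_constant_stack_gives_flat_profile(self):
        series = _series_from_planes([7.0] * 10)
        p = mean_profile(series, 0)
        assert np.all(p.intensity == 7.0)
        np.testing.assert_allclose(p.depths, np.arange(10.0))

    def test_depths_measured_from_surface_plane(self):
        series = _series_from_planes([1.0] * 12, z_step=0.5, surface_index=3)
        p = mean_profile(series, 0)
        assert p.depths[0] == 0.0
        assert len(p.depths) == 9
        assert p.depths[-1] == pytest.approx(8 * 0.5)

    def test_matches_forward_model_on_noiseless_stack(self, standard_params, noiseless_series):
        p = mean_profile(noiseless_series, 2)
        expected = fluorescence(standard_params, p.time, p.depths)
        np.testing.assert_allclose(p.intensity / p.intensity.max(), expected, atol=1e-12)

    def test_step_stack_gives_step_profile(self):
        series = _series_from_planes([5.0, 5.0, 0.0, 0.0])
        p = mean_profile(series, 0)
        np.testing.assert_array_equal(p.intensity, [5.0, 5.0, 0.0, 0.0])


class TestMaskedProfile:
    def _fiber_series(self):
        rng = np.random.default_rng(3)
        depth_law = np.linspace(1.0, 0.0, 8)
        stack = np.zeros((8, 6, 6))
        stack += depth_law[:, None, None]
        series = StackSeries(
            times=np.array([5.0]), stacks=[stack], z_step=1.0, surface_index=0
        )
        return series

    def test_full_mask_equals_mean_profile(self):
        series = self._fiber_series()
        full = FiberMaskSet(masks=[np.ones((8, 6, 6), dtype=bool)])
        np.testing.assert_allclose(
            masked_profile(series, 0, full).intensity,
            mean_profile(series, 0).intensity,
        )

    def test_disjoint_masks_with_identical_signal_average_to_same_profile(self):
        series = self._fiber_series()
        m1 = np.zeros((8, 6, 6), dtype=bool)
        m2 = np.zeros((8, 6, 6), dtype=bool)
        m1[:, 1, 1] = True
        m2[:, 4, 4] = True
        two = masked_profile(series, 0, FiberMaskSet(masks=[m1, m2]))
        one = masked_profile(series, 0, FiberMaskSet(masks=[m1]))
        np.testing.assert_allclose(two.intensity, one.intensity)

    def test_empty_masks_rejected(self):
        with pytest.raises(InputError):
            FiberMaskSet(masks=[np.zeros((2, 2, 2), dtype=bool)])


class TestNormalizeProfile:
    def test_affine_invariance(self, standard_params):
        z = np.arange(0.0, 30.0)
        model = np.asarray(fluorescence(standard_params, 300.0, z))
        raw = DepthProfile(time=300.0, depths=z, intensity=1234.5 * model + 60.0)
        norm = normalize_profile(raw, background=60.0)
        np.testing.assert_allclose(norm.intensity, model, atol=1e-9)

    def test_background_as_fraction_of_plateau(self, standard_params):
        # a GFP-like profile with a 10% background floor folded into the signal
        z = np.arange(0.0, 30.0)
        model = np.asarray(fluorescence(standard_params, 300.0, z))
        scale, bg = 800.0, 0.1
        raw_vals = scale * (bg + (1.0 - bg) * model)
        raw = DepthProfile(time=300.0, depths=z, intensity=raw_vals)
        norm = normalize_profile(raw, background=0.1, background_is_fraction=True)
        np.testing.assert_allclose(norm.intensity, model, atol=1e-9)

    def test_flat_background_profile_is_degenerate(self):
        raw = DepthProfile(
            time=10.0, depths=np.arange(5.0), intensity=np.full(5, 60.0)
        )
        with pytest.raises(DegenerateProfileError):
            normalize_profile(raw, background=60.0)

    def test_negative_noise_clipped_to_zero(self):
        raw = DepthProfile(
            time=10.0,
            depths=np.arange(6.0),
            intensity=np.array([100.0, 100.0, 100.0, 5.0, 2.0, 4.0]),
        )
        norm = normalize_profile(raw, background=4.0)
        assert np.all(norm.intensity >= 0.0)


class TestContourDepth:
    def test_step_profile_interpolates_midpoint(self):
        p = DepthProfile(
            time=1.0,
            depths=np.arange(10.0),
            intensity=np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=float),
            normalized=True,
        )
        assert contour_depth(p, 0.5) == pytest.approx(5.5)

    def test_matches_forward_model_half_depth(self, hm20_params):
        z = np.arange(0.0, 25.0, 0.5)
        p = DepthProfile(
            time=100.0,
            depths=z,
            intensity=np.asarray(fluorescence(hm20_params, 100.0, z)),
            normalized=True,
        )
        # published 0.5-contour slope 0.210 => 2.10 um at t=100 s
        assert contour_depth(p, 0.5) == pytest.approx(2.10, abs=0.02)

    def test_level_above_plateau_not_yet_penetrated(self):
        p = DepthProfile(
            time=1.0,
            depths=np.arange(5.0),
            intensity=np.array([0.8, 0.7, 0.5, 0.3, 0.1]),
            normalized=True,
        )
        with pytest.raises(NotYetPenetratedError):
            contour_depth(p, 0.9)

    def test_first_downward_crossing_wins_on_bumpy_tail(self):
        p = DepthProfile(
            time=1.0,
            depths=np.arange(6.0),
            intensity=np.array([1.0, 0.9, 0.4, 0.6, 0.4, 0.1]),
            normalized=True,
        )
        # crossing of 0.5 between depths 1 and 2, not the later re-crossing
        assert 1.0 < contour_depth(p, 0.5) < 2.0

    def test_monotone_decreasing_in_level(self, standard_params):
        z = np.arange(0.0, 30.0)
        p = DepthProfile(
            time=300.0,
            depths=z,
            intensity=np.asarray(fluorescence(standard_params, 300.0, z)),
            normalized=True,
        )
        depths = [contour_depth(p, lv) for lv in (0.3, 0.5, 0.7, 0.9)]
        assert depths == sorted(depths, reverse=True)


class TestBuildContours:
    def _profiles(self, params, times, z_max=40.0, z_step=1.0):
        z = np.arange(0.0, z_max, z_step)
        return [
            DepthProfile(
                time=t,
                depths=z,
                intensity=np.asarray(fluorescence(params, t, z)),
                normalized=True,
            )
            for t in times
        ]

    def test_noiseless_contours_follow_sqrt_t_slope(self, standard_params):
        times = [50.0, 150.0, 300.0, 650.0]
        contours = build_contours(self._profiles(standard_params, times), [0.5])
        expected = slope_at_level(standard_params, 0.5) * np.sqrt(times)
        np.testing.assert_allclose(contours[0].depths, expected, rtol=0.01)

    def test_level_ordering_between_series(self, standard_params):
        contours = build_contours(
            self._profiles(standard_params, [50.0, 150.0, 300.0]), [0.5, 0.9]
        )
        by_level = {c.level: c for c in contours}
        assert np.all(by_level[0.5].depths > by_level[0.9].depths)

    def test_single_usable_time_rejected(self, standard_params):
        with pytest.raises(InsufficientDataError):
            build_contours(self._profiles(standard_params, [50.0]), [0.5])
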