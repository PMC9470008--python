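"""Spiral waveform design and rotated stack-of-spirals assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaspiral.trajectory import (GOLDEN13_INCREMENT, GOLDEN_ANGLE,
                                 RotationSchedule, SpiralDesignError,
                                 build_trajectory, design_vd_spiral,
                                 rotation_angle, schedule_period,
                                 slice_encode_order,
                                 undersampling_profile)

GAMMA_CM = 425.764


class TestVDSpiralDesign:
    def test_kmax_matches_resolution(self, waveform):
        # k_max = 1/(2 * resolution); 2.88 mm -> 1.736 cycles/cm
        wf = design_vd_spiral(fov=24.0, target_resolution=2.88,
                              duration=6.144)
        assert wf.k_max == pytest.approx(1.0 / (2 * 0.288), rel=1e-12)
        assert wf.k_max == pytest.approx(1.736, abs=5e-4)

    def test_starts_at_origin_radius_monotone(self, waveform):
        assert waveform.k_samples[0] == 0
        r = np.abs(waveform.k_samples)
        assert np.all(np.diff(r) > -1e-9 * waveform.k_max)
        assert r[-1] == pytest.approx(waveform.k_max, rel=2e-3)

    def test_duration_and_sample_count(self, waveform):
        assert waveform.n_samples * waveform.dwell == pytest.approx(
            3.0e3, abs=waveform.dwell)

    def test_gradient_and_slew_limits(self):
        wf = design_vd_spiral(fov=24.0, target_resolution=2.88,
                              g_max=40.0, slew_max=150.0, duration=6.144)
        g = np.abs(wf.g_samples)
        slew = np.abs(np.diff(wf.g_samples)) / (wf.dwell * 1e-6) / 1e3
        assert g.max() <= 40.0 * 1.01
        assert slew.max() <= 150.0 * 1.01

    def test_density_endpoints(self, waveform):
        """Single-shot pitch: Nyquist in the core, 8x relaxed at the edge."""
        th = np.unwrap(np.angle(waveform.k_samples[1:]))
        r = np.abs(waveform.k_samples[1:])
        drdth = np.gradient(r, th)
        measured_u = 2 * np.pi * drdth * 24.0  # pitch / (1/fov)
        rn = r / waveform.k_max
        core = (rn > 0.01) & (rn < 0.04)
        edge = rn > 0.97
        assert np.median(measured_u[core]) == pytest.approx(1.0, rel=0.05)
        assert np.median(measured_u[edge]) == pytest.approx(8.0, rel=0.05)

    def test_density_profile_monotone_between_endpoints(self, waveform):
        th = np.unwrap(np.angle(waveform.k_samples[1:]))
        r = np.abs(waveform.k_samples[1:])
        drdth = np.gradient(r, th)
        measured_u = 2 * np.pi * drdth * 24.0
        rn = r / waveform.k_max
        # binned profile grows monotonically and tracks the target within 20%
        bins = np.linspace(0.05, 1.0, 12)
        prof = [np.median(measured_u[(rn >= a) & (rn < b)])
                for a, b in zip(bins[:-1], bins[1:])]
        assert np.all(np.diff(prof) > -0.05)
        target = undersampling_profile(0.5 * (bins[:-1] + bins[1:]),
                                       0.05, 8.0)
        assert np.all(np.abs(np.asarray(prof) / target - 1.0) < 0.2)

    def test_uniform_limit_gap_is_inverse_fov(self):
        wf = design_vd_spiral(fov=24.0, target_resolution=7.5,
                              inner_full_fraction=1.0,
                              outer_undersampling=1.0, duration=8.0)
        th = np.unwrap(np.angle(wf.k_samples[1:]))
        r = np.abs(wf.k_samples[1:])
        from scipy.interpolate import interp1d
        f = interp1d(th, r)
        probe = np.linspace(th[0] + 0.2, th[-1] - 2 * np.pi - 0.2, 24)
        gaps = f(probe + 2 * np.pi) - f(probe)
        assert np.allclose(gaps, 1.0 / 24.0, rtol=0.02)

    def test_infeasible_duration_raises_named_constraint(self):
        with pytest.raises(SpiralDesignError, match="constraint"):
            design_vd_spiral(fov=24.0, target_resolution=2.88,
                             duration=0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            design_vd_spiral(fov=-1.0, target_resolution=2.88)
        with pytest.raises(ValueError):
            design_vd_spiral(fov=24.0, target_resolution=2.88,
                             outer_undersampling=0.5)

    def test_single_shot_voronoi_density_tracks_profile(self):
        """Voronoi cell areas grow from Nyquist at the core to 8x Nyquist.

        Uses the fine full-geometry waveform (1536 samples) so enough
        spiral turns exist for bounded Voronoi cells at every radius.
        """
        from scipy.spatial import Voronoi
        wf = design_vd_spiral(fov=24.0, target_resolution=2.88,
                              duration=6.144)
        pts = np.stack([wf.k_samples.real, wf.k_samples.imag], -1)
        vor = Voronoi(pts[1:])  # skip the k=0 origin sample
        rn = np.abs(wf.k_samples[1:]) / wf.k_max
        areas = np.full(len(rn), np.nan)
        for i, reg in enumerate(vor.point_region):
            v = vor.regions[reg]
            if -1 in v or not v:
                continue
            poly = vor.vertices[v]
            x, y = poly[:, 0], poly[:, 1]
            areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1))
                                 - np.dot(y, np.roll(x, 1)))
        # cell area ~ along-track spacing * radial gap; divide the track
        # spacing out to isolate the radial (undersampling) density
        ds = np.abs(np.diff(wf.k_samples))
        ds = 0.5 * (np.concatenate([[ds[0]], ds])
                    + np.concatenate([ds, [ds[-1]]]))[1:]
        u = areas / ds * 24.0
        ok = np.isfinite(u) & (rn > 0.08) & (rn < 0.85)
        bins = np.linspace(0.08, 0.85, 10)
        prof = np.array([np.median(u[ok][(rn[ok] >= a) & (rn[ok] < b)])
                         for a, b in zip(bins[:-1], bins[1:])])
        target = undersampling_profile(0.5 * (bins[:-1] + bins[1:]),
                                       0.05, 8.0)
        assert np.all(np.abs(prof / target - 1.0) < 0.2)
        assert np.all(np.diff(prof) > -0.1)


class TestRotationSchedule:
    def test_angle_examples(self):
        assert rotation_angle(0, 1) == 0.0
        assert np.degrees(rotation_angle(1, 1)) == pytest.approx(
            138.46, abs=0.01)
        assert rotation_angle(13, 1, n_slice_encodes=32) == pytest.approx(
            0.0, abs=1e-12)

    def test_angle_formula_and_reduction(self):
        sched = RotationSchedule(n_slice_encodes=32)
        for se, il in [(-16, 1), (5, 7), (15, 13)]:
            expect = np.mod(GOLDEN13_INCREMENT * (se + il - 1), 2 * np.pi)
            assert sched.angle(se, il) == pytest.approx(expect, abs=1e-13)

    def test_out_of_range_slice_encode(self):
        sched = RotationSchedule(n_slice_encodes=32)
        with pytest.raises(IndexError):
            sched.angle(16, 1)
        with pytest.raises(IndexError):
            sched.angle(0, 0)

    @given(se=st.integers(-16, 15), il=st.integers(1, 39))
    @settings(deadline=None, max_examples=50)
    def test_angle_always_reduced(self, se, il):
        a = rotation_angle(se, il, n_slice_encodes=32)
        assert 0.0 <= a < 2 * np.pi

    def test_period_golden13_is_13(self):
        assert schedule_period(GOLDEN13_INCREMENT) == 13

    def test_period_quarter_turn(self):
        assert schedule_period(np.pi / 2) == 4

    def test_true_golden_angle_aperiodic(self):
        assert schedule_period(GOLDEN_ANGLE, cap=10**6) is None


class TestSliceEncodeOrder:
    def test_centric_small(self):
        assert list(slice_encode_order(4, "centric")) == [0, 1, -1, -2]

    def test_linear(self):
        assert list(slice_encode_order(4, "linear")) == [-2, -1, 0, 1]

    def test_centric_is_permutation_starting_at_zero(self):
        order = slice_encode_order(32, "centric")
        assert order[0] == 0
        assert sorted(order) == list(range(-16, 16))

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            slice_encode_order(5)


class TestBuildTrajectory:
    def test_rotation_set_uniform_per_kz(self, trajectory):
        """13 interleaves tile every kz plane with 2*pi/13-spaced angles."""
        for e in range(trajectory.n_echoes):
            ang = np.sort(trajectory.angles[:, e])
            gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
            assert np.allclose(gaps, 2 * np.pi / 13, atol=1e-12)

    def test_each_kz_visited_once_per_shot(self, trajectory):
        dkz = 1.0 / (8 * 0.4)
        for j in range(trajectory.n_shots):
            kz = trajectory.kz[j, :, 0] / dkz
            assert sorted(np.round(kz).astype(int)) == list(range(-4, 4))

    def test_rotation_across_kz_within_shot(self, waveform):
        """Within one shot, echo angles follow increment * slice_encode."""
        sched = RotationSchedule(n_slice_encodes=2)
        traj = build_trajectory(waveform, sched, 2, 4.0, 24.0, 32)
        for e, se in enumerate(traj.slice_encode_order):
            expect = np.mod(GOLDEN13_INCREMENT * se, 2 * np.pi)
            assert traj.angles[0, e] == pytest.approx(expect, abs=1e-12)

    def test_identity_schedule_shares_orientation(self, waveform):
        sched = RotationSchedule(increment=0.0, n_slice_encodes=8)
        traj = build_trajectory(waveform, sched, 8, 4.0, 24.0, 32)
        assert np.all(traj.angles == 0.0)
        # in-plane samples identical across echoes
        assert np.allclose(traj.kx[0, 0], traj.kx[0, 7])

    def test_conventional_mode_equals_direct_construction(self, waveform):
        """Unrotated stack = the waveform replicated on every kz plane."""
        sched = RotationSchedule(increment=0.0, n_slice_encodes=4)
        traj = build_trajectory(waveform, sched, 4, 4.0, 24.0, 32,
                                order_mode="linear")
        for j in range(traj.n_shots):
            for e in range(4):
                assert np.array_equal(traj.kx[j, e],
                                      waveform.k_samples.real)
                assert np.array_equal(traj.ky[j, e],
                                      waveform.k_samples.imag)

    def test_slice_count_mismatch_rejected(self, waveform):
        sched = RotationSchedule(n_slice_encodes=16)
        with pytest.raises(ValueError):
            build_trajectory(waveform, sched, 8, 4.0, 24.0, 32)
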