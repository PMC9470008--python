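"""Reconstruction pipeline: subtraction, corrections, solvers, ESPIRiT, CS."""

import numpy as np
import pytest

from gaspiral.nufft import NufftOperator
from gaspiral.phantom import (make_coils, perfusion_image, simulate_kspace,
                              simulate_acquisition)
from gaspiral.recon import (ReconConfig, adjoint_recon, cg_sense,
                            density_compensation, echo_decay_correction,
                            estimate_sensitivities, fermi_filter,
                            recon_cs, recon_l2, reconstruct_series,
                            subtract_kspace, sum_of_squares)
from gaspiral.sequence import (EchoTrain, build_acquisition_schedule,
                               epg_echo_amplitudes)

from conftest import MATRIX, in_support_nrmse


class TestSubtract:
    def test_equal_inputs_zero(self, clean_kspace):
        out = subtract_kspace(clean_kspace, clean_kspace)
        assert np.all(out.data == 0)
        assert all(t == "dm" for t in out.tags)

    def test_zero_label_passthrough(self, clean_kspace):
        zero = clean_kspace.copy_with(data=np.zeros_like(clean_kspace.data))
        out = subtract_kspace(clean_kspace, zero)
        assert np.array_equal(out.data, clean_kspace.data)

    def test_acquisition_subtraction_matches_forward_model(
            self, phantom, trajectory, coils, clean_kspace):
        """control - label equals the dM forward projection exactly."""
        sched = build_acquisition_schedule(13, 1)
        label, control = simulate_acquisition(phantom, trajectory, coils,
                                              sched)
        dm = subtract_kspace(control, label)
        for p in range(13):
            il = dm.interleaves[p] - 1
            assert np.allclose(dm.data[p], clean_kspace.data[il],
                               rtol=1e-10, atol=1e-13)

    def test_mismatched_pairing_rejected(self, clean_kspace):
        other = clean_kspace.copy_with()
        other.interleaves = other.interleaves[::-1].copy()
        with pytest.raises(ValueError):
            subtract_kspace(clean_kspace, other)


class TestDecayCorrection:
    def test_constant_amplitudes_identity(self, clean_kspace):
        out = echo_decay_correction(clean_kspace, np.ones(8))
        assert np.array_equal(out.data, clean_kspace.data)

    def test_half_amplitude_doubles(self, clean_kspace):
        amps = np.ones(8)
        amps[1] = 0.5
        out = echo_decay_correction(clean_kspace, amps)
        assert np.allclose(out.data[:, 1], 2.0 * clean_kspace.data[:, 1])
        assert np.allclose(out.data[:, 2], clean_kspace.data[:, 2])

    def test_inverts_simulated_decay(self, dm_truth, trajectory, coils,
                                     clean_kspace):
        train = EchoTrain(np.full(8, 120.0))
        amps = epg_echo_amplitudes(train, T1=1400.0, T2=100.0)
        decayed = simulate_kspace(dm_truth, trajectory, coils,
                                  echo_amplitudes=amps)
        fixed = echo_decay_correction(decayed, amps)
        assert np.allclose(fixed.data, amps[0] * clean_kspace.data,
                           rtol=1e-9)

    def test_zero_amplitude_rejected(self, clean_kspace):
        with pytest.raises(ValueError):
            echo_decay_correction(clean_kspace, np.zeros(8))


class TestFermiFilter:
    def test_center_gain_near_unity(self, clean_kspace):
        out = fermi_filter(clean_kspace, 0.9, 0.06)
        # the k = 0 sample (first sample of every spiral) is barely touched
        expected = 1.0 / (1.0 + np.exp(-0.9 / 0.06))
        ratio = out.data[0, 0, 0, 0] / clean_kspace.data[0, 0, 0, 0]
        assert ratio.real == pytest.approx(expected, rel=1e-6)

    def test_half_gain_at_cutoff(self, trajectory, coils, dm_truth):
        ds = simulate_kspace(dm_truth, trajectory, coils)
        out = fermi_filter(ds, 0.9, 0.06)
        traj = ds.trajectory
        kmax = [n / (2 * f) for n, f in zip(traj.matrix, traj.fov)]
        rad = np.sqrt((traj.kx / kmax[0]) ** 2 + (traj.ky / kmax[1]) ** 2
                      + (traj.kz / kmax[2]) ** 2)
        idx = np.unravel_index(np.argmin(np.abs(rad - 0.9)), rad.shape)
        ratio = (out.data[idx][0] / ds.data[idx][0]).real
        gain = 1.0 / (1.0 + np.exp((rad[idx] - 0.9) / 0.06))
        assert ratio == pytest.approx(gain, rel=1e-9)
        assert abs(gain - 0.5) < 0.05

    def test_suppresses_high_band(self, noisy_kspace):
        """Filtered recon carries less energy beyond 0.9 k_max."""
        from scipy.fft import fftn, fftshift, ifftshift
        filt = fermi_filter(noisy_kspace, 0.9, 0.06)
        raw_img = sum_of_squares(adjoint_recon(noisy_kspace))
        f_img = sum_of_squares(adjoint_recon(filt))
        def band_energy(img):
            spec = np.abs(fftshift(fftn(ifftshift(img)))) ** 2
            n = img.shape
            g = np.meshgrid(*[(np.arange(d) - d // 2) / (d / 2)
                              for d in n], indexing="ij")
            rad = np.sqrt(sum(a ** 2 for a in g))
            return spec[rad > 0.9].sum()
        assert band_energy(f_img) < 0.5 * band_energy(raw_img)


class TestLinearRecon:
    def test_fully_sampled_l2_accuracy(self, clean_kspace, dm_truth,
                                       phantom):
        """Noiseless 13-interleave set reconstructs below 10% NRMSE."""
        sos = sum_of_squares(recon_l2(clean_kspace, 0.01))
        assert in_support_nrmse(sos, dm_truth, phantom.support) < 0.10

    def test_adjoint_dcf_accuracy(self, clean_kspace, dm_truth, phantom):
        sos = sum_of_squares(adjoint_recon(clean_kspace))
        assert in_support_nrmse(sos, dm_truth, phantom.support) < 0.10

    def test_large_lambda_shrinks_solution(self, clean_kspace):
        norms = []
        for lam in (0.01, 1.0, 100.0):
            vols = recon_l2(clean_kspace, lam, cg_iterations=15)
            norms.append(np.linalg.norm(sum_of_squares(vols)))
        assert norms[0] > norms[1] > norms[2]

    def test_zero_data_zero_image(self, clean_kspace):
        zero = clean_kspace.copy_with(data=np.zeros_like(clean_kspace.data))
        vols = recon_l2(zero, 0.01, cg_iterations=5)
        assert np.all(sum_of_squares(vols) == 0)

    def test_sos_single_and_duplicate_coils(self):
        vol = np.random.default_rng(0).normal(size=(4, 4, 2)) \
            + 1j * np.random.default_rng(1).normal(size=(4, 4, 2))
        assert np.allclose(sum_of_squares([vol]), np.abs(vol))
        assert np.allclose(sum_of_squares([vol, vol]),
                           np.sqrt(2) * np.abs(vol))


class TestEspirit:
    def test_recovers_known_smooth_coils(self, espirit_maps, coils,
                                         phantom):
        """Estimated maps match truth up to a voxelwise phase."""
        m = espirit_maps.mask & phantom.support
        est = espirit_maps.maps[:, m]
        tru = coils.profiles[:, m]
        num = np.abs(np.sum(np.conj(est) * tru, axis=0))
        den = np.linalg.norm(est, axis=0) * np.linalg.norm(tru, axis=0)
        assert np.median(num / den) > 0.98

    def test_uniform_single_coil(self, phantom):
        from scipy.fft import fftn, fftshift, ifftshift
        img = phantom.m0.astype(complex)
        ck = np.stack([fftshift(fftn(ifftshift(img)))])
        maps = estimate_sensitivities(ck, kernel=(4, 4, 4),
                                      calib=(16, 16, 8))
        m = maps.mask & phantom.support
        assert m.sum() > 0
        assert np.allclose(np.abs(maps.maps[0][m]), 1.0, atol=1e-6)
        assert np.median(maps.eigenvalues[phantom.support]) > 0.98

    def test_thresholding_contract(self, espirit_maps):
        below = espirit_maps.eigenvalues < 0.8
        assert np.all(espirit_maps.maps[:, below] == 0)

    def test_small_calibration_rejected(self):
        ck = np.zeros((2, 16, 16, 8), complex)
        with pytest.raises(ValueError):
            estimate_sensitivities(ck, kernel=(6, 6, 6), calib=(4, 4, 4))


def _admm_vs_cg_sense_well_posed(n, fov, seed=0):
    """Relative difference of ADMM(lambda1=0) and CG-SENSE on a
    well-conditioned SENSE problem (full Cartesian sampling, RSS-1 coils)."""
    import gaspiral.recon as R
    rng = np.random.default_rng(seed)
    ki = np.stack(np.meshgrid(
        *[np.arange(-d // 2, d // 2) for d in n], indexing="ij"),
        -1).reshape(-1, 3) / np.array(fov)
    plan = NufftOperator(ki, n, fov)
    x, y, z = np.meshgrid(*[np.linspace(-1, 1, d) for d in n],
                          indexing="ij")
    phi = 0.3 + 0.45 * (1 + np.sin(1.3 * x + 0.7 * y + 0.5 * z))
    maps = R.CoilSensitivityMaps(
        np.stack([np.cos(phi), np.sin(phi) * np.exp(0.5j * x)]),
        np.ones(n, bool))
    truth = (rng.normal(size=n) + 1j * rng.normal(size=n))
    E = R._SenseOperator(plan, maps.maps)
    d = E.forward(truth) + 0.01 * (
        rng.normal(size=(plan.n_samples, 2))
        + 1j * rng.normal(size=(plan.n_samples, 2)))
    cfg = ReconConfig(admm_iterations=40, inner_cg_iterations=10)
    v_admm = recon_cs(d, maps, cfg, plan=plan, lambda_l1=0.0)
    v_cg = cg_sense(d, plan, maps.maps, n_iter=100, tol=1e-12)
    return np.linalg.norm(v_admm.data - v_cg) / np.linalg.norm(v_cg)


@pytest.fixture(scope="module")
def shot_plan(trajectory):
    return NufftOperator(trajectory.coords(shots=0), trajectory.matrix,
                         trajectory.fov)


class TestCompressedSensing:
    def test_zero_data_zero_image(self, espirit_maps, shot_plan):
        cfg = ReconConfig(admm_iterations=5)
        vol = recon_cs(np.zeros((shot_plan.n_samples, 4), complex),
                       espirit_maps, cfg, plan=shot_plan)
        assert np.allclose(vol.data, 0.0)

    def test_lambda_zero_matches_cg_sense(self):
        """With no L1 term the ADMM solution equals CG-SENSE.

        Asserted where the least-squares minimizer is unique (full
        Cartesian coverage, RSS-1 maps, so E^H E is proportional to the
        identity); on undersampled data the two solvers agree only up to
        the weakly determined subspace.
        """
        import gaspiral.recon as R
        n, fov = (16, 16, 8), (16.0, 16.0, 8.0)
        rel = _admm_vs_cg_sense_well_posed(n, fov, seed=0)
        assert rel < 1e-3

    def test_cs_beats_zero_filled_on_undersampled_shot(
            self, noisy_kspace, espirit_maps, shot_plan, dm_truth,
            phantom):
        """Single 8x-undersampled shot: CS >= 20% lower NRMSE than the
        density-compensated adjoint of the same data."""
        d = noisy_kspace.data[0].reshape(-1, noisy_kspace.n_coils)
        w = density_compensation(shot_plan)
        zf = sum_of_squares([shot_plan.adjoint(w * d[:, c])
                             for c in range(noisy_kspace.n_coils)])
        cfg = ReconConfig(admm_iterations=60)
        vol = recon_cs(noisy_kspace.data[0], espirit_maps, cfg,
                       plan=shot_plan)
        e_zf = in_support_nrmse(zf, dm_truth, phantom.support)
        e_cs = in_support_nrmse(vol.data, dm_truth, phantom.support)
        assert e_cs <= 0.8 * e_zf

    def test_intensity_linearity(self, noisy_kspace, espirit_maps,
                                 shot_plan):
        """Scaling the data scales the solution (no data rescaling)."""
        cfg = ReconConfig(admm_iterations=25)
        v1 = recon_cs(noisy_kspace.data[0], espirit_maps, cfg,
                      plan=shot_plan)
        v2 = recon_cs(3.0 * noisy_kspace.data[0], espirit_maps, cfg,
                      plan=shot_plan)
        rel = np.linalg.norm(v2.data - 3.0 * v1.data) \
            / np.linalg.norm(3.0 * v1.data)
        assert rel < 1e-3

    def test_objective_monotone_after_burnin(self, noisy_kspace,
                                             espirit_maps, shot_plan):
        cfg = ReconConfig(admm_iterations=40)
        _, obj = recon_cs(noisy_kspace.data[0], espirit_maps, cfg,
                          plan=shot_plan, return_objective=True)
        tail = obj[5:]
        assert np.all(np.diff(tail) <= np.abs(tail[:-1]) * 1e-6)


class TestReconstructSeries:
    def test_series_shape_and_static_consistency(self, phantom, trajectory,
                                                 coils):
        """Static phantom: volumes from the same interleave agree."""
        sched = build_acquisition_schedule(13, 2)
        label, control = simulate_acquisition(phantom, trajectory, coils,
                                              sched)
        cfg = ReconConfig(admm_iterations=15)
        series, avg, maps = reconstruct_series(label, control, cfg)
        assert len(series) == 26
        v0 = np.abs(series.volumes[0])
        v13 = np.abs(series.volumes[13])  # same interleave, next average
        rel = np.linalg.norm(v0 - v13) / np.linalg.norm(v0)
        assert rel < 1e-6

    def test_missing_interleave_rejected(self, phantom, trajectory, coils):
        sched = build_acquisition_schedule(13, 1)
        label, control = simulate_acquisition(phantom, trajectory, coils,
                                              sched)
        keep = label.interleaves != 5
        lab = label.copy_with(data=label.data[keep],
                              tags=[t for t, k in zip(label.tags, keep)
                                    if k])
        lab.interleaves = label.interleaves[keep]
        ctl = control.copy_with(data=control.data[keep],
                                tags=[t for t, k in zip(control.tags, keep)
                                      if k])
        ctl.interleaves = control.interleaves[keep]
        with pytest.raises(ValueError, match="5"):
            reconstruct_series(lab, ctl, ReconConfig(admm_iterations=2))
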