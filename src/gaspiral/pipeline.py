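"""End-to-end orchestration: design -> simulate -> reconstruct -> analyze.

``run_pipeline`` executes the whole study on the synthetic phantom under a
single configuration and seed: trajectory and flip-train design, raw
k-space simulation of the label/control schedule, time-averaged and
single-shot reconstructions, quality metrics, CBF quantification, and —
when a network is planted — seed-based correlation analysis.  All outputs
(NIfTI volumes/series, HDF5 raw data, JSON report) carry the configuration
hash and seed for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io, metrics
from .config import RunConfig, config_hash, save_config
from .dynamics import global_normalize, preprocess_series, seed_correlation
from .phantom import (FluctuationSpec, make_coils, make_phantom,
                      simulate_acquisition, simulate_kspace)
from .recon import (ReconConfig, recon_l2, reconstruct_series,
                    sum_of_squares, ImageVolume)
from .sequence import (BackgroundSuppressionSchedule,
                       build_acquisition_schedule,
                       design_constant_amplitude_flip_train,
                       epg_echo_amplitudes)
from .trajectory import (GOLDEN13_INCREMENT, GOLDEN_ANGLE, RotationSchedule,
                         build_trajectory, design_vd_spiral)

logger = logging.getLogger("gaspiral")

__all__ = ["run_pipeline", "design_from_config", "recon_config_from"]


def _increment(value) -> float:
    if value == "golden13":
        return GOLDEN13_INCREMENT
    if value == "golden":
        return GOLDEN_ANGLE
    if value == "none":
        return 0.0
    return float(value)


def design_from_config(cfg: RunConfig):
    """Design waveform, trajectory, flip train and schedules from a config."""
    t = cfg.trajectory
    wf = design_vd_spiral(
        fov=t.fov_cm, target_resolution=t.resolution_mm,
        nominal_interleaves=t.n_interleaves,
        inner_full_fraction=t.inner_full_fraction,
        outer_undersampling=t.outer_undersampling,
        g_max=t.g_max_mT_m, slew_max=t.slew_max_T_m_s,
        dwell=t.dwell_us, duration=t.duration_ms)
    rot = RotationSchedule(_increment(t.increment), t.n_interleaves,
                           t.n_slices)
    traj = build_trajectory(wf, rot, t.n_slices, t.slice_thickness_mm,
                            t.fov_cm, cfg.matrix[0], t.order)
    train = design_constant_amplitude_flip_train(
        t.n_slices, cfg.sequence.asymptotic_flip,
        cfg.sequence.echo_spacing_ms)
    schedule = build_acquisition_schedule(
        t.n_interleaves, cfg.sequence.n_averages, cfg.sequence.include_m0)
    return wf, traj, train, schedule


def recon_config_from(cfg: RunConfig) -> ReconConfig:
    r = cfg.recon
    return ReconConfig(
        lambda_l2=r.lambda_l2, lambda_l1=r.lambda_l1,
        lambda_l1_relative=r.lambda_l1_relative,
        admm_iterations=r.admm_iterations, admm_rho=r.admm_rho,
        cg_iterations=r.cg_iterations,
        espirit_eig_threshold=r.espirit_eig_threshold,
        espirit_null_threshold=r.espirit_null_threshold,
        fermi_cutoff=r.fermi_cutoff, fermi_width=r.fermi_width,
        wavelet_name=r.wavelet_name, wavelet_levels=r.wavelet_levels,
        t2_corr=r.t2_corr_ms, t1_corr=r.t1_corr_ms)


def run_pipeline(cfg: RunConfig | None = None, seed: int | None = None,
                 out_dir=None, write_outputs: bool = True) -> dict:
    """Run the full synthetic study; returns the JSON-serializable report."""
    cfg = cfg or RunConfig()
    if seed is not None:
        cfg = cfg.model_copy(deep=True)
        cfg.seed = int(seed)
    out = Path(out_dir or cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    report = {"config_hash": chash, "seed": cfg.seed, "stages": {}}

    def stage(name):
        logger.debug("pipeline stage: %s", name)
        report["stages"][name] = {"t_start": time.time()}
        return time.time()

    try:
        t0 = stage("design")
        wf, traj, train, schedule = design_from_config(cfg)
        amps = epg_echo_amplitudes(train, T1=cfg.sequence.t1_tissue_ms,
                                   T2=cfg.sequence.t2_tissue_ms)
        bs = BackgroundSuppressionSchedule(
            presat_end=cfg.sequence.presat_ms,
            inversion_times=tuple(cfg.sequence.bs_times_ms),
            inversion_efficiency=cfg.sequence.inversion_efficiency)
        report["stages"]["design"]["wall_s"] = time.time() - t0

        t0 = stage("simulate")
        matrix = cfg.matrix
        fov3 = (cfg.trajectory.fov_cm, cfg.trajectory.fov_cm,
                cfg.trajectory.n_slices
                * cfg.trajectory.slice_thickness_mm / 10.0)
        phantom = make_phantom(matrix, fov3, seed=cfg.seed)
        coils = make_coils(matrix, cfg.phantom.n_coils, seed=cfg.seed + 1)
        fluct = None
        if cfg.phantom.planted_network:
            fluct = _default_network(phantom, cfg)
        cbf_params = _cbf_params(cfg)
        # noise referenced to the perfusion-difference data (the signal the
        # reconstruction recovers), not the much larger M0 spectrum
        dm_probe = simulate_kspace(
            _truth_dm(phantom, cbf_params).astype(complex), traj, coils)
        noise_sd = cfg.phantom.noise_sd_relative * float(
            np.sqrt(np.mean(np.abs(dm_probe.data) ** 2)))
        label, control = simulate_acquisition(
            phantom, traj, coils, schedule, echo_amplitudes=amps,
            fluct=fluct, static_residual=cfg.phantom.static_residual,
            noise_sd=noise_sd, seed=cfg.seed + 2)
        m0_data = simulate_kspace(phantom.m0.astype(complex), traj, coils,
                                  echo_amplitudes=amps,
                                  noise_sd=noise_sd, seed=cfg.seed + 3,
                                  tag="m0")
        if write_outputs:
            io.write_raw(control, out / "raw_control.h5",
                         {"config_hash": chash})
            io.write_raw(label, out / "raw_label.h5",
                         {"config_hash": chash})
            io.save_nifti(phantom.m0, out / "truth_m0.nii.gz",
                          _voxels(traj))
        report["stages"]["simulate"]["wall_s"] = time.time() - t0
        report["noise_sd"] = noise_sd
        report["bs_residual_max_percent"] = 100.0 * max(
            abs(_bs_res(bs, t1)) for t1 in np.linspace(700, 4500, 200))

        t0 = stage("reconstruct")
        rcfg = recon_config_from(cfg)
        series, avg_vol, maps = reconstruct_series(
            label, control, rcfg, echo_amplitudes=amps,
            volume_interval=cfg.dynamics.volume_interval_s)
        m0_vol = ImageVolume(
            sum_of_squares(recon_l2(m0_data, rcfg.lambda_l2,
                                    cg_iterations=rcfg.cg_iterations)),
            avg_vol.voxel_size, units="M0 a.u.")
        if write_outputs:
            io.save_nifti(avg_vol, out / "perfusion_avg.nii.gz")
            io.save_nifti(series, out / "perfusion_series.nii.gz")
            io.save_nifti(m0_vol, out / "m0.nii.gz")
        report["stages"]["reconstruct"]["wall_s"] = time.time() - t0
        report["series_length"] = len(series)

        t0 = stage("metrics")
        mask = metrics.brain_mask(m0_vol, cfg.metrics.mask_threshold)
        truth_dm = _truth_dm(phantom, cbf_params)
        rep_m = {
            "nrmse_avg_vs_truth": metrics.nrmse(avg_vol, truth_dm, mask),
            "nrmse_csmean_vs_avg": metrics.nrmse(
                series.mean_volume(), avg_vol, mask),
            "blur_3d_avg": metrics.blur_metric_3d(avg_vol,
                                                  cfg.metrics.blur_kernel),
            "blur_3d_cs_mean": metrics.blur_metric_3d(
                series.mean_volume(), cfg.metrics.blur_kernel),
        }
        cbf = metrics.quantify_cbf(avg_vol.data, m0_vol.data, cbf_params,
                                   mask)
        gm = phantom.tissue_map == 1
        rep_m["cbf_gm_mean"] = float(np.nanmean(cbf[gm & mask.mask]))
        rep_m["cbf_gm_truth"] = float(
            phantom.tissue_values[1][4])
        report["metrics"] = rep_m
        if write_outputs:
            io.save_nifti(np.nan_to_num(cbf), out / "cbf.nii.gz",
                          avg_vol.voxel_size)
        report["stages"]["metrics"]["wall_s"] = time.time() - t0

        if fluct is not None:
            t0 = stage("network")
            pre = preprocess_series(
                series, cfg.dynamics.fermi_cutoff, cfg.dynamics.fermi_width,
                cfg.dynamics.gaussian_fwhm_mm, cfg.dynamics.drop_first)
            pre = global_normalize(pre, mask.mask)
            cmap = seed_correlation(pre, fluct.rois[0])
            remote = fluct.rois[1]
            bg = mask.mask & ~fluct.rois[0] & ~remote
            report["network"] = {
                "z_remote_mean": float(cmap.z[remote].mean()),
                "z_remote_sd": float(cmap.z[remote].std()),
                "n_remote": int(remote.sum()),
                "z_background_mean": float(cmap.z[bg].mean()),
                "z_background_sd": float(cmap.z[bg].std()),
                "n_background": int(bg.sum()),
            }
            report["stages"]["network"]["wall_s"] = time.time() - t0
    except Exception as exc:  # partial outputs retained on stage failure
        failed = [k for k, v in report["stages"].items()
                  if "wall_s" not in v]
        raise RuntimeError(
            f"pipeline stage {failed[-1] if failed else '?'} failed: {exc}"
        ) from exc

    if write_outputs:
        save_config(cfg, out / "config.yaml")
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _voxels(traj):
    return tuple(10.0 * f / n for f, n in zip(traj.fov, traj.matrix))


def _bs_res(bs, t1):
    from .sequence import simulate_background_suppression
    return simulate_background_suppression(bs, t1)


def _cbf_params(cfg: RunConfig):
    m = cfg.metrics
    return metrics.CBFParams(
        labeling_duration=m.labeling_duration_s,
        post_labeling_delay=m.post_labeling_delay_s,
        blood_t1=m.blood_t1_ms,
        labeling_efficiency=m.labeling_efficiency,
        bs_efficiency=m.bs_efficiency,
        partition_coefficient=m.partition_coefficient,
        model=m.cbf_model)


def _truth_dm(phantom, cbf_params):
    return metrics.perfusion_to_dm(phantom.perfusion, phantom.m0,
                                   cbf_params)


def _default_network(phantom, cfg: RunConfig):
    """Two spherical ROIs inside gray matter sharing one slow sinusoid."""
    nx, ny, nz = phantom.matrix
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    gm = phantom.tissue_map == 1
    rois = []
    for cx in (nx // 4, 3 * nx // 4):
        sphere = ((x - cx) ** 2 + (y - ny // 2) ** 2
                  + ((z - nz // 2) * (nx / nz / 2)) ** 2) \
            <= (max(2, nx // 10)) ** 2
        rois.append(sphere & gm)
    return FluctuationSpec(
        rois=rois, course="sinusoid",
        amplitude=cfg.phantom.fluct_amplitude,
        frequency=cfg.phantom.fluct_frequency_hz,
        volume_interval=cfg.dynamics.volume_interval_s,
        noise_sd=cfg.phantom.fluct_noise_sd, seed=cfg.seed + 7)
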