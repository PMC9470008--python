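# gaspiral

Simulation and reconstruction toolkit for **pseudo golden-angle rotated
stack-of-spirals 3D RARE arterial spin labeling (ASL)**.

## The problem

ASL perfusion MRI measures cerebral blood flow (CBF) from the difference
between magnetically labeled ("label") and unlabeled ("control") images.
3D stack-of-spirals fast-spin-echo readouts are the standard because they
pair well with background suppression, but a conventional interleaved
acquisition needs many excitations per volume, discarding the temporal
fluctuations of blood flow that carry resting-state network information.

This package implements and validates, end to end on synthetic
brain-perfusion phantoms, an acquisition/reconstruction strategy that keeps
the time-averaged image fully sampled **and** makes every single excitation
reconstructable on its own:

* a **variable-density spiral** readout, fully sampled (single-shot
  Nyquist) in the inner 5% of k-space radius and 8-fold undersampled
  outside, designed under gradient amplitude/slew constraints;
* the spiral rotated by the **pseudo golden angle** θ = 10π/13 = 138.46°
  per (slice-encode + interleave) step, i.e.
  θ(s, j) = (10π/13)·(s + j − 1).  Because 13·(10π/13) ≡ 0 (mod 2π), any
  13 consecutive interleaves tile each kz plane with 13 uniformly spaced
  spiral orientations — a fully sampled set — while each single shot
  samples 3D k-space incoherently;
* a **reduced refocusing flip-angle train** (111.1°, 72.2°, 62.8°, … → 62°)
  designed by inverse extended-phase-graph (EPG) prescription for constant
  echo amplitude, and **background suppression** (presaturation 3.6 s +
  four timed inversions) that leaves < 1% of M0 in static tissue;
* the reconstruction chain: complex k-space subtraction
  ΔM = M_control − M_label, per-echo T2-decay correction from EPG
  simulation (T2 = 100 ms, T1 = 1400 ms), spherical Fermi filter, 3D
  non-uniform FFT with L2 regularization (λ = 0.01) and sum-of-squares for
  the fully sampled average, ESPIRiT coil calibration (eigenvalue
  threshold 0.8, null-space threshold 0.01), and per-shot
  **L1-wavelet compressed sensing** solved by ADMM
  (argmin_x ½‖Ex − d‖² + λ₁‖Ψx‖₁, 100 iterations, no data rescaling);
* quality metrics (masked NRMSE, a no-reference 3D blur score), CBF
  quantification via the pCASL kinetic model, and a toy seed-based
  resting-state correlation analysis on the single-shot series.

It is aimed at MR physicists and methods researchers who want a
self-contained, dependency-light sandbox for golden-angle spiral sampling,
EPG sequence design, and parallel-imaging/compressed-sensing
reconstruction, without scanner data.

## Worked example

```python
import numpy as np
from gaspiral import (design_vd_spiral, design_constant_amplitude_flip_train,
                      max_background_residual)

wf = design_vd_spiral(fov=24.0, target_resolution=2.88, duration=6.144)
print(wf.n_samples, round(wf.k_max, 3),
      round(np.abs(wf.g_samples).max(), 1))
# 1536 1.736 22.0

train = design_constant_amplitude_flip_train(32, asymptotic_flip=62.0)
print(np.round(train.flip_angles[:5], 1))
# [111.1  72.2  62.7  60.5  60.9]

print(round(100 * max_background_residual(), 2))
# 0.73
```

The spiral reaches the 2.88 mm k-space radius (k_max = 1.736 cycles/cm) in
1536 samples at 4 µs dwell with a 22 mT/m peak gradient; the flip train
reproduces the constant-echo-amplitude ramp; static tissue is suppressed to
at most 0.73% of M0 across tissue T1 values of 700–4500 ms.

A full desk-scale study (phantom → 39 label/control pairs → time-averaged
and single-shot reconstructions → metrics) runs through one call:

```python
from gaspiral import RunConfig, run_pipeline

cfg = RunConfig()
cfg.trajectory.resolution_mm = 7.5   # 32 x 32 x 8 grid for speed
cfg.trajectory.n_slices = 8
cfg.trajectory.duration_ms = 3.0
cfg.phantom.n_coils = 4
cfg.recon.admm_iterations = 30
report = run_pipeline(cfg, seed=3, out_dir="out")
print(report["series_length"])                      # 39
print(round(report["metrics"]["nrmse_csmean_vs_avg"], 3))   # 0.126
print(round(report["metrics"]["blur_3d_avg"], 3),
      round(report["metrics"]["blur_3d_cs_mean"], 3))  # 0.225 0.28
print(round(report["metrics"]["cbf_gm_mean"], 1))   # 63.0  (truth: 60)
```

The mean of the 39 compressed-sensing single-shot volumes agrees with the
fully sampled average to 12.6% NRMSE and is slightly blurrier (blur score
0.280 vs 0.225) — the expected cost of single-shot acceleration — while
gray-matter CBF is recovered within 5% of the planted ground truth.

A `gaspiral` console command exposes the same stages
(`design-trajectory`, `simulate`, `recon-average`, `recon-series`,
`metrics`, `cbf`, `network`, `run`); see `gaspiral --help`.

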