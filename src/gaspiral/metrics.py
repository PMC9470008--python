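"""Image-quality metrics and perfusion quantification.

* NRMSE: root-mean-square error over a brain mask divided by the RMS of the
  reference in the same mask.
* A no-reference 3D blur metric (Crete-Roffet construction extended to
  three axes): compares the total absolute neighbour variation of a volume
  before and after a strong one-dimensional low-pass along each axis;
  blurry inputs lose little variation (score near 1), sharp or noisy
  inputs lose much (score near 0).
* Brain masking by robust thresholding of an M0 image.
* CBF quantification from the perfusion-weighted difference signal dM and
  the M0 reference via the standard pCASL kinetic model, with an optional
  two-compartment (tissue/capillary exchange) correction factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger("gaspiral")

__all__ = [
    "BrainMask",
    "CBFParams",
    "nrmse",
    "blur_metric_3d",
    "brain_mask",
    "quantify_cbf",
    "perfusion_to_dm",
]


@dataclass
class BrainMask:
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty brain mask")


@dataclass
class CBFParams:
    """Kinetic-model parameters for pCASL quantification.

    labeling_duration and post_labeling_delay in seconds (1.8 / 1.8 by
    default), blood_t1 in ms, efficiencies unitless, partition coefficient
    in mL/g.
    """

    labeling_duration: float = 1.8
    post_labeling_delay: float = 1.8
    blood_t1: float = 1650.0
    labeling_efficiency: float = 0.85
    bs_efficiency: float = 0.75
    partition_coefficient: float = 0.9
    model: str = "one-compartment"
    exchange_correction: float = 1.0   # two-compartment scale factor

    @property
    def total_efficiency(self) -> float:
        return self.labeling_efficiency * self.bs_efficiency


def _as_array(vol):
    return vol.data if hasattr(vol, "data") else np.asarray(vol)


def nrmse(test, reference, mask: BrainMask) -> float:
    """RMSE over the mask divided by the RMS of the reference in the mask."""
    t = np.abs(_as_array(test))
    r = np.abs(_as_array(reference))
    if t.shape != r.shape:
        raise ValueError("geometry mismatch")
    m = mask.mask
    if m.shape != r.shape:
        raise ValueError("mask geometry mismatch")
    ref_rms = np.sqrt(np.mean(r[m] ** 2))
    if ref_rms == 0:
        raise ValueError("reference has zero RMS inside the mask")
    return float(np.sqrt(np.mean((t[m] - r[m]) ** 2)) / ref_rms)


def _axis_blur_score(vol: np.ndarray, axis: int, length: int) -> float:
    """One-axis score of the no-reference blur metric (higher = blurrier)."""
    blurred = ndimage.uniform_filter1d(vol, size=length, axis=axis,
                                       mode="nearest")
    d_orig = np.abs(np.diff(vol, axis=axis))
    d_blur = np.abs(np.diff(blurred, axis=axis))
    s_v = d_orig.sum()
    if s_v == 0:
        raise ValueError("volume constant along axis; blur metric undefined")
    # variation lost to the additional blur
    lost = np.maximum(0.0, d_orig - d_blur).sum()
    return float(np.clip(1.0 - lost / s_v, 0.0, 1.0))


def blur_metric_3d(volume, kernel_length: int = 9,
                   per_axis: bool = False):
    """No-reference perceptual blur score in [0, 1], mean over the 3 axes.

    For each axis the volume is low-passed with a ``kernel_length``-point
    uniform kernel; the score is the fraction of absolute neighbour
    variation that the extra blur does NOT remove.  Already-blurry volumes
    lose little variation and score high; sharp or noisy volumes score low.
    ``per_axis=True`` additionally returns the three axis scores (useful to
    isolate slice-direction blurring).
    """
    v = np.abs(_as_array(volume)).astype(float)
    if v.ndim != 3:
        raise ValueError("expected a 3D volume")
    if np.ptp(v) == 0:
        raise ValueError("constant volume; blur metric undefined")
    scores = [_axis_blur_score(v, ax, kernel_length) for ax in range(3)]
    mean = float(np.mean(scores))
    return (mean, tuple(scores)) if per_axis else mean


def brain_mask(m0, threshold_fraction: float = 0.3) -> BrainMask:
    """Threshold at ``threshold_fraction`` x robust max (99th percentile),
    keep the largest connected component."""
    v = np.abs(_as_array(m0))
    robust_max = np.percentile(v, 99)
    raw = v >= threshold_fraction * robust_max
    if not raw.any():
        raise ValueError("brain mask empty at this threshold")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    return BrainMask(raw)


def _kinetic_denominator(m0: np.ndarray, params: CBFParams) -> np.ndarray:
    """Denominator of the pCASL model, per voxel (dM = CBF * m0 * denom/6000)."""
    t1b_s = params.blood_t1 / 1000.0
    denom = (2.0 * params.total_efficiency * t1b_s
             * np.exp(-params.post_labeling_delay / t1b_s)
             * (1.0 - np.exp(-params.labeling_duration / t1b_s)))
    if params.model == "two-compartment":
        denom = denom * params.exchange_correction
    elif params.model != "one-compartment":
        raise ValueError(f"unknown model {params.model!r}")
    return denom * m0 / params.partition_coefficient


def quantify_cbf(dm, m0, params: CBFParams | None = None,
                 mask: BrainMask | None = None,
                 clip: tuple = (0.0, 300.0)) -> np.ndarray:
    """CBF map (mL/100g/min) from dM and M0 via the pCASL kinetic model.

    CBF = 6000 * lambda_p * dM * exp(w/T1b) /
          (2 alpha T1b [s] * M0 * (1 - exp(-tau/T1b)))

    Voxels with near-zero M0 inside the mask are flagged invalid (NaN) and
    excluded from the clip logging.
    """
    params = params or CBFParams()
    dm_v = np.real(_as_array(dm))
    m0_v = np.abs(_as_array(m0))
    m = mask.mask if mask is not None else np.ones_like(m0_v, bool)
    denom = _kinetic_denominator(m0_v, params)
    out = np.zeros_like(dm_v, dtype=float)
    eps = 1e-12 * max(float(m0_v.max()), 1.0)
    valid = m & (np.abs(denom) > eps)
    out[valid] = 6000.0 * dm_v[valid] / denom[valid]
    out[m & ~valid] = np.nan
    n_clip = int(np.sum((out[valid] < clip[0]) | (out[valid] > clip[1])))
    if n_clip:
        logger.debug("CBF clipping applied to %d voxels", n_clip)
    out[valid] = np.clip(out[valid], clip[0], clip[1])
    return out


def perfusion_to_dm(perfusion: np.ndarray, m0: np.ndarray,
                    params: CBFParams | None = None) -> np.ndarray:
    """Forward kinetic model: perfusion (mL/100g/min) -> dM (a.u.).

    Exact inverse of :func:`quantify_cbf` (before clipping), used by the
    phantom to plant a known ground-truth CBF.
    """
    params = params or CBFParams()
    return np.asarray(perfusion, float) * _kinetic_denominator(
        np.abs(np.asarray(m0, float)), params) / 6000.0
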