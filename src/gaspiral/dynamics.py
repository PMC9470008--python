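"""Toy-scale resting-state analysis of reconstructed single-shot series.

The single-shot perfusion volumes form a low-rate time series (one volume
per label/control pair, 13.2 s apart at the default schedule).  Spontaneous
perfusion fluctuations are low-frequency, so even this coarse sampling can
recover correlated networks.  The processing mirrors a minimal ASL
connectivity pipeline: light in-plane Fermi apodization, heavier Gaussian
smoothing, removal of the initial transient volume, per-volume global
intensity normalization, and seed-based Pearson correlation with Fisher-z
transform.  Confound regression steps specific to BOLD (CSF/WM nuisance,
hemodynamic weighting) are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, ifft2, fftshift, ifftshift

from .recon import ImageSeries

__all__ = [
    "CorrelationMap",
    "preprocess_series",
    "global_normalize",
    "seed_correlation",
]

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = sigma * 2 sqrt(2 ln 2)


@dataclass
class CorrelationMap:
    r: np.ndarray          # voxelwise Pearson r vs the seed course
    z: np.ndarray          # Fisher z = atanh(r)
    seed_course: np.ndarray


def _fermi_apodize_inplane(vol: np.ndarray, cutoff: float,
                           width: float) -> np.ndarray:
    """2D (in-plane) Fermi k-space apodization of one volume."""
    nx, ny = vol.shape[:2]
    kx = (np.arange(nx) - nx // 2) / (nx / 2.0)
    ky = (np.arange(ny) - ny // 2) / (ny / 2.0)
    rad = np.sqrt(kx[:, None] ** 2 + ky[None, :] ** 2)
    gain = 1.0 / (1.0 + np.exp((rad - cutoff) / width))
    spec = fftshift(fft2(ifftshift(vol, axes=(0, 1)), axes=(0, 1)),
                    axes=(0, 1))
    out = fftshift(ifft2(ifftshift(spec * gain[..., None], axes=(0, 1)),
                         axes=(0, 1)), axes=(0, 1))
    return out.real if np.isrealobj(vol) else out


def preprocess_series(series: ImageSeries,
                      fermi_cutoff: float | None = 0.8,
                      fermi_width: float = 0.1,
                      gaussian_fwhm: float = 4.0,
                      drop_first: bool = True) -> ImageSeries:
    """Fermi apodization, 3D Gaussian smoothing, first-volume removal.

    ``gaussian_fwhm`` in mm (0 disables); ``fermi_cutoff=None`` disables
    the k-space filter.  Smoothing kernels are normalized, so in-mask mean
    intensity is preserved up to boundary effects.
    """
    if len(series) < 3:
        raise ValueError("series too short to preprocess")
    vols = np.abs(series.volumes).astype(float)
    if fermi_cutoff is not None:
        vols = np.stack([
            _fermi_apodize_inplane(v, fermi_cutoff, fermi_width)
            for v in vols])
    if gaussian_fwhm > 0:
        sigma_vox = [gaussian_fwhm * FWHM_TO_SIGMA / vs
                     for vs in series.voxel_size]
        vols = np.stack([
            ndimage.gaussian_filter(v, sigma=sigma_vox) for v in vols])
    if drop_first:
        vols = vols[1:]
    return replace(series, volumes=vols)


def global_normalize(series: ImageSeries, mask: np.ndarray) -> ImageSeries:
    """Scale each volume so its in-mask spatial mean equals the grand mean."""
    mask = np.asarray(mask, bool)
    vols = np.abs(series.volumes).astype(float)
    means = vols[:, mask].mean(axis=1)
    if np.any(means == 0):
        raise ValueError("volume with zero in-mask mean")
    grand = means.mean()
    return replace(series, volumes=vols * (grand / means)[:, None, None, None])


def seed_correlation(series: ImageSeries, seed_roi: np.ndarray,
                     min_volumes: int = 10) -> CorrelationMap:
    """Voxelwise Pearson correlation with the seed-ROI mean time course."""
    if len(series) < min_volumes:
        raise ValueError(f"need at least {min_volumes} volumes")
    seed_roi = np.asarray(seed_roi, bool)
    if not seed_roi.any():
        raise ValueError("empty seed ROI")
    vols = np.abs(series.volumes).astype(float)
    course = vols[:, seed_roi].mean(axis=1)
    cs = course - course.mean()
    denom_c = np.sqrt(np.sum(cs**2))
    if denom_c == 0:
        raise ValueError("constant seed time course")
    v = vols - vols.mean(axis=0, keepdims=True)
    num = np.tensordot(cs, v, axes=(0, 0))
    denom_v = np.sqrt(np.sum(v**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (denom_c * denom_v)
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    z = np.arctanh(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
    return CorrelationMap(r=r, z=z, seed_course=course)
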