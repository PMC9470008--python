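"""Reconstruction pipeline: k-space subtraction, echo-decay correction,
Fermi filtering, regularized nuFFT reconstruction, ESPIRiT coil calibration,
and single-shot L1-wavelet compressed sensing via ADMM.

Pipeline order for a full acquisition (mirroring the acquisition design):

1. complex k-space subtraction dM = control - label, pairwise per shot;
2. per-echo decay correction with EPG amplitudes at T2 = 100 ms,
   T1 = 1400 ms (first echo as reference);
3. spherical Fermi filter against Gibbs ringing;
4. fully sampled reconstruction of the time-averaged data: per-coil
   Tikhonov-regularized nuFFT inversion (CG, lambda = 0.01) + sum of
   squares;
5. ESPIRiT sensitivity maps from the Cartesian spectrum of (4);
6. per-shot CS reconstruction: argmin_x ||Ex - d||^2/2 + lambda1 |Psi x|_1
   with E = nuFFT o coil multiplication and Psi an orthogonal 3D wavelet,
   solved by ADMM with a fixed iteration count and no data rescaling
   (absolute intensities are preserved for quantification).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy.fft import fftn, ifftn, fftshift, ifftshift

from .nufft import NufftOperator
from .phantom import KSpaceDataSet

logger = logging.getLogger("gaspiral")

__all__ = [
    "ReconConfig",
    "ImageVolume",
    "ImageSeries",
    "CoilSensitivityMaps",
    "subtract_kspace",
    "echo_decay_correction",
    "fermi_filter",
    "nufft_forward",
    "nufft_adjoint",
    "density_compensation",
    "adjoint_recon",
    "recon_l2",
    "sum_of_squares",
    "estimate_sensitivities",
    "cg_sense",
    "recon_cs",
    "reconstruct_series",
]


@dataclass
class ReconConfig:
    lambda_l2: float = 0.01
    lambda_l1: float = 2000.0        # absolute, a.u. (full-geometry scale)
    lambda_l1_relative: float | None = 3e-4  # fraction of max |x_adj|
    admm_iterations: int = 100
    admm_rho: float = 0.2            # relative to the E^H E spectral norm
    cg_iterations: int = 30
    cg_tol: float = 1e-6
    inner_cg_iterations: int = 8
    espirit_eig_threshold: float = 0.8
    espirit_null_threshold: float = 0.01
    espirit_kernel: tuple = (6, 6, 6)
    espirit_calib: tuple = (24, 24, 16)
    fermi_cutoff: float = 0.9        # fraction of k_max
    fermi_width: float = 0.06
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    t2_corr: float = 100.0           # ms
    t1_corr: float = 1400.0

    def __post_init__(self):
        if self.lambda_l2 < 0 or self.admm_iterations < 1:
            raise ValueError("invalid reconstruction parameters")
        for th in (self.espirit_eig_threshold, self.espirit_null_threshold):
            if not 0 < th < 1:
                raise ValueError("ESPIRiT thresholds must lie in (0, 1)")


@dataclass
class ImageVolume:
    """3D voxel grid with geometry metadata."""

    data: np.ndarray
    voxel_size: tuple          # mm
    units: str = "a.u."        # 'perfusion-weighted a.u.'|'M0 a.u.'|...

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voxel values")

    @property
    def shape(self):
        return self.data.shape

    def magnitude(self) -> "ImageVolume":
        return replace(self, data=np.abs(self.data))


@dataclass
class ImageSeries:
    volumes: np.ndarray        # (t, x, y, z)
    voxel_size: tuple
    volume_interval: float = 13.2   # s
    units: str = "a.u."

    def __len__(self):
        return self.volumes.shape[0]

    def mean_volume(self) -> ImageVolume:
        return ImageVolume(np.mean(np.abs(self.volumes), axis=0),
                           self.voxel_size, self.units)


@dataclass
class CoilSensitivityMaps:
    maps: np.ndarray           # (coils, x, y, z) complex
    mask: np.ndarray           # validity mask (leading eigenvalue >= thresh)
    eigenvalues: np.ndarray = None


def _voxel_size_mm(traj) -> tuple:
    return tuple(10.0 * f / n for f, n in zip(traj.fov, traj.matrix))


# ---------------------------------------------------------------------------
# k-space preprocessing
# ---------------------------------------------------------------------------

def subtract_kspace(control: KSpaceDataSet,
                    label: KSpaceDataSet) -> KSpaceDataSet:
    """Complex k-space subtraction dM = control - label, shotwise."""
    if control.data.shape != label.data.shape:
        raise ValueError("control/label shape mismatch")
    if not np.array_equal(control.interleaves, label.interleaves):
        raise ValueError("control/label shots are not pairwise matched")
    if control.trajectory is not label.trajectory and not (
        np.array_equal(control.trajectory.kx, label.trajectory.kx)
        and np.array_equal(control.trajectory.ky, label.trajectory.ky)
        and np.array_equal(control.trajectory.kz, label.trajectory.kz)
    ):
        raise ValueError("control/label trajectories differ")
    return control.copy_with(data=control.data - label.data,
                             tags=["dm"] * len(control.tags))


def echo_decay_correction(data: KSpaceDataSet,
                          amplitudes: np.ndarray) -> KSpaceDataSet:
    """Scale echo e by amplitudes[0] / amplitudes[e] (first echo = reference)."""
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size != data.trajectory.n_echoes:
        raise ValueError("amplitudes length != n_echoes")
    if np.any(amp <= 0):
        raise ValueError("echo amplitudes must be positive")
    corr = amp[0] / amp
    return data.copy_with(data=data.data * corr[None, :, None, None])


def fermi_filter(data: KSpaceDataSet, cutoff: float = 0.9,
                 width: float = 0.06) -> KSpaceDataSet:
    """Spherical Fermi filter 1/(1 + exp((|k|/k_max - cutoff)/width)).

    |k| is the 3D radius with each axis normalized by its own Nyquist
    extent, so the sphere respects the anisotropic kz sampling.
    """
    if cutoff <= 0 or width <= 0:
        raise ValueError("cutoff and width must be positive")
    traj = data.trajectory
    kmax = [n / (2.0 * f) for n, f in zip(traj.matrix, traj.fov)]
    rad = np.sqrt((traj.kx / kmax[0]) ** 2 + (traj.ky / kmax[1]) ** 2
                  + (traj.kz / kmax[2]) ** 2)
    gain = 1.0 / (1.0 + np.exp((rad - cutoff) / width))
    # one gain row per data shot: shots reference trajectory interleaves
    gain_rows = gain[np.asarray(data.interleaves) - 1]
    return data.copy_with(data=data.data * gain_rows[..., None])


# ---------------------------------------------------------------------------
# nuFFT wrappers and density compensation
# ---------------------------------------------------------------------------

def nufft_forward(image: np.ndarray, trajectory, shots=None,
                  plan: NufftOperator | None = None) -> np.ndarray:
    """Type-2 3D NUFFT of an image at the trajectory's sample locations."""
    op = plan or NufftOperator(trajectory.coords(shots), trajectory.matrix,
                               trajectory.fov)
    return op.forward(np.asarray(image))


def nufft_adjoint(samples: np.ndarray, trajectory, shots=None,
                  plan: NufftOperator | None = None) -> np.ndarray:
    """Type-1 3D NUFFT (adjoint of :func:`nufft_forward`)."""
    op = plan or NufftOperator(trajectory.coords(shots), trajectory.matrix,
                               trajectory.fov)
    return op.adjoint(np.asarray(samples).ravel())


def density_compensation(plan: NufftOperator, n_iter: int = 15) -> np.ndarray:
    """Pipe–Menon density compensation weights, PSF-normalized.

    Iterates w <- w / (C w) with C the gridding-kernel density convolution,
    then fixes the global scale so that ``adjoint(w * forward(.))`` has
    unit gain for a flat object (measured over the central half-FOV, away
    from edge roll-off), making the weighted adjoint intensity-faithful.
    """
    A = plan._interp
    w = np.ones(plan.n_samples)
    for _ in range(n_iter):
        denom = np.abs(A @ (A.conj().T @ w))
        w = w / np.maximum(denom, 1e-30)
    flat = np.ones(plan.matrix, dtype=complex)
    gain_map = plan.adjoint(w * plan.forward(flat)).real
    core = tuple(slice(n // 4, n - n // 4) for n in plan.matrix)
    return w / float(np.mean(gain_map[core]))


def adjoint_recon(data: KSpaceDataSet, shots=None,
                  plans=None) -> list:
    """Density-compensated adjoint ('zero-filled') recon, one volume/coil."""
    traj = data.trajectory
    op = plans or NufftOperator(traj.coords(shots), traj.matrix, traj.fov)
    w = density_compensation(op)
    sel = slice(None) if shots is None else shots
    d = data.data[sel].reshape(-1, data.n_coils)
    return list(op.adjoint_batch(w[:, None] * d))


# ---------------------------------------------------------------------------
# linear (fully sampled) reconstruction
# ---------------------------------------------------------------------------

def _cg(apply_normal, rhs, x0=None, n_iter=30, tol=1e-6):
    """Conjugate gradients on the (Hermitian PSD) normal equations."""
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - apply_normal(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0:
        return np.zeros_like(rhs)
    for _ in range(n_iter):
        Ap = apply_normal(p)
        denom = np.vdot(p, Ap).real
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) < tol * rhs_norm:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def _cg_block(apply_normal, rhs, n_iter=30, tol=1e-6):
    """CG on columns of rhs simultaneously (same operator, per-column
    step sizes); apply_normal maps (n, C) -> (n, C)."""
    x = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = np.sum(np.abs(r) ** 2, axis=0)
    rhs_norm = np.sqrt(np.sum(np.abs(rhs) ** 2, axis=0))
    active = rhs_norm > 0
    for _ in range(n_iter):
        Ap = apply_normal(p)
        denom = np.sum(np.conj(p) * Ap, axis=0).real
        ok = active & (denom > 0)
        if not ok.any():
            break
        alpha = np.where(ok, rs / np.where(denom > 0, denom, 1.0), 0.0)
        x += alpha[None] * p
        r -= alpha[None] * Ap
        rs_new = np.sum(np.abs(r) ** 2, axis=0)
        active = active & (np.sqrt(rs_new) >= tol * rhs_norm)
        beta = np.where(rs > 0, rs_new / np.where(rs > 0, rs, 1.0), 0.0)
        p = r + beta[None] * p
        rs = rs_new
        if not active.any():
            break
    return x


def recon_l2(data: KSpaceDataSet, lambda_l2: float = 0.01, shots=None,
             cg_iterations: int = 30, cg_tol: float = 1e-6,
             plan=None) -> list:
    """Per-coil Tikhonov-regularized nuFFT inversion (CG solver).

    Solves min_x ||A x - d_c||^2 + lambda ||x||^2 for each coil c, where A
    is the NUFFT over the selected shots.  Returns a list of complex
    volumes, one per coil.
    """
    traj = data.trajectory
    op = plan or NufftOperator(traj.coords(shots), traj.matrix, traj.fov)
    # precondition with the density-compensated adjoint as the initial guess
    sel = slice(None) if shots is None else shots
    d = data.data[sel].reshape(-1, data.n_coils)
    if d.shape[0] != op.n_samples:
        raise ValueError("data/trajectory sample count mismatch")
    scale = 1.0 / max(float(np.prod(traj.matrix)), 1.0)
    nc = data.n_coils

    def normal_block(x_cols):                       # (voxels, C)
        imgs = x_cols.T.reshape((nc,) + traj.matrix)
        y = op.adjoint_batch(op.forward_batch(imgs)) * scale
        return (y.reshape(nc, -1) + lambda_l2 * imgs.reshape(nc, -1)).T

    rhs = (op.adjoint_batch(d) * scale).reshape(nc, -1).T
    x = _cg_block(normal_block, rhs, n_iter=cg_iterations, tol=cg_tol)
    if not np.all(np.isfinite(x)):
        res = np.linalg.norm(normal_block(x) - rhs) \
            / max(np.linalg.norm(rhs), 1e-30)
        raise RuntimeError(f"CG diverged: relative residual {res:.3e}")
    return [x[:, c].reshape(traj.matrix) for c in range(nc)]


def sum_of_squares(coil_volumes) -> np.ndarray:
    """Voxelwise root-sum-of-squares combination."""
    stack = np.asarray(coil_volumes)
    if stack.ndim < 4:
        stack = stack[None]
    return np.sqrt(np.sum(np.abs(stack) ** 2, axis=0))


# ---------------------------------------------------------------------------
# ESPIRiT coil-sensitivity calibration
# ---------------------------------------------------------------------------

def estimate_sensitivities(coil_kspace: np.ndarray,
                           eig_threshold: float = 0.8,
                           null_threshold: float = 0.01,
                           kernel=(6, 6, 6),
                           calib=(24, 24, 16)) -> CoilSensitivityMaps:
    """ESPIRiT sensitivity maps from Cartesian multi-coil k-space.

    ``coil_kspace``: (coils, nx, ny, nz), zero-frequency at the centre.
    A block-Hankel calibration matrix is built from the central
    ``calib`` region with sliding ``kernel`` windows; right-singular
    vectors with sigma >= null_threshold * sigma_max span the signal
    subspace, whose voxelwise operator is eigen-decomposed.  The first
    eigenvector (phase-referenced to coil 0) is retained where the leading
    eigenvalue >= eig_threshold, zero elsewhere.
    """
    ks = np.asarray(coil_kspace)
    nc = ks.shape[0]
    grid = ks.shape[1:]
    kernel = tuple(int(k) for k in kernel)
    calib = tuple(min(int(c), g) for c, g in zip(calib, grid))
    if any(c < k for c, k in zip(calib, kernel)):
        raise ValueError("calibration region smaller than the kernel")

    centre = tuple(slice(g // 2 - c // 2, g // 2 - c // 2 + c)
                   for g, c in zip(grid, calib))
    cal = ks[(slice(None),) + centre]

    # block-Hankel matrix: rows = sliding windows, cols = kernel x coils
    nwin = tuple(c - k + 1 for c, k in zip(calib, kernel))
    windows = np.lib.stride_tricks.sliding_window_view(
        cal, kernel, axis=(1, 2, 3))      # (nc, *nwin, *kernel)
    A = windows.reshape(nc, np.prod(nwin), np.prod(kernel))
    A = np.moveaxis(A, 0, 1).reshape(np.prod(nwin), nc * np.prod(kernel))

    _, s, Vh = np.linalg.svd(A, full_matrices=False)
    keep = s >= null_threshold * s[0]
    V = Vh[keep].conj()                    # (n_kept, nc*prod(kernel))
    n_kept = V.shape[0]
    kern = V.reshape(n_kept, nc, *kernel)

    # transform kernels to image space on the full grid
    pad = np.zeros((n_kept, nc) + grid, dtype=complex)
    sl = tuple(slice(g // 2 - k // 2, g // 2 - k // 2 + k)
               for g, k in zip(grid, kernel))
    pad[(slice(None), slice(None)) + sl] = kern[:, :, ::-1, ::-1, ::-1]
    gimg = fftshift(ifftn(ifftshift(pad, axes=(2, 3, 4)),
                          axes=(2, 3, 4)), axes=(2, 3, 4))
    # Parseval scaling so an ideal signal subspace gives eigenvalue 1
    gimg *= np.sqrt(np.prod(grid) ** 2 / np.prod(kernel))

    # voxelwise nc x nc operator: sum_q g_q(r) g_q(r)^H
    G = np.moveaxis(gimg, (0, 1), (-2, -1))     # (*grid, n_kept, nc)
    M = np.einsum("...qc,...qd->...cd", G.conj(), G)
    evals, evecs = np.linalg.eigh(M)
    lead = evals[..., -1].real
    vec = evecs[..., -1]
    # phase-reference to coil 0
    ph = np.exp(-1j * np.angle(vec[..., 0]))
    vec = vec * ph[..., None]
    mask = lead >= eig_threshold
    maps = np.moveaxis(vec, -1, 0) * mask[None]
    return CoilSensitivityMaps(maps=maps, mask=mask, eigenvalues=lead)


# ---------------------------------------------------------------------------
# SENSE operator and solvers
# ---------------------------------------------------------------------------

class _SenseOperator:
    """E = (NUFFT o coil multiplication); E^H its exact adjoint."""

    def __init__(self, plan: NufftOperator, maps: np.ndarray):
        self.plan = plan
        self.maps = maps
        self.n_coils = maps.shape[0]
        self.matrix = plan.matrix

    def forward(self, x):
        return self.plan.forward_batch(x[None] * self.maps)

    def adjoint(self, y):
        imgs = self.plan.adjoint_batch(y.reshape(self.plan.n_samples,
                                                 self.n_coils))
        return np.sum(np.conj(self.maps) * imgs, axis=0)

    def normal(self, x):
        return self.adjoint(self.forward(x))

    def spectral_norm(self, n_iter=8, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.matrix) \
            + 1j * rng.standard_normal(self.matrix)
        x /= np.linalg.norm(x)
        lam = 1.0
        for _ in range(n_iter):
            y = self.normal(x)
            lam = np.linalg.norm(y)
            if lam == 0:
                return 1.0
            x = y / lam
        return lam


def cg_sense(data_samples: np.ndarray, plan: NufftOperator,
             maps: np.ndarray, n_iter: int = 60,
             tol: float = 1e-9) -> np.ndarray:
    """SENSE least-squares reconstruction by CG on the normal equations."""
    E = _SenseOperator(plan, maps)
    scale = 1.0 / E.spectral_norm()
    rhs = (E.adjoint(data_samples) * scale).ravel()

    def normal(x_flat):
        return (E.normal(x_flat.reshape(E.matrix)) * scale).ravel()

    return _cg(normal, rhs, n_iter=n_iter, tol=tol).reshape(E.matrix)


class _WaveletTransform:
    """Orthogonal 3D DWT with flat coefficient vector (Parseval-tight)."""

    def __init__(self, shape, name="db4", levels=3):
        self.shape = shape
        self.name = name
        # orthonormality under periodization holds at any depth; cap only
        # by the dyadic limit of the shortest axis
        self.levels = max(1, min(levels,
                                 int(np.log2(max(2, min(shape)))) - 1))
        c = self._dec(np.zeros(shape))
        _, self._slices = pywt.coeffs_to_array(c)

    def _dec(self, x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return pywt.wavedecn(x, self.name, mode="periodization",
                                 level=self.levels)

    def forward(self, x):
        arr, self._slices = pywt.coeffs_to_array(self._dec(x))
        return arr

    def adjoint(self, arr):
        c = pywt.array_to_coeffs(arr, self._slices, output_format="wavedecn")
        return pywt.waverecn(c, self.name, mode="periodization")


def recon_cs(data: KSpaceDataSet | np.ndarray, maps: CoilSensitivityMaps,
             config: ReconConfig | None = None, shots=None,
             plan: NufftOperator | None = None,
             lambda_l1: float | None = None,
             return_objective: bool = False):
    """Single-shot L1-wavelet compressed-sensing reconstruction (ADMM).

    Solves argmin_x 0.5 ||E x - d||^2 + lambda1 |Psi x|_1 with a fixed
    number of ADMM iterations; no automatic data rescaling, so the output
    intensity scale follows the input data (scaling the data by c scales
    the solution by c when lambda1 is given in relative form).

    ``lambda_l1`` overrides the config (absolute units); otherwise
    ``config.lambda_l1_relative`` scales the peak magnitude of the density-
    compensated adjoint reconstruction (a data-scale proxy that keeps the
    threshold meaningful across geometries), falling back to the absolute
    ``config.lambda_l1``.
    """
    config = config or ReconConfig()
    if isinstance(data, KSpaceDataSet):
        traj = data.trajectory
        sel = slice(None) if shots is None else shots
        d = data.data[sel].reshape(-1, data.n_coils)
        op = plan or NufftOperator(traj.coords(shots), traj.matrix, traj.fov)
        voxel = _voxel_size_mm(traj)
    else:
        if plan is None:
            raise ValueError("raw sample arrays require an explicit plan")
        op = plan
        d = np.asarray(data).reshape(-1, maps.maps.shape[0])
        voxel = (1.0, 1.0, 1.0)

    E = _SenseOperator(op, maps.maps)
    L = E.spectral_norm()
    scale = 1.0 / L if L > 0 else 1.0
    d_samples = d.reshape((op.n_samples, E.n_coils))
    ehd = E.adjoint(np.moveaxis(d_samples, -1, -1)) * scale

    psi = _WaveletTransform(E.matrix, config.wavelet_name,
                            config.wavelet_levels)
    if lambda_l1 is not None:
        lam = float(lambda_l1)
    elif config.lambda_l1_relative is not None:
        w = density_compensation(op)
        xadj = np.sum(np.conj(maps.maps)
                      * op.adjoint_batch(w[:, None] * d_samples), axis=0)
        lam = config.lambda_l1_relative * float(np.max(np.abs(xadj)))
    else:
        lam = config.lambda_l1 * scale

    rho = config.admm_rho  # operator already normalized to unit norm
    x = np.zeros(E.matrix, dtype=complex)
    z = psi.forward(x)
    u = np.zeros_like(z)
    objective = []

    def normal_rho(x_flat):
        xv = x_flat.reshape(E.matrix)
        return (E.normal(xv) * scale + rho * xv).ravel()

    for it in range(config.admm_iterations):
        rhs = (ehd + rho * psi.adjoint(z - u)).ravel()
        x = _cg(normal_rho, rhs, x0=x.ravel(),
                n_iter=config.inner_cg_iterations, tol=1e-10)
        x = x.reshape(E.matrix)
        wx = psi.forward(x)
        z = _soft_threshold(wx + u, lam / rho)
        u = u + wx - z
        if return_objective:
            resid = E.forward(x) - d_samples
            objective.append(
                0.5 * scale * np.vdot(resid, resid).real
                + lam * np.sum(np.abs(wx)))
    if return_objective and len(objective) > 12:
        tail = np.asarray(objective[-10:])
        if np.all(np.diff(tail) > 0):
            warnings.warn("ADMM objective increasing over final iterations",
                          RuntimeWarning)
    vol = ImageVolume(x, voxel, units="perfusion-weighted a.u.")
    return (vol, np.asarray(objective)) if return_objective else vol


def _soft_threshold(v, t):
    mag = np.abs(v)
    return np.where(mag > t, v * (1.0 - t / np.maximum(mag, 1e-30)), 0.0)


# ---------------------------------------------------------------------------
# full-series pipeline
# ---------------------------------------------------------------------------

def reconstruct_series(label: KSpaceDataSet, control: KSpaceDataSet,
                       config: ReconConfig | None = None,
                       echo_amplitudes: np.ndarray | None = None,
                       volume_interval: float = 13.2):
    """Reconstruct the time-averaged volume and the per-shot CS series.

    Returns ``(series, avg_volume, maps)`` where ``series`` holds one CS
    volume per label/control pair (39 at the default schedule) and
    ``avg_volume`` is the sum-of-squares combined L2 reconstruction of the
    interleave-averaged data.
    """
    config = config or ReconConfig()
    traj = label.trajectory
    dm = subtract_kspace(control, label)
    if echo_amplitudes is not None:
        dm = echo_decay_correction(dm, echo_amplitudes)
    dm = fermi_filter(dm, config.fermi_cutoff, config.fermi_width)

    # average pairs sharing an interleave -> one fully sampled 13-shot set
    ils = np.unique(dm.interleaves)
    n_int = traj.n_shots
    if set(ils) != set(range(1, n_int + 1)):
        missing = sorted(set(range(1, n_int + 1)) - set(ils))
        raise ValueError(f"schedule incomplete: missing interleaves "
                         f"{missing}")
    avg_data = np.stack([
        dm.data[dm.interleaves == il].mean(axis=0) for il in ils])
    full = KSpaceDataSet(avg_data, traj, ["dm"] * n_int,
                         np.arange(1, n_int + 1), dict(dm.meta))

    full_plan = NufftOperator(traj.coords(), traj.matrix, traj.fov)
    coil_imgs = recon_l2(full, config.lambda_l2,
                         cg_iterations=config.cg_iterations,
                         cg_tol=config.cg_tol, plan=full_plan)
    avg_volume = ImageVolume(sum_of_squares(coil_imgs),
                             _voxel_size_mm(traj),
                             units="perfusion-weighted a.u.")

    # ESPIRiT maps from the Cartesian spectrum of the per-coil averages
    coil_k = np.stack([
        fftshift(fftn(ifftshift(img))) for img in coil_imgs])
    kernel = tuple(min(k, max(4, g // 6)) for k, g in
                   zip(config.espirit_kernel, traj.matrix))
    calib = tuple(min(c, g) for c, g in
                  zip(config.espirit_calib, traj.matrix))
    maps = estimate_sensitivities(
        coil_k, config.espirit_eig_threshold, config.espirit_null_threshold,
        kernel=kernel, calib=calib)

    shot_plans = {}
    vols = []
    for p in range(dm.data.shape[0]):
        il = int(dm.interleaves[p])
        if il not in shot_plans:
            shot_plans[il] = NufftOperator(traj.coords(shots=il - 1),
                                           traj.matrix, traj.fov)
        v = recon_cs(dm.data[p], maps, config, plan=shot_plans[il])
        vols.append(v.data)
        logger.debug("CS volume %d/%d (interleave %d) done",
                     p + 1, dm.data.shape[0], il)
    series = ImageSeries(np.asarray(vols), _voxel_size_mm(traj),
                         volume_interval=volume_interval,
                         units="perfusion-weighted a.u.")
    return series, avg_volume, maps
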