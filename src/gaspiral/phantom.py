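"""Synthetic brain-perfusion phantoms and the multi-coil k-space forward model.

The phantom is a multi-ellipsoid 3D object with background / gray matter /
white matter / CSF labels and per-tissue M0, T1, T2 and perfusion values
(GM 60, WM 20 mL/100g/min by default).  Coil sensitivities are smooth
complex Gaussian lobes with linear phase, normalized to unit root-sum-of-
squares over the object.  The ASL signal model: control and label volumes
share the (background-suppressed) static tissue magnetization and differ by
the perfusion-weighted difference magnetization dM, optionally modulated in
time by a shared low-frequency course inside planted network regions.

The forward model samples the 3D non-uniform Fourier transform of each coil
image at the trajectory's (kx, ky, kz) locations, scales echo e by the EPG
echo amplitude for that echo index, and adds complex white Gaussian noise.
It deliberately matches the reconstruction's data model (a static volume
per shot, per-echo scalar amplitude): this keeps simulation-vs-recon
comparisons free of model mismatch and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import NufftOperator
from .trajectory import StackOfSpiralsTrajectory

__all__ = [
    "TISSUES",
    "PhantomSpec",
    "CoilProfileSet",
    "FluctuationSpec",
    "KSpaceDataSet",
    "make_phantom",
    "make_coils",
    "perfusion_image",
    "simulate_kspace",
    "simulate_acquisition",
]

#: label -> (name, M0 [a.u.], T1 [ms], T2 [ms], perfusion [mL/100g/min])
TISSUES = {
    0: ("background", 0.0, 1.0, 1.0, 0.0),
    1: ("gm", 1.0, 1400.0, 100.0, 60.0),
    2: ("wm", 0.75, 900.0, 80.0, 20.0),
    3: ("csf", 1.3, 4300.0, 1500.0, 0.0),
}


@dataclass
class PhantomSpec:
    matrix: tuple
    fov: tuple                      # cm
    tissue_map: np.ndarray          # integer labels
    tissue_values: dict             # label -> (name, m0, t1, t2, perfusion)
    seed: int

    def tissue_property(self, index: int) -> np.ndarray:
        """Voxelwise map of one per-tissue property (1=m0 .. 4=perfusion)."""
        lut = np.zeros(max(self.tissue_values) + 1)
        for lab, vals in self.tissue_values.items():
            lut[lab] = vals[index]
        return lut[self.tissue_map]

    @property
    def m0(self) -> np.ndarray:
        return self.tissue_property(1)

    @property
    def perfusion(self) -> np.ndarray:
        return self.tissue_property(4)

    @property
    def support(self) -> np.ndarray:
        return self.tissue_map > 0


@dataclass
class CoilProfileSet:
    profiles: np.ndarray            # (n_coils, *matrix) complex

    @property
    def n_coils(self) -> int:
        return self.profiles.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.profiles) ** 2, axis=0))


@dataclass
class FluctuationSpec:
    """Planted low-frequency perfusion fluctuations in network regions.

    ``rois``: list of boolean masks sharing one time course.  Amplitude is
    a fraction of the local baseline perfusion signal; frequency in Hz must
    stay below the volume-rate Nyquist (0.0379 Hz at the 13.2 s interval).
    """

    rois: list = field(default_factory=list)
    course: str = "sinusoid"        # 'sinusoid' | 'ar1'
    amplitude: float = 0.10
    frequency: float = 0.02         # Hz
    volume_interval: float = 13.2   # s
    noise_sd: float = 0.0           # voxelwise, fraction of baseline dM
    phase: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.frequency >= 0.5 / self.volume_interval:
            raise ValueError("fluctuation frequency above volume Nyquist")

    def course_value(self, t_index: int) -> float:
        t = t_index * self.volume_interval
        if self.course == "sinusoid":
            return self.amplitude * np.sin(
                2 * np.pi * self.frequency * t + self.phase)
        if self.course == "ar1":
            # deterministic per seed: generate the whole path lazily
            rng = np.random.default_rng(self.seed)
            rho = np.exp(-2 * np.pi * self.frequency * self.volume_interval)
            x = 0.0
            for _ in range(t_index + 1):
                x = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal()
            return self.amplitude * x
        raise ValueError(f"unknown course {self.course!r}")


@dataclass
class KSpaceDataSet:
    """Raw multi-coil samples with trajectory reference and shot tags."""

    data: np.ndarray                # (shots, echoes, samples, coils) complex
    trajectory: StackOfSpiralsTrajectory
    tags: list                      # per shot: 'label'|'control'|'dm'|'m0'
    interleaves: np.ndarray         # per shot, 1-based interleave index
    meta: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.data.shape[3]

    def copy_with(self, data=None, tags=None):
        return KSpaceDataSet(
            data=self.data.copy() if data is None else data,
            trajectory=self.trajectory,
            tags=list(self.tags) if tags is None else tags,
            interleaves=self.interleaves.copy(),
            meta=dict(self.meta),
        )


def _ellipsoid(grid, center, radii):
    return sum(((g - c) / r) ** 2
               for g, c, r in zip(grid, center, radii)) <= 1.0


def make_phantom(matrix=(64, 64, 16), fov=(24.0, 24.0, 12.8),
                 seed: int = 0) -> PhantomSpec:
    """Reproducible multi-ellipsoid brain-like phantom.

    An outer brain ellipsoid of gray matter encloses a white-matter core and
    two CSF ventricles; ellipsoid axes are jittered a few percent by the
    seed so different seeds give different (but statistically matched)
    objects.
    """
    matrix = tuple(int(n) for n in matrix)
    if min(matrix) < 8 or max(matrix[:2]) < 16:
        raise ValueError("matrix too small for a structured phantom")
    rng = np.random.default_rng(seed)
    nx, ny, nz = matrix
    grid = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
        np.linspace(-1, 1, nz), indexing="ij")
    j = lambda: 1.0 + 0.04 * rng.standard_normal()

    labels = np.zeros(matrix, dtype=np.int8)
    brain = _ellipsoid(grid, (0, 0, 0), (0.82 * j(), 0.88 * j(), 0.80 * j()))
    labels[brain] = 1   # GM shell by default
    wm = _ellipsoid(grid, (0.02 * rng.standard_normal(), 0.0, 0.0),
                    (0.58 * j(), 0.64 * j(), 0.55 * j()))
    labels[brain & wm] = 2
    for sx in (-1, 1):
        vent = _ellipsoid(grid, (0.16 * sx, -0.05, 0.05),
                          (0.10 * j(), 0.26 * j(), 0.28 * j()))
        labels[brain & vent] = 3
    return PhantomSpec(matrix=matrix, fov=tuple(fov), tissue_map=labels,
                       tissue_values=dict(TISSUES), seed=seed)


def make_coils(matrix=(64, 64, 16), n_coils: int = 8, seed: int = 0,
               bandwidth: float = 0.0375, variation: float = 0.5
               ) -> CoilProfileSet:
    """Smooth complex coil profiles, RSS-normalized and band-limited.

    Profiles are synthesized directly in k-space: each coil's spectrum is a
    complex Gaussian random field under a Gaussian envelope of width
    ``bandwidth`` (fraction of the per-axis Nyquist extent), hard-limited
    to a 22% k-radius, on top of a dominant DC term so magnitudes stay
    bounded away from zero.  Root-sum-of-squares is exactly 1 everywhere
    and out-of-band spectral energy stays below the 1% bound used by the
    smoothness check, while the random components keep the coil geometry
    distinct enough for parallel imaging.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    matrix = tuple(int(n) for n in matrix)
    if n_coils == 1:
        return CoilProfileSet(np.ones((1,) + matrix, dtype=complex))
    from scipy.fft import ifftn, fftshift, ifftshift

    rng = np.random.default_rng(seed)
    nx, ny, nz = matrix
    kx, ky, kz = np.meshgrid(np.arange(nx) - nx // 2,
                             np.arange(ny) - ny // 2,
                             np.arange(nz) - nz // 2, indexing="ij")
    sig = [max(1.0, bandwidth * n) for n in matrix]
    env = np.exp(-0.5 * ((kx / sig[0]) ** 2 + (ky / sig[1]) ** 2
                         + (kz / sig[2]) ** 2))
    krad = np.sqrt((2.0 * kx / nx) ** 2 + (2.0 * ky / ny) ** 2
                   + (2.0 * kz / nz) ** 2)
    env[krad > 0.22] = 0.0
    profiles = np.empty((n_coils,) + matrix, dtype=complex)
    for c in range(n_coils):
        spec = env * (rng.standard_normal(matrix)
                      + 1j * rng.standard_normal(matrix)) * variation
        spec[nx // 2, ny // 2, nz // 2] = 1.0 + abs(
            spec[nx // 2, ny // 2, nz // 2])
        profiles[c] = fftshift(ifftn(ifftshift(spec))) \
            * np.sqrt(np.prod(matrix))
    rss = np.sqrt(np.sum(np.abs(profiles) ** 2, axis=0))
    profiles /= rss
    return CoilProfileSet(profiles)


def perfusion_image(phantom: PhantomSpec, t: int = 0,
                    fluct: FluctuationSpec | None = None,
                    dm_scale: float | None = None,
                    cbf_params=None) -> np.ndarray:
    """Perfusion-weighted difference magnetization dM at volume index t.

    By default the baseline dM follows the pCASL kinetic forward model
    (:func:`gaspiral.metrics.perfusion_to_dm`; GM dM lands at ~0.5% of GM
    M0, a typical ASL fraction), so quantification closes the loop exactly.
    Passing ``dm_scale`` instead uses the simple linear mapping
    dM = perfusion * m0 * dm_scale.  The planted network time course and
    voxel noise come from ``fluct``.
    """
    if dm_scale is None:
        from .metrics import perfusion_to_dm
        base = perfusion_to_dm(phantom.perfusion, phantom.m0, cbf_params)
    else:
        base = phantom.perfusion * phantom.m0 * dm_scale
    if fluct is None:
        return base
    img = base.copy()
    cv = fluct.course_value(t)
    for roi in fluct.rois:
        img[roi] *= 1.0 + cv
    if fluct.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([fluct.seed, t, 0x5EED]))
        img += fluct.noise_sd * base.mean() * rng.standard_normal(img.shape) \
            * phantom.support
    return img


def _forward_all(image, traj, coils, echo_amplitudes, plan=None):
    """NUFFT-forward one volume through all coils, per-echo amplitudes."""
    op = plan or NufftOperator(traj.coords(), traj.matrix, traj.fov)
    n_shot, n_echo, n_samp = traj.kx.shape
    amp = np.asarray(echo_amplitudes, dtype=float)
    if amp.size != n_echo:
        raise ValueError("echo_amplitudes length != n_echoes")
    s = op.forward_batch(image[None] * coils.profiles)
    out = s.reshape(n_shot, n_echo, n_samp, coils.n_coils)
    out = out * amp[None, :, None, None]
    return out


def simulate_kspace(image, trajectory, coils, echo_amplitudes=None,
                    noise_sd: float = 0.0, seed: int = 0,
                    tag: str = "dm", plan=None) -> KSpaceDataSet:
    """Simulate raw k-space of a single volume for every trajectory shot."""
    if image.shape != trajectory.matrix:
        raise ValueError("image geometry does not match trajectory matrix")
    if echo_amplitudes is None:
        echo_amplitudes = np.ones(trajectory.n_echoes)
    data = _forward_all(image, trajectory, coils, echo_amplitudes, plan)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape)
            + 1j * rng.standard_normal(data.shape)) / np.sqrt(2.0)
    return KSpaceDataSet(
        data=data, trajectory=trajectory,
        tags=[tag] * trajectory.n_shots,
        interleaves=np.arange(1, trajectory.n_shots + 1),
        meta={"noise_sd": noise_sd, "seed": seed},
    )


def simulate_acquisition(phantom, trajectory, coils, schedule,
                         echo_amplitudes=None, fluct=None,
                         static_residual: float = 0.005,
                         noise_sd: float = 0.0, seed: int = 0,
                         dm_scale: float | None = None):
    """Simulate a full label/control acquisition schedule.

    Returns (label_data, control_data), each of shape
    (n_pairs, echoes, samples, coils), sharing the 13-interleave trajectory:
    pair p uses trajectory shot ``(interleave - 1)``.  The static tissue
    contributes ``static_residual * M0`` to both label and control (the
    background-suppression residual); control - label equals the
    forward-projected dM volume of that pair's time index exactly.
    """
    if echo_amplitudes is None:
        echo_amplitudes = np.ones(trajectory.n_echoes)
    amp = np.asarray(echo_amplitudes, dtype=float)
    op_full = NufftOperator(trajectory.coords(), trajectory.matrix,
                            trajectory.fov)
    static = static_residual * phantom.m0
    static_k = _forward_all(static, trajectory, coils, amp, op_full)

    n_echo, n_samp = trajectory.n_echoes, trajectory.n_samples
    shot_ops = [
        NufftOperator(trajectory.coords(shots=j), trajectory.matrix,
                      trajectory.fov)
        for j in range(trajectory.n_shots)
    ]

    def forward_shot(image, j):
        s = shot_ops[j].forward_batch(image[None] * coils.profiles)
        return s.reshape(n_echo, n_samp, coils.n_coils) \
            * amp[:, None, None]

    rng = np.random.default_rng(seed)
    pairs = list(schedule.pairs())
    lab = np.empty((len(pairs), n_echo, n_samp, coils.n_coils), dtype=complex)
    ctl = np.empty_like(lab)
    interleaves = np.empty(len(pairs), dtype=int)
    static_dm_k = {}  # shot -> forward of the (static) baseline dM
    for p, (l_shot, c_shot) in enumerate(pairs):
        il = l_shot.interleave
        interleaves[p] = il
        if fluct is None:
            if il not in static_dm_k:
                static_dm_k[il] = forward_shot(
                    perfusion_image(phantom, dm_scale=dm_scale), il - 1)
            dm_k = static_dm_k[il]
        else:
            dm_k = forward_shot(
                perfusion_image(phantom, t=p, fluct=fluct,
                                dm_scale=dm_scale), il - 1)
        s = static_k[il - 1]
        lab[p] = s - 0.5 * dm_k
        ctl[p] = s + 0.5 * dm_k
        if noise_sd > 0:
            for arr in (lab, ctl):
                arr[p] += noise_sd * (
                    rng.standard_normal(arr[p].shape)
                    + 1j * rng.standard_normal(arr[p].shape)) / np.sqrt(2.0)

    def pack(data, tag):
        return KSpaceDataSet(
            data=data, trajectory=trajectory, tags=[tag] * len(pairs),
            interleaves=interleaves,
            meta={"noise_sd": noise_sd, "seed": seed, "dm_scale": dm_scale},
        )

    return pack(lab, "label"), pack(ctl, "control")
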