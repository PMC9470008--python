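"""Variable-density spiral design and the rotated stack-of-spirals trajectory.

A single variable-density 2D spiral readout is designed under gradient
amplitude and slew-rate constraints, then replicated across slice encodes
(kz) and interleaved excitations with a pseudo golden-angle rotation of
10*pi/13 = 138.46 deg per (slice_encode + interleave) step.  Because
10*pi/13 is a rational fraction of 2*pi, the schedule repeats every 13
rotations, so any 13 consecutive interleaves tile each kz plane with 13
uniformly spaced spiral orientations — full sampling for the time-averaged
reconstruction — while each single shot samples 3D k-space incoherently.

Units: k-space in cycles/cm, FOV in cm, gradients in mT/m, slew in T/m/s,
time in microseconds for the dwell and milliseconds for durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN13_INCREMENT",
    "SpiralDesignError",
    "SpiralWaveform",
    "RotationSchedule",
    "StackOfSpiralsTrajectory",
    "design_vd_spiral",
    "rotation_angle",
    "schedule_period",
    "slice_encode_order",
    "build_trajectory",
]

#: pseudo golden-angle increment (exactly periodic with period 13)
GOLDEN13_INCREMENT = 10.0 * np.pi / 13.0

#: true golden angle in radians (aperiodic), for comparison studies
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: gyromagnetic ratio of 1H, in (cycles/cm) per (mT/m * s)
GAMMA_CM = 42.5764e6 * 1e-3 / 100.0  # = 425.764


class SpiralDesignError(ValueError):
    """Raised when a spiral cannot be realized under the given constraints."""


@dataclass
class SpiralWaveform:
    """One variable-density 2D spiral readout."""

    k_samples: np.ndarray  # complex, cycles/cm
    g_samples: np.ndarray  # complex, mT/m
    dwell: float           # microseconds
    k_max: float           # cycles/cm
    density_profile: np.ndarray  # target undersampling factor vs r in [0,1]

    @property
    def n_samples(self) -> int:
        return self.k_samples.size


@dataclass
class RotationSchedule:
    """Pseudo golden-angle rotation schedule across slice encodes/interleaves."""

    increment: float = GOLDEN13_INCREMENT
    n_interleaves: int = 13
    n_slice_encodes: int = 32

    def angle(self, slice_encode: int, interleave: int) -> float:
        lo, hi = -self.n_slice_encodes // 2, self.n_slice_encodes // 2 - 1
        if not lo <= slice_encode <= hi:
            raise IndexError(
                f"slice encode {slice_encode} outside [{lo}, {hi}]")
        if interleave < 1:
            raise IndexError("interleave indices are 1-based")
        return float(np.mod(self.increment * (slice_encode + interleave - 1),
                            2.0 * np.pi))


@dataclass
class StackOfSpiralsTrajectory:
    """Per-(shot, echo) rotated spiral coordinates plus the kz slice encodes."""

    kx: np.ndarray  # (shots, echoes, samples) cycles/cm
    ky: np.ndarray
    kz: np.ndarray
    slice_encode_order: np.ndarray  # echo index -> signed kz index
    fov: tuple            # (x, y, z) cm
    matrix: tuple         # (nx, ny, nz)
    dwell: float          # microseconds
    increment: float
    angles: np.ndarray = field(default=None)  # (shots, echoes)

    @property
    def n_shots(self) -> int:
        return self.kx.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.kx.shape[1]

    @property
    def n_samples(self) -> int:
        return self.kx.shape[2]

    def coords(self, shots=None) -> np.ndarray:
        """Flattened (M, 3) sample coordinates, optionally for a shot subset."""
        sel = slice(None) if shots is None else shots
        return np.stack(
            [self.kx[sel].ravel(), self.ky[sel].ravel(), self.kz[sel].ravel()],
            axis=-1,
        )


def undersampling_profile(r, inner_full_fraction, outer_undersampling,
                          transition_end: float = 0.5):
    """Target in-plane undersampling factor vs normalized radius.

    Unity (single-shot Nyquist) out to the fully sampled core, a smooth
    half-cosine ramp up to ``transition_end``, then constant at the outer
    factor.  The default transition end of 0.5 keeps the outer half of
    k-space uniformly relaxed and makes the full-geometry readout (2.88 mm
    at 1536 samples / 6.1 ms) realizable under standard gradient limits.
    """
    r = np.asarray(r, dtype=float)
    if inner_full_fraction >= 1.0 or outer_undersampling == 1.0:
        return np.ones_like(r)
    hi = max(transition_end, inner_full_fraction + 1e-6)
    t = np.clip((r - inner_full_fraction) / (hi - inner_full_fraction), 0, 1)
    return 1.0 + (outer_undersampling - 1.0) * 0.5 * (1.0 - np.cos(np.pi * t))


def design_vd_spiral(
    fov: float,
    target_resolution: float,
    nominal_interleaves: int = 13,
    inner_full_fraction: float = 0.05,
    outer_undersampling: float = 8.0,
    g_max: float = 40.0,
    slew_max: float = 150.0,
    dwell: float = 4.0,
    duration: float = 6.0,
) -> SpiralWaveform:
    """Design a variable-density spiral under gradient constraints.

    Parameters: ``fov`` in cm, ``target_resolution`` in mm, ``dwell`` in
    microseconds, ``duration`` in ms, ``g_max`` in mT/m, ``slew_max`` in
    T/m/s.  The spiral pitch follows ``undersampling_profile`` relative to
    the single-shot Nyquist spacing ``1 / fov`` (fully sampled core within
    every shot); ``nominal_interleaves`` documents how many rotations
    combine to a fully sampled set and must be at least
    ``outer_undersampling`` for the combined set to reach Nyquist.  The
    gradient speed along the curve is maximized by a forward/backward pass
    under the amplitude and slew limits, then stretched uniformly to fill
    the requested readout duration.
    """
    if fov <= 0 or target_resolution <= 0:
        raise ValueError("fov and target_resolution must be positive")
    if not 0 < inner_full_fraction <= 1:
        raise ValueError("inner_full_fraction must be in (0, 1]")
    if outer_undersampling < 1:
        raise ValueError("outer_undersampling must be >= 1")
    if g_max <= 0 or slew_max <= 0:
        raise ValueError("gradient limits must be positive")

    k_max = 1.0 / (2.0 * target_resolution / 10.0)  # cycles/cm

    # integrate r(theta): dr/dtheta = pitch(r) / (2*pi)
    n_theta = 200_000
    r = np.empty(n_theta)
    theta = np.empty(n_theta)
    r[0], theta[0] = 0.0, 0.0
    # pitch relative to SINGLE-SHOT Nyquist: the k-space centre is fully
    # sampled within each shot (gap 1/fov), the outer region relaxes to
    # outer_undersampling/fov; combining nominal_interleaves rotations then
    # (over)samples the outer region whenever
    # nominal_interleaves >= outer_undersampling.
    base_pitch = 1.0 / fov
    i = 0
    while r[i] < k_max and i < n_theta - 1:
        pitch = base_pitch * undersampling_profile(
            r[i] / k_max, inner_full_fraction, outer_undersampling)
        dtheta = min(2.0 * np.pi / 256.0,
                     0.02 * k_max * 2.0 * np.pi / pitch)
        # midpoint rule
        r_mid = r[i] + 0.5 * dtheta * pitch / (2.0 * np.pi)
        pitch_mid = base_pitch * undersampling_profile(
            min(r_mid, k_max) / k_max, inner_full_fraction, outer_undersampling)
        r[i + 1] = r[i] + dtheta * pitch_mid / (2.0 * np.pi)
        theta[i + 1] = theta[i] + dtheta
        i += 1
    r, theta = r[: i + 1], theta[: i + 1]
    r[-1] = min(r[-1], k_max)

    kx = r * np.cos(theta)
    ky = r * np.sin(theta)
    dk = np.hypot(np.diff(kx), np.diff(ky))
    s = np.concatenate([[0.0], np.cumsum(dk)])

    # curvature of the polar curve
    dr = np.gradient(r, theta, edge_order=2)
    d2r = np.gradient(dr, theta, edge_order=2)
    denom = (r**2 + dr**2) ** 1.5
    denom = np.where(denom == 0, 1e-30, denom)
    kappa = np.abs(r**2 + 2 * dr**2 - r * d2r) / denom

    v_amp = GAMMA_CM * g_max                      # (cycles/cm)/s
    a_max = GAMMA_CM * slew_max * 1e3             # (cycles/cm)/s^2
    # partition the slew budget between centripetal (v^2 kappa) and
    # tangential (dv/dt) acceleration so their quadrature sum stays within
    # a_max everywhere
    beta = 0.9
    a_curv = beta * a_max
    a_tang = np.sqrt(1.0 - beta**2) * a_max
    with np.errstate(divide="ignore"):
        v_lim = np.minimum(v_amp, np.sqrt(a_curv / np.maximum(kappa, 1e-12)))

    # forward/backward pass for the tangential slew limit
    v = np.empty_like(v_lim)
    v[0] = 0.0
    ds = np.diff(s)
    for j in range(len(v) - 1):
        v[j + 1] = min(v_lim[j + 1], np.sqrt(v[j] ** 2 + 2 * a_tang * ds[j]))
    for j in range(len(v) - 2, -1, -1):
        v[j] = min(v[j], np.sqrt(v[j + 1] ** 2 + 2 * a_tang * ds[j]))

    v_safe = np.maximum(0.5 * (v[1:] + v[:-1]), 1e-9)
    t = np.concatenate([[0.0], np.cumsum(ds / v_safe)])  # seconds
    t_min = t[-1]

    duration_s = duration * 1e-3
    if t_min > duration_s * (1 + 1e-9):
        binding = "slew rate" if np.mean(v >= v_amp * 0.999) < 0.5 else \
            "gradient amplitude"
        raise SpiralDesignError(
            f"readout of {duration} ms too short to reach k_max={k_max:.3f} "
            f"1/cm (needs {t_min*1e3:.2f} ms; binding constraint: {binding})")

    # stretch time uniformly to fill the requested duration
    t = t * (duration_s / t_min)

    n_samples = int(round(duration_s / (dwell * 1e-6)))
    ts = np.arange(n_samples) * dwell * 1e-6
    kxs = np.interp(ts, t, kx)
    kys = np.interp(ts, t, ky)
    k = kxs + 1j * kys

    g = np.gradient(k, dwell * 1e-6) / GAMMA_CM   # mT/m
    r_grid = np.linspace(0, 1, 101)
    profile = undersampling_profile(
        r_grid, inner_full_fraction, outer_undersampling)
    return SpiralWaveform(
        k_samples=k, g_samples=g, dwell=dwell, k_max=k_max,
        density_profile=profile,
    )


def rotation_angle(slice_encode: int, interleave: int,
                   increment: float = GOLDEN13_INCREMENT,
                   n_slice_encodes: int = 32) -> float:
    """Rotation (radians, reduced to [0, 2*pi)) for one slice encode/interleave."""
    return RotationSchedule(increment, n_slice_encodes=n_slice_encodes).angle(
        slice_encode, interleave)


def schedule_period(increment: float, cap: int = 1_000_000,
                    tol: float = 1e-9):
    """Smallest n >= 1 with n*increment = 0 (mod 2*pi); None if aperiodic.

    Scans up to ``cap`` multiples; irrational multiples of 2*pi (such as the
    true golden angle) report as aperiodic (None).
    """
    if not 0 < increment < 2 * np.pi:
        raise ValueError("increment must lie in (0, 2*pi)")
    n = np.arange(1, cap + 1, dtype=float)
    frac = np.mod(n * (increment / (2 * np.pi)), 1.0)
    hit = np.flatnonzero(np.minimum(frac, 1.0 - frac) < tol)
    return int(hit[0] + 1) if hit.size else None


def slice_encode_order(n_slices: int, mode: str = "centric",
                       positive_first: bool = True) -> np.ndarray:
    """Echo-index -> signed kz index ordering.

    Centric starts at kz=0 and alternates outward (+1, -1, +2, -2, ... with
    the default sign convention; the final extreme is -n/2, which has no
    positive partner).  Linear runs -n/2 .. n/2-1.
    """
    if n_slices < 2 or n_slices % 2:
        raise ValueError("n_slices must be even and >= 2")
    if mode == "linear":
        return np.arange(-n_slices // 2, n_slices // 2)
    if mode != "centric":
        raise ValueError(f"unknown ordering mode {mode!r}")
    sign = 1 if positive_first else -1
    order = [0]
    for m in range(1, n_slices // 2):
        order += [sign * m, -sign * m]
    order.append(-sign * (n_slices // 2))
    return np.asarray(order)


def build_trajectory(
    waveform: SpiralWaveform,
    schedule: RotationSchedule,
    n_slices: int,
    slice_thickness: float,
    fov: float,
    matrix_inplane: int,
    order_mode: str = "centric",
) -> StackOfSpiralsTrajectory:
    """Assemble the rotated stack-of-spirals sample set.

    ``slice_thickness`` in mm; kz spacing is 1/(n_slices * thickness_cm) so
    the kz values form the Cartesian slice-encode grid.  Echo ``e`` of shot
    ``j`` uses the in-plane rotation ``schedule.angle(kz_index(e), j)``.
    """
    if schedule.n_slice_encodes != n_slices:
        raise ValueError("schedule.n_slice_encodes does not match n_slices")
    order = slice_encode_order(n_slices, order_mode)
    dz_cm = slice_thickness / 10.0
    dkz = 1.0 / (n_slices * dz_cm)
    n_shots = schedule.n_interleaves
    n_samp = waveform.n_samples
    kx = np.empty((n_shots, n_slices, n_samp))
    ky = np.empty_like(kx)
    kz = np.empty_like(kx)
    angles = np.empty((n_shots, n_slices))
    for j in range(n_shots):
        for e, se in enumerate(order):
            th = schedule.angle(int(se), j + 1)
            rot = waveform.k_samples * np.exp(1j * th)
            kx[j, e] = rot.real
            ky[j, e] = rot.imag
            kz[j, e] = se * dkz
            angles[j, e] = th
    return StackOfSpiralsTrajectory(
        kx=kx, ky=ky, kz=kz, slice_encode_order=order,
        fov=(fov, fov, n_slices * dz_cm),
        matrix=(matrix_inplane, matrix_inplane, n_slices),
        dwell=waveform.dwell, increment=schedule.increment, angles=angles,
    )
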