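"""Run configuration: schema-validated, serializable, with desk-scale defaults.

The default profile is a desk-scale study (64 x 64 x 16 grid, 8 coils,
512-sample spiral) that exercises the full acquisition/reconstruction
chain in minutes; ``full_profile()`` switches to the full acquisition
geometry (128 x 128 x 32, 32 coils, 1536-sample spiral, 2.88 mm in-plane).
Unknown keys are rejected so configuration typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TrajectoryConfig(_Section):
    fov_cm: float = 24.0
    resolution_mm: float = 3.75
    n_interleaves: int = 13
    increment: str | float = "golden13"   # 'golden13' | 'golden' | radians
    inner_full_fraction: float = 0.05
    outer_undersampling: float = 8.0
    g_max_mT_m: float = 40.0
    slew_max_T_m_s: float = 150.0
    dwell_us: float = 4.0
    duration_ms: float = 2.048
    n_slices: int = 16
    slice_thickness_mm: float = 4.0
    order: str = "centric"
    matrix_inplane: int | None = None   # recon grid; default fov/resolution

    @field_validator("increment")
    @classmethod
    def _check_increment(cls, v):
        if isinstance(v, str) and v not in ("golden13", "golden", "none"):
            raise ValueError("increment must be 'golden13', 'golden', "
                             "'none' or a value in radians")
        return v


class SequenceConfig(_Section):
    asymptotic_flip: float = 62.0
    echo_spacing_ms: float = 12.9
    presat_ms: float = 3600.0
    bs_times_ms: tuple = (2848.0, 1546.0, 605.0, 131.0)
    inversion_efficiency: float = 1.0
    n_averages: int = 3
    include_m0: bool = True
    t1_tissue_ms: float = 1400.0
    t2_tissue_ms: float = 100.0


class PhantomConfig(_Section):
    n_coils: int = 8
    noise_sd_relative: float = 0.05    # fraction of the RMS sample magnitude
    static_residual: float = 0.005
    fluct_amplitude: float = 0.10
    fluct_frequency_hz: float = 0.02
    fluct_noise_sd: float = 0.0
    planted_network: bool = False


class ReconSection(_Section):
    lambda_l2: float = 0.01
    lambda_l1: float = 2000.0
    lambda_l1_relative: float | None = 3e-4
    admm_iterations: int = 100
    admm_rho: float = 0.2
    cg_iterations: int = 30
    espirit_eig_threshold: float = 0.8
    espirit_null_threshold: float = 0.01
    fermi_cutoff: float = 0.9
    fermi_width: float = 0.06
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    t2_corr_ms: float = 100.0
    t1_corr_ms: float = 1400.0


class MetricsConfig(_Section):
    mask_threshold: float = 0.3
    blur_kernel: int = 9
    labeling_duration_s: float = 1.8
    post_labeling_delay_s: float = 1.8
    blood_t1_ms: float = 1650.0
    labeling_efficiency: float = 0.85
    bs_efficiency: float = 0.75
    partition_coefficient: float = 0.9
    cbf_model: str = "one-compartment"


class DynamicsConfig(_Section):
    fermi_cutoff: float = 0.8
    fermi_width: float = 0.1
    gaussian_fwhm_mm: float = 4.0
    drop_first: bool = True
    volume_interval_s: float = 13.2


class RunConfig(_Section):
    trajectory: TrajectoryConfig = Field(default_factory=TrajectoryConfig)
    sequence: SequenceConfig = Field(default_factory=SequenceConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    recon: ReconSection = Field(default_factory=ReconSection)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    seed: int = 0
    out_dir: str = "gaspiral_out"

    @property
    def matrix(self) -> tuple:
        t = self.trajectory
        n_inplane = t.matrix_inplane or int(round(
            t.fov_cm * 10.0 / t.resolution_mm))
        return (n_inplane, n_inplane, t.n_slices)

    @classmethod
    def full_profile(cls) -> "RunConfig":
        """The full acquisition geometry: 2.88 mm spiral resolution
        reconstructed on a 128 x 128 x 32 grid with 32 coils."""
        cfg = cls()
        cfg.trajectory.resolution_mm = 2.88
        cfg.trajectory.duration_ms = 6.144
        cfg.trajectory.n_slices = 32
        cfg.trajectory.matrix_inplane = 128
        cfg.phantom.n_coils = 32
        return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; empty file -> full defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, for output provenance."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
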