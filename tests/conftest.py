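"""Shared fixtures: a desk-scale study geometry reused across the suite.

Everything is generated programmatically (no stored data).  Session scope
keeps expensive objects (trajectory plans, simulated k-space, ESPIRiT
maps) computed once.
"""

import warnings

import numpy as np
import pytest

from gaspiral.phantom import make_coils, make_phantom, simulate_kspace
from gaspiral.recon import (ReconConfig, estimate_sensitivities, recon_l2,
                            sum_of_squares)
from gaspiral.trajectory import (RotationSchedule, build_trajectory,
                                 design_vd_spiral)

warnings.filterwarnings("ignore", category=UserWarning, module="pywt")

MATRIX = (32, 32, 8)
FOV = (24.0, 24.0, 3.2)          # cm; 4 mm slices
N_COILS = 4


@pytest.fixture(scope="session")
def waveform():
    return design_vd_spiral(fov=24.0, target_resolution=7.5,
                            nominal_interleaves=13, dwell=4.0, duration=3.0)


@pytest.fixture(scope="session")
def trajectory(waveform):
    sched = RotationSchedule(n_slice_encodes=MATRIX[2])
    return build_trajectory(waveform, sched, MATRIX[2], 4.0, 24.0,
                            MATRIX[0])


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(MATRIX, FOV, seed=1)


@pytest.fixture(scope="session")
def coils():
    return make_coils(MATRIX, N_COILS, seed=2)


@pytest.fixture(scope="session")
def dm_truth(phantom):
    from gaspiral.phantom import perfusion_image
    return perfusion_image(phantom)


@pytest.fixture(scope="session")
def clean_kspace(dm_truth, trajectory, coils):
    return simulate_kspace(dm_truth, trajectory, coils)


@pytest.fixture(scope="session")
def data_rms(clean_kspace):
    return float(np.sqrt(np.mean(np.abs(clean_kspace.data) ** 2)))


@pytest.fixture(scope="session")
def noisy_kspace(dm_truth, trajectory, coils, data_rms):
    return simulate_kspace(dm_truth, trajectory, coils,
                           noise_sd=0.05 * data_rms, seed=5)


@pytest.fixture(scope="session")
def coil_images_noisy(noisy_kspace):
    return recon_l2(noisy_kspace, 0.01)


@pytest.fixture(scope="session")
def espirit_maps(coil_images_noisy):
    from scipy.fft import fftn, fftshift, ifftshift
    ck = np.stack([fftshift(fftn(ifftshift(im)))
                   for im in coil_images_noisy])
    return estimate_sensitivities(ck, kernel=(6, 6, 4), calib=(24, 24, 8))


def in_support_nrmse(recon, truth, support):
    r = np.abs(np.asarray(recon))
    return float(np.sqrt(np.mean((r[support] - truth[support]) ** 2))
                 / np.sqrt(np.mean(truth[support] ** 2)))


@pytest.fixture(scope="session")
def nrmse_in_support():
    return in_support_nrmse
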