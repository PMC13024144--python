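"""Shared fixtures: coarse grids and small synthetic calibration sets.

Coarse wavenumber grids keep simulation-heavy tests fast; every quantity
checked against a closed form is grid-independent or computed on the grid
actually used.
"""
import numpy as np
import pytest

from surfir.plsr import CalibrationDataset
from surfir.preprocess import preprocess_matrix
from surfir.spectrum import WavenumberGrid
from surfir.synthetic import (MeasurementModel, build_reference_library,
                              sample_mixture_compositions,
                              simulate_mixture_measurements)


@pytest.fixture(scope="session")
def coarse_grid():
    """Full range, 16 cm^-1 spacing: 198 points."""
    return WavenumberGrid(4000, 848, 16)


@pytest.fixture(scope="session")
def mid_grid():
    """Mid-IR band range at 4 cm^-1: used for quality/ANOVA sims."""
    return WavenumberGrid(3100, 900, 4)


@pytest.fixture(scope="session")
def full_grid():
    return WavenumberGrid()


@pytest.fixture(scope="session")
def coarse_library(coarse_grid):
    return build_reference_library(grid=coarse_grid)


@pytest.fixture(scope="session")
def mid_library(mid_grid):
    return build_reference_library(grid=mid_grid)


def make_calibration_dataset(grid, n_samples=30, run_sd_log=0.05,
                             scan_noise_sd=2.6e-4, scans_per_sample=1,
                             seed=0, scheme="latin_hypercube"):
    """Small preprocessed calibration dataset from the generator."""
    library = build_reference_library(grid=grid)
    comps = sample_mixture_compositions(n_samples=n_samples, scheme=scheme,
                                        seed=seed)
    model = MeasurementModel(route_gain=2.5207, run_sd_log=run_sd_log,
                             scan_noise_sd=scan_noise_sd,
                             baseline_drift_amp=0.0)
    data = simulate_mixture_measurements(comps, library, model,
                                         scans_per_sample, seed=seed + 1)
    _, d2 = preprocess_matrix(data.wavenumbers, data.absorbance)
    return CalibrationDataset.from_spectra(d2, data.meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
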