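"""Synthetic dried-film ATR-FTIR data.

Generates everything the downstream pipeline consumes without any
instrument: Gaussian-band reference absorptivity spectra for the five
surfactant lipids (DPPC, POPC, sphingomyelin S, PG, cholesterol), mixture
compositions inside the five-lipid calibration domain, nested
route/run/scan replicate measurements with a configurable variance
structure, and reference L/S cohorts with binary RDS labels.

Signal model per scan::

    A(nu) = route_gain * run_effect * sum_lipid c_lipid * eps_lipid(nu)
            + baseline_drift(run, nu) + white_noise(scan, nu)

The run effect is multiplicative log-normal (film thickness / effective
coverage scales the whole spectrum), drift is a smooth low-order polynomial
per run, and scan noise is additive white Gaussian — the variance
consequences of film deposition, not its physics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc, truncnorm

from .errors import ConfigError, DataError
from .spectrum import SpectraSet, WavenumberGrid

LIPIDS = ("dppc", "popc", "s", "pg", "chol")

#: Five-lipid calibration concentration bounds (mM).
CALIBRATION_BOUNDS: dict[str, tuple[float, float]] = {
    "dppc": (1.035, 1.308),
    "popc": (0.508, 0.632),
    "s": (0.273, 0.853),
    "pg": (0.008, 0.333),
    "chol": (0.207, 0.310),
}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: centre (cm^-1), sigma (cm^-1),
    relative absorptivity (absorbance units per mM at the band centre)."""

    center: float
    width: float
    relative_absorptivity: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band at {self.center}: width must be > 0")
        if self.relative_absorptivity < 0:
            raise ConfigError(f"band at {self.center}: absorptivity must be >= 0")


# Band positions follow the standard lipid mid-IR assignments (CH2
# antisym/sym stretch ~2920/2850, ester C=O ~1740, sphingolipid amide I
# ~1648 and amide II ~1540, phosphate PO2- antisym ~1250 for phospholipids
# only, P-O-R / C-O-C ~1090/1065, choline ~970). Sigmas give FWHM of the
# order of the assignment-region widths; absorptivities are scaled so the
# mid-point mixture's 2920 cm^-1 peak height is ~0.21 absorbance at unit
# route gain. Cholesterol carries no phosphate or ester-carbonyl band.
DEFAULT_BAND_TABLE: dict[str, tuple[BandSpec, ...]] = {
    # gel-phase saturated chains: CH stretches at the low edge of the region
    "dppc": (
        BandSpec(2920, 8, 0.077), BandSpec(2850, 7, 0.054),
        BandSpec(1742, 7, 0.046), BandSpec(1472, 6, 0.015),
        BandSpec(1255, 9, 0.038), BandSpec(1095, 7, 0.031),
        BandSpec(1068, 6, 0.019), BandSpec(972, 5, 0.019),
    ),
    # unsaturated (oleoyl) chains: CH stretches shifted up, plus a weak
    # C=C stretch in the 1650-region
    "popc": (
        BandSpec(2924, 8, 0.077), BandSpec(2854, 7, 0.052),
        BandSpec(1737, 7, 0.048), BandSpec(1652, 7, 0.012),
        BandSpec(1466, 6, 0.015),
        BandSpec(1245, 9, 0.036), BandSpec(1088, 7, 0.030),
        BandSpec(1062, 6, 0.018), BandSpec(966, 5, 0.018),
    ),
    # ceramide backbone: amide I/II instead of the ester carbonyl
    "s": (
        BandSpec(2921, 8, 0.077), BandSpec(2851, 7, 0.050),
        BandSpec(1648, 7, 0.062), BandSpec(1540, 7, 0.023),
        BandSpec(1250, 9, 0.034), BandSpec(1090, 7, 0.028),
        BandSpec(968, 5, 0.015),
    ),
    # glycerol headgroup: no choline band, strong P-O-R region
    "pg": (
        BandSpec(2922, 8, 0.077), BandSpec(2852, 7, 0.050),
        BandSpec(1740, 7, 0.042), BandSpec(1468, 6, 0.013),
        BandSpec(1242, 9, 0.040), BandSpec(1093, 7, 0.033),
        BandSpec(1061, 6, 0.025),
    ),
    # sterol: no phosphate, no ester carbonyl
    "chol": (
        BandSpec(2928, 8, 0.077), BandSpec(2856, 7, 0.058),
        BandSpec(1465, 6, 0.019), BandSpec(1055, 7, 0.027),
    ),
}


@dataclass
class ReferenceLibrary:
    """Per-lipid band lists evaluated as absorptivity spectra on a grid."""

    bands: dict[str, tuple[BandSpec, ...]]
    grid: WavenumberGrid
    absorptivity: dict[str, np.ndarray]

    def matrix(self, order: tuple[str, ...] = LIPIDS) -> np.ndarray:
        """(n_lipids, n_points) absorptivity matrix in ``order``."""
        return np.vstack([self.absorptivity[name] for name in order])


def build_reference_library(
    band_table: dict[str, tuple[BandSpec, ...]] | None = None,
    grid: WavenumberGrid | None = None,
) -> ReferenceLibrary:
    """Evaluate each lipid's absorptivity spectrum as its sum of Gaussians."""
    band_table = dict(DEFAULT_BAND_TABLE) if band_table is None else band_table
    grid = grid or WavenumberGrid()
    nu = grid.values
    absorptivity: dict[str, np.ndarray] = {}
    for lipid, bands in band_table.items():
        spec = np.zeros_like(nu)
        for b in bands:
            if not (grid.end <= b.center <= grid.start):
                raise ConfigError(
                    f"band of '{lipid}' centred at {b.center} cm^-1 lies outside "
                    f"the grid range [{grid.end}, {grid.start}]"
                )
            spec += b.relative_absorptivity * np.exp(
                -0.5 * ((nu - b.center) / b.width) ** 2
            )
        absorptivity[lipid] = spec
    return ReferenceLibrary(
        bands={k: tuple(v) for k, v in band_table.items()},
        grid=grid, absorptivity=absorptivity,
    )


@dataclass(frozen=True)
class LipidComposition:
    """Concentrations of the five components, mM."""

    dppc: float
    popc: float
    s: float
    pg: float
    chol: float

    def __post_init__(self) -> None:
        for name in LIPIDS:
            if getattr(self, name) < 0:
                raise DataError(f"negative concentration for {name}")

    @property
    def l(self) -> float:
        """Lecithin: total phosphatidylcholine, DPPC + POPC (mM)."""
        return self.dppc + self.popc

    @property
    def ls(self) -> float:
        """Lecithin / sphingomyelin molar ratio."""
        return self.l / self.s

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in LIPIDS])

    def in_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        bounds = bounds or CALIBRATION_BOUNDS
        return all(
            bounds[n][0] <= getattr(self, n) <= bounds[n][1] for n in bounds
        )


def midpoint_composition(
    bounds: dict[str, tuple[float, float]] | None = None,
) -> LipidComposition:
    """Arithmetic mid-point of the calibration bounds."""
    bounds = bounds or CALIBRATION_BOUNDS
    return LipidComposition(**{n: (lo + hi) / 2 for n, (lo, hi) in bounds.items()})


def sample_mixture_compositions(
    bounds: dict[str, tuple[float, float]] | None = None,
    n_samples: int = 33,
    scheme: str = "vertices_plus_center",
    seed: int = 0,
) -> list[LipidComposition]:
    """Design points inside the five-lipid concentration box.

    ``vertices_plus_center`` always contains the 2^5 corner points plus the
    mid-point (33 points); requesting more tops up with Latin-hypercube
    fill, requesting fewer is an error. ``latin_hypercube`` draws a seeded
    space-filling sample of exactly ``n_samples`` points.
    """
    bounds = bounds or CALIBRATION_BOUNDS
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ConfigError(f"lower bound exceeds upper bound for {name}")
    names = list(bounds)
    lows = np.array([bounds[n][0] for n in names])
    highs = np.array([bounds[n][1] for n in names])

    def lhs(n: int, seed_: int) -> np.ndarray:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed_)
        return qmc.scale(sampler.random(n), lows, highs)

    if scheme == "vertices_plus_center":
        n_design = 2 ** len(names) + 1
        if n_samples < n_design:
            raise ConfigError(
                f"vertices_plus_center needs n_samples >= {n_design}"
            )
        corners = np.array(
            [[bounds[n][bit] for n, bit in zip(names, bits)]
             for bits in np.ndindex(*(2,) * len(names))],
            dtype=float,
        )
        points = np.vstack([corners, (lows + highs) / 2])
        if n_samples > n_design:
            points = np.vstack([points, lhs(n_samples - n_design, seed)])
    elif scheme == "latin_hypercube":
        points = lhs(n_samples, seed)
    else:
        raise ConfigError(f"unknown sampling scheme '{scheme}'")
    return [LipidComposition(**dict(zip(names, row))) for row in points]


@dataclass(frozen=True)
class MeasurementModel:
    """Variance structure of one preparation route.

    route_gain scales the mean effective signal (film coverage / coupling to
    the evanescent field); run_sd_log is the SD of the log-normal run-level
    multiplicative effect (deposition-to-deposition variability);
    scan_noise_sd is additive white detector noise; baseline_drift_amp is
    the amplitude of a smooth quadratic per-run additive baseline.
    """

    route_gain: float = 1.0
    run_sd_log: float = 0.0
    scan_noise_sd: float = 0.0
    baseline_drift_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.route_gain <= 0:
            raise ConfigError("route_gain must be > 0")
        if min(self.run_sd_log, self.scan_noise_sd, self.baseline_drift_amp) < 0:
            raise ConfigError("model SDs/amplitudes must be >= 0")


#: Default route models emulating the nested repeatability study conditions:
#: gains set so the noiseless mid-point-mixture 2920 cm^-1 peak heights are
#: 0.210 (DCM) / 0.507 (AQ); run-level CVs 23.5% / 16.2%; scan-level
#: residual SD ~2.6e-4.
DEFAULT_MEASUREMENT_MODELS: dict[str, MeasurementModel] = {
    "DCM-dry": MeasurementModel(
        route_gain=1.0441, run_sd_log=0.235, scan_noise_sd=2.6e-4,
        baseline_drift_amp=2e-4,
    ),
    "AQ-dry": MeasurementModel(
        route_gain=2.5207, run_sd_log=0.162, scan_noise_sd=2.6e-4,
        baseline_drift_amp=2e-4,
    ),
}

#: Calibration-protocol measurement model. Calibration standards are
#: deposited under a controlled aqueous protocol, so film-to-film scale
#: variability is far below the free-deposition repeatability-study level;
#: a purely multiplicative 16% film effect would make absolute calibration
#: over these narrow concentration ranges information-theoretically
#: impossible, which the printed calibration performance rules out.
CALIBRATION_MEASUREMENT_MODEL = MeasurementModel(
    route_gain=2.5207, run_sd_log=0.05, scan_noise_sd=2.6e-4,
    baseline_drift_amp=2e-4,
)


@dataclass(frozen=True)
class NestedDesign:
    """Balanced route x run x scan replicate layout."""

    n_routes: int = 2
    runs_per_route: int = 9
    scans_per_run: int = 9

    def __post_init__(self) -> None:
        if min(self.n_routes, self.runs_per_route, self.scans_per_run) < 2:
            raise ConfigError("all design counts must be >= 2 for estimability")


def _run_drift(rng: np.random.Generator, nu: np.ndarray, amp: float) -> np.ndarray:
    """Smooth quadratic baseline for one run, amplitude-scaled."""
    if amp == 0:
        return np.zeros_like(nu)
    t = np.linspace(-1.0, 1.0, len(nu))
    c = rng.normal(size=3)
    return amp * (c[0] + c[1] * t + c[2] * t**2)


def simulate_nested_measurements(
    composition: LipidComposition,
    library: ReferenceLibrary,
    model_by_route: dict[str, MeasurementModel] | None = None,
    design: NestedDesign = NestedDesign(),
    seed: int = 0,
) -> SpectraSet:
    """Nested replicate measurements of one composition under each route.

    Route order follows the key order of ``model_by_route``; spectra are
    labelled ``{route}_{run}_{scan}``. Bit-reproducible for a given seed.
    """
    model_by_route = model_by_route or DEFAULT_MEASUREMENT_MODELS
    if len(model_by_route) != design.n_routes:
        raise ConfigError(
            f"design declares {design.n_routes} routes but "
            f"{len(model_by_route)} measurement models were given"
        )
    nu = library.grid.values
    base = composition.as_array() @ library.matrix()
    rng = np.random.default_rng(seed)
    rows, traces = [], []
    conc = {f"{n}_mM": getattr(composition, n) for n in LIPIDS}
    for route, model in model_by_route.items():
        for run in range(1, design.runs_per_route + 1):
            run_effect = math.exp(rng.normal(0.0, model.run_sd_log)) \
                if model.run_sd_log > 0 else 1.0
            drift = _run_drift(rng, nu, model.baseline_drift_amp)
            signal = model.route_gain * run_effect * base + drift
            for scan in range(1, design.scans_per_run + 1):
                noise = rng.normal(0.0, model.scan_noise_sd, size=nu.shape) \
                    if model.scan_noise_sd > 0 else 0.0
                traces.append(signal + noise)
                rows.append({"spectrum_id": f"{route}_{run}_{scan}",
                             "route": route, "run": run, "scan": scan, **conc})
    return SpectraSet(nu, np.vstack(traces), pd.DataFrame(rows))


def simulate_mixture_measurements(
    compositions: list[LipidComposition],
    library: ReferenceLibrary,
    model: MeasurementModel,
    scans_per_sample: int = 3,
    seed: int = 0,
) -> SpectraSet:
    """One film (run) per mixture sample, several scans per film.

    This is the calibration-set layout: each physical sample is deposited
    once and scanned repeatedly, so the run-level multiplicative effect is
    shared by all scans of a sample.
    """
    if scans_per_sample < 1:
        raise ConfigError("scans_per_sample must be >= 1")
    nu = library.grid.values
    mat = library.matrix()
    rng = np.random.default_rng(seed)
    rows, traces = [], []
    for k, comp in enumerate(compositions):
        base = comp.as_array() @ mat
        run_effect = math.exp(rng.normal(0.0, model.run_sd_log)) \
            if model.run_sd_log > 0 else 1.0
        drift = _run_drift(rng, nu, model.baseline_drift_amp)
        signal = model.route_gain * run_effect * base + drift
        conc = {f"{n}_mM": getattr(comp, n) for n in LIPIDS}
        for scan in range(1, scans_per_sample + 1):
            noise = rng.normal(0.0, model.scan_noise_sd, size=nu.shape) \
                if model.scan_noise_sd > 0 else 0.0
            traces.append(signal + noise)
            rows.append({"spectrum_id": f"sample{k}_{scan}",
                         "sample_id": f"sample{k}", "scan": scan, **conc})
    return SpectraSet(nu, np.vstack(traces), pd.DataFrame(rows))


@dataclass(frozen=True)
class CohortSpec:
    """Reference L/S cohort: class sizes and truncated-normal parameters.

    Defaults give a plausibly separated neonatal cohort (non-RDS mean 3.0,
    RDS mean 1.6 on the L/S scale, both truncated below at 0.2) with the
    published class sizes 74 non-RDS / 59 RDS.
    """

    n_nonrds: int = 74
    n_rds: int = 59
    nonrds_loc: float = 3.0
    nonrds_scale: float = 0.8
    rds_loc: float = 1.6
    rds_scale: float = 0.5
    lower_truncation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonrds < 0 or self.n_rds < 0:
            raise ConfigError("cohort counts must be >= 0")
        if self.nonrds_scale < 0 or self.rds_scale < 0:
            raise ConfigError("distribution scales must be >= 0")


def simulate_cohort_ls(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a reference cohort: columns ``ls`` (true L/S) and ``rds`` (0/1)."""
    rng = np.random.default_rng(spec.seed)

    def draw(n: int, loc: float, scale: float) -> np.ndarray:
        if scale == 0:
            return np.full(n, loc)
        a = (spec.lower_truncation - loc) / scale
        return truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n,
                             random_state=rng)

    ls = np.concatenate([
        draw(spec.n_nonrds, spec.nonrds_loc, spec.nonrds_scale),
        draw(spec.n_rds, spec.rds_loc, spec.rds_scale),
    ])
    rds = np.concatenate([np.zeros(spec.n_nonrds, int), np.ones(spec.n_rds, int)])
    return pd.DataFrame({"ls": ls, "rds": rds})
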