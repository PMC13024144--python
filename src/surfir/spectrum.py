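"""Wavenumber grids, single spectra and the wide-CSV interchange format.

Spectra are stored on a strictly descending, uniformly spaced wavenumber
axis (cm^-1), the native ordering of FTIR instrument exports. The on-disk
dialect is a wide CSV whose first column is ``wavenumber_cm-1`` and whose
remaining columns are one absorbance trace per scan, plus a sidecar
metadata CSV keyed by ``spectrum_id``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

WAVENUMBER_COLUMN = "wavenumber_cm-1"


@dataclass
class WavenumberGrid:
    """Uniform descending wavenumber axis.

    Defaults cover the mid-IR working range 4000-850 cm^-1 at 2 cm^-1 point
    spacing (a 4 cm^-1 optical resolution instrument typically exports
    <= 2 cm^-1 point spacing).
    """

    start: float = 4000.0
    end: float = 850.0
    spacing: float = 2.0

    def __post_init__(self) -> None:
        self.start = float(self.start)
        self.end = float(self.end)
        self.spacing = float(self.spacing)
        if self.start <= self.end:
            raise ConfigError("grid start must exceed end (descending axis)")
        if self.spacing <= 0:
            raise ConfigError("grid spacing must be positive")
        n_steps = (self.start - self.end) / self.spacing
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("grid span must be an integer multiple of spacing")
        self._values = self.start - self.spacing * np.arange(int(round(n_steps)) + 1)

    @property
    def values(self) -> np.ndarray:
        return self._values

    def __len__(self) -> int:
        return len(self._values)

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``; ties break toward
        the higher wavenumber (lower index on a descending axis)."""
        if not (self.end <= wavenumber <= self.start):
            raise ConfigError(
                f"wavenumber {wavenumber} outside grid range [{self.end}, {self.start}]"
            )
        pos = (self.start - wavenumber) / self.spacing
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(self) - 1)
        # equidistant -> keep lo, the higher wavenumber
        return lo if (pos - lo) <= (hi - pos) else hi


def nearest_index(wavenumbers: np.ndarray, target: float) -> int:
    """Nearest-point lookup on an arbitrary descending axis (tie -> higher nu)."""
    if not (wavenumbers.min() <= target <= wavenumbers.max()):
        raise ConfigError(f"wavenumber {target} outside axis range")
    d = np.abs(wavenumbers - target)
    # argmin returns the first (highest-wavenumber) index among ties
    return int(np.argmin(d))


@dataclass
class Spectrum:
    """A single absorbance trace with acquisition metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise DataError("wavenumber and absorbance vectors differ in length")
        if not np.all(np.isfinite(self.absorbance)):
            raise DataError("absorbance contains non-finite values")

    def replace(self, **kw) -> "Spectrum":
        d = {"wavenumbers": self.wavenumbers, "absorbance": self.absorbance,
             "meta": dict(self.meta)}
        d.update(kw)
        return Spectrum(**d)


@dataclass
class SpectraSet:
    """A collection of spectra sharing one wavenumber axis.

    ``absorbance`` is (n_spectra, n_points); ``meta`` carries one row per
    spectrum and always includes a ``spectrum_id`` column.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != len(self.wavenumbers):
            raise DataError("absorbance column count does not match the axis")
        if len(self.meta) != self.absorbance.shape[0]:
            raise DataError("metadata row count does not match spectra count")
        if "spectrum_id" not in self.meta.columns:
            raise DataError("metadata must carry a spectrum_id column")

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def spectra(self):
        for i, (_, row) in enumerate(self.meta.iterrows()):
            yield Spectrum(self.wavenumbers, self.absorbance[i], row.to_dict())

    def write(self, spectra_path: str | Path, meta_path: str | Path | None = None) -> None:
        columns = {WAVENUMBER_COLUMN: self.wavenumbers}
        columns.update(
            {str(sid): self.absorbance[i]
             for i, sid in enumerate(self.meta["spectrum_id"])}
        )
        pd.DataFrame(columns).to_csv(spectra_path, index=False)
        if meta_path is not None:
            self.meta.to_csv(meta_path, index=False)

    @classmethod
    def read(cls, spectra_path: str | Path, meta_path: str | Path | None = None) -> "SpectraSet":
        wide = pd.read_csv(spectra_path)
        if WAVENUMBER_COLUMN not in wide.columns:
            raise DataError(f"spectra CSV must have a '{WAVENUMBER_COLUMN}' first column")
        wavenumbers = wide[WAVENUMBER_COLUMN].to_numpy()
        ids = [c for c in wide.columns if c != WAVENUMBER_COLUMN]
        absorbance = wide[ids].to_numpy().T
        if meta_path is not None:
            meta = pd.read_csv(meta_path)
            meta["spectrum_id"] = meta["spectrum_id"].astype(str)
            meta = meta.set_index("spectrum_id").loc[ids].reset_index()
        else:
            meta = pd.DataFrame({"spectrum_id": ids})
        return cls(wavenumbers, absorbance, meta)
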