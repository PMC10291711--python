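"""Wavelength grids, spectrum containers, resampling, integration and CSV I/O.

Every downstream stage (synthetic generation, quantum-catch calculation, the
classifier pipeline) works on :class:`Spectrum` objects that share one common
wavelength grid.  The master grid of the analysis is 300–700 nm at 2 nm
resolution (201 samples, endpoints inclusive); all inputs are resampled onto
it before any computation.

Numerical integration uses a left-Riemann sum times the grid step.  Quantum
catches are ratios of such sums over the same grid, so the choice of
quadrature rule cancels to first order and only needs to be consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_KINDS = ("reflectance", "irradiance", "sensitivity")


class SpectrumError(ValueError):
    """Base class for spectral validation failures."""


class GridMismatchError(SpectrumError):
    """Operands do not share an identical wavelength grid."""


class RangeError(SpectrumError):
    """Target grid lies outside the source spectrum's coverage."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm, endpoints inclusive.

    Grid points are exactly ``start + i * step`` for ``i = 0 .. n-1``.
    """

    start: float = 300.0
    stop: float = 700.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise SpectrumError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise SpectrumError(f"grid step must be positive, got {self.step}")
        n_intervals = (self.stop - self.start) / self.step
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise SpectrumError(
                f"grid span {self.start}-{self.stop} is not an integer number of "
                f"{self.step} nm steps"
            )

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))

    def index_of(self, wavelength: float) -> int:
        """Index of the grid point nearest to ``wavelength``."""
        return int(round((wavelength - self.start) / self.step))


#: the 2 nm master grid used throughout the analysis
MASTER_GRID = WavelengthGrid(300.0, 700.0, 2.0)


@dataclass
class Spectrum:
    """A non-negative spectrum sampled on a :class:`WavelengthGrid`.

    ``kind`` is one of ``reflectance`` (fraction, values in [0, 1]),
    ``irradiance`` (photon flux, arbitrary scale) or ``sensitivity``
    (dimensionless, usually peak-normalized).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}; expected one of {VALID_KINDS}")
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise SpectrumError(
                f"spectrum {self.id!r}: {self.values.size} values for a grid of "
                f"{len(self.grid)} points"
            )
        if not np.all(np.isfinite(self.values)):
            raise SpectrumError(f"spectrum {self.id!r} contains non-finite values")
        if np.any(self.values < 0):
            bad = int(np.argmin(self.values))
            raise SpectrumError(
                f"spectrum {self.id!r} has negative value {self.values[bad]:g} at "
                f"{self.grid.wavelengths[bad]:g} nm"
            )
        if self.kind == "reflectance" and np.any(self.values > 1.0 + 1e-9):
            bad = int(np.argmax(self.values))
            raise SpectrumError(
                f"reflectance {self.id!r} exceeds 1 (value {self.values[bad]:g} at "
                f"{self.grid.wavelengths[bad]:g} nm); express reflectance as a fraction"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def value_at(self, wavelength: float) -> float:
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def with_values(self, values: np.ndarray, id: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, self.kind, self.id if id is None else id)

    def scaled(self, factor: float, id: str | None = None) -> "Spectrum":
        return self.with_values(self.values * factor, id=id)


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Piecewise-linear resampling of ``spectrum`` onto ``target``.

    Values at target wavelengths are linear interpolants of the source
    samples; beyond the source endpoints (by at most one source step) the
    endpoint value is held.  Kind and id are preserved.
    """
    src = spectrum.grid
    if target.start < src.start - src.step or target.stop > src.stop + src.step:
        raise RangeError(
            f"target grid {target.start}-{target.stop} nm outside source coverage "
            f"{src.start}-{src.stop} nm (±one source step)"
        )
    values = np.interp(target.wavelengths, spectrum.wavelengths, spectrum.values)
    return Spectrum(target, values, spectrum.kind, spectrum.id)


def integrate_product(factors: Sequence[Spectrum]) -> float:
    """Left-Riemann integral of the pointwise product of ``factors``.

    Returns ``sum_over_points_except_last(prod(factors)) * step``.  All
    factors must share one grid.  With a single constant-1 factor on the
    master grid this is exactly 400 (the last grid point is the right edge
    of no interval and does not contribute).
    """
    if len(factors) == 0:
        raise SpectrumError("integrate_product needs at least one factor")
    grid = factors[0].grid
    for f in factors[1:]:
        if f.grid != grid:
            raise GridMismatchError(
                f"factor {f.id!r} on grid {f.grid} does not match {grid}"
            )
    product = np.multiply.reduce([f.values for f in factors])
    return float(np.sum(product[:-1]) * grid.step)


@dataclass
class SpectrumTable:
    """Ordered collection of spectra sharing one grid, with a class label each.

    Labels follow the convention ``leaf``, ``animal`` or ``fabric:<kind>``,
    but arbitrary strings are accepted so the container stays generic.
    """

    spectra: list[Spectrum] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectrumError(f"duplicate spectrum ids: {dupes}")
        if self.spectra:
            grid = self.spectra[0].grid
            for s in self.spectra[1:]:
                if s.grid != grid:
                    raise GridMismatchError(f"spectrum {s.id!r} not on the shared grid")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise SpectrumError(f"missing class labels for: {missing}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.spectra]

    @property
    def grid(self) -> WavelengthGrid:
        if not self.spectra:
            raise SpectrumError("empty table has no grid")
        return self.spectra[0].grid

    def get(self, id: str) -> Spectrum:
        for s in self.spectra:
            if s.id == id:
                return s
        raise KeyError(id)

    def values_matrix(self) -> np.ndarray:
        """(n_spectra, n_wavelengths) matrix of values."""
        return np.stack([s.values for s in self.spectra])

    def subset(self, label: str) -> "SpectrumTable":
        keep = [s for s in self.spectra if self.labels[s.id] == label]
        return SpectrumTable(keep, {s.id: label for s in keep})

    def mean_spectrum(self, id: str = "mean", label: str | None = None) -> Spectrum:
        """Mean of all member spectra (or of those with class ``label``)."""
        table = self if label is None else self.subset(label)
        if not len(table):
            raise SpectrumError(f"no spectra with label {label!r}")
        mean = table.values_matrix().mean(axis=0)
        return Spectrum(table.grid, mean, table.spectra[0].kind, id)

    def resampled(self, target: WavelengthGrid) -> "SpectrumTable":
        return SpectrumTable([resample(s, target) for s in self.spectra], dict(self.labels))

    @staticmethod
    def concat(tables: Iterable["SpectrumTable"]) -> "SpectrumTable":
        spectra: list[Spectrum] = []
        labels: dict[str, str] = {}
        for t in tables:
            spectra.extend(t.spectra)
            labels.update(t.labels)
        return SpectrumTable(spectra, labels)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"wavelength_nm": self.grid.wavelengths})
        for s in self.spectra:
            frame[s.id] = s.values
        return frame


LabelSpec = str | Mapping[str, str] | Callable[[str], str] | None


def _resolve_label(label: LabelSpec, id: str) -> str:
    if label is None:
        return "unlabelled"
    if isinstance(label, str):
        return label
    if callable(label):
        return label(id)
    return label[id]


def read_spectra_csv(path: str | Path, kind: str, label: LabelSpec = None) -> SpectrumTable:
    """Read a spectral table: first column wavelength (nm), one column per spectrum.

    Wavelengths must be strictly increasing and uniformly spaced.  Reflectance
    tables given in percent (max value > 1.5) are rescaled to fractions, with
    a log message recording the conversion.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise SpectrumError(f"{path}: need a wavelength column plus at least one spectrum")
    wl = frame.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise SpectrumError(f"{path}: wavelengths not strictly increasing at data row {row}")
    step = diffs[0]
    if np.any(np.abs(diffs - step) > 1e-6):
        raise SpectrumError(f"{path}: wavelength spacing is not uniform")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))

    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}
    for col in frame.columns[1:]:
        values = frame[col].to_numpy(dtype=float)
        neg = np.where(values < 0)[0]
        if neg.size:
            raise SpectrumError(
                f"{path}: negative value {values[neg[0]]:g} in column {col!r} at "
                f"{wl[neg[0]]:g} nm"
            )
        if kind == "reflectance" and np.nanmax(values) > 1.5:
            logger.info("%s: column %r looks like percent reflectance; dividing by 100", path, col)
            values = values / 100.0
        spectra.append(Spectrum(grid, values, kind, str(col)))
        labels[str(col)] = _resolve_label(label, str(col))
    return SpectrumTable(spectra, labels)


def write_spectra_csv(table: SpectrumTable, path: str | Path) -> None:
    """Write a :class:`SpectrumTable` in the same CSV layout ``read_spectra_csv`` expects."""
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


__all__ = [
    "MASTER_GRID",
    "VALID_KINDS",
    "GridMismatchError",
    "RangeError",
    "Spectrum",
    "SpectrumError",
    "SpectrumTable",
    "WavelengthGrid",
    "integrate_product",
    "read_spectra_csv",
    "resample",
    "write_spectra_csv",
]
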