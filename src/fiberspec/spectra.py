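"""Core spectrum containers and arithmetic.

A :class:`Spectrum` is a vector of values (detector counts, counts per
second, or a dimensionless reflectance) sampled on a shared
:class:`WavelengthGrid`.  Every other module builds on the four primitive
operations defined here: resampling, subtraction, masked division and
ensemble averaging.

Conventions
-----------
* Grids are strictly increasing, finite, positive, in nanometres.  Spacing
  may be non-uniform and is kept exactly as given.
* Arithmetic between two spectra requires *identical* grids; resampling is
  always explicit (:func:`resample`), never implicit.
* Negative values (routine after dark/background subtraction) are retained,
  never clamped — clamping would bias downstream ensemble averages.  Use
  :func:`negative_fraction` to raise QC flags instead.
* Invalid points are carried in a boolean mask (``True`` = masked/invalid);
  :func:`divide` masks rather than emitting infinities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "GridMismatchError",
    "default_grid",
    "resample",
    "subtract",
    "add",
    "divide",
    "ensemble_average",
    "negative_fraction",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

VALID_UNITS = ("counts", "counts_per_s", "reflectance", "dimensionless")


class GridMismatchError(ValueError):
    """Raised when an operation requires two spectra on one grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing spectral axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid must be 1-D with at least 2 points")
        if not np.all(np.isfinite(w)):
            raise ValueError("wavelength grid must be finite")
        if np.any(w <= 0):
            raise ValueError("wavelengths must be positive (nm)")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:
        return hash((self.wavelengths.size, float(self.wavelengths[0]), float(self.wavelengths[-1])))

    @property
    def span(self) -> float:
        return float(self.wavelengths[-1] - self.wavelengths[0])

    def contains(self, other: "WavelengthGrid") -> bool:
        return (
            other.wavelengths[0] >= self.wavelengths[0] - 1e-12
            and other.wavelengths[-1] <= self.wavelengths[-1] + 1e-12
        )


def default_grid(start: float = 400.0, stop: float = 800.0, step: float = 0.25) -> WavelengthGrid:
    """The working grid: uniform 0.25-nm sampling over 400–800 nm.

    0.25 nm matches the spectrometer resolution; 400–800 nm covers the
    visible band where haemoglobin absorption features live.
    """
    n = int(round((stop - start) / step)) + 1
    return WavelengthGrid(start + step * np.arange(n))


@dataclass
class Spectrum:
    """Values on a wavelength grid with a units tag and validity mask.

    ``mask[i] is True`` marks point *i* invalid (e.g. produced by a division
    whose denominator fell below the floor).  Masked values are stored as 0.
    """

    grid: WavelengthGrid
    values: np.ndarray
    units: str = "counts"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.wavelengths.shape:
            raise ValueError("values shape does not match grid")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if self.mask is None:
            m = np.zeros(v.shape, dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("mask shape does not match values")
        if not np.all(np.isfinite(v[~m])):
            raise ValueError("unmasked spectrum values must be finite")
        v = v.copy()
        v[m] = 0.0
        self.values = v
        self.mask = m

    # -- convenience -------------------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.values.copy(), self.units, self.mask.copy())

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, units or self.units, self.mask.copy())

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.values * factor, self.units, self.mask.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.grid == other.grid
            and self.units == other.units
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.mask, other.mask)
        )


def _require_same_grid(a: Spectrum, b: Spectrum) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            "spectra are on different wavelength grids; resample explicitly first"
        )


def resample(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Piecewise-linear resampling of ``s`` onto ``target``.

    The target range must lie inside the source range; no smoothing and no
    extrapolation (sharp features such as emission lines must survive
    unaltered apart from linear interpolation).
    """
    if target == s.grid:
        return s.copy()
    if not s.grid.contains(target):
        raise ValueError(
            f"target grid [{target.wavelengths[0]}, {target.wavelengths[-1]}] nm "
            f"extends outside source [{s.wavelengths[0]}, {s.wavelengths[-1]}] nm"
        )
    vals = np.interp(target.wavelengths, s.wavelengths, s.values)
    if s.mask.any():
        # a target point is invalid if either bracketing source point is
        mask_f = np.interp(target.wavelengths, s.wavelengths, s.mask.astype(float))
        mask = mask_f > 0
    else:
        mask = None
    return Spectrum(target, vals, s.units, mask)


def subtract(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise ``a − b``.  Negative results are retained."""
    _require_same_grid(a, b)
    return Spectrum(a.grid, a.values - b.values, a.units, a.mask | b.mask)


def add(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise ``a + b`` (the exact inverse of :func:`subtract`)."""
    _require_same_grid(a, b)
    return Spectrum(a.grid, a.values + b.values, a.units, a.mask | b.mask)


def divide(a: Spectrum, b: Spectrum, floor: float = 1e-12, units: str = "dimensionless") -> Spectrum:
    """Pointwise ``a / b`` with masking where ``|b| < floor``.

    Never emits non-finite values: points where the denominator magnitude
    falls below ``floor`` (and points already masked in either operand) are
    masked in the output.
    """
    _require_same_grid(a, b)
    if not floor > 0:
        raise ValueError("floor must be positive")
    small = np.abs(b.values) < floor
    mask = a.mask | b.mask | small
    out = np.zeros_like(a.values)
    ok = ~mask
    out[ok] = a.values[ok] / b.values[ok]
    return Spectrum(a.grid, out, units, mask)


def ensemble_average(spectra: Sequence[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Pointwise mean and unbiased variance of a set of spectra.

    With a single spectrum the variance is all zero.  Used to average
    repeated accumulations at distinct probe locations so that independent
    speckle realisations cancel.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("ensemble_average requires at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        _require_same_grid(first, s)
    stack = np.stack([s.values for s in spectra])
    mask = np.zeros(first.values.shape, dtype=bool)
    for s in spectra:
        mask |= s.mask
    mean = stack.mean(axis=0)
    if len(spectra) == 1:
        var = np.zeros_like(mean)
    else:
        var = stack.var(axis=0, ddof=1)
    return (
        Spectrum(first.grid, mean, first.units, mask),
        Spectrum(first.grid, var, first.units, mask.copy()),
    )


def negative_fraction(s: Spectrum) -> float:
    """Fraction of unmasked points with negative value (QC metric)."""
    ok = ~s.mask
    if not ok.any():
        return 0.0
    return float((s.values[ok] < 0).sum() / ok.sum())


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_spectrum_csv(s: Spectrum, path) -> None:
    """Two-column CSV (wavelength_nm, value) with a ``# units:`` header.

    Values print at 17 significant digits so a read/write round trip is
    bit-stable; masked points are written as ``nan``.
    """
    buf = io.StringIO()
    buf.write(f"# units: {s.units}\n")
    buf.write("wavelength_nm,value\n")
    for w, v, m in zip(s.wavelengths, s.values, s.mask):
        buf.write(f"{w:.17g},{'nan' if m else format(v, '.17g')}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_spectrum_csv(path) -> Spectrum:
    units = "counts"
    wl: list[float] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line:
                    units = line.split("units:", 1)[1].strip()
                continue
            if line.startswith("wavelength"):
                continue
            a, b = line.split(",")
            wl.append(float(a))
            vals.append(float(b))
    values = np.asarray(vals)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return Spectrum(WavelengthGrid(np.asarray(wl)), values, units, mask)
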