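"""Real-time flat-field correction for symmetric fiber probes.

Endoscopic bending changes each fiber's throughput (OTF) by more than 1.5 %
after the bench calibration, which a static flat-field cannot correct.  For a
probe whose two illumination fibers sit at mirrored distances from the two
collection fibers, illuminating the outer fibers sequentially gives four
measurements of the same two tissue regions:

    S21 = L * T1_ill * T2_coll * S_alpha      (fiber 1 lit, fiber 2 collects)
    S31 = L * T1_ill * T3_coll * S_beta
    S24 = L * T4_ill * T2_coll * S_beta       (fiber 4 lit; the collection
    S34 = L * T4_ill * T3_coll * S_alpha       fibers swap tissue regions)

so the product ratio (S21*S34)/(S24*S31) cancels the lamp and every
per-fiber throughput exactly, leaving (S_alpha/S_beta)**2.  The default
``sqrt`` mode takes the square root and returns S_alpha/S_beta, the ratio of
the two intrinsic tissue responses; ``literal`` mode returns the raw product
ratio.  Only a per-channel-pair background subtraction is required — no
other calibration survives bending, this ratio does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .measurement import ChannelPair, RawMeasurement
from .spectra import Spectrum, divide, subtract

__all__ = [
    "ProbeGeometry",
    "SymmetricPairSet",
    "SymmetryDiagnostic",
    "correct_ratio",
    "naive_ratio",
    "stream_correct",
    "validate_symmetry",
    "default_geometry",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber positions in the probe-face plane (mm) and their roles."""

    positions: Mapping[int, tuple[float, float]]
    illumination: tuple[int, int] = (1, 4)
    collection: tuple[int, int] = (2, 3)

    def distance(self, a: int, b: int) -> float:
        (xa, ya), (xb, yb) = self.positions[a], self.positions[b]
        return float(np.hypot(xa - xb, ya - yb))


def default_geometry(pitch_mm: float = 0.060) -> ProbeGeometry:
    """The linear four-fiber array: 1 (illum), 2, 3 (collect), 4 (illum) at
    ~60-µm center-to-center pitch."""
    return ProbeGeometry(
        positions={i: ((i - 1) * pitch_mm, 0.0) for i in (1, 2, 3, 4)},
    )


@dataclass
class SymmetryDiagnostic:
    valid: bool
    message: str
    short_distances: tuple[float, float] = (0.0, 0.0)
    long_distances: tuple[float, float] = (0.0, 0.0)


def validate_symmetry(geometry: ProbeGeometry, tol_mm: float = 1e-3) -> SymmetryDiagnostic:
    """Check the cross-distance equalities the correction relies on.

    With illumination fibers (i1, i2) and collection fibers (c1, c2) the
    requirement is d(i1, c1) == d(i2, c2) and d(i1, c2) == d(i2, c1), i.e.
    each collection fiber sees the two illumination fibers at the mirrored
    pair of separations.  Default tolerance 1 µm.
    """
    i1, i2 = geometry.illumination
    c1, c2 = geometry.collection
    d_short = (geometry.distance(i1, c1), geometry.distance(i2, c2))
    d_long = (geometry.distance(i1, c2), geometry.distance(i2, c1))
    problems = []
    if abs(d_short[0] - d_short[1]) > tol_mm:
        problems.append(
            f"d({i1},{c1})={d_short[0]:.6f} mm != d({i2},{c2})={d_short[1]:.6f} mm"
        )
    if abs(d_long[0] - d_long[1]) > tol_mm:
        problems.append(
            f"d({i1},{c2})={d_long[0]:.6f} mm != d({i2},{c1})={d_long[1]:.6f} mm"
        )
    if problems:
        return SymmetryDiagnostic(False, "; ".join(problems), d_short, d_long)
    return SymmetryDiagnostic(True, "symmetric within tolerance", d_short, d_long)


@dataclass
class SymmetricPairSet:
    """The four measurements of one correction cycle.

    Naming is S_{collection,illumination}: ``s21`` is collection fiber 2
    under illumination fiber 1.  The two frames (illumination 1, then 4) are
    consecutive in time.
    """

    s21: RawMeasurement
    s31: RawMeasurement
    s24: RawMeasurement
    s34: RawMeasurement
    geometry: ProbeGeometry = field(default_factory=default_geometry)

    def __post_init__(self) -> None:
        ms = (self.s21, self.s31, self.s24, self.s34)
        illums = {m.illum_fiber for m in ms}
        collects = {m.collect_fiber for m in ms}
        if len(illums) != 2 or len(collects) != 2:
            raise ValueError(
                "a symmetric pair set must cover exactly two illumination and "
                "two collection fibers"
            )
        if self.s21.illum_fiber != self.s31.illum_fiber:
            raise ValueError("s21 and s31 must share the first illumination fiber")
        if self.s24.illum_fiber != self.s34.illum_fiber:
            raise ValueError("s24 and s34 must share the second illumination fiber")
        if self.s21.collect_fiber != self.s24.collect_fiber:
            raise ValueError("s21 and s24 must share a collection fiber")
        if self.s31.collect_fiber != self.s34.collect_fiber:
            raise ValueError("s31 and s34 must share a collection fiber")

    @property
    def measurements(self) -> tuple[RawMeasurement, ...]:
        return (self.s21, self.s31, self.s24, self.s34)

    @property
    def time(self) -> float:
        return self.s21.time


def _background_subtracted(
    m: RawMeasurement, backgrounds: Mapping[ChannelPair, Spectrum]
) -> Spectrum:
    if m.pair not in backgrounds:
        raise KeyError(f"no background measurement for channel pair {m.pair}")
    return subtract(m.dark_subtracted(), backgrounds[m.pair])


def correct_ratio(
    p: SymmetricPairSet,
    backgrounds: Mapping[ChannelPair, Spectrum],
    mode: str = "sqrt",
    floor: float = 1e-9,
) -> Spectrum:
    """The throughput-free ratio of the two intrinsic tissue responses.

    ``sqrt`` (default): sqrt[(S21·S34) / (S24·S31)] = S_alpha / S_beta.
    ``literal``: the raw product ratio, i.e. (S_alpha / S_beta)**2.

    Each measurement is dark- and background-subtracted first (the
    cancellation only holds after background subtraction).  Points where any
    of the four inputs falls at or below ``floor`` (relative to its own peak)
    are masked, so the output is always finite.
    """
    if mode not in ("sqrt", "literal"):
        raise ValueError("mode must be 'sqrt' or 'literal'")
    x21, x31, x24, x34 = (
        _background_subtracted(m, backgrounds) for m in p.measurements
    )
    grid = x21.grid
    mask = x21.mask | x31.mask | x24.mask | x34.mask
    for x in (x21, x31, x24, x34):
        mask |= x.values <= floor * np.abs(x.values).max(initial=0.0)
    num = x21.values * x34.values
    den = x24.values * x31.values
    mask |= den == 0.0
    out = np.zeros(len(grid))
    ok = ~mask
    out[ok] = num[ok] / den[ok]
    if mode == "sqrt":
        out[ok] = np.sqrt(out[ok])
    return Spectrum(grid, out, "dimensionless", mask)


def naive_ratio(
    p: SymmetricPairSet,
    backgrounds: Mapping[ChannelPair, Spectrum],
    flatfield: Mapping[int, Spectrum] | None = None,
    floor: float = 1e-9,
) -> Spectrum:
    """The traditional short-SDS / long-SDS channel division, S21 / S31.

    Optionally normalised by a *static* flat-field taken at calibration time;
    any OTF change after that calibration lands directly in this ratio, which
    is exactly the failure mode the four-measurement correction removes.
    """
    x21 = _background_subtracted(p.s21, backgrounds)
    x31 = _background_subtracted(p.s31, backgrounds)
    if flatfield is not None:
        ff2 = flatfield[p.s21.collect_fiber]
        ff3 = flatfield[p.s31.collect_fiber]
        x21 = divide(x21, ff2, floor=floor * float(np.abs(ff2.values).max()))
        x31 = divide(x31, ff3, floor=floor * float(np.abs(ff3.values).max()))
    return divide(x21, x31, floor=floor * float(np.abs(x31.values).max(initial=0.0)))


@dataclass
class StreamResult:
    outputs: list[Spectrum]
    flagged: list[bool]          # True = in-motion set, output unreliable


def _rel_change(a: Spectrum, b: Spectrum) -> float:
    # median over wavelengths: a mid-cycle OTF change moves the whole spectrum
    # multiplicatively, while per-point read noise must not trip the flag
    ok = ~(a.mask | b.mask) & (np.abs(b.values) > 0)
    if not ok.any():
        return np.inf
    return float(np.median(np.abs(a.values[ok] / b.values[ok] - 1.0)))


def stream_correct(
    stream: Sequence[SymmetricPairSet],
    backgrounds: Mapping[ChannelPair, Spectrum],
    mode: str = "sqrt",
    jump_threshold: float = 0.005,
    floor: float = 1e-9,
) -> StreamResult:
    """Apply :func:`correct_ratio` along a time-ordered stream and flag
    in-motion sets.

    A bending event that falls *between* a set's two illumination frames
    changes a collection OTF mid-cycle, so that set's output is wrong; the
    corrected output is OTF-invariant, so such a set shows up as an isolated
    spike: a jump above ``jump_threshold`` relative to the previous set,
    with the following set back at the pre-jump level.  Trailing sets are
    flagged on the jump alone.  The only unreliable outputs are these
    flagged, in-motion sets; once the probe is still again, the very next
    cycle is correct even if the fibers never return to their original state.
    """
    outputs = [correct_ratio(p, backgrounds, mode=mode, floor=floor) for p in stream]
    n = len(outputs)
    flagged = [False] * n
    for i in range(1, n):
        jump = _rel_change(outputs[i], outputs[i - 1])
        if jump <= jump_threshold:
            continue
        if i == n - 1:
            flagged[i] = True
        else:
            back = _rel_change(outputs[i + 1], outputs[i - 1])
            if back <= jump_threshold:
                flagged[i] = True
            elif flagged[i - 1]:
                # recovery edge after a flagged spike: current set is fine
                continue
            else:
                flagged[i] = True
    return StreamResult(outputs=outputs, flagged=flagged)
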