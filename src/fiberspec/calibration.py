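"""The automated calibration sequence and its application to sample spectra.

A calibration run measures, in order: the background fixture (internal probe
reflections), the flat-field fixture (per-channel throughput, probe lamp
off), the white reflectance standard (lamp shape, speckle-averaged over
stage positions), a Hg–Ar lamp (wavelength-axis registration) and two solid
scattering phantoms (stability tracking).  Processing a sample measurement
then inverts the instrument model

    S_measured = L * (B + T_ill * T_coll * S_sample)

step by step: paired-dark subtraction removes bias/external light, the
background measurement removes L*B, flat-field division removes per-channel
throughput, and white-standard division removes the remaining lamp shape —
leaving the sample reflectance relative to the 99 % standard.

Processing order matters: background must come off before any normalisation
(white division does not commute with background subtraction when B != 0).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .measurement import ChannelPair, RawMeasurement
from .simulate import hgar_reference_lines
from .spectra import (
    Spectrum,
    WavelengthGrid,
    divide,
    ensemble_average,
    negative_fraction,
    read_spectrum_csv,
    subtract,
    write_spectrum_csv,
)

__all__ = [
    "CalibrationConfig",
    "CalibrationMeasurements",
    "CalibrationSet",
    "QCReport",
    "SpeckleAverage",
    "ShiftEstimate",
    "CalibrationError",
    "CalibrationIncompleteError",
    "ShiftEstimationError",
    "run_calibration_sequence",
    "speckle_averaged_measurement",
    "estimate_wavelength_shift",
    "apply_wavelength_correction",
    "process_sample",
    "qc_evaluate",
    "save_calibration_set",
    "load_calibration_set",
]


class CalibrationError(RuntimeError):
    """A calibration step failed outright (e.g. non-positive flat-field)."""

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"calibration step {step!r} failed: {message}")


class CalibrationIncompleteError(CalibrationError):
    """A required calibration measurement is missing."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__("completeness", "missing measurements: " + ", ".join(self.missing))


class ShiftEstimationError(CalibrationError):
    def __init__(self, message: str):
        super().__init__("wavelength", message)


@dataclass
class CalibrationConfig:
    """Tunables of the calibration sequence and its QC gates."""

    n_locations: int = 20               # stage positions per solid standard
    shift_limit: float = 0.5            # nm; larger estimated shift fails QC
    phantom_sd_limit: float = 0.01      # white-standard units, across calibrations
    phantom_mad_limit: float = 0.01     # deviation of current from history mean
    negative_fraction_limit: float = 0.05
    correction_min_shift: float = 0.05  # nm; below this, skip resampling correction
    match_window: float = 3.0           # nm; peak-to-reference matching radius
    min_matched_lines: int = 3
    rel_floor: float = 1e-9             # relative division floor
    white_reflectance: float = 0.99     # the Spectralon standard


@dataclass
class CalibrationMeasurements:
    """Everything one run of the automated calibration tool yields.

    All entries are raw signal+dark pairs; ``white`` and ``phantoms`` carry
    one measurement per stage location so speckle can be ensemble-averaged.
    """

    background: dict[ChannelPair, RawMeasurement]
    white: dict[ChannelPair, list[RawMeasurement]]
    flatfield: dict[int, RawMeasurement]            # collection fiber -> frame
    hgar: RawMeasurement | None
    phantoms: dict[str, dict[ChannelPair, list[RawMeasurement]]]


@dataclass
class SpeckleAverage:
    mean: Spectrum            # counts/s, dark-subtracted
    variance: Spectrum        # pointwise unbiased variance across locations
    n: int


@dataclass
class ShiftEstimate:
    """Global wavelength-axis offset with per-line diagnostics."""

    shift: float                          # nm, median over matched lines
    residuals: dict[float, float]         # reference line -> centroid - reference
    n_matched: int

    def __float__(self) -> float:
        return float(self.shift)


@dataclass
class QCReport:
    passed: bool
    failed_step: str | None = None
    failures: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    prompt_repeat: bool = False
    phantom_sd: dict[str, float] = field(default_factory=dict)        # mean pointwise SD
    phantom_deviation: dict[str, float] = field(default_factory=dict) # MAD from history mean
    negative_fractions: dict[str, float] = field(default_factory=dict)
    wavelength_shift: float = 0.0
    shift_history: list[float] = field(default_factory=list)


@dataclass
class CalibrationSet:
    """The complete, processed output of one calibration sequence."""

    background: dict[ChannelPair, Spectrum]   # counts/s, dark-subtracted
    white: dict[ChannelPair, Spectrum]        # counts/s, dark- and background-subtracted, speckle-averaged
    flatfield: dict[int, Spectrum]            # counts/s, bias-subtracted only
    wavelength_shift: float
    shift_residuals: dict[float, float] = field(default_factory=dict)
    phantom_refs: dict[str, Spectrum] = field(default_factory=dict)   # fully processed
    white_variance: dict[ChannelPair, Spectrum] = field(default_factory=dict)
    qc: QCReport | None = None

    @property
    def passed(self) -> bool:
        return bool(self.qc and self.qc.passed)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _rel_floor(s: Spectrum, rel: float) -> float:
    m = float(np.abs(s.values[~s.mask]).max(initial=0.0))
    return max(m * rel, np.finfo(float).tiny)


def speckle_averaged_measurement(measurements: Sequence[RawMeasurement]) -> SpeckleAverage:
    """Dark-subtract each accumulation, then ensemble-average over locations.

    Distinct stage locations carry independent speckle realisations, so the
    pointwise variance of the mean falls as 1/n; repeated accumulations at
    one location share a frozen speckle field and gain nothing, which is why
    duplicate location indices draw a warning.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("speckle_averaged_measurement requires at least one measurement")
    pair = measurements[0].pair
    for m in measurements[1:]:
        if m.pair != pair:
            raise ValueError("all measurements must share one channel pair")
    locations = [m.location for m in measurements]
    if len(set(locations)) < len(locations):
        warnings.warn(
            "duplicate stage locations in speckle average: repeated accumulations "
            "at one location share the same speckle pattern",
            stacklevel=2,
        )
    spectra = [m.dark_subtracted() for m in measurements]
    mean, var = ensemble_average(spectra)
    return SpeckleAverage(mean=mean, variance=var, n=len(spectra))


def estimate_wavelength_shift(
    hgar: Spectrum,
    reference_lines: Sequence[float] | None = None,
    match_window: float = 3.0,
    min_matched_lines: int = 3,
) -> ShiftEstimate:
    """Global wavelength-axis offset from a dark-subtracted Hg–Ar frame.

    Local maxima are matched to the nearest reference line within
    ``match_window``; each matched peak centroid is refined by a three-point
    parabola on the log of the baseline-subtracted counts (exact for a
    Gaussian line of any width); the estimate is the median of
    (centroid − reference), robust to an occasional mismatched line.
    """
    if reference_lines is None:
        reference_lines = hgar_reference_lines()
    refs = np.asarray(reference_lines, dtype=float)
    lam = hgar.wavelengths
    in_range = (refs > lam[0]) & (refs < lam[-1])
    refs = refs[in_range]
    if refs.size < min_matched_lines:
        raise ShiftEstimationError(
            f"only {refs.size} reference lines inside the grid range"
        )

    v = hgar.values.astype(float).copy()
    v[hgar.mask] = 0.0
    v = v - np.median(v)
    if v.max() <= 0:
        raise ShiftEstimationError("no signal above baseline")
    peaks, _ = find_peaks(v, height=0.05 * v.max(), distance=2)
    peaks = peaks[(peaks > 0) & (peaks < len(v) - 1)]
    if peaks.size == 0:
        raise ShiftEstimationError("no emission peaks detected")

    centroids = []
    for p in peaks:
        y = v[p - 1 : p + 2]
        if np.all(y > 0):
            ly = np.log(y)
            denom = ly[0] - 2.0 * ly[1] + ly[2]
            delta = 0.5 * (ly[0] - ly[2]) / denom if denom != 0 else 0.0
        else:
            denom = y[0] - 2.0 * y[1] + y[2]
            delta = 0.5 * (y[0] - y[2]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -1.0, 1.0))
        local_step = 0.5 * (lam[p + 1] - lam[p - 1])
        centroids.append(lam[p] + delta * local_step)
    centroids = np.asarray(centroids)

    residuals: dict[float, float] = {}
    for ref in refs:
        d = np.abs(centroids - ref)
        i = int(np.argmin(d))
        if d[i] <= match_window:
            residuals[float(ref)] = float(centroids[i] - ref)
    if len(residuals) < min_matched_lines:
        raise ShiftEstimationError(
            f"only {len(residuals)} lines matched within ±{match_window} nm "
            f"(need {min_matched_lines})"
        )
    shift = float(np.median(list(residuals.values())))
    return ShiftEstimate(shift=shift, residuals=residuals, n_matched=len(residuals))


def apply_wavelength_correction(
    s: Spectrum, shift: float, target: WavelengthGrid | None = None
) -> Spectrum:
    """Undo a wavelength mis-registration of ``shift`` nm.

    The recorded axis reads ``true + shift``, so the grid is relabelled by
    −shift and the spectrum linearly resampled back onto the standard grid.
    The ≤|shift|-wide sliver that falls outside the relabelled range is
    filled by edge-hold (nearest value).
    """
    if abs(shift) >= s.grid.span / 10.0:
        raise ValueError("|shift| must be below a tenth of the grid span")
    if target is None:
        target = s.grid
    if shift == 0.0 and target == s.grid:
        return s.copy()
    src = s.wavelengths - shift
    vals = np.interp(target.wavelengths, src, s.values)
    if s.mask.any():
        mask = np.interp(target.wavelengths, src, s.mask.astype(float)) > 0
    else:
        mask = None
    return Spectrum(target, vals, s.units, mask)


# ---------------------------------------------------------------------------
# the sequence
# ---------------------------------------------------------------------------

def _check_complete(meas: CalibrationMeasurements) -> None:
    missing: list[str] = []
    if not meas.white:
        missing.append("white standard (no channel pairs)")
    pairs = set(meas.white)
    for ph, per_pair in meas.phantoms.items():
        pairs |= set(per_pair)
    for pair in sorted(pairs):
        if pair not in meas.background:
            missing.append(f"background for channel pair {pair}")
    for pair in sorted(pairs):
        if pair[1] not in meas.flatfield:
            missing.append(f"flat-field for collection fiber {pair[1]}")
    if meas.hgar is None:
        missing.append("Hg–Ar lamp measurement")
    if not meas.phantoms:
        missing.append("scattering phantom measurements")
    for ph, per_pair in meas.phantoms.items():
        if not per_pair:
            missing.append(f"phantom {ph!r} measurements")
    if missing:
        raise CalibrationIncompleteError(missing)


def run_calibration_sequence(
    meas: CalibrationMeasurements,
    config: CalibrationConfig | None = None,
    history: Sequence[CalibrationSet] = (),
) -> CalibrationSet:
    """Execute the full calibration pipeline on one measurement set.

    Order: dark subtraction everywhere → background extraction → flat-field
    (bias-subtracted only: the probe lamp is off during flat-field, so there
    is no background to remove) → speckle-averaged white standard → Hg–Ar
    shift estimation → phantom processing → QC.

    Hard failures (missing measurements, non-positive flat-field, shift
    estimation breakdown) raise :class:`CalibrationError`.  QC failures
    (shift over limit, unstable phantoms) return the set with
    ``qc.passed = False`` and ``qc.prompt_repeat = True`` so the operator can
    be asked to repeat the calibration.
    """
    cfg = config or CalibrationConfig()
    _check_complete(meas)

    background = {pair: m.dark_subtracted() for pair, m in meas.background.items()}

    flatfield: dict[int, Spectrum] = {}
    for fiber, m in meas.flatfield.items():
        ff = m.dark_subtracted()
        if np.any(ff.values[~ff.mask] <= 0):
            raise CalibrationError(
                "flatfield", f"non-positive throughput on collection fiber {fiber}"
            )
        flatfield[fiber] = ff

    white: dict[ChannelPair, Spectrum] = {}
    white_var: dict[ChannelPair, Spectrum] = {}
    for pair, frames in meas.white.items():
        avg = speckle_averaged_measurement(frames)
        white[pair] = subtract(avg.mean, background[pair])
        white_var[pair] = avg.variance

    shift_est = estimate_wavelength_shift(
        meas.hgar.dark_subtracted(),
        match_window=cfg.match_window,
        min_matched_lines=cfg.min_matched_lines,
    )

    cal = CalibrationSet(
        background=background,
        white=white,
        flatfield=flatfield,
        wavelength_shift=shift_est.shift,
        shift_residuals=shift_est.residuals,
        white_variance=white_var,
    )

    for ph, per_pair in meas.phantoms.items():
        processed = []
        for pair, frames in per_pair.items():
            avg = speckle_averaged_measurement(frames)
            processed.append(_process_spectrum(avg.mean, pair, cal, cfg))
        mean, _ = ensemble_average(processed)
        cal.phantom_refs[ph] = mean

    cal.qc = qc_evaluate(history, cal, cfg)
    return cal


def _process_spectrum(
    x: Spectrum, pair: ChannelPair, cal: CalibrationSet, cfg: CalibrationConfig
) -> Spectrum:
    """Background → flat-field → white normalisation of a dark-subtracted,
    counts/s spectrum, then wavelength correction if the estimated shift is
    above the resolution of the estimator."""
    if pair not in cal.background:
        raise CalibrationError("background", f"no background for channel pair {pair}")
    ff = cal.flatfield[pair[1]]
    y = subtract(x, cal.background[pair])
    y = divide(y, ff, floor=_rel_floor(ff, cfg.rel_floor))
    w = divide(cal.white[pair], ff, floor=_rel_floor(ff, cfg.rel_floor))
    r = divide(y, w, floor=_rel_floor(w, cfg.rel_floor), units="reflectance")
    if abs(cal.wavelength_shift) > cfg.correction_min_shift:
        r = apply_wavelength_correction(r, cal.wavelength_shift)
    return r


def process_sample(
    m: RawMeasurement,
    cal: CalibrationSet,
    config: CalibrationConfig | None = None,
    override: bool = False,
) -> Spectrum:
    """Fully calibrated reflectance of one sample measurement.

    Returns ``S_sample / S_white`` — dimensionless reflectance relative to
    the 99 % standard; masked points (division floors) propagate.
    Requires a passing calibration unless ``override`` is set.
    """
    cfg = config or CalibrationConfig()
    if cal.qc is not None and not cal.qc.passed and not override:
        raise CalibrationError(
            "qc", "calibration did not pass QC; repeat it or pass override=True"
        )
    if m.pair not in cal.background:
        raise CalibrationError("background", f"no background for channel pair {m.pair}")
    return _process_spectrum(m.dark_subtracted(), m.pair, cal, cfg)


def qc_evaluate(
    history: Sequence[CalibrationSet],
    current: CalibrationSet,
    config: CalibrationConfig | None = None,
) -> QCReport:
    """Stability metrics of the current calibration against its history.

    Per phantom: pointwise SD across history + current and the mean absolute
    deviation of the current spectrum from the history mean, both in
    white-standard units.  Plus the wavelength-shift magnitude/drift and the
    negative-value fraction of the processed references.  ``passed`` is True
    iff every metric sits inside its configured tolerance.
    """
    cfg = config or CalibrationConfig()
    report = QCReport(passed=True, wavelength_shift=current.wavelength_shift)
    history = list(history)
    if not history:
        report.flags.append("baseline")

    if abs(current.wavelength_shift) > cfg.shift_limit:
        report.failures.append(
            f"wavelength shift {current.wavelength_shift:+.3f} nm exceeds "
            f"limit {cfg.shift_limit} nm"
        )
        report.failed_step = report.failed_step or "wavelength"
    report.shift_history = [h.wavelength_shift for h in history]

    for ph, ref in current.phantom_refs.items():
        ok = ~ref.mask
        nf = negative_fraction(ref)
        report.negative_fractions[ph] = nf
        if nf > cfg.negative_fraction_limit:
            report.failures.append(
                f"phantom {ph!r}: {nf:.1%} of points negative after processing"
            )
            report.failed_step = report.failed_step or "phantom"
        past = [h.phantom_refs[ph] for h in history if ph in h.phantom_refs]
        stack = np.stack([p.values for p in past] + [ref.values])
        if stack.shape[0] > 1:
            sd = float(stack.std(axis=0, ddof=1)[ok].mean())
            report.phantom_sd[ph] = sd
            if sd > cfg.phantom_sd_limit:
                report.failures.append(
                    f"phantom {ph!r}: pointwise SD {sd:.4f} exceeds "
                    f"limit {cfg.phantom_sd_limit}"
                )
                report.failed_step = report.failed_step or "phantom"
        if past:
            hist_mean = np.stack([p.values for p in past]).mean(axis=0)
            mad = float(np.abs(ref.values - hist_mean)[ok].mean())
            report.phantom_deviation[ph] = mad
            if mad > cfg.phantom_mad_limit:
                report.failures.append(
                    f"phantom {ph!r}: deviates {mad:.4f} from calibration history "
                    f"(limit {cfg.phantom_mad_limit})"
                )
                report.failed_step = report.failed_step or "phantom"

    if report.failures:
        report.passed = False
        report.prompt_repeat = True
    return report


# ---------------------------------------------------------------------------
# archive I/O (plain-text CSVs + a JSON manifest)
# ---------------------------------------------------------------------------

def _pair_key(pair: ChannelPair) -> str:
    return f"{pair[0]}-{pair[1]}"


def save_calibration_set(cal: CalibrationSet, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    manifest: dict = {
        "wavelength_shift_nm": cal.wavelength_shift,
        "shift_residuals": {f"{k:.3f}": v for k, v in cal.shift_residuals.items()},
        "background": {},
        "white": {},
        "flatfield": {},
        "phantom_refs": {},
        "qc": None,
    }
    for pair, s in cal.background.items():
        fn = f"background_{_pair_key(pair)}.csv"
        write_spectrum_csv(s, os.path.join(path, fn))
        manifest["background"][_pair_key(pair)] = fn
    for pair, s in cal.white.items():
        fn = f"white_{_pair_key(pair)}.csv"
        write_spectrum_csv(s, os.path.join(path, fn))
        manifest["white"][_pair_key(pair)] = fn
    for fiber, s in cal.flatfield.items():
        fn = f"flatfield_{fiber}.csv"
        write_spectrum_csv(s, os.path.join(path, fn))
        manifest["flatfield"][str(fiber)] = fn
    for ph, s in cal.phantom_refs.items():
        fn = f"phantom_{ph}.csv"
        write_spectrum_csv(s, os.path.join(path, fn))
        manifest["phantom_refs"][ph] = fn
    if cal.qc is not None:
        manifest["qc"] = {
            "passed": cal.qc.passed,
            "failed_step": cal.qc.failed_step,
            "failures": cal.qc.failures,
            "flags": cal.qc.flags,
            "prompt_repeat": cal.qc.prompt_repeat,
            "phantom_sd": cal.qc.phantom_sd,
            "phantom_deviation": cal.qc.phantom_deviation,
            "negative_fractions": cal.qc.negative_fractions,
            "wavelength_shift": cal.qc.wavelength_shift,
            "shift_history": cal.qc.shift_history,
        }
    with open(os.path.join(path, "calibration.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_calibration_set(path: str) -> CalibrationSet:
    with open(os.path.join(path, "calibration.json")) as fh:
        manifest = json.load(fh)

    def unpair(key: str) -> ChannelPair:
        a, b = key.split("-")
        return (int(a), int(b))

    cal = CalibrationSet(
        background={
            unpair(k): read_spectrum_csv(os.path.join(path, fn))
            for k, fn in manifest["background"].items()
        },
        white={
            unpair(k): read_spectrum_csv(os.path.join(path, fn))
            for k, fn in manifest["white"].items()
        },
        flatfield={
            int(k): read_spectrum_csv(os.path.join(path, fn))
            for k, fn in manifest["flatfield"].items()
        },
        wavelength_shift=float(manifest["wavelength_shift_nm"]),
        shift_residuals={float(k): v for k, v in manifest["shift_residuals"].items()},
        phantom_refs={
            ph: read_spectrum_csv(os.path.join(path, fn))
            for ph, fn in manifest["phantom_refs"].items()
        },
    )
    if manifest.get("qc"):
        q = manifest["qc"]
        cal.qc = QCReport(
            passed=q["passed"],
            failed_step=q["failed_step"],
            failures=q["failures"],
            flags=q["flags"],
            prompt_repeat=q["prompt_repeat"],
            phantom_sd=q["phantom_sd"],
            phantom_deviation=q["phantom_deviation"],
            negative_fractions=q["negative_fractions"],
            wavelength_shift=q["wavelength_shift"],
            shift_history=q["shift_history"],
        )
    return cal
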