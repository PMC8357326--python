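"""Synthetic forward model of the fiber-probe spectroscopy instrument.

The detector signal for an illumination/collection fiber pair is modelled as

    S_measured(lam) = L(lam) * [ B(lam) + T_ill(lam) * T_coll(lam) * S_sample(lam) ]

where ``L`` is the lamp spectrum, ``B`` the internal-reflection background
fraction of the probe, and ``T_ill``/``T_coll`` the throughput (optical
transfer function, OTF) of the illumination and collection fibers.  On top of
this deterministic core the simulator layers the nuisance processes a real
clinical instrument exhibits:

* **bias** — a detector offset per readout, drifting linearly in time
  (non-temperature-controlled detectors);
* **read noise** — i.i.d. Gaussian counts per pixel per frame;
* **external light** — room light entering the probe, present in both the
  signal frame and its shutter-closed dark frame;
* **speckle** — a multiplicative, unit-mean, spectrally correlated field for
  solid samples under partially coherent illumination.  The field is frozen
  for a fixed probe/sample location and independent across locations, which
  is exactly what makes ensemble averaging over stage positions effective.
* **fiber bending** — scheduled multiplicative perturbations of per-fiber
  OTFs (endoscopic bending changes throughput by more than 1.5 %).

Every random draw derives from ``rng_seed`` through named sub-streams, so
any simulated measurement is exactly reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .measurement import RawMeasurement
from .spectra import Spectrum, WavelengthGrid, default_grid

__all__ = [
    "InstrumentModel",
    "Sample",
    "BendingSchedule",
    "BendingEvent",
    "ContactSegment",
    "hgar_reference_lines",
    "hgar_line_spectrum",
    "speckle_field",
    "simulate_measurement",
    "simulate_hgar",
    "apply_bending",
    "simulate_contact_trace",
    "default_model",
    "noise_free",
    "hgar_sample",
    "white_standard_sample",
    "phantom_sample",
    "tissue_sample",
    "background_sample",
    "flatfield_fixture_radiance",
]

# named RNG sub-streams
_STREAM_SPECKLE = 1
_STREAM_NOISE = 2
_STREAM_TRACE = 3

SAMPLE_KINDS = (
    "white_standard",
    "phantom",
    "tissue",
    "hgar_lamp",
    "ideal_background",
    "flatfield",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    """A sample presented to the probe.

    ``reflectance`` is the intrinsic spectral response (dimensionless, >= 0);
    for emissive kinds (``hgar_lamp``, ``flatfield``) it is instead the source
    radiance in counts/s reaching the probe face, bypassing the lamp and
    illumination path.  ``region_map`` optionally provides distinct responses
    (S_alpha, S_beta) for the short- and long-separation tissue regions of a
    symmetric probe; solid samples (``is_solid``) acquire speckle.
    """

    kind: str
    reflectance: Spectrum
    region_map: tuple[Spectrum, Spectrum] | None = None
    is_solid: bool = False
    background_excess: float = 1.0  # fixture return relative to an ideal background

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.background_excess <= 0:
            raise ValueError("background_excess must be positive")


@dataclass(frozen=True)
class BendingEvent:
    time: float           # s
    fiber: int
    factor: object        # positive scalar or Spectrum

    def factor_values(self, grid: WavelengthGrid) -> np.ndarray:
        if isinstance(self.factor, Spectrum):
            if self.factor.grid != grid:
                raise ValueError("bending factor spectrum on wrong grid")
            vals = self.factor.values
        else:
            vals = np.full(len(grid), float(self.factor))
        if np.any(vals <= 0):
            raise ValueError("bending factors must be strictly positive")
        return vals


@dataclass
class BendingSchedule:
    """Timeline of multiplicative per-fiber OTF perturbations."""

    events: list[BendingEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if not isinstance(ev.factor, Spectrum) and float(ev.factor) <= 0:
                raise ValueError("bending factors must be strictly positive")

    def active_events(self, t: float) -> list[BendingEvent]:
        return [ev for ev in self.events if ev.time <= t]


@dataclass
class InstrumentModel:
    """Ground-truth instrument state; see module docstring for the signal model."""

    lamp: Spectrum                              # L, counts/s scale
    illumination_otf: dict[int, Spectrum]       # fiber id -> T_ill in (0, 1]
    collection_otf: dict[int, Spectrum]         # fiber id -> T_coll in (0, 1]
    background: Spectrum                        # B, dimensionless fraction
    bias_level: float = 120.0                   # counts per readout
    bias_drift_rate: float = 0.05               # counts/s of session time
    read_noise_sd: float = 5.0                  # counts rms per pixel per frame
    external_light: Spectrum | None = None      # counts/s entering the probe
    speckle_contrast: float = 0.02              # relative SD of the speckle field
    speckle_corr_length: float = 2.0            # nm, spectral autocorrelation length
    resolution_fwhm: float = 0.25               # nm, spectrometer line width
    rng_seed: int = 0

    def __post_init__(self) -> None:
        grid = self.lamp.grid
        for name, s in [("background", self.background)] + [
            (f"illumination_otf[{k}]", v) for k, v in self.illumination_otf.items()
        ] + [(f"collection_otf[{k}]", v) for k, v in self.collection_otf.items()]:
            if s.grid != grid:
                raise ValueError(f"{name} is not on the lamp grid")
        for k, v in {**self.illumination_otf, **self.collection_otf}.items():
            if np.any(v.values <= 0):
                raise ValueError(f"OTF of fiber {k} must be strictly positive")
        if not (0 <= self.speckle_contrast < 1):
            raise ValueError("speckle_contrast must be in [0, 1)")
        if self.external_light is None:
            self.external_light = Spectrum(
                grid, np.zeros(len(grid)), "counts_per_s"
            )
        elif self.external_light.grid != grid:
            raise ValueError("external_light is not on the lamp grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.lamp.grid

    def bias(self, t: float) -> float:
        return self.bias_level + self.bias_drift_rate * t

    def copy(self) -> "InstrumentModel":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class ContactSegment:
    """One phase of a probe approach/contact trace."""

    duration: float   # s
    mean: float       # normalized intensity (white standard = 1)
    jitter: float     # relative, uniform +/- jitter


# ---------------------------------------------------------------------------
# Hg–Ar reference lines
# ---------------------------------------------------------------------------

def hgar_reference_lines(with_intensities: bool = False):
    """Reference Hg–Ar emission-line wavelengths (nm), from the bundled table."""
    wl: list[float] = []
    inten: list[float] = []
    text = resources.files("fiberspec.data").joinpath("hgar_lines.csv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("wavelength"):
            continue
        a, b = line.split(",")
        wl.append(float(a))
        inten.append(float(b))
    if with_intensities:
        return np.asarray(wl), np.asarray(inten)
    return np.asarray(wl)


def hgar_line_spectrum(
    grid: WavelengthGrid,
    shift: float = 0.0,
    fwhm: float = 0.25,
    peak_rate: float = 2.0e5,
) -> Spectrum:
    """Emission-line spectrum: Gaussian lines of width ``fwhm`` at the
    reference wavelengths displaced by ``shift`` (counts/s)."""
    lines, inten = hgar_reference_lines(with_intensities=True)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lam = grid.wavelengths
    vals = np.zeros(len(grid))
    for c, a in zip(lines + shift, inten):
        vals += a * peak_rate * np.exp(-0.5 * ((lam - c) / sigma) ** 2)
    return Spectrum(grid, vals, "counts_per_s")


# ---------------------------------------------------------------------------
# stochastic fields
# ---------------------------------------------------------------------------

_KEY_MASK = (1 << 63) - 1


def _rng(model: InstrumentModel, stream: int, *keys: int) -> np.random.Generator:
    # keys may be negative (emissive frames use illum fiber -1): mask to non-negative
    entropy = [int(model.rng_seed) & _KEY_MASK, stream] + [int(k) & _KEY_MASK for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def speckle_field(model: InstrumentModel, location: int) -> np.ndarray:
    """Multiplicative speckle realisation for a probe location.

    Stationary log-normal field over wavelength with unit mean, pointwise SD
    equal to ``speckle_contrast`` and Gaussian autocorrelation of length
    ``speckle_corr_length``.  Deterministic in (seed, location): repeated
    accumulations at one location see the identical field, distinct locations
    see independent fields.
    """
    n = len(model.grid)
    c = model.speckle_contrast
    if c == 0:
        return np.ones(n)
    spacing = float(np.median(np.diff(model.grid.wavelengths)))
    # kernel sigma such that the field autocorrelation is exp(-d^2 / (2 ell^2))
    s_samp = max(model.speckle_corr_length / np.sqrt(2.0) / spacing, 1e-6)
    half = max(int(np.ceil(6 * s_samp)), 1)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / s_samp) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))  # unit variance after filtering white noise
    rng = _rng(model, _STREAM_SPECKLE, location)
    white = rng.standard_normal(n + 2 * half)
    g = np.convolve(white, kernel, mode="valid")  # length n, unit variance
    sigma_ln = np.sqrt(np.log1p(c * c))
    return np.exp(sigma_ln * g - 0.5 * sigma_ln**2)


def _select_region(sample: Sample, illum: int, collect: int) -> Spectrum:
    """Which intrinsic response a given channel pair samples.

    For the symmetric four-fiber probe the short source–detector separations
    (|illum − collect| smaller) see S_alpha, the long ones S_beta.
    """
    if sample.region_map is None:
        return sample.reflectance
    s_alpha, s_beta = sample.region_map
    return s_alpha if abs(illum - collect) <= 1 else s_beta


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_measurement(
    model: InstrumentModel,
    illum_fiber: int,
    collect_fiber: int,
    sample: Sample,
    t: float = 0.0,
    location: int = 0,
    accumulation: float = 0.5,
) -> RawMeasurement:
    """Simulate one acquisition: signal frame plus paired shutter-closed dark.

    Deterministic in (seed, t, location, fiber pair, accumulation): two calls
    with identical arguments return identical counts.
    """
    if not accumulation > 0:
        raise ValueError("accumulation must be positive")
    grid = model.grid
    n = len(grid)
    emissive = sample.kind in ("hgar_lamp", "flatfield")

    if emissive:
        if collect_fiber not in model.collection_otf:
            raise KeyError(f"unknown collection fiber {collect_fiber}")
        t_coll = model.collection_otf[collect_fiber].values
        rate = sample.reflectance.values * t_coll
    else:
        if illum_fiber not in model.illumination_otf:
            raise KeyError(f"unknown illumination fiber {illum_fiber}")
        if collect_fiber not in model.collection_otf:
            raise KeyError(f"unknown collection fiber {collect_fiber}")
        t_ill = model.illumination_otf[illum_fiber].values
        t_coll = model.collection_otf[collect_fiber].values
        if sample.kind == "ideal_background":
            rate = model.lamp.values * model.background.values * sample.background_excess
        else:
            s_eff = _select_region(sample, illum_fiber, collect_fiber).values
            rate = model.lamp.values * (
                model.background.values + t_ill * t_coll * s_eff
            )

    if sample.is_solid and model.speckle_contrast > 0:
        rate = rate * speckle_field(model, location)

    bias = model.bias(t)
    external = model.external_light.values * accumulation
    rng = _rng(
        model,
        _STREAM_NOISE,
        round(t * 1e6),
        location,
        illum_fiber,
        collect_fiber,
        round(accumulation * 1e6),
    )
    if model.read_noise_sd > 0:
        noise_sig = rng.normal(0.0, model.read_noise_sd, n)
        noise_dark = rng.normal(0.0, model.read_noise_sd, n)
    else:
        noise_sig = noise_dark = np.zeros(n)

    signal = Spectrum(grid, rate * accumulation + bias + external + noise_sig, "counts")
    dark = Spectrum(grid, bias + external + noise_dark, "counts")
    return RawMeasurement(
        signal=signal,
        dark=dark,
        illum_fiber=illum_fiber,
        collect_fiber=collect_fiber,
        time=t,
        location=location,
        accumulation=accumulation,
    )


def simulate_hgar(
    model: InstrumentModel,
    true_shift: float,
    collect_fiber: int | None = None,
    t: float = 0.0,
    accumulation: float = 0.25,
    peak_rate: float = 2.0e5,
) -> Spectrum:
    """Hg–Ar lamp frame with the wavelength axis mis-registered by ``true_shift`` nm.

    Returns the signal frame (bias and read noise included); pair it with a
    dark frame via :func:`simulate_measurement` and a ``hgar_lamp`` sample
    when the full raw-measurement contract is needed.
    """
    if abs(true_shift) >= 10:
        raise ValueError("|true_shift| must be < 10 nm")
    sample = hgar_sample(model.grid, true_shift, fwhm=model.resolution_fwhm, peak_rate=peak_rate)
    if collect_fiber is None:
        collect_fiber = next(iter(model.collection_otf))
    m = simulate_measurement(
        model, illum_fiber=-1, collect_fiber=collect_fiber,
        sample=sample, t=t, location=0, accumulation=accumulation,
    )
    return m.signal


def hgar_sample(
    grid: WavelengthGrid, shift: float = 0.0, fwhm: float = 0.25, peak_rate: float = 2.0e5
) -> Sample:
    return Sample(
        kind="hgar_lamp",
        reflectance=hgar_line_spectrum(grid, shift=shift, fwhm=fwhm, peak_rate=peak_rate),
        is_solid=False,
    )


def apply_bending(model: InstrumentModel, schedule: BendingSchedule, t: float) -> InstrumentModel:
    """Instrument state at time ``t``: all events with time <= t applied
    multiplicatively to the named fiber's OTFs.  The input model is untouched."""
    out = model.copy()
    for ev in schedule.active_events(t):
        vals = ev.factor_values(model.grid)
        touched = False
        if ev.fiber in out.illumination_otf:
            s = out.illumination_otf[ev.fiber]
            out.illumination_otf[ev.fiber] = s.with_values(s.values * vals)
            touched = True
        if ev.fiber in out.collection_otf:
            s = out.collection_otf[ev.fiber]
            out.collection_otf[ev.fiber] = s.with_values(s.values * vals)
            touched = True
        if not touched:
            raise KeyError(f"bending event names unknown fiber {ev.fiber}")
    return out


def simulate_contact_trace(
    segments: Sequence[ContactSegment],
    tick: float = 0.010,
    seed: int = 0,
) -> np.ndarray:
    """Normalized monitor-intensity trace, one value per tick (default 10 ms).

    Each segment emits ``round(duration / tick)`` samples of
    ``mean * (1 + jitter * U(-1, 1))``; a segment with jitter j therefore has
    worst-case relative range 2j, so a 1 % jitter stable contact always sits
    inside a 3 % stability window while a 5 % slide generally does not.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_TRACE]))
    parts = []
    for seg in segments:
        n = int(round(seg.duration / tick))
        if n <= 0:
            continue
        u = rng.uniform(-1.0, 1.0, n)
        parts.append(seg.mean * (1.0 + seg.jitter * u))
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# default instrument and samples
# ---------------------------------------------------------------------------

def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def default_model(
    grid: WavelengthGrid | None = None,
    seed: int = 0,
    *,
    speckle_contrast: float = 0.02,
    read_noise_sd: float = 5.0,
    bias_level: float = 120.0,
    bias_drift_rate: float = 0.05,
    external_level: float = 10.0,
    n_fibers: int = 4,
) -> InstrumentModel:
    """A realistic default instrument on the standard grid.

    Fibers 1 and 4 illuminate, 2 and 3 collect (the symmetric linear array).
    The lamp is a smooth broadband curve (two wide Gaussians peaking near 480
    and 650 nm, xenon-like); per-fiber OTFs are smooth, distinct and strictly
    inside (0, 1]; the internal-reflection background is a small decaying
    fraction of the lamp.
    """
    if grid is None:
        grid = default_grid()
    lam = grid.wavelengths
    lamp = Spectrum(
        grid,
        2.0e5 * (0.9 * _gauss(lam, 480.0, 80.0) + 1.0 * _gauss(lam, 650.0, 100.0)) + 1.0e4,
        "counts_per_s",
    )
    x = (lam - 600.0) / 400.0
    illum = {
        1: Spectrum(grid, 0.60 * (1.0 + 0.08 * x - 0.05 * x * x), "dimensionless"),
        4: Spectrum(grid, 0.55 * (1.0 - 0.06 * x + 0.04 * x * x), "dimensionless"),
    }
    coll = {
        2: Spectrum(grid, 0.50 * (1.0 + 0.10 * x), "dimensionless"),
        3: Spectrum(grid, 0.45 * (1.0 - 0.07 * x), "dimensionless"),
    }
    if n_fibers != 4:
        raise ValueError("default_model builds the 4-fiber symmetric probe")
    background = Spectrum(grid, 0.008 * (1.0 + 0.5 * np.exp(-(lam - 400.0) / 120.0)), "dimensionless")
    external = Spectrum(grid, np.full(len(grid), float(external_level)), "counts_per_s")
    return InstrumentModel(
        lamp=lamp,
        illumination_otf=illum,
        collection_otf=coll,
        background=background,
        bias_level=bias_level,
        bias_drift_rate=bias_drift_rate,
        read_noise_sd=read_noise_sd,
        external_light=external,
        speckle_contrast=speckle_contrast,
        rng_seed=seed,
    )


def noise_free(model: InstrumentModel) -> InstrumentModel:
    """Copy of ``model`` with read noise and speckle disabled.

    Bias, drift and external light may stay on: they cancel exactly in the
    paired dark subtraction.
    """
    out = model.copy()
    out.read_noise_sd = 0.0
    out.speckle_contrast = 0.0
    return out


def white_standard_sample(grid: WavelengthGrid) -> Sample:
    """The 99 %-reflective Spectralon standard: flat, solid (speckles)."""
    return Sample(
        kind="white_standard",
        reflectance=Spectrum(grid, np.full(len(grid), 0.99), "dimensionless"),
        is_solid=True,
    )


def phantom_sample(grid: WavelengthGrid, which: str = "a") -> Sample:
    """Two solid scattering phantoms with power-law reflectance spectra."""
    lam = grid.wavelengths
    if which == "a":
        vals = 0.60 * (lam / 600.0) ** -0.4
    elif which == "b":
        vals = 0.35 * (lam / 600.0) ** -1.2
    else:
        raise ValueError("phantom id must be 'a' or 'b'")
    return Sample(kind="phantom", reflectance=Spectrum(grid, vals, "dimensionless"), is_solid=True)


def tissue_sample(grid: WavelengthGrid, scale: float = 0.35) -> Sample:
    """Smooth mucosal-tissue-like reflectance with haemoglobin dips at 542/577 nm."""
    lam = grid.wavelengths
    base = (lam / 600.0) ** 0.8
    dips = 0.35 * _gauss(lam, 542.0, 9.0) + 0.30 * _gauss(lam, 577.0, 8.0)
    vals = scale * base * (1.0 - dips)
    return Sample(kind="tissue", reflectance=Spectrum(grid, vals, "dimensionless"), is_solid=False)


def background_sample(grid: WavelengthGrid, excess: float = 1.03) -> Sample:
    """The cone background fixture: returns ``excess`` x the ideal background
    (the physical fixture measures a few percent above ideal)."""
    return Sample(
        kind="ideal_background",
        reflectance=Spectrum(grid, np.zeros(len(grid)), "dimensionless"),
        is_solid=False,
        background_excess=excess,
    )


def flatfield_fixture_radiance(grid: WavelengthGrid, level: float = 5.0e4) -> Sample:
    """The transmission flat-field fixture: probe lamp off, a smooth external
    source delivering equal radiance to every collection channel."""
    lam = grid.wavelengths
    vals = level * (0.8 + 0.4 * _gauss(lam, 580.0, 150.0))
    return Sample(kind="flatfield", reflectance=Spectrum(grid, vals, "counts_per_s"), is_solid=False)
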