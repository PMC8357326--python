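# Methods

## The instrument model

All processing in this package inverts one multiplicative signal model for a
fiber-probe reflectance spectrometer.  For an illumination fiber *i* and a
collection fiber *c*, the detector records

    S_measured(λ) = L(λ) · [ B(λ) + T_i(λ) · T_c(λ) · S_sample(λ) ]

where `L` is the lamp spectrum, `B` the probe's internal-reflection
background (a small dimensionless fraction of the lamp), `T_i`/`T_c` the
throughputs (optical transfer functions, OTFs) of the two fibers, and
`S_sample` the intrinsic sample reflectance to be isolated.  On top of this
deterministic core the simulator (`fiberspec.simulate`) layers the nuisance
processes a clinical instrument exhibits; each is also the subject of one
calibration stage:

| process | model | default | removed by |
|---|---|---|---|
| detector bias | offset per readout, linear drift in time | 120 counts + 0.05 counts/s | paired shutter-closed dark frame |
| external room light | additive counts/s, present in signal and dark | 10 counts/s | paired dark frame |
| read noise | i.i.d. Gaussian counts per pixel per frame | 5 counts rms | averaging |
| internal reflections | `L·B` | `B` ≈ 0.8–1.2 % | background-fixture measurement |
| lamp shape, fiber OTFs | smooth multiplicative spectra | see `default_model` | flat-field + white-standard normalisation |
| speckle | multiplicative unit-mean field, frozen per probe location | contrast 0.02 | ensemble averaging over stage locations |
| fiber bending | scheduled multiplicative OTF factors | — | real-time four-frame correction |

Because the dark frame shares the signal frame's acquisition time and
accumulation, bias, drift and external light cancel *exactly* in the
subtraction; "noise off" in the exactness tests therefore means read noise
and speckle disabled (and the background fixture set ideal) — bias and room
light may stay on.

All randomness flows from a single integer seed through named sub-streams
(speckle keyed by location, frame noise keyed by time/location/fiber pair,
contact traces), so every simulated measurement is bit-reproducible.

## Speckle model and the ×20 variance ratio

Partially coherent illumination of a solid standard produces a speckle
pattern that is frozen for a fixed probe/sample position and independent
across positions.  The simulator realises this as a stationary log-normal
field over wavelength with unit mean, pointwise relative SD equal to the
speckle *contrast*, and Gaussian autocorrelation of length 2 nm.  Averaging
n accumulations at one location keeps the frozen pattern (variance unchanged);
averaging over n distinct stage locations suppresses it by 1/n.  The
fixed/moving variance ratio of a 20-accumulation average is therefore 20,
independent of the contrast — which is why the acceptance script reports that
ratio rather than an absolute noise amplitude.  The source system's contrast
is not known; 0.02 is used as a realistic value for a broadband arc lamp that
gains only weak spatial coherence in a 9-mm glass spacer.  Every asserted
speckle quantity (the ×20 ratio, 1/n scaling) is contrast-independent.

## Calibration pipeline

`run_calibration_sequence` executes, in order: dark subtraction of every
frame (normalised to counts/s, since accumulations of 250–1000 ms are mixed)
→ background extraction per channel pair → flat-field per collection fiber
(**bias-subtracted only**: the probe lamp is off during flat-field, so there
is no background to remove) → speckle-averaged, background-subtracted white
standard → Hg–Ar wavelength-shift estimation → phantom processing → QC.
`process_sample` then computes

    R = [ (S − dark)/t − background ] / flatfield / ( white / flatfield )

a dimensionless reflectance relative to the 99 % Spectralon standard.  The
order is load-bearing: white normalisation does not commute with background
subtraction when `B ≠ 0` (a regression test guards this).  With read noise
and speckle off the pipeline is the exact algebraic inverse of the signal
model (round trip ≤ 1e−9); at default noise with 20-location averaging a
phantom is recovered within 1 % RMS.

Negative values after subtraction are retained, never clamped (clamping
would bias ensemble averages); a QC flag fires if more than 5 % of processed
points are negative.

## Wavelength registration

The shift estimator detects local maxima in a dark-subtracted Hg–Ar frame,
matches each to the nearest reference line within ±3 nm, and refines each
centroid with a three-point parabola on the **log** of the
baseline-subtracted counts — exact for a Gaussian line of any width, whereas
a parabola on raw counts is badly biased once the line width approaches the
pixel pitch.  The global shift is the median residual (robust to one
mismatched line when two lines sit closer together than the shift).
Measured accuracy is well inside the 0.05-nm contract for shifts in ±3 nm at
default noise, on the standard 0.25-nm working grid.

Correction relabels the wavelength axis by −shift and linearly resamples to
the standard grid (edge-hold for the ≤ shift-wide sliver at the ends).  Two
numerical points:

* In `process_sample` the correction is applied only when |shift| exceeds
  0.05 nm (the estimator's accuracy bound); below that, resampling would add
  interpolation error without information.
* The line-subtraction *artifact demonstration* is run on a 0.05-nm
  detector-pixel grid (5 pixels per 0.25-nm optical FWHM).  At 1 pixel per
  FWHM a narrow line cannot be relocated by any interpolation scheme —
  that is precisely why mis-registration artifacts are dangerous.  On the
  properly sampled grid the correction shrinks the artifact ≥ 38× for
  arbitrary shifts in ±3 nm.  Broadband tissue spectra are smooth at 0.25 nm,
  so the working grid needs no refinement.

## Real-time flat-field correction

For a symmetric probe (two illumination fibers at mirrored distances from
two collection fibers), illuminating the outer fibers sequentially yields
four measurements in which the collection fibers swap tissue regions.  After
per-pair background subtraction, the product ratio
`(S21·S34)/(S24·S31)` cancels the lamp and every per-fiber OTF exactly,
leaving `(S_α/S_β)²`; the default `sqrt` mode returns `S_α/S_β`, the named
ratio of intrinsic responses, and `literal` mode returns the raw product
ratio (its square) for comparability.  Exactness holds to ≤ 1e−12 under
arbitrary rescaling of any single fiber's OTF — verified by a 1000-draw
randomised property.

`stream_correct` flags *in-motion* cycles: an OTF change landing between a
cycle's two illumination frames breaks the cancellation for that cycle only.
Since the corrected output is OTF-invariant, such a cycle appears as an
isolated spike; the flag fires when the output jumps more than 0.5 %
(median relative change across the band — the median, not the max, so that
per-pixel read noise at the dim spectrum edges cannot trip it) and the next
cycle returns to the pre-jump level.  On the default bending scenario
(four static perturbations up to ±5 %) the corrected stream's RMS error,
excluding flagged cycles, is two orders of magnitude below the naive
short-separation / long-separation channel division, which retains a
persistent offset even after the probe is released.

## Contact-triggered acquisition

The monitor samples reflectance every 10 ms at one wavelength, normalised to
the white standard.  The machine is a four-phase automaton
(ARMED → CONTACT_CANDIDATE → MEASURING → AWAITING_REMOVAL) with declared
defaults: contact threshold 0.5, removal threshold 0.3, stability window 10
ticks, tolerance 3 %, full accumulation 500 ms.  "Variability" is the
relative range (max−min)/mean over the window — the strictest common
statistic and exactly computable online.  The window resets on any
violation (stability must be consecutive), the monitor stream is ignored
while the spectrometer integrates, and re-arming requires the intensity to
fall below the removal threshold, so trigger and removal events strictly
alternate — the operator is forced to fully retract the probe between
measurements.  On a clean step input the trigger latency is exactly the
window length.

## Synthetic data: what it does and does not cover

The simulator's defaults are chosen as a realistic clinical operating point:
xenon-like broadband lamp peaking near 480/650 nm, per-fiber OTFs in
0.4–0.66, background fixture returning 3 % above ideal, phantoms with
power-law scattering spectra, tissue with haemoglobin dips at 542/577 nm.
What it does **not** model: photon (shot) noise proportional to √signal,
stray light and detector non-linearity, wavelength-dependent speckle
contrast, spatial non-overlap of the fibers' tissue sampling volumes
(exposed as a knob via `Sample.region_map` but defaulting to identical
regions), and physical coherence theory.  Passing tests therefore
demonstrate the *algorithms* are correct inverses of the stated model with
realistic noise magnitudes — not that the model captures every artifact of a
physical instrument.

## Problem sizes

Defaults used by the test suite and the acceptance script: 1601-point
0.25-nm grid (16001 points for the fine-grid registration demo), 20 stage
locations per solid standard, 200 Monte-Carlo repetitions for variance
ratios, 25-cycle bending streams, 1000-draw exactness and state-machine
property checks.
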