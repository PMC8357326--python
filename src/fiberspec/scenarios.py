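"""Scenario builders: turn an instrument model into complete measurement sets.

These functions script the instrument simulator into the sequences the
hardware would produce — a full calibration run, a four-frame correction
stream under a bending schedule, a probe approach/contact/withdraw trace —
so every pipeline stage can be exercised end-to-end without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationMeasurements
from .flatfield import ProbeGeometry, SymmetricPairSet, default_geometry
from .measurement import ChannelPair, RawMeasurement
from .simulate import (
    BendingSchedule,
    ContactSegment,
    InstrumentModel,
    Sample,
    apply_bending,
    background_sample,
    flatfield_fixture_radiance,
    hgar_sample,
    phantom_sample,
    simulate_contact_trace,
    simulate_measurement,
    white_standard_sample,
)
from .spectra import Spectrum, divide

__all__ = [
    "default_pairs",
    "simulate_calibration_measurements",
    "simulate_pair_stream",
    "ground_truth_region_ratio",
    "contact_cycle_segments",
]

#: channel pairs of the default symmetric probe: illumination 1 and 4,
#: collection 2 and 3
DEFAULT_PAIRS: tuple[ChannelPair, ...] = ((1, 2), (1, 3), (4, 2), (4, 3))


def default_pairs() -> tuple[ChannelPair, ...]:
    return DEFAULT_PAIRS


def simulate_calibration_measurements(
    model: InstrumentModel,
    pairs: Sequence[ChannelPair] = DEFAULT_PAIRS,
    n_locations: int = 20,
    accumulation: float = 0.5,
    hgar_shift: float = 0.0,
    background_excess: float = 1.03,
    start_time: float = 0.0,
    frame_interval: float = 1.5,
) -> CalibrationMeasurements:
    """One full pass of the automated calibration tool.

    Per channel pair: a background-fixture frame, ``n_locations``
    white-standard frames at distinct stage positions, and ``n_locations``
    frames of each of the two scattering phantoms; per collection fiber one
    flat-field frame; plus one Hg–Ar frame with the wavelength axis
    mis-registered by ``hgar_shift``.  Time advances ``frame_interval``
    seconds per frame so bias drift behaves as in a real session.
    """
    grid = model.grid
    t = [start_time]

    def clock() -> float:
        t[0] += frame_interval
        return t[0]

    bg_sample = background_sample(grid, excess=background_excess)
    background = {
        pair: simulate_measurement(
            model, pair[0], pair[1], bg_sample, t=clock(), location=0,
            accumulation=accumulation,
        )
        for pair in pairs
    }

    ff_sample = flatfield_fixture_radiance(grid)
    flatfield = {
        fiber: simulate_measurement(
            model, -1, fiber, ff_sample, t=clock(), location=0,
            accumulation=accumulation,
        )
        for fiber in sorted({p[1] for p in pairs})
    }

    white = {
        pair: [
            simulate_measurement(
                model, pair[0], pair[1], white_standard_sample(grid),
                t=clock(), location=loc, accumulation=accumulation,
            )
            for loc in range(n_locations)
        ]
        for pair in pairs
    }

    hgar = simulate_measurement(
        model, -1, sorted({p[1] for p in pairs})[0],
        hgar_sample(grid, shift=hgar_shift, fwhm=model.resolution_fwhm),
        t=clock(), location=0, accumulation=0.25,
    )

    phantoms = {
        ph: {
            pair: [
                simulate_measurement(
                    model, pair[0], pair[1], phantom_sample(grid, ph),
                    t=clock(), location=100 + loc, accumulation=accumulation,
                )
                for loc in range(n_locations)
            ]
            for pair in pairs
        }
        for ph in ("a", "b")
    }

    return CalibrationMeasurements(
        background=background,
        white=white,
        flatfield=flatfield,
        hgar=hgar,
        phantoms=phantoms,
    )


def simulate_pair_stream(
    model: InstrumentModel,
    sample: Sample,
    schedule: BendingSchedule | None = None,
    n_sets: int = 20,
    start_time: float = 0.0,
    frame_interval: float = 0.3,
    accumulation: float = 0.25,
    location: int = 0,
    geometry: ProbeGeometry | None = None,
) -> list[SymmetricPairSet]:
    """A time-ordered stream of four-frame correction cycles.

    Set *k* acquires its illumination-1 frame at ``start_time + k*2*dt`` and
    its illumination-4 frame one ``frame_interval`` later; the bending
    schedule is applied at each frame time, so an event landing between a
    set's two frames produces the mid-cycle OTF change the stream corrector
    must flag.  The probe is held still against the sample (one location:
    the frozen speckle field cancels in the ratio like any other
    multiplicative throughput).
    """
    schedule = schedule or BendingSchedule()
    geometry = geometry or default_geometry()
    sets: list[SymmetricPairSet] = []
    for k in range(n_sets):
        t1 = start_time + k * 2.0 * frame_interval
        t4 = t1 + frame_interval
        m1 = apply_bending(model, schedule, t1)
        m4 = apply_bending(model, schedule, t4)
        s21 = simulate_measurement(m1, 1, 2, sample, t=t1, location=location, accumulation=accumulation)
        s31 = simulate_measurement(m1, 1, 3, sample, t=t1, location=location, accumulation=accumulation)
        s24 = simulate_measurement(m4, 4, 2, sample, t=t4, location=location, accumulation=accumulation)
        s34 = simulate_measurement(m4, 4, 3, sample, t=t4, location=location, accumulation=accumulation)
        sets.append(SymmetricPairSet(s21=s21, s31=s31, s24=s24, s34=s34, geometry=geometry))
    return sets


def ground_truth_region_ratio(sample: Sample, floor: float = 1e-12) -> Spectrum:
    """The true S_alpha / S_beta the corrected stream should recover."""
    if sample.region_map is None:
        grid = sample.reflectance.grid
        return Spectrum(grid, np.ones(len(grid)), "dimensionless")
    s_alpha, s_beta = sample.region_map
    return divide(s_alpha, s_beta, floor=floor)


def contact_cycle_segments(
    n_cycles: int = 3,
    approach: float = 0.5,
    contact: float = 1.0,
    withdrawn: float = 0.3,
    contact_level: float = 0.8,
    approach_level: float = 0.1,
    contact_jitter: float = 0.01,
) -> list[ContactSegment]:
    """Segments for ``n_cycles`` approach → stable contact → withdraw cycles."""
    segs: list[ContactSegment] = []
    for _ in range(n_cycles):
        segs.append(ContactSegment(approach, approach_level, 0.2))
        segs.append(ContactSegment(contact, contact_level, contact_jitter))
        segs.append(ContactSegment(withdrawn, approach_level, 0.2))
    return segs
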