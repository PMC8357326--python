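"""Contact-triggered in-vivo acquisition state machine.

The probe's reflectance at a single monitor wavelength is sampled every
10 ms and normalised to the white-standard signal in real time.  A full
spectral measurement fires only once the probe makes *stable* tissue
contact: the normalised intensity must exceed the contact threshold and
stay within a small relative range (<3 % by default) for a configured
number of consecutive ticks.  After the measurement the machine waits for
the intensity to drop below a lower removal threshold — the operator must
fully retract the probe — before it re-arms.  This removes user technique
(pressure, timing, sliding) from the measurement and guarantees that two
triggers are always separated by a probe withdrawal.

Phases::

    ARMED -> CONTACT_CANDIDATE -> MEASURING -> AWAITING_REMOVAL -> ARMED
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Event",
    "AcquisitionConfig",
    "AcquisitionState",
    "initial_state",
    "step",
    "run",
]


class Phase(enum.Enum):
    ARMED = "ARMED"
    CONTACT_CANDIDATE = "CONTACT_CANDIDATE"
    MEASURING = "MEASURING"
    AWAITING_REMOVAL = "AWAITING_REMOVAL"


@dataclass(frozen=True)
class Event:
    tick: int
    name: str   # TRIGGER_MEASUREMENT | MEASUREMENT_COMPLETE | PROBE_REMOVED


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of the contact-sensing trigger.

    Thresholds are normalized intensities (white standard = 1); the paper's
    thresholds are user-defined, so the defaults here are declared choices.
    ``stability_tolerance`` is the relative range (max−min)/mean the window
    must stay within — the strictest common reading of "<3 % variability".
    """

    monitor_wavelength: float = 650.0     # nm
    tick: float = 0.010                   # s, monitor accumulation
    contact_threshold: float = 0.5
    removal_threshold: float = 0.3
    stability_window: int = 10            # consecutive ticks
    stability_tolerance: float = 0.03
    full_accumulation: float = 0.500      # s

    def __post_init__(self) -> None:
        if not self.removal_threshold < self.contact_threshold:
            raise ValueError("removal_threshold must be below contact_threshold")
        if self.stability_window < 2:
            raise ValueError("stability_window must be at least 2")
        if not self.stability_tolerance > 0:
            raise ValueError("stability_tolerance must be positive")

    @property
    def measuring_ticks(self) -> int:
        return max(int(np.ceil(self.full_accumulation / self.tick)), 1)


@dataclass(frozen=True)
class AcquisitionState:
    """Immutable machine state; transitions happen only through :func:`step`."""

    phase: Phase = Phase.ARMED
    window: tuple[float, ...] = ()
    tick: int = 0
    measuring_remaining: int = 0
    n_triggers: int = 0
    n_removals: int = 0


def initial_state() -> AcquisitionState:
    return AcquisitionState()


def _window_stable(window: Sequence[float], tol: float) -> bool:
    w = np.asarray(window)
    mean = w.mean()
    if mean <= 0:
        return False
    return float((w.max() - w.min()) / mean) <= tol


def step(
    state: AcquisitionState, intensity: float, config: AcquisitionConfig
) -> tuple[AcquisitionState, list[Event]]:
    """Advance the machine by one monitor tick.

    All intensities are legal inputs; the machine never raises.  The
    stability window *resets* on any violation (a value at or below the
    contact threshold, or a window whose relative range exceeds tolerance):
    stability must hold for consecutive ticks, a sliding pass is not enough.
    On a clean step input the trigger therefore fires exactly
    ``stability_window`` ticks after the threshold crossing.
    """
    if intensity < 0:
        raise ValueError("monitor intensity must be non-negative")
    events: list[Event] = []
    tick = state.tick
    phase = state.phase
    window = state.window
    measuring_remaining = state.measuring_remaining
    n_triggers = state.n_triggers
    n_removals = state.n_removals

    if phase is Phase.ARMED:
        if intensity > config.contact_threshold:
            phase = Phase.CONTACT_CANDIDATE
            window = ()

    elif phase is Phase.CONTACT_CANDIDATE:
        if intensity <= config.contact_threshold:
            phase = Phase.ARMED
            window = ()
        else:
            window = window + (float(intensity),)
            if len(window) >= config.stability_window:
                if _window_stable(window[-config.stability_window :], config.stability_tolerance):
                    events.append(Event(tick, "TRIGGER_MEASUREMENT"))
                    n_triggers += 1
                    phase = Phase.MEASURING
                    measuring_remaining = config.measuring_ticks
                    window = ()
                else:
                    window = ()  # reset: stability must be consecutive

    elif phase is Phase.MEASURING:
        # the spectrometer is integrating the full spectrum; the monitor
        # stream is ignored until the accumulation completes
        measuring_remaining -= 1
        if measuring_remaining <= 0:
            events.append(Event(tick, "MEASUREMENT_COMPLETE"))
            phase = Phase.AWAITING_REMOVAL

    elif phase is Phase.AWAITING_REMOVAL:
        if intensity < config.removal_threshold:
            events.append(Event(tick, "PROBE_REMOVED"))
            n_removals += 1
            phase = Phase.ARMED
            window = ()

    new_state = AcquisitionState(
        phase=phase,
        window=window,
        tick=tick + 1,
        measuring_remaining=measuring_remaining,
        n_triggers=n_triggers,
        n_removals=n_removals,
    )
    return new_state, events


def run(
    trace: Iterable[float], config: AcquisitionConfig | None = None
) -> tuple[list[Event], AcquisitionState]:
    """Fold :func:`step` over a monitor trace; returns (event log, final state).

    Guarantee: between any two TRIGGER_MEASUREMENT events there is exactly
    one PROBE_REMOVED event — the operator must retract the probe before the
    next measurement can fire.
    """
    cfg = config or AcquisitionConfig()
    state = initial_state()
    log: list[Event] = []
    for intensity in trace:
        state, events = step(state, float(intensity), cfg)
        log.extend(events)
    return log, state
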