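"""The raw acquisition unit: a signal frame paired with its shutter-closed dark frame.

Every acquisition — calibration or in-vivo — closes an in-line shutter
immediately after the signal frame and records a second frame of identical
accumulation time.  That dark frame contains detector bias, read noise and
any external room light, but no photons from the probe's own optical path,
so subtracting it removes all additive nuisance terms exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectra import Spectrum, subtract

__all__ = ["RawMeasurement", "ChannelPair"]

# (illumination fiber id, collection fiber id)
ChannelPair = tuple[int, int]


@dataclass
class RawMeasurement:
    """One channel-pair acquisition: signal + paired dark + metadata."""

    signal: Spectrum            # counts
    dark: Spectrum              # counts, shutter closed, same accumulation
    illum_fiber: int
    collect_fiber: int
    time: float = 0.0           # s since session start
    location: int = 0           # stage/probe location index (speckle realisation)
    accumulation: float = 0.5   # s

    def __post_init__(self) -> None:
        if self.signal.grid != self.dark.grid:
            raise ValueError("signal and dark frames must share one wavelength grid")
        if not self.accumulation > 0:
            raise ValueError("accumulation must be positive")

    @property
    def pair(self) -> ChannelPair:
        return (self.illum_fiber, self.collect_fiber)

    def dark_subtracted(self) -> Spectrum:
        """Signal − dark, normalised to counts per second.

        Normalising by accumulation lets measurements of different
        accumulation times (250–1000 ms are all in routine use) be combined.
        """
        d = subtract(self.signal, self.dark)
        return Spectrum(d.grid, d.values / self.accumulation, "counts_per_s", d.mask)
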