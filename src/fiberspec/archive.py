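"""On-disk session format: plain-text spectrum CSVs plus a JSON manifest.

A measurement directory holds every frame of a session (calibration set,
optional tissue four-frame streams, contact trace) as two-column CSVs, with
``manifest.json`` recording per frame the channel pair, acquisition time,
stage location, accumulation and the link to its paired dark frame.
Plain text keeps every byte of a clinical session inspectable.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np

from .calibration import CalibrationMeasurements
from .flatfield import SymmetricPairSet, default_geometry
from .measurement import ChannelPair, RawMeasurement
from .spectra import read_spectrum_csv, write_spectrum_csv

__all__ = [
    "save_raw_measurement",
    "load_raw_measurement",
    "save_measurements",
    "load_measurements",
    "save_pair_stream",
    "load_pair_stream",
    "save_trace_csv",
    "load_trace_csv",
]


def save_raw_measurement(m: RawMeasurement, directory: str, stem: str) -> dict:
    """Write signal/dark CSVs and return the manifest entry."""
    sig = f"{stem}_signal.csv"
    dark = f"{stem}_dark.csv"
    write_spectrum_csv(m.signal, os.path.join(directory, sig))
    write_spectrum_csv(m.dark, os.path.join(directory, dark))
    return {
        "signal": sig,
        "dark": dark,
        "illum_fiber": m.illum_fiber,
        "collect_fiber": m.collect_fiber,
        "time": m.time,
        "location": m.location,
        "accumulation": m.accumulation,
    }


def load_raw_measurement(entry: dict, directory: str) -> RawMeasurement:
    return RawMeasurement(
        signal=read_spectrum_csv(os.path.join(directory, entry["signal"])),
        dark=read_spectrum_csv(os.path.join(directory, entry["dark"])),
        illum_fiber=int(entry["illum_fiber"]),
        collect_fiber=int(entry["collect_fiber"]),
        time=float(entry["time"]),
        location=int(entry["location"]),
        accumulation=float(entry["accumulation"]),
    )


def _pair_key(pair: ChannelPair) -> str:
    return f"{pair[0]}-{pair[1]}"


def _unpair(key: str) -> ChannelPair:
    a, b = key.split("-")
    return (int(a), int(b))


def save_measurements(
    meas: CalibrationMeasurements, path: str, extra: dict | None = None
) -> dict:
    """Write a calibration measurement set; returns the manifest written."""
    os.makedirs(path, exist_ok=True)
    manifest: dict = {"background": {}, "flatfield": {}, "white": {}, "phantoms": {}}
    for pair, m in meas.background.items():
        manifest["background"][_pair_key(pair)] = save_raw_measurement(
            m, path, f"background_{_pair_key(pair)}"
        )
    for fiber, m in meas.flatfield.items():
        manifest["flatfield"][str(fiber)] = save_raw_measurement(
            m, path, f"flatfield_{fiber}"
        )
    for pair, frames in meas.white.items():
        manifest["white"][_pair_key(pair)] = [
            save_raw_measurement(m, path, f"white_{_pair_key(pair)}_{i:02d}")
            for i, m in enumerate(frames)
        ]
    if meas.hgar is not None:
        manifest["hgar"] = save_raw_measurement(meas.hgar, path, "hgar")
    for ph, per_pair in meas.phantoms.items():
        manifest["phantoms"][ph] = {
            _pair_key(pair): [
                save_raw_measurement(m, path, f"phantom_{ph}_{_pair_key(pair)}_{i:02d}")
                for i, m in enumerate(frames)
            ]
            for pair, frames in per_pair.items()
        }
    if extra:
        manifest.update(extra)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_measurements(path: str) -> tuple[CalibrationMeasurements, dict]:
    """Read a measurement directory back; returns (measurements, manifest)."""
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    meas = CalibrationMeasurements(
        background={
            _unpair(k): load_raw_measurement(e, path)
            for k, e in manifest.get("background", {}).items()
        },
        flatfield={
            int(k): load_raw_measurement(e, path)
            for k, e in manifest.get("flatfield", {}).items()
        },
        white={
            _unpair(k): [load_raw_measurement(e, path) for e in entries]
            for k, entries in manifest.get("white", {}).items()
        },
        hgar=(
            load_raw_measurement(manifest["hgar"], path)
            if "hgar" in manifest
            else None
        ),
        phantoms={
            ph: {
                _unpair(k): [load_raw_measurement(e, path) for e in entries]
                for k, entries in per_pair.items()
            }
            for ph, per_pair in manifest.get("phantoms", {}).items()
        },
    )
    return meas, manifest


def save_pair_stream(sets: Sequence[SymmetricPairSet], path: str, name: str = "stream") -> list[dict]:
    """Write a four-frame correction stream; returns its manifest entries."""
    os.makedirs(path, exist_ok=True)
    entries = []
    for k, p in enumerate(sets):
        entries.append(
            {
                label: save_raw_measurement(m, path, f"{name}_{k:03d}_{label}")
                for label, m in zip(("s21", "s31", "s24", "s34"), p.measurements)
            }
        )
    return entries


def load_pair_stream(entries: Sequence[dict], path: str) -> list[SymmetricPairSet]:
    return [
        SymmetricPairSet(
            s21=load_raw_measurement(e["s21"], path),
            s31=load_raw_measurement(e["s31"], path),
            s24=load_raw_measurement(e["s24"], path),
            s34=load_raw_measurement(e["s34"], path),
            geometry=default_geometry(),
        )
        for e in entries
    ]


def save_trace_csv(trace: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tick_index,intensity\n")
        for i, v in enumerate(trace):
            fh.write(f"{i},{v:.17g}\n")


def load_trace_csv(path: str) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("tick"):
                continue
            vals.append(float(line.split(",")[1]))
    return np.asarray(vals)
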