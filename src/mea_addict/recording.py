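"""Spike-list I/O and raw-trace spike detection for multiwell MEA recordings.

A recording session is one 15-minute acquisition of a whole multiwell plate
at one dose step of a cumulative-dosing experiment.  On disk a session is a
plain CSV spike list (``well,electrode,time_s``) plus a YAML sidecar carrying
per-well metadata (compound, concentration, unit, phase).  A tolerant reader
for vendor (Axion-style) spike-list CSV exports is provided for
interoperability.

The optional raw-voltage path mirrors the standard MEA acquisition chain:
zero-phase 200 Hz high-pass filtering, robust noise-floor estimation, and
two-sided ±k·sigma threshold crossing detection (default k = 5.3).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import signal

__all__ = [
    "BEFORE",
    "AFTER",
    "PHASES",
    "SpikeTrain",
    "RecordingMeta",
    "WellRecording",
    "PlateRecording",
    "RawTrace",
    "read_spike_list",
    "write_spike_list",
    "read_raw_h5",
    "highpass_filter",
    "estimate_noise_sigma",
    "detect_spikes",
]

BEFORE = "before_chronic"
AFTER = "after_chronic"
PHASES = (BEFORE, AFTER)


class SpikeListParseError(ValueError):
    """Raised when a spike-list file cannot be parsed."""


@dataclass
class SpikeTrain:
    """Spike times (seconds from recording start) of one electrode."""

    electrode_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def validate(self, duration: float) -> None:
        t = self.spike_times
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError(f"electrode {self.electrode_id}: spike times not strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > duration):
            raise ValueError(f"electrode {self.electrode_id}: spike times outside [0, {duration}]")


@dataclass
class RecordingMeta:
    """Per-well metadata for one recording session."""

    well_id: str
    compound: str = "unknown"
    concentration: float = 0.0
    unit: str = ""
    phase: str = BEFORE
    recording_duration: float = 900.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")

    @property
    def is_baseline(self) -> bool:
        """True for the pre-dose vehicle recording of a well (concentration 0)."""
        return self.concentration == 0.0


@dataclass
class WellRecording:
    """All spike trains of one well in one session, keyed by electrode."""

    meta: RecordingMeta
    trains: dict[str, SpikeTrain] = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains.values())

    @property
    def n_active_electrodes(self) -> int:
        return sum(1 for t in self.trains.values() if t.n_spikes > 0)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, electrode index) of all spikes, sorted by time."""
        ids = sorted(self.trains)
        if not ids:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate([self.trains[e].spike_times for e in ids])
        eidx = np.concatenate(
            [np.full(self.trains[e].n_spikes, i, dtype=int) for i, e in enumerate(ids)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], eidx[order]


@dataclass
class PlateRecording:
    """One recording session of a whole plate: wells keyed by well id."""

    plate_id: str
    wells: dict[str, WellRecording] = field(default_factory=dict)

    def add_well(self, well: WellRecording) -> None:
        if well.meta.well_id in self.wells:
            raise ValueError(f"duplicate well id {well.meta.well_id!r}")
        self.wells[well.meta.well_id] = well


@dataclass
class RawTrace:
    """A single-channel extracellular voltage trace in microvolts."""

    samples: np.ndarray
    sampling_rate: float = 12500.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


# ---------------------------------------------------------------------------
# spike-list files
# ---------------------------------------------------------------------------

_NATIVE_HEADER = ["well", "electrode", "time_s"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def _meta_from_sidecar(sidecar: Mapping, well_id: str, duration: float) -> RecordingMeta:
    info = sidecar.get("wells", {}).get(well_id)
    if info is None:
        raise ValueError(f"well {well_id!r} present in spike list but missing from sidecar")
    return RecordingMeta(
        well_id=well_id,
        compound=str(info.get("compound", "unknown")),
        concentration=float(info.get("concentration", 0.0)),
        unit=str(info.get("unit", "")),
        phase=str(info.get("phase", BEFORE)),
        recording_duration=duration,
    )


def read_spike_list(path: str | Path, dialect: str = "native") -> PlateRecording:
    """Read a spike-list CSV into a :class:`PlateRecording`.

    Parameters
    ----------
    path:
        CSV file.  For the native dialect a ``<stem>.meta.yaml`` sidecar next
        to the file, when present, supplies per-well metadata; without it
        wells receive placeholder metadata.
    dialect:
        ``"native"`` (``well,electrode,time_s`` header) or ``"axion_compat"``
        (vendor export: preamble lines are skipped until a header containing
        both "Time" and "Electrode"; well ids are parsed from electrode
        labels such as ``A1_12``).

    Spike times are sorted on read; metadata-only wells (listed in the
    sidecar but with no spikes) are returned as empty wells.
    """
    path = Path(path)
    if dialect not in ("native", "axion_compat"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "native":
        rows = _read_native_rows(path)
        sidecar = {}
        sc_path = _sidecar_path(path)
        if sc_path.exists():
            with open(sc_path) as fh:
                sidecar = yaml.safe_load(fh) or {}
    else:
        rows = _read_axion_rows(path)
        sidecar = {}

    duration = float(sidecar.get("recording_duration", 900.0))
    plate = PlateRecording(plate_id=str(sidecar.get("plate_id", path.stem)))

    by_well: dict[str, dict[str, list[float]]] = {}
    for well_id, electrode_id, t in rows:
        by_well.setdefault(well_id, {}).setdefault(electrode_id, []).append(t)

    well_ids = set(by_well)
    if sidecar:
        unknown = well_ids - set(sidecar.get("wells", {}))
        if unknown:
            raise ValueError(f"wells {sorted(unknown)} in spike list but not in sidecar")
        well_ids |= set(sidecar.get("wells", {}))

    for well_id in sorted(well_ids):
        if sidecar:
            meta = _meta_from_sidecar(sidecar, well_id, duration)
        else:
            meta = RecordingMeta(well_id=well_id, recording_duration=duration)
        trains = {
            eid: SpikeTrain(eid, np.sort(np.asarray(ts, dtype=float)))
            for eid, ts in sorted(by_well.get(well_id, {}).items())
        }
        if sidecar:
            roster = sidecar.get("wells", {}).get(well_id, {}).get("electrodes") or []
            for eid in roster:
                trains.setdefault(eid, SpikeTrain(eid, np.empty(0)))
        plate.add_well(WellRecording(meta=meta, trains=trains))
    return plate


def _read_native_rows(path: Path) -> list[tuple[str, str, float]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpikeListParseError(f"{path}: empty file, expected header {_NATIVE_HEADER}")
        if [h.strip() for h in header] != _NATIVE_HEADER:
            raise SpikeListParseError(f"{path}: line 1: expected header {_NATIVE_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise SpikeListParseError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            try:
                t = float(row[2])
            except ValueError:
                raise SpikeListParseError(f"{path}: line {lineno}: bad time value {row[2]!r}")
            rows.append((row[0].strip(), row[1].strip(), t))
    return rows


def _read_axion_rows(path: Path) -> list[tuple[str, str, float]]:
    """Tolerant reader for vendor spike-list exports.

    Skips any preamble until a comma-separated header line whose fields
    mention both "Time" and "Electrode", then reads (time, electrode) pairs;
    the well id is the electrode label up to the first underscore.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        t_col = e_col = None
        for lineno, row in enumerate(reader, start=1):
            if t_col is None:
                lowered = [c.strip().lower() for c in row]
                has_t = any("time" in c for c in lowered)
                has_e = any("electrode" in c for c in lowered)
                if has_t and has_e:
                    t_col = next(i for i, c in enumerate(lowered) if "time" in c)
                    e_col = next(i for i, c in enumerate(lowered) if "electrode" in c)
                continue
            if len(row) <= max(t_col, e_col) or not row[t_col].strip():
                continue
            try:
                t = float(row[t_col])
            except ValueError:
                raise SpikeListParseError(f"{path}: line {lineno}: bad time value {row[t_col]!r}")
            label = row[e_col].strip()
            well = label.split("_", 1)[0]
            rows.append((well, label, t))
        if t_col is None:
            raise SpikeListParseError(f"{path}: no header containing 'Time' and 'Electrode' found")
    return rows


def write_spike_list(plate: PlateRecording, path: str | Path) -> Path:
    """Write a plate as native CSV plus YAML metadata sidecar.

    Output is deterministic (wells and electrodes sorted, times ascending,
    shortest round-trip float formatting), so repeated writes of the same
    plate are byte-identical and ``read_spike_list`` restores the plate
    exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_NATIVE_HEADER) + "\n")
        for well_id in sorted(plate.wells):
            well = plate.wells[well_id]
            for eid in sorted(well.trains):
                for t in well.trains[eid].spike_times:
                    fh.write(f"{well_id},{eid},{float(t)!r}\n")

    durations = {w.meta.recording_duration for w in plate.wells.values()}
    sidecar = {
        "plate_id": plate.plate_id,
        "recording_duration": float(durations.pop()) if len(durations) == 1 else 900.0,
        "wells": {
            wid: {
                "compound": w.meta.compound,
                "concentration": float(w.meta.concentration),
                "unit": w.meta.unit,
                "phase": w.meta.phase,
                # roster keeps silent electrodes across the round trip
                "electrodes": sorted(w.trains),
            }
            for wid, w in sorted(plate.wells.items())
        },
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def read_raw_h5(path: str | Path) -> list[RawTrace]:
    """Read raw voltage traces from an HDF5 container.

    Expects a dataset ``traces`` shaped (channel, sample) with a
    ``sampling_rate`` attribute (Hz).
    """
    import h5py

    with h5py.File(path, "r") as fh:
        data = np.asarray(fh["traces"])
        fs = float(fh["traces"].attrs.get("sampling_rate", fh.attrs.get("sampling_rate", 12500.0)))
    return [RawTrace(samples=row, sampling_rate=fs) for row in data]


# ---------------------------------------------------------------------------
# raw-trace spike detection
# ---------------------------------------------------------------------------


def highpass_filter(trace: RawTrace, cutoff_hz: float = 200.0) -> RawTrace:
    """Zero-phase 4th-order Butterworth high-pass.

    Forward-backward application keeps spike times unshifted.  The cutoff
    must lie below the Nyquist frequency.
    """
    nyq = trace.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=trace.sampling_rate, output="sos")
    return replace(trace, samples=signal.sosfiltfilt(sos, trace.samples))


def estimate_noise_sigma(trace: RawTrace, window_s: float = 1.0, quiet_fraction: float = 0.5) -> float:
    """Robust baseline-noise SD from the quietest stretches of a trace.

    The trace is cut into ``window_s`` windows; the ``quiet_fraction`` of
    windows with the lowest mean power are taken as quiescent, and sigma is
    estimated as 1.4826 × the median absolute deviation of their samples,
    which is insensitive to residual spikes.
    """
    x = np.asarray(trace.samples, dtype=float)
    n_win = max(1, int(len(x) / (window_s * trace.sampling_rate)))
    wlen = len(x) // n_win
    if wlen < 1:
        raise ValueError("trace too short for noise estimation")
    windows = x[: n_win * wlen].reshape(n_win, wlen)
    power = np.mean(windows**2, axis=1)
    n_keep = max(1, int(np.ceil(quiet_fraction * n_win)))
    quiet = windows[np.argsort(power)[:n_keep]].ravel()
    sigma = 1.4826 * float(np.median(np.abs(quiet - np.median(quiet))))
    if sigma == 0.0:
        warnings.warn("baseline sigma is zero (constant trace?)", stacklevel=2)
    return sigma


def detect_spikes(
    trace: RawTrace,
    k_sigma: float = 5.3,
    refractory_ms: float = 1.0,
    sigma: float | None = None,
) -> np.ndarray:
    """Two-sided threshold-crossing spike detection on a filtered trace.

    A spike is an excursion of the (high-pass-filtered) signal beyond
    ±``k_sigma``·sigma; each suprathreshold crossing yields one event timed
    at its sample of largest absolute amplitude, and events closer than the
    refractory window are merged into the larger one.

    Returns spike times in seconds.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    x = np.asarray(trace.samples, dtype=float)
    if sigma is None:
        sigma = estimate_noise_sigma(trace)
    if sigma == 0.0:
        raise ValueError("sigma is zero; cannot form a detection threshold")

    thr = k_sigma * sigma
    above = np.flatnonzero(np.abs(x) > thr)
    if above.size == 0:
        return np.empty(0)
    refr = max(1, int(round(refractory_ms * 1e-3 * trace.sampling_rate)))
    # split suprathreshold samples into events separated by > refractory gap
    breaks = np.flatnonzero(np.diff(above) > refr)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [above.size - 1]])
    peaks = []
    for s, e in zip(starts, ends):
        seg = above[s : e + 1]
        peaks.append(seg[np.argmax(np.abs(x[seg]))])
    return np.asarray(peaks, dtype=float) / trace.sampling_rate
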