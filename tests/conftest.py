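"""Shared fixtures: tiny hand-built wells and one full simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from mea_addict import (
    PlateRecording,
    RecordingMeta,
    SpikeTrain,
    WellRecording,
    default_design,
    run_study,
)


def make_well(
    spikes: dict[str, list[float]],
    well_id: str = "A1",
    duration: float = 900.0,
    **meta_kwargs,
) -> WellRecording:
    """Build a well from {electrode_id: spike time list}."""
    meta = RecordingMeta(well_id=well_id, recording_duration=duration, **meta_kwargs)
    trains = {
        eid: SpikeTrain(eid, np.sort(np.asarray(ts, dtype=float)))
        for eid, ts in spikes.items()
    }
    return WellRecording(meta=meta, trains=trains)


def cluster_well(
    cluster_times: list[float],
    n_electrodes: int = 8,
    spikes_per_cluster: int = 200,
    width: float = 0.5,
    duration: float = 900.0,
    seed: int = 0,
) -> WellRecording:
    """A silent well with dense synchronous spike clusters at given times."""
    rng = np.random.default_rng(seed)
    spikes: dict[str, list[float]] = {f"E{e:02d}": [] for e in range(n_electrodes)}
    for t0 in cluster_times:
        ts = rng.uniform(t0, t0 + width, spikes_per_cluster)
        owners = rng.integers(0, n_electrodes, spikes_per_cluster)
        for t, e in zip(ts, owners):
            spikes[f"E{e:02d}"].append(float(t))
    return make_well(spikes, duration=duration)


@pytest.fixture(scope="session")
def study_result():
    """One full simulated study (default design, seed 42), analysed end to end."""
    return run_study(default_design(seed=42))


@pytest.fixture(scope="session")
def default_study_design():
    return default_design(seed=42)
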