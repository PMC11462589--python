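"""Spike-list I/O and raw-trace spike detection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mea_addict import (
    PlateRecording,
    RawTrace,
    RecordingMeta,
    SpikeTrain,
    WellRecording,
    detect_spikes,
    estimate_noise_sigma,
    highpass_filter,
    read_spike_list,
    write_spike_list,
)
from mea_addict.recording import SpikeListParseError


# ---------------------------------------------------------------------------
# native CSV
# ---------------------------------------------------------------------------


def test_native_csv_roundtrip_of_tiny_plate(tmp_path):
    csv = tmp_path / "p.csv"
    csv.write_text("well,electrode,time_s\nA1,E01,0.1\nA1,E01,0.2\nA1,E01,0.3\n")
    plate = read_spike_list(csv)
    assert len(plate.wells) == 1
    train = plate.wells["A1"].trains["E01"]
    assert train.spike_times.tolist() == [0.1, 0.2, 0.3]


def test_empty_file_with_header_gives_zero_wells(tmp_path):
    csv = tmp_path / "p.csv"
    csv.write_text("well,electrode,time_s\n")
    assert read_spike_list(csv).wells == {}


def test_unsorted_times_are_sorted_on_read(tmp_path):
    rng = np.random.default_rng(3)
    times = rng.uniform(0, 900, 50)
    csv = tmp_path / "p.csv"
    lines = ["well,electrode,time_s"] + [f"A1,E01,{float(t)!r}" for t in times]
    csv.write_text("\n".join(lines) + "\n")
    got = read_spike_list(csv).wells["A1"].trains["E01"].spike_times
    np.testing.assert_array_equal(got, np.sort(times))


@pytest.mark.parametrize(
    "row,match",
    [("A1,E01", "expected 3 fields"), ("A1,E01,notanumber", "bad time")],
)
def test_malformed_row_errors_name_the_line(tmp_path, row, match):
    csv = tmp_path / "p.csv"
    csv.write_text(f"well,electrode,time_s\nA1,E01,0.5\n{row}\n")
    with pytest.raises(SpikeListParseError, match="line 3"):
        read_spike_list(csv)


def test_well_missing_from_sidecar_is_an_error(tmp_path):
    csv = tmp_path / "p.csv"
    csv.write_text("well,electrode,time_s\nA1,E01,0.5\nZ9,E01,0.7\n")
    (tmp_path / "p.meta.yaml").write_text(
        "plate_id: p\nrecording_duration: 900.0\nwells:\n  A1: {compound: nicotine, concentration: 1.0, unit: uM, phase: before_chronic}\n"
    )
    with pytest.raises(ValueError, match="Z9"):
        read_spike_list(csv)


def _plate_strategy():
    time_lists = st.lists(
        st.floats(0, 900, allow_nan=False, allow_infinity=False, width=32),
        max_size=20,
        unique=True,
    )
    well = st.builds(
        lambda times_by_el, comp, conc, phase: (times_by_el, comp, conc, phase),
        st.dictionaries(st.sampled_from(["E01", "E02", "E03"]), time_lists, max_size=3),
        st.sampled_from(["nicotine", "DMSO", "ethanol"]),
        st.floats(0, 100, allow_nan=False, width=16),
        st.sampled_from(["before_chronic", "after_chronic"]),
    )
    return st.dictionaries(st.sampled_from(["A1", "A2", "B1"]), well, max_size=3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(_plate_strategy())
def test_write_read_roundtrip_is_lossless(tmp_path_factory, wells):
    plate = PlateRecording(plate_id="hyp")
    for wid, (times_by_el, comp, conc, phase) in wells.items():
        trains = {
            eid: SpikeTrain(eid, np.sort(np.asarray(ts, dtype=float)))
            for eid, ts in times_by_el.items()
        }
        meta = RecordingMeta(
            well_id=wid, compound=comp, concentration=float(conc), unit="uM", phase=phase
        )
        plate.add_well(WellRecording(meta=meta, trains=trains))
    path = tmp_path_factory.mktemp("rt") / "p.csv"
    write_spike_list(plate, path)
    back = read_spike_list(path)
    assert set(back.wells) == set(plate.wells)
    for wid, w in plate.wells.items():
        got = back.wells[wid]
        assert got.meta == w.meta
        assert set(got.trains) == {e for e, t in w.trains.items()}
        for eid, train in w.trains.items():
            np.testing.assert_array_equal(got.trains[eid].spike_times, train.spike_times)


def test_repeated_writes_are_byte_identical(tmp_path):
    from mea_addict import BurstProcessParams, generate_well

    plate = PlateRecording(plate_id="big")
    for i in range(3):
        meta = RecordingMeta(well_id=f"A{i}", compound="nicotine", concentration=1.0, unit="uM")
        plate.add_well(generate_well(BurstProcessParams(), seed=i, meta=meta))
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_spike_list(plate, p1)
    write_spike_list(plate, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.meta.yaml").read_bytes() == (tmp_path / "b.meta.yaml").read_bytes()


def test_empty_well_survives_roundtrip(tmp_path):
    plate = PlateRecording(plate_id="p")
    plate.add_well(WellRecording(meta=RecordingMeta(well_id="A1", compound="DMSO")))
    path = tmp_path / "p.csv"
    write_spike_list(plate, path)
    back = read_spike_list(path)
    assert "A1" in back.wells and back.wells["A1"].n_spikes == 0


def test_axion_compat_reader_skips_preamble(tmp_path):
    csv = tmp_path / "vendor.csv"
    csv.write_text(
        "some vendor banner\n"
        "Investigator,Jane\n"
        "\n"
        "Time (s),Electrode,Amplitude (mV)\n"
        "0.5,A1_11,0.04\n"
        "0.25,A1_12,0.05\n"
        "1.5,B2_21,0.06\n"
    )
    plate = read_spike_list(csv, dialect="axion_compat")
    assert set(plate.wells) == {"A1", "B2"}
    assert plate.wells["A1"].n_spikes == 2
    assert plate.wells["A1"].trains["A1_12"].spike_times.tolist() == [0.25]


# ---------------------------------------------------------------------------
# raw-trace path
# ---------------------------------------------------------------------------


def test_highpass_rejects_dc_and_keeps_spike_band():
    fs = 12500.0
    t = np.arange(int(fs)) / fs
    # DC
    out = highpass_filter(RawTrace(np.full(t.size, 10.0), fs)).samples
    assert np.max(np.abs(out)) < 1e-6 * 10.0
    # 1 kHz passes within 5%
    s1k = highpass_filter(RawTrace(np.sin(2 * np.pi * 1000 * t), fs)).samples
    mid = slice(2000, -2000)
    assert np.max(np.abs(s1k[mid])) == pytest.approx(1.0, rel=0.05)
    # 10 Hz attenuated by > 20 dB
    s10 = highpass_filter(RawTrace(np.sin(2 * np.pi * 10 * t), fs)).samples
    assert np.max(np.abs(s10[mid])) < 0.1


def test_highpass_cutoff_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        highpass_filter(RawTrace(np.zeros(100), sampling_rate=1000.0), cutoff_hz=600.0)


def test_noise_sigma_robust_to_inserted_spikes():
    rng = np.random.default_rng(11)
    fs = 12500.0
    x = rng.normal(0, 4.0, int(10 * fs))
    clean = estimate_noise_sigma(RawTrace(x.copy(), fs))
    assert clean == pytest.approx(4.0, rel=0.05)
    idx = rng.choice(x.size, 50, replace=False)
    x[idx] += 40.0
    assert estimate_noise_sigma(RawTrace(x, fs)) == pytest.approx(4.0, rel=0.10)


def test_noise_sigma_zero_for_constant_trace_warns():
    with pytest.warns(UserWarning, match="sigma is zero"):
        assert estimate_noise_sigma(RawTrace(np.zeros(25000))) == 0.0


def _biphasic(amplitude: float, fs: float) -> np.ndarray:
    n = int(0.002 * fs)
    t = np.arange(n) / fs
    shape = np.sin(2 * np.pi * 1000 * t) * np.exp(-t / 0.0005)
    return amplitude * shape / np.max(np.abs(shape))


def test_single_suprathreshold_pulse_detected_at_extremum():
    fs = 12500.0
    sigma = 1.0
    x = np.zeros(int(fs))
    pulse = _biphasic(10.0, fs)
    x[5000 : 5000 + pulse.size] += pulse
    times = detect_spikes(RawTrace(x, fs), sigma=sigma)
    assert times.size == 1
    expected = (5000 + np.argmax(np.abs(pulse))) / fs
    assert times[0] == pytest.approx(expected, abs=1e-9)


def test_subthreshold_pulse_not_detected():
    fs = 12500.0
    x = np.zeros(int(fs))
    pulse = _biphasic(4.0, fs)
    x[5000 : 5000 + pulse.size] += pulse
    assert detect_spikes(RawTrace(x, fs), sigma=1.0).size == 0


def test_pulses_in_noise_counted_and_polarity_invariant():
    rng = np.random.default_rng(5)
    fs = 12500.0
    x = rng.normal(0, 1.0, int(30 * fs))
    pulse = _biphasic(8.0, fs)
    starts = (np.arange(100) * int(0.3 * fs)) + 1000
    for s in starts:
        x[s : s + pulse.size] += pulse
    n_pos = detect_spikes(RawTrace(x, fs), sigma=1.0).size
    n_neg = detect_spikes(RawTrace(-x, fs), sigma=1.0).size
    assert abs(n_pos - 100) <= 2
    assert n_pos == n_neg


def test_noise_only_false_positive_rate_matches_gaussian_exceedance():
    """Two-sided threshold crossings on white noise follow the analytic
    Gaussian exceedance rate (checked at a lower k so counts are testable)."""
    rng = np.random.default_rng(17)
    fs = 12500.0
    n = int(80 * fs)  # 1e6 samples
    x = rng.normal(0, 1.0, n)
    k = 4.0
    times = detect_spikes(RawTrace(x, fs), k_sigma=k, sigma=1.0)
    expected = n * 2 * sps.norm.sf(k)
    assert abs(times.size - expected) < 4 * np.sqrt(expected) + 0.05 * expected


def test_zero_sigma_cannot_form_threshold():
    with pytest.raises(ValueError, match="sigma"):
        detect_spikes(RawTrace(np.zeros(25000)), sigma=0.0)
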