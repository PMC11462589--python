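"""Network-burst detection, the 13 parameters, and vehicle normalization."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from mea_addict import (
    BurstDetectionConfig,
    FeatureTable,
    NetworkBurst,
    PARAMETERS,
    array_wide_histogram,
    compute_parameters,
    detect_network_bursts,
    normalize_to_vehicle,
    periodicity,
)
from conftest import cluster_well, make_well


# ---------------------------------------------------------------------------
# brute-force reference of the same four steps (pure Python, O(bins × spikes))
# ---------------------------------------------------------------------------


def brute_force_network_bursts(well, cfg: BurstDetectionConfig):
    times, eidx = well.pooled()
    bin_s = cfg.bin_ms / 1000.0
    n_bins = int(math.ceil(well.meta.recording_duration / bin_s))
    counts = [0] * n_bins
    for t in times:
        counts[min(int(t / bin_s), n_bins - 1)] += 1
    thr = cfg.resolve_rate_threshold(np.asarray(counts))
    min_el = cfg.resolve_min_electrodes(well.n_active_electrodes)
    flagged = [i for i in range(n_bins) if counts[i] >= thr]
    runs = []
    for b in flagged:
        if runs and b - runs[-1][-1] <= int(cfg.merge_gap_ms / cfg.bin_ms):
            runs[-1].append(b)
        else:
            runs.append([b])
    out = []
    for run in runs:
        lo, hi = run[0] * bin_s, (run[-1] + 1) * bin_s
        member = [(t, e) for t, e in zip(times, eidx) if lo <= t < hi]
        if len(member) < cfg.min_spikes_per_nb:
            continue
        if len({e for _, e in member}) < min_el:
            continue
        seg = counts[run[0] : run[-1] + 1]
        peak_rel = int(np.argmax(seg))
        out.append(
            {
                "start": member[0][0],
                "end": member[-1][0],
                "n_spikes": len(member),
                "peak": seg[peak_rel],
                "peak_time": (run[0] + peak_rel + 0.5) * bin_s,
            }
        )
    return out


def random_small_well(seed: int):
    """≤500 spikes: sparse background plus a few synchronous clusters."""
    rng = np.random.default_rng(seed)
    duration = 60.0
    spikes = {f"E{e}": list(rng.uniform(0, duration, rng.integers(0, 20))) for e in range(8)}
    for _ in range(rng.integers(0, 5)):
        t0 = rng.uniform(0, duration - 1)
        n = int(rng.integers(10, 80))
        ts = rng.uniform(t0, t0 + rng.uniform(0.1, 0.8), n)
        owners = rng.integers(0, 8, n)
        for t, e in zip(ts, owners):
            spikes[f"E{e}"].append(float(t))
    return make_well(spikes, duration=duration)


def assert_matches_brute_force(well, cfg):
    got = detect_network_bursts(well, cfg)
    ref = brute_force_network_bursts(well, cfg)
    assert len(got) == len(ref)
    for g, r in zip(got, ref):
        assert g.start_s == pytest.approx(r["start"], abs=1e-9)
        assert g.n_spikes == r["n_spikes"]
        assert g.peak_bin_count == r["peak"]
        assert g.peak_time_s == pytest.approx(r["peak_time"], abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_detector_matches_brute_force_reference(seed):
    assert_matches_brute_force(random_small_well(seed), BurstDetectionConfig())


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


def test_histogram_counts_pool_electrodes_and_sum_to_total():
    well = make_well({"E1": list(np.linspace(0, 0.09, 6)), "E2": [0.05, 0.07, 500.0, 899.99]})
    hist = array_wide_histogram(well, bin_ms=100.0)
    assert hist.size == 9000
    assert hist[0] == 8
    assert hist.sum() == well.n_spikes


def test_histogram_of_empty_well_is_zero_vector():
    hist = array_wide_histogram(make_well({}), bin_ms=100.0)
    assert hist.size == math.ceil(900 / 0.1)
    assert not hist.any()


def test_uniform_spikes_give_poisson_level_bins():
    rng = np.random.default_rng(0)
    well = make_well({"E1": list(rng.uniform(0, 900, 9000))})
    hist = array_wide_histogram(well)
    assert hist.mean() == pytest.approx(1.0, abs=0.01)
    assert hist.max() <= 8  # Poisson(1) tail


# ---------------------------------------------------------------------------
# detection behaviour
# ---------------------------------------------------------------------------


def test_empty_well_has_no_bursts():
    assert detect_network_bursts(make_well({})) == []


def test_single_dense_cluster_is_one_burst_with_all_spikes():
    well = cluster_well([100.0], spikes_per_cluster=200)
    bursts = detect_network_bursts(well, BurstDetectionConfig())
    assert len(bursts) == 1
    assert bursts[0].n_spikes == 200


def test_cluster_separation_vs_merge_gap():
    far = cluster_well([100.0, 105.0])
    assert len(detect_network_bursts(far)) == 2
    # second cluster starts 0.1 s after the first ends: gap <= merge_gap
    near = cluster_well([100.0, 100.6])
    assert len(detect_network_bursts(near)) == 1


def test_burst_spike_count_never_exceeds_well_total():
    for seed in range(5):
        well = random_small_well(seed)
        bursts = detect_network_bursts(well)
        assert sum(b.n_spikes for b in bursts) <= well.n_spikes
        for b in bursts:
            assert b.peak_bin_count <= b.n_spikes


def test_burst_count_stable_under_half_bin_origin_shift():
    """Shifting all spikes by half a bin changes the NB count by at most 1."""
    for seed in range(5):
        base = cluster_well([50.0, 150.0, 250.0, 350.0], seed=seed)
        n0 = len(detect_network_bursts(base))
        shifted = make_well(
            {eid: list(tr.spike_times + 0.05) for eid, tr in base.trains.items()},
            duration=base.meta.recording_duration,
        )
        n1 = len(detect_network_bursts(shifted))
        assert abs(n0 - n1) <= 1


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _nb(start, end, n=50, peak=20, peak_time=None):
    return NetworkBurst(start, end, n, peak, peak_time if peak_time is not None else (start + end) / 2)


def test_ibi_is_end_to_next_start():
    well = make_well({"E1": [0.5, 3.5]})
    pv = compute_parameters(well, [_nb(0.5, 1.0), _nb(3.0, 3.5)])
    assert pv.IBI == pytest.approx(2.0)


def test_mf_averages_per_burst_peak_bin():
    bursts = [_nb(i * 10.0, i * 10.0 + 1.0, n=12, peak=7) for i in range(10)]
    pv = compute_parameters(make_well({"E1": [0.1]}), bursts)
    assert pv.MF == 7.0


def test_equal_durations_give_zero_dispersion():
    bursts = [_nb(i * 10.0, i * 10.0 + 0.5) for i in range(5)]
    pv = compute_parameters(make_well({"E1": [0.1]}), bursts)
    assert pv.CV_Duration == 0.0
    assert pv.Duration_IQR == 0.0


def test_sparse_wells_flag_missing_not_zero():
    pv0 = compute_parameters(make_well({"E1": [1.0]}), [])
    assert pv0.n_NB == 0 and pv0.TS == 1
    assert np.isnan(pv0.Duration) and np.isnan(pv0.IBI) and "IBI" in pv0.missing
    pv1 = compute_parameters(make_well({"E1": [1.0]}), [_nb(1.0, 1.5)])
    assert not np.isnan(pv1.Duration)
    assert np.isnan(pv1.IBI) and np.isnan(pv1.Duration_IQR)


def test_cv_uses_sample_sd():
    durs = [0.4, 0.5, 0.6]
    bursts = [_nb(i * 10.0, i * 10.0 + d) for i, d in enumerate(durs)]
    pv = compute_parameters(make_well({"E1": [0.1]}), bursts)
    assert pv.CV_Duration == pytest.approx(np.std(durs, ddof=1) / np.mean(durs))


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------


def test_periodic_comb_scores_high():
    hist = np.zeros(9000)
    hist[::100] = 50  # burst every 10 s
    assert periodicity(hist) >= 0.9


def test_poisson_histogram_scores_low():
    rng = np.random.default_rng(1)
    low = [periodicity(rng.poisson(2.0, 9000)) for _ in range(10)]
    assert np.mean(np.asarray(low) < 0.2) > 0.8


def test_degenerate_histograms_score_zero():
    assert periodicity(np.zeros(1000)) == 0.0
    assert periodicity(np.full(1000, 3.0)) == 0.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _feature_frame(rows):
    cols = ["well", "compound", "concentration", "unit", "phase"] + list(PARAMETERS)
    return pd.DataFrame(rows, columns=cols)


def _row(well, conc, phase="before_chronic", **vals):
    base = {p: 10.0 for p in PARAMETERS}
    base.update(vals)
    return [well, "drugX", conc, "uM", phase] + [base[p] for p in PARAMETERS]


def test_normalization_is_percent_of_same_well_vehicle():
    table = FeatureTable(_feature_frame([_row("A1", 0.0, TS=50.0), _row("A1", 1.0, TS=75.0)]))
    norm = normalize_to_vehicle(table)
    dose = norm.data[norm.data.concentration == 1.0].iloc[0]
    veh = norm.data[norm.data.concentration == 0.0].iloc[0]
    assert dose["TS"] == pytest.approx(150.0)
    assert all(veh[p] == pytest.approx(100.0) for p in PARAMETERS)


def test_zero_vehicle_value_becomes_missing_not_infinite(caplog):
    table = FeatureTable(
        _feature_frame([_row("A1", 0.0, Duration=0.0), _row("A1", 1.0, Duration=5.0)])
    )
    norm = normalize_to_vehicle(table)
    assert np.isnan(norm.data.loc[norm.data.concentration == 1.0, "Duration"]).all()
    assert norm.data.loc[norm.data.concentration == 1.0, "TS"].iloc[0] == pytest.approx(100.0)


def test_normalizing_twice_is_rejected():
    table = FeatureTable(_feature_frame([_row("A1", 0.0), _row("A1", 1.0)]))
    with pytest.raises(ValueError, match="already normalized"):
        normalize_to_vehicle(normalize_to_vehicle(table))


def test_feature_table_tidy_csv_roundtrip(tmp_path):
    table = FeatureTable(
        _feature_frame([_row("A1", 0.0), _row("A1", 1.0, TS=42.0), _row("A2", 0.0)]),
        normalized=False,
    )
    path = tmp_path / "f.csv"
    table.to_tidy_csv(path)
    back = FeatureTable.from_tidy_csv(path)
    merged = back.data.sort_values(["well", "concentration"]).reset_index(drop=True)
    orig = table.data.sort_values(["well", "concentration"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(merged, orig, check_like=True)
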