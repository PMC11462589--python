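"""Network-burst detection and the 13 analytical parameters of a well.

A network burst (NB) is a transient, array-wide episode of synchronized
high-frequency firing.  Detection pools all electrodes of a well into a
100-ms histogram and applies a four-step rule:

1. count spikes of all electrodes in every 100-ms bin;
2. flag bins whose count reaches ``rate_threshold`` (default 5 spikes/bin;
   an adaptive variant — 25% of the 99th-percentile bin count, floored at
   5 — is available via ``rate_threshold="adaptive"``);
3. merge runs of flagged bins separated by gaps of at most
   ``merge_gap_ms``;
4. discard candidates with fewer than ``min_spikes_per_nb`` spikes or with
   spikes on fewer than ``min_electrodes`` electrodes (default: 25% of the
   well's active electrodes).

Burst start/end are snapped to bin edges and then refined to the first and
last member spike.  Each recording of a well is summarised by 13 parameters
(total spikes, NB count, inter-burst interval, duration, spikes per NB, max
frequency, inter-max-frequency interval, four coefficients of variation,
periodicity and the duration interquartile range); parameters that need at
least two bursts are reported as missing (NaN) for nearly silent wells
rather than zero, and dose values are normalised per well to the pre-dose
vehicle recording (vehicle = 100%).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .recording import PlateRecording, WellRecording

__all__ = [
    "PARAMETERS",
    "BurstDetectionConfig",
    "NetworkBurst",
    "ParameterVector",
    "FeatureTable",
    "array_wide_histogram",
    "detect_network_bursts",
    "compute_parameters",
    "periodicity",
    "extract_features",
    "normalize_to_vehicle",
    "dose_response_summary",
]

logger = logging.getLogger(__name__)

#: The 13 analytical parameters, in canonical column order.
PARAMETERS = (
    "TS",
    "n_NB",
    "IBI",
    "Duration",
    "Spikes",
    "MF",
    "IMFI",
    "CV_Duration",
    "CV_Spikes",
    "CV_MF",
    "CV_IMFI",
    "Periodicity",
    "Duration_IQR",
)

#: Index/metadata columns of a feature table.
META_COLUMNS = ("well", "compound", "concentration", "unit", "phase")


@dataclass
class BurstDetectionConfig:
    """Thresholds of the four-step network-burst detector.

    ``rate_threshold`` may be a fixed spikes-per-bin count (default 5) or
    the string ``"adaptive"`` for max(5, 0.25 × 99th-percentile bin count).
    ``min_electrodes=None`` means 25% of the well's active electrodes.
    """

    bin_ms: float = 100.0
    rate_threshold: float | str = 5.0
    merge_gap_ms: float = 200.0
    min_spikes_per_nb: int = 10
    min_electrodes: int | None = None
    min_electrode_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.bin_ms <= 0 or self.merge_gap_ms < self.bin_ms:
            raise ValueError("need bin_ms > 0 and merge_gap_ms >= bin_ms")
        if self.min_spikes_per_nb <= 0:
            raise ValueError("min_spikes_per_nb must be positive")
        if isinstance(self.rate_threshold, str) and self.rate_threshold != "adaptive":
            raise ValueError("rate_threshold must be a number or 'adaptive'")

    def resolve_rate_threshold(self, histogram: np.ndarray) -> float:
        if self.rate_threshold == "adaptive":
            if histogram.size == 0:
                return 5.0
            return max(5.0, 0.25 * float(np.percentile(histogram, 99)))
        return float(self.rate_threshold)

    def resolve_min_electrodes(self, n_active: int) -> int:
        if self.min_electrodes is not None:
            return self.min_electrodes
        return max(1, math.ceil(self.min_electrode_fraction * n_active))


@dataclass
class NetworkBurst:
    """One detected array-wide burst."""

    start_s: float
    end_s: float
    n_spikes: int
    peak_bin_count: int
    peak_time_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("burst end must be after start")
        if self.peak_bin_count > self.n_spikes:
            raise ValueError("peak bin count cannot exceed burst spike count")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ParameterVector:
    """The 13 analytical parameters of one well at one recording.

    Fields that are undefined (fewer than two bursts, or a zero-mean CV
    divisor) hold NaN and are listed in ``missing``.
    """

    TS: float
    n_NB: float
    IBI: float
    Duration: float
    Spikes: float
    MF: float
    IMFI: float
    CV_Duration: float
    CV_Spikes: float
    CV_MF: float
    CV_IMFI: float
    Periodicity: float
    Duration_IQR: float
    missing: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series({p: getattr(self, p) for p in PARAMETERS})


def array_wide_histogram(well: WellRecording, bin_ms: float = 100.0) -> np.ndarray:
    """Pooled spike-count histogram of a well (all electrodes, fixed bins).

    The histogram covers the full recording duration; the sum of counts
    equals the well's total spike count.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil(well.meta.recording_duration / bin_s))
    times, _ = well.pooled()
    if times.size == 0:
        return np.zeros(n_bins, dtype=int)
    idx = np.minimum((times / bin_s).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def detect_network_bursts(
    well: WellRecording, cfg: BurstDetectionConfig | None = None
) -> list[NetworkBurst]:
    """Four-step network-burst detection (see module docstring).

    Returns non-overlapping bursts sorted by start time.
    """
    cfg = cfg or BurstDetectionConfig()
    bin_s = cfg.bin_ms / 1000.0
    times, eidx = well.pooled()
    hist = array_wide_histogram(well, cfg.bin_ms)
    if times.size == 0:
        return []

    thr = cfg.resolve_rate_threshold(hist)
    min_el = cfg.resolve_min_electrodes(well.n_active_electrodes)
    flagged = np.flatnonzero(hist >= thr)
    if flagged.size == 0:
        return []

    gap_bins = int(cfg.merge_gap_ms / cfg.bin_ms)
    breaks = np.flatnonzero(np.diff(flagged) > gap_bins)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [flagged.size - 1]])

    bursts: list[NetworkBurst] = []
    for rs, re in zip(run_starts, run_ends):
        b0, b1 = flagged[rs], flagged[re]
        lo, hi = b0 * bin_s, (b1 + 1) * bin_s
        i0, i1 = np.searchsorted(times, [lo, hi])
        member = slice(i0, i1)
        n_sp = i1 - i0
        if n_sp < cfg.min_spikes_per_nb:
            continue
        if np.unique(eidx[member]).size < min_el:
            continue
        seg = hist[b0 : b1 + 1]
        peak_rel = int(np.argmax(seg))
        bursts.append(
            NetworkBurst(
                start_s=float(times[i0]),
                end_s=float(times[i1 - 1]) + 1e-9,
                n_spikes=int(n_sp),
                peak_bin_count=int(seg[peak_rel]),
                peak_time_s=(b0 + peak_rel + 0.5) * bin_s,
            )
        )
    return bursts


def periodicity(histogram: np.ndarray, min_lag_bins: int = 3) -> float:
    """Bounded periodicity score of a pooled spike-rate histogram.

    Computes the normalised autocorrelation of the mean-subtracted
    histogram and returns the height of its largest local maximum at lag ≥
    ``min_lag_bins`` bins, clipped to [0, 1].  A perfectly periodic comb
    scores near 1; a homogeneous (Poisson) histogram scores near 0; an
    empty or constant histogram scores exactly 0.
    """
    x = np.asarray(histogram, dtype=float)
    if x.size < 2:
        return 0.0
    x = x - x.mean()
    if not np.any(x):
        return 0.0
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n]
    acf /= acf[0]
    if n <= min_lag_bins + 1:
        return 0.0
    interior = acf[1:-1]
    is_peak = (interior > acf[:-2]) & (interior >= acf[2:])
    lags = np.flatnonzero(is_peak) + 1
    lags = lags[lags >= min_lag_bins]
    if lags.size == 0:
        return 0.0
    return float(np.clip(np.max(acf[lags]), 0.0, 1.0))


def _cv(values: np.ndarray) -> float:
    """Sample-SD coefficient of variation; NaN when undefined."""
    if values.size < 2:
        return np.nan
    m = values.mean()
    if m == 0:
        return np.nan
    return float(values.std(ddof=1) / m)


def compute_parameters(
    well: WellRecording,
    bursts: Sequence[NetworkBurst],
    bin_ms: float = 100.0,
) -> ParameterVector:
    """Compute the 13 analytical parameters from detected bursts.

    TS and the NB count are always defined.  With a single burst the burst
    averages (Duration, Spikes, MF) are defined but all interval- and
    dispersion-based parameters are missing; with none, every burst
    parameter is missing.  CVs use the sample SD (ddof=1); the duration IQR
    uses linear-interpolation quartiles.
    """
    ts = float(well.n_spikes)
    n_nb = len(bursts)
    values: dict[str, float] = {p: np.nan for p in PARAMETERS}
    values["TS"] = ts
    values["n_NB"] = float(n_nb)

    if n_nb >= 1:
        dur = np.array([b.duration for b in bursts])
        spk = np.array([b.n_spikes for b in bursts], dtype=float)
        mf = np.array([b.peak_bin_count for b in bursts], dtype=float)
        values["Duration"] = float(dur.mean())
        values["Spikes"] = float(spk.mean())
        values["MF"] = float(mf.mean())

    if n_nb >= 2:
        starts = np.array([b.start_s for b in bursts])
        ends = np.array([b.end_s for b in bursts])
        peaks = np.array([b.peak_time_s for b in bursts])
        ibis = starts[1:] - ends[:-1]
        imfis = np.diff(peaks)
        values["IBI"] = float(ibis.mean())
        values["IMFI"] = float(imfis.mean())
        values["CV_Duration"] = _cv(dur)
        values["CV_Spikes"] = _cv(spk)
        values["CV_MF"] = _cv(mf)
        values["CV_IMFI"] = _cv(imfis)
        values["Duration_IQR"] = float(
            np.percentile(dur, 75, method="linear") - np.percentile(dur, 25, method="linear")
        )
        values["Periodicity"] = periodicity(array_wide_histogram(well, bin_ms))

    missing = tuple(p for p in PARAMETERS if np.isnan(values[p]))
    return ParameterVector(**values, missing=missing)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Well-level parameter table of a study.

    ``data`` holds one row per (well, compound, concentration, phase) with
    the metadata columns of :data:`META_COLUMNS` followed by the 13
    parameter columns.  ``normalized`` records whether values are raw or
    percent-of-vehicle.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        cols = list(META_COLUMNS) + list(PARAMETERS)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        self.data = self.data[cols].reset_index(drop=True)

    def dose_rows(self) -> pd.DataFrame:
        """Rows at non-zero concentration (the baseline rows are the
        per-well vehicle recordings used only for normalisation)."""
        return self.data[self.data["concentration"] > 0]

    def to_tidy_csv(self, path: str | Path) -> Path:
        """Serialise as tidy CSV (one row per well × parameter)."""
        path = Path(path)
        tidy = self.data.melt(
            id_vars=list(META_COLUMNS), value_vars=list(PARAMETERS),
            var_name="parameter", value_name="value",
        )
        tidy["normalized"] = self.normalized
        tidy.to_csv(path, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_tidy_csv(cls, path: str | Path) -> "FeatureTable":
        tidy = pd.read_csv(path, dtype={"concentration": float, "value": float})
        normalized = bool(tidy["normalized"].iloc[0]) if len(tidy) else False
        wide = tidy.pivot(
            index=list(META_COLUMNS), columns="parameter", values="value"
        ).reset_index()
        wide.columns.name = None
        return cls(data=wide, normalized=normalized)


def extract_features(
    plates: Iterable[PlateRecording],
    cfg: BurstDetectionConfig | None = None,
) -> FeatureTable:
    """Run burst detection and parameter computation over whole plates."""
    cfg = cfg or BurstDetectionConfig()
    records = []
    for plate in plates:
        for well_id in sorted(plate.wells):
            well = plate.wells[well_id]
            bursts = detect_network_bursts(well, cfg)
            pv = compute_parameters(well, bursts, bin_ms=cfg.bin_ms)
            row = {
                "well": well.meta.well_id,
                "compound": well.meta.compound,
                "concentration": well.meta.concentration,
                "unit": well.meta.unit,
                "phase": well.meta.phase,
            }
            row.update({p: getattr(pv, p) for p in PARAMETERS})
            records.append(row)
    return FeatureTable(data=pd.DataFrame.from_records(records), normalized=False)


def normalize_to_vehicle(table: FeatureTable) -> FeatureTable:
    """Express every parameter as percent of the same well's vehicle value.

    Each well's pre-dose vehicle recording (concentration 0) in the same
    phase defines 100%; dose rows become ``100 × value / vehicle_value``
    per parameter.  A zero or missing vehicle value yields a missing
    normalised value (never infinity) and is logged.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    df = table.data.copy()
    out_rows = []
    for (well, phase), grp in df.groupby(["well", "phase"], sort=True):
        base = grp[grp["concentration"] == 0]
        if len(base) != 1:
            raise ValueError(f"well {well!r} phase {phase!r}: expected exactly one vehicle row, got {len(base)}")
        base_vals = base.iloc[0][list(PARAMETERS)].astype(float)
        for _, row in grp.iterrows():
            new = row.copy()
            for p in PARAMETERS:
                b = base_vals[p]
                v = row[p]
                if not np.isfinite(b) or b == 0:
                    if np.isfinite(v):
                        logger.warning(
                            "well %s phase %s: vehicle value for %s is %s; normalised value set missing",
                            well, phase, p, b,
                        )
                    new[p] = np.nan
                elif not np.isfinite(v):
                    new[p] = np.nan
                else:
                    new[p] = 100.0 * v / b
            out_rows.append(new)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return FeatureTable(data=out, normalized=True)


def dose_response_summary(
    table: FeatureTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Group means with many-to-one significance flags versus vehicle.

    For each compound × phase × parameter, compares the well values at each
    concentration against the same wells' vehicle (concentration 0) values
    with one-way ANOVA followed by Dunnett's test.  Returns a tidy frame
    (heat-map analogue) with columns compound, phase, parameter,
    concentration, mean, sd, n, p_adj, significant.
    """
    from .stats import dunnett_test

    df = table.data
    rows = []
    for (compound, phase, _unit), grp in df.groupby(["compound", "phase", "unit"], sort=True):
        concs = sorted(grp["concentration"].unique())
        if 0.0 not in concs or len(concs) < 2:
            continue
        for p in PARAMETERS:
            control = grp.loc[grp["concentration"] == 0, p].dropna().to_numpy()
            treat_concs = [c for c in concs if c > 0]
            treatments = [
                grp.loc[grp["concentration"] == c, p].dropna().to_numpy() for c in treat_concs
            ]
            usable = [i for i, t in enumerate(treatments) if t.size >= 2]
            p_adj = {c: np.nan for c in treat_concs}
            if control.size >= 2 and usable:
                try:
                    res = dunnett_test(control, [treatments[i] for i in usable], alpha=alpha)
                    for i, pv in zip(usable, res.p_adjusted):
                        p_adj[treat_concs[i]] = pv
                except ValueError:
                    pass
            for c in concs:
                vals = grp.loc[grp["concentration"] == c, p].dropna()
                rows.append(
                    {
                        "compound": compound,
                        "phase": phase,
                        "parameter": p,
                        "concentration": c,
                        "mean": vals.mean() if len(vals) else np.nan,
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                        "n": len(vals),
                        "p_adj": np.nan if c == 0 else p_adj.get(c, np.nan),
                        "significant": bool(c > 0 and np.isfinite(p_adj.get(c, np.nan)) and p_adj[c] < alpha),
                    }
                )
    return pd.DataFrame(rows)
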