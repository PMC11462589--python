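"""Seeded synthetic MEA study generator.

Real recordings of this assay are not publicly deposited, so the pipeline
is exercised on simulated plates that carry the statistical structure the
analysis assumes: per-electrode homogeneous Poisson background firing plus
array-wide network bursts from a Gamma renewal process, each burst an
inhomogeneous Poisson packet with triangular intensity shared across a
random subset of electrodes.

The study layout mirrors the screening design: 16-electrode wells recorded
for 15 minutes at a vehicle step plus five cumulative doses, in two
sessions (before and after a 10-day chronic exposure), with ten wells per
compound, five addictive-profile compounds, four non-addictive-profile
compounds and a DMSO vehicle analogue.  Acute dose effects follow Hill
curves on the burst-process parameters (equal in both phases); addictive
profiles additionally apply multiplicative *chronic* shifts to the
burst-timing parameters (burst interval, duration median and duration
dispersion) in the after-chronic phase only, which is the signature the
subset search is meant to recover.  Non-addictive and vehicle profiles
have no chronic shift.

All randomness flows from a single study seed through documented
``numpy`` seed-list substreams, so identical designs and seeds reproduce
identical plates, features and detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bursts import PARAMETERS, FeatureTable
from .recording import AFTER, BEFORE, PHASES, PlateRecording, RecordingMeta, SpikeTrain, WellRecording

__all__ = [
    "BurstProcessParams",
    "HillEffect",
    "CompoundProfile",
    "StudyDesign",
    "generate_well",
    "apply_compound",
    "generate_study",
    "default_design",
    "planted_feature_table",
    "design_to_yaml",
    "design_from_yaml",
]

#: The burst-timing feature columns an addictive chronic shift drives.
TIMING_PARAMETERS = ("IBI", "Duration", "IMFI", "Duration_IQR")


@dataclass
class BurstProcessParams:
    """Parameters of the spike-train process of one well at one recording.

    ``background_rate`` is per electrode (Hz).  Burst onsets follow a Gamma
    renewal process with mean interval ``nb_interval_mean`` (s) and shape
    ``nb_interval_shape`` (larger = more regular).  Burst durations are
    LogNormal with median ``nb_duration_median`` (s) and log-SD
    ``nb_duration_logsd``.  ``nb_peak_rate`` is the pooled spike count in a
    100-ms bin at the peak of the triangular burst envelope.  A non-finite
    ``nb_interval_mean`` switches bursting off entirely.
    """

    background_rate: float = 0.4
    nb_interval_mean: float = 12.0
    nb_interval_shape: float = 8.0
    nb_duration_median: float = 0.5
    nb_duration_logsd: float = 0.25
    nb_peak_rate: float = 80.0
    n_electrodes: int = 16
    participation: float = 0.85

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.nb_peak_rate <= 0:
            raise ValueError("rates must be positive")
        if self.nb_duration_median <= 0 or self.nb_interval_shape <= 0:
            raise ValueError("durations and shape must be positive")

    def expected_parameters(
        self, duration: float = 900.0, rate_threshold: float = 5.0, bin_s: float = 0.1
    ) -> dict[str, float]:
        """Analytic targets for the recoverable burst features.

        Accounts for the detector's flagging level truncating the triangular
        envelope below ``rate_threshold`` spikes/bin.
        """
        mean_d = self.nb_duration_median * math.exp(self.nb_duration_logsd**2 / 2)
        thr_frac = min(1.0, rate_threshold / self.nb_peak_rate)
        det_d = mean_d * (1.0 - thr_frac)
        peak_hz = self.nb_peak_rate / bin_s
        return {
            "n_NB": duration / self.nb_interval_mean,
            "Duration": det_d,
            "Spikes": 0.5 * peak_hz * mean_d * (1.0 - thr_frac**2)
            + self.background_rate * self.n_electrodes * det_d,
            "MF": self.nb_peak_rate * max(0.0, 1.0 - bin_s / (2 * mean_d)),
            "IBI": self.nb_interval_mean - det_d,
            "IMFI": self.nb_interval_mean,
        }


@dataclass
class HillEffect:
    """Multiplicative Hill-type acute dose effect on one process parameter.

    multiplier(c) = 1 + (max_effect − 1) · cˢ / (cˢ + EC50ˢ); at c = 0 the
    multiplier is exactly 1 and it approaches ``max_effect`` at saturation.
    ``max_effect`` < 1 encodes suppression.
    """

    ec50: float
    max_effect: float
    slope: float = 1.5

    def multiplier(self, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        if concentration == 0:
            return 1.0
        cs = concentration**self.slope
        return 1.0 + (self.max_effect - 1.0) * cs / (cs + self.ec50**self.slope)


#: process-parameter keys a compound effect may act on
_EFFECT_KEYS = (
    "background_rate",
    "nb_interval_mean",
    "nb_duration_median",
    "nb_duration_logsd",
    "nb_peak_rate",
)


@dataclass
class CompoundProfile:
    """Dose series and effect structure of one test compound."""

    name: str
    label: str  # "addictive" | "non_addictive" | "vehicle"
    unit: str
    concentrations: tuple[float, ...]
    acute: dict[str, HillEffect] = field(default_factory=dict)
    chronic_shift: dict[str, float] = field(default_factory=dict)
    extinction_concentration: float | None = None  # bursting off at >= this dose, after phase

    def __post_init__(self) -> None:
        if self.label not in ("addictive", "non_addictive", "vehicle"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label != "addictive" and any(v != 1.0 for v in self.chronic_shift.values()):
            raise ValueError(f"{self.name}: only addictive profiles may carry a chronic shift")
        for key in list(self.acute) + list(self.chronic_shift):
            if key not in _EFFECT_KEYS:
                raise ValueError(f"unknown effect key {key!r}")

    @property
    def addictive(self) -> bool:
        return self.label == "addictive"


def apply_compound(
    base: BurstProcessParams,
    profile: CompoundProfile,
    concentration: float,
    phase: str,
) -> BurstProcessParams:
    """Apply a compound's acute and (after-chronic) chronic effects.

    The concentration must be 0 (vehicle step) or one of the profile's
    doses.  Acute Hill multipliers act in both phases; chronic shifts only
    in the after-chronic phase.
    """
    if phase not in PHASES:
        raise ValueError(f"bad phase {phase!r}")
    if concentration != 0 and concentration not in profile.concentrations:
        raise ValueError(f"{profile.name}: concentration {concentration} not in dose list")
    mult = {k: 1.0 for k in _EFFECT_KEYS}
    for key, eff in profile.acute.items():
        mult[key] *= eff.multiplier(concentration)
    # Chronic exposure manifests as altered responsiveness to compound
    # challenge: the shift acts on dose recordings.  The vehicle step of
    # each session is the well's reference point in both phases (a uniform
    # baseline change would be removed by vehicle normalization anyway).
    if phase == AFTER and concentration > 0:
        for key, m in profile.chronic_shift.items():
            mult[key] *= m
    out = replace(
        base,
        **{k: getattr(base, k) * mult[k] for k in _EFFECT_KEYS},
    )
    if (
        phase == AFTER
        and profile.extinction_concentration is not None
        and concentration >= profile.extinction_concentration
    ):
        out = replace(out, nb_interval_mean=math.inf)
    return out


def generate_well(
    params: BurstProcessParams,
    seed: int | np.random.Generator,
    meta: RecordingMeta | None = None,
) -> WellRecording:
    """Simulate one 15-minute well recording.

    Background spikes are homogeneous Poisson per electrode; bursts are
    Gamma-renewal packets of triangular-intensity Poisson spikes shared
    across a random electrode subset.  Fully reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = meta or RecordingMeta(well_id="W00")
    T = meta.recording_duration
    n_el = params.n_electrodes
    per_electrode: list[list[np.ndarray]] = [[] for _ in range(n_el)]

    for e in range(n_el):
        n_bg = rng.poisson(params.background_rate * T)
        per_electrode[e].append(rng.uniform(0.0, T, n_bg))

    if np.isfinite(params.nb_interval_mean):
        shape = params.nb_interval_shape
        scale = params.nb_interval_mean / shape
        t = rng.uniform(0.0, params.nb_interval_mean)
        starts = []
        while t < T:
            starts.append(t)
            t += rng.gamma(shape, scale)
        logmean = math.log(params.nb_duration_median)
        peak_hz = params.nb_peak_rate / 0.1
        n_part = max(1, round(params.participation * n_el))
        for s in starts:
            d = rng.lognormal(logmean, params.nb_duration_logsd)
            n_sp = rng.poisson(0.5 * peak_hz * d)
            if n_sp == 0:
                continue
            tt = rng.triangular(s, s + d / 2.0, s + d, n_sp)
            tt = tt[tt < T]
            if tt.size == 0:
                continue
            part = rng.choice(n_el, size=n_part, replace=False)
            owners = part[rng.integers(0, n_part, tt.size)]
            for e in np.unique(owners):
                per_electrode[e].append(tt[owners == e])

    trains = {}
    for e in range(n_el):
        eid = f"E{e + 1:02d}"
        times = np.unique(np.concatenate(per_electrode[e]))
        trains[eid] = SpikeTrain(eid, times)
    return WellRecording(meta=meta, trains=trains)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Full layout of a two-phase cumulative-dosing study."""

    compounds: list[CompoundProfile]
    wells_per_compound: int = 10
    recording_duration: float = 900.0
    baseline: BurstProcessParams = field(default_factory=BurstProcessParams)
    well_cv: float = 0.15  # per-well biological baseline spread (lognormal)
    state_cv: float = 0.06  # per-recording state fluctuation (lognormal)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.wells_per_compound < 8:
            raise ValueError("design needs at least 8 wells per compound")
        vehicles = [c for c in self.compounds if c.label == "vehicle"]
        if len(vehicles) != 1:
            raise ValueError("design needs exactly one vehicle profile")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    @property
    def labels(self) -> dict[str, str]:
        return {c.name: c.label for c in self.compounds}

    @property
    def vehicle_name(self) -> str:
        return next(c.name for c in self.compounds if c.label == "vehicle")


def _timing_shift(interval: float, duration: float, logsd: float) -> dict[str, float]:
    return {
        "nb_interval_mean": interval,
        "nb_duration_median": duration,
        "nb_duration_logsd": logsd,
    }


def default_design(seed: int = 42, wells_per_compound: int = 10) -> StudyDesign:
    """The default ten-compound screening design.

    Five addictive-profile compounds (nicotine-, ethanol-, flunitrazepam-,
    phenobarbital- and methamphetamine-like), four non-addictive analogues
    chosen to share acute mechanisms with the addictive set (varenicline-,
    muscimol-, amantadine-, acetaminophen-like), and a DMSO vehicle.  Dose
    ladders follow the screen's cumulative series; acute effect directions
    follow the observed acute pharmacology (e.g. the varenicline analogue
    lowers firing while raising burst counts); chronic shifts of roughly
    1.4–1.6× act on burst timing for addictive profiles only.  The ethanol
    analogue loses bursting entirely at its top dose after chronic
    exposure, exercising the missing-value path.
    """
    compounds = [
        CompoundProfile(
            "nicotine", "addictive", "uM", (1, 3, 10, 30, 100),
            acute={
                "background_rate": HillEffect(ec50=10.0, max_effect=1.6),
                "nb_interval_mean": HillEffect(ec50=10.0, max_effect=0.8),
            },
            chronic_shift=_timing_shift(1.5, 1.4, 1.3),
        ),
        CompoundProfile(
            "ethanol", "addictive", "%", (0.03, 0.1, 0.3, 1, 3),
            acute={"background_rate": HillEffect(ec50=0.5, max_effect=0.7)},
            chronic_shift=_timing_shift(1.6, 1.35, 1.3),
            extinction_concentration=3.0,
        ),
        CompoundProfile(
            "flunitrazepam", "addictive", "uM", (0.1, 0.3, 1, 3, 10),
            acute={"nb_peak_rate": HillEffect(ec50=1.0, max_effect=0.7)},
            chronic_shift=_timing_shift(1.5, 0.68, 1.3),
        ),
        CompoundProfile(
            "phenobarbital", "addictive", "uM", (1, 3, 10, 30, 100),
            acute={"background_rate": HillEffect(ec50=30.0, max_effect=0.75)},
            chronic_shift=_timing_shift(1.55, 1.4, 1.25),
        ),
        CompoundProfile(
            "methamphetamine", "addictive", "uM", (0.3, 1, 3, 10, 30),
            acute={"background_rate": HillEffect(ec50=3.0, max_effect=1.4)},
            chronic_shift=_timing_shift(0.65, 1.35, 1.3),
        ),
        CompoundProfile(
            "varenicline", "non_addictive", "uM", (0.1, 0.3, 1, 3, 10),
            acute={
                "background_rate": HillEffect(ec50=1.0, max_effect=0.6),
                "nb_interval_mean": HillEffect(ec50=1.0, max_effect=0.85),
            },
        ),
        CompoundProfile(
            "muscimol", "non_addictive", "uM", (3, 10, 30, 100, 300),
            acute={
                "background_rate": HillEffect(ec50=30.0, max_effect=1.15),
                "nb_interval_mean": HillEffect(ec50=30.0, max_effect=0.9),
            },
        ),
        CompoundProfile(
            "amantadine", "non_addictive", "uM", (0.03, 0.1, 0.3, 1, 3),
            acute={"background_rate": HillEffect(ec50=0.3, max_effect=1.15)},
        ),
        CompoundProfile(
            "acetaminophen", "non_addictive", "uM", (1, 3, 10, 30, 100),
            acute={"background_rate": HillEffect(ec50=30.0, max_effect=1.05)},
        ),
        CompoundProfile(
            "DMSO", "vehicle", "%", (0.2, 0.3, 0.4, 0.5, 0.6),
            # the solvent itself perturbs activity and burst timing; the 2SD
            # threshold is meant to absorb exactly this solvent-scale variation
            acute={
                "background_rate": HillEffect(ec50=0.4, max_effect=0.92),
                "nb_interval_mean": HillEffect(ec50=0.4, max_effect=0.88),
                "nb_duration_median": HillEffect(ec50=0.4, max_effect=0.93),
            },
        ),
    ]
    return StudyDesign(compounds=compounds, wells_per_compound=wells_per_compound, seed=seed)


def _lognormal_mult(rng: np.random.Generator, cv: float, size: int | None = None):
    """Multiplicative lognormal noise with mean 1."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(-(s**2) / 2.0, s, size)


_WELL_NOISE_KEYS = ("background_rate", "nb_interval_mean", "nb_duration_median", "nb_peak_rate")


def generate_study(design: StudyDesign) -> list[PlateRecording]:
    """Simulate every recording session of a study.

    Returns one :class:`PlateRecording` per phase × dose step (a 15-minute
    session of all wells at that step), 12 sessions for the default design.
    Per-well lognormal baseline multipliers are shared across all of a
    well's recordings (both phases, all doses); an independent smaller
    per-recording state fluctuation is applied on top.  Substreams:
    ``[seed, 1, ci, w]`` seeds well baselines and ``[seed, 2, ci, w, pi,
    d]`` seeds recording ``d`` of phase ``pi`` for well ``w`` of compound
    ``ci``.
    """
    seed = design.seed
    well_mults: dict[tuple[int, int], dict[str, float]] = {}
    for ci in range(len(design.compounds)):
        for w in range(design.wells_per_compound):
            rng = np.random.default_rng([seed, 1, ci, w])
            well_mults[(ci, w)] = {
                k: float(_lognormal_mult(rng, design.well_cv)) for k in _WELL_NOISE_KEYS
            }

    plates = []
    for pi, phase in enumerate(PHASES):
        for d in range(6):  # 0 = vehicle step, 1..5 = cumulative doses
            plate = PlateRecording(plate_id=f"{phase}_d{d}")
            for ci, profile in enumerate(design.compounds):
                conc = 0.0 if d == 0 else float(profile.concentrations[d - 1])
                for w in range(design.wells_per_compound):
                    base = design.baseline
                    wm = well_mults[(ci, w)]
                    base = replace(base, **{k: getattr(base, k) * wm[k] for k in wm})
                    params = apply_compound(base, profile, conc, phase)
                    rng = np.random.default_rng([seed, 2, ci, w, pi, d])
                    state = {
                        k: getattr(params, k) * float(_lognormal_mult(rng, design.state_cv))
                        for k in _WELL_NOISE_KEYS
                        if np.isfinite(getattr(params, k))
                    }
                    params = replace(params, **state)
                    meta = RecordingMeta(
                        well_id=f"{profile.name}_w{w:02d}",
                        compound=profile.name,
                        concentration=conc,
                        unit=profile.unit,
                        phase=phase,
                        recording_duration=design.recording_duration,
                    )
                    plate.add_well(generate_well(params, rng, meta=meta))
            plates.append(plate)
    return plates


# ---------------------------------------------------------------------------
# feature-level planted-effect generator
# ---------------------------------------------------------------------------


def planted_feature_table(
    seed: int,
    shift_params: Sequence[str] = TIMING_PARAMETERS,
    shift: float = 1.5,
    n_addictive: int = 5,
    n_non_addictive: int = 4,
    wells: int = 10,
    n_concentrations: int = 5,
    noise_cv: float = 0.12,
    acute_amp: float = 0.3,
) -> tuple[FeatureTable, dict[str, str]]:
    """Directly generate a vehicle-normalized feature table with a planted
    chronic effect.

    A fast stand-in for the spike-level pipeline used to calibrate the
    subset search: every value is 100 × (deterministic per-compound acute
    dose trend) × (lognormal noise, CV ``noise_cv``); addictive compounds
    are additionally multiplied by ``shift`` in the after-chronic phase,
    but only in the ``shift_params`` columns.  Returns the table and the
    compound → class label map (a DMSO vehicle is always included).
    """
    rng = np.random.default_rng(seed)
    names = (
        [f"addictive_{i}" for i in range(n_addictive)]
        + [f"non_addictive_{i}" for i in range(n_non_addictive)]
        + ["DMSO"]
    )
    labels = {
        n: ("addictive" if n.startswith("addictive") else "vehicle" if n == "DMSO" else "non_addictive")
        for n in names
    }
    concs = [float(c) for c in np.logspace(0, n_concentrations - 1, n_concentrations, base=3.0)]
    rows = []
    for name in names:
        # mild compound-specific acute dose-response trend per parameter
        amps = rng.uniform(-acute_amp, acute_amp, len(PARAMETERS))
        for w in range(wells):
            well_id = f"{name}_w{w:02d}"
            for phase in PHASES:
                for conc_idx, conc in enumerate([0.0] + concs):
                    row = {
                        "well": well_id,
                        "compound": name,
                        "concentration": conc,
                        "unit": "uM",
                        "phase": phase,
                    }
                    for j, p in enumerate(PARAMETERS):
                        if conc == 0.0:
                            row[p] = 100.0
                            continue
                        acute = 1.0 + amps[j] * conc_idx / n_concentrations
                        val = 100.0 * acute * float(_lognormal_mult(rng, noise_cv))
                        if labels[name] == "addictive" and phase == AFTER and p in shift_params:
                            val *= shift
                        row[p] = val
                    rows.append(row)
    table = FeatureTable(data=pd.DataFrame(rows), normalized=True)
    return table, labels


# ---------------------------------------------------------------------------
# design (de)serialisation
# ---------------------------------------------------------------------------


def design_to_yaml(design: StudyDesign, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "wells_per_compound": design.wells_per_compound,
        "recording_duration": design.recording_duration,
        "well_cv": design.well_cv,
        "state_cv": design.state_cv,
        "seed": design.seed,
        "baseline": {
            k: getattr(design.baseline, k)
            for k in (
                "background_rate", "nb_interval_mean", "nb_interval_shape",
                "nb_duration_median", "nb_duration_logsd", "nb_peak_rate",
                "n_electrodes", "participation",
            )
        },
        "compounds": [
            {
                "name": c.name,
                "label": c.label,
                "unit": c.unit,
                "concentrations": list(c.concentrations),
                "acute": {
                    k: {"ec50": e.ec50, "max_effect": e.max_effect, "slope": e.slope}
                    for k, e in c.acute.items()
                },
                "chronic_shift": dict(c.chronic_shift),
                "extinction_concentration": c.extinction_concentration,
            }
            for c in design.compounds
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def design_from_yaml(path: str | Path) -> StudyDesign:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    compounds = [
        CompoundProfile(
            name=c["name"],
            label=c["label"],
            unit=c["unit"],
            concentrations=tuple(float(x) for x in c["concentrations"]),
            acute={k: HillEffect(**e) for k, e in (c.get("acute") or {}).items()},
            chronic_shift={k: float(v) for k, v in (c.get("chronic_shift") or {}).items()},
            extinction_concentration=c.get("extinction_concentration"),
        )
        for c in d["compounds"]
    ]
    return StudyDesign(
        compounds=compounds,
        wells_per_compound=int(d.get("wells_per_compound", 10)),
        recording_duration=float(d.get("recording_duration", 900.0)),
        baseline=BurstProcessParams(**(d.get("baseline") or {})),
        well_cv=float(d.get("well_cv", 0.15)),
        state_cv=float(d.get("state_cv", 0.06)),
        seed=int(d.get("seed", 42)),
    )
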