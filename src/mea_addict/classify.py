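"""Chronic-shift classification on the PC1–PC2 plane.

Wells are projected with the selected PCA model; for every compound ×
concentration the Euclidean distance between the before- and after-chronic
centroids quantifies the chronic response.  The decision threshold is twice
the sample SD of the vehicle's (DMSO analogue) own before/after shift
distances — by default the per-well shift distances pooled over the
vehicle's concentrations, which places the threshold on the single-well
noise scale; the per-concentration centroid variant is available via
``threshold_mode``.  A centroid shift exceeding the threshold is called an
addiction-like response; a compound is called addiction-like when at least
one concentration responds, reported as "≥ lowest positive concentration"
(non-monotone positivity patterns are reported verbatim and flagged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bursts import FeatureTable, PARAMETERS
from .recording import AFTER, BEFORE
from .search import PCAModel
from .stats import manova_two_group

__all__ = [
    "CentroidPoint",
    "DetectionResult",
    "ClassificationReport",
    "project",
    "centroids",
    "chronic_shift_distance",
    "dmso_threshold",
    "classify",
]

logger = logging.getLogger(__name__)


@dataclass
class CentroidPoint:
    """Mean PC1/PC2 position of one compound × concentration × phase."""

    compound: str
    concentration: float
    unit: str
    phase: str
    PC1: float
    PC2: float
    n_wells: int


@dataclass
class DetectionResult:
    """Chronic-shift call for one compound × concentration."""

    compound: str
    concentration: float
    unit: str
    distance: float
    threshold: float
    addiction_like: bool
    manova_p: float = np.nan


@dataclass
class ClassificationReport:
    """Full study classification output."""

    detections: list[DetectionResult]
    threshold: float
    vehicle_compound: str
    threshold_mode: str
    compound_calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def detections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound": d.compound,
                    "concentration": d.concentration,
                    "unit": d.unit,
                    "distance": d.distance,
                    "threshold": d.threshold,
                    "addiction_like": d.addiction_like,
                    "manova_p": d.manova_p,
                }
                for d in self.detections
            ]
        )

    def write_csv(self, path: str | Path) -> Path:
        """Deterministic CSV export of the per-concentration detections."""
        path = Path(path)
        self.detections_frame().to_csv(path, index=False, float_format="%.10g")
        return path


def project(model: PCAModel, table: FeatureTable, n_components: int = 2) -> pd.DataFrame:
    """Project the table's dose rows onto the model's components.

    Rows with a missing value in any subset parameter are dropped (and
    logged); an all-dropped table is an error.  Returns the metadata
    columns plus PC1..PCn score columns.
    """
    df = table.dose_rows().reset_index(drop=True)
    cols = list(model.subset)
    complete = df[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("project: dropped %d incomplete rows", n_dropped)
    df = df[complete].reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete rows to project")
    scores = model.transform(df[cols].to_numpy(dtype=float), n_components=n_components)
    out = df[["well", "compound", "concentration", "unit", "phase"]].copy()
    for j in range(scores.shape[1]):
        out[f"PC{j + 1}"] = scores[:, j]
    return out


def centroids(scores: pd.DataFrame, min_wells: int = 1) -> list[CentroidPoint]:
    """Arithmetic-mean centroids per compound × concentration × phase."""
    pts = []
    for (comp, conc, unit, phase), grp in scores.groupby(
        ["compound", "concentration", "unit", "phase"], sort=True
    ):
        if len(grp) < min_wells:
            continue
        pts.append(
            CentroidPoint(
                compound=comp,
                concentration=float(conc),
                unit=unit,
                phase=phase,
                PC1=float(grp["PC1"].mean()),
                PC2=float(grp["PC2"].mean()),
                n_wells=len(grp),
            )
        )
    return pts


def chronic_shift_distance(before: CentroidPoint, after: CentroidPoint) -> float:
    """Euclidean PC1–PC2 distance between phase centroids of one group."""
    if before.compound != after.compound or before.concentration != after.concentration:
        raise ValueError("centroids must share compound and concentration")
    if before.phase == after.phase:
        raise ValueError("centroids must come from different phases")
    return float(np.hypot(before.PC1 - after.PC1, before.PC2 - after.PC2))


def dmso_threshold(dmso_distances: np.ndarray, k: float = 2.0) -> float:
    """Detection threshold: k × sample SD of the vehicle shift distances."""
    d = np.asarray(dmso_distances, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need at least 2 vehicle distances")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "vehicle shift distances have zero SD; threshold is 0 and every "
            "nonzero shift will be called addiction-like",
            stacklevel=2,
        )
    return k * sd


def _vehicle_distances(
    scores: pd.DataFrame, vehicle: str, mode: str, min_wells: int
) -> np.ndarray:
    veh = scores[scores["compound"] == vehicle]
    if veh.empty:
        raise ValueError(f"vehicle compound {vehicle!r} absent from scores")
    if mode == "per_concentration":
        pts = centroids(veh, min_wells=min_wells)
        by = {}
        for p in pts:
            by.setdefault(p.concentration, {})[p.phase] = p
        return np.array(
            [
                chronic_shift_distance(d[BEFORE], d[AFTER])
                for d in by.values()
                if BEFORE in d and AFTER in d
            ]
        )
    if mode != "per_well":
        raise ValueError(f"unknown threshold_mode {mode!r}")
    wide = veh.pivot_table(
        index=["well", "concentration"], columns="phase", values=["PC1", "PC2"]
    )
    need = [("PC1", BEFORE), ("PC1", AFTER), ("PC2", BEFORE), ("PC2", AFTER)]
    have = [c for c in need if c in wide.columns]
    if len(have) < 4:
        raise ValueError("vehicle wells lack paired before/after recordings")
    wide = wide.dropna(subset=need)
    return np.hypot(
        wide[("PC1", BEFORE)] - wide[("PC1", AFTER)],
        wide[("PC2", BEFORE)] - wide[("PC2", AFTER)],
    ).to_numpy()


def classify(
    table: FeatureTable,
    model: PCAModel,
    labels: Mapping[str, str] | None = None,
    vehicle_compound: str = "DMSO",
    k: float = 2.0,
    threshold_mode: str = "per_well",
    min_wells: int = 3,
) -> ClassificationReport:
    """Classify every compound × concentration as addiction-like or not.

    Projects the normalized table with ``model``, derives the threshold
    from the vehicle's own before/after shift distances, and compares each
    compound × concentration centroid shift against it.  Groups missing a
    phase (or with fewer than ``min_wells`` complete wells in a phase) are
    skipped and logged.  Also reports, per group, the two-group MANOVA p of
    before- vs after-phase scores when computable.
    """
    scores = project(model, table)
    thr = dmso_threshold(
        _vehicle_distances(scores, vehicle_compound, threshold_mode, min_wells), k=k
    )

    pts = centroids(scores, min_wells=min_wells)
    by_group: dict[tuple[str, float, str], dict[str, CentroidPoint]] = {}
    for p in pts:
        by_group.setdefault((p.compound, p.concentration, p.unit), {})[p.phase] = p

    detections: list[DetectionResult] = []
    for (comp, conc, unit), phases in sorted(by_group.items()):
        if BEFORE not in phases or AFTER not in phases:
            logger.info("classify: %s @ %g %s missing a phase; skipped", comp, conc, unit)
            continue
        dist = chronic_shift_distance(phases[BEFORE], phases[AFTER])
        grp = scores[
            (scores["compound"] == comp) & (scores["concentration"] == conc)
        ]
        a = grp.loc[grp["phase"] == BEFORE, ["PC1", "PC2"]].to_numpy()
        b = grp.loc[grp["phase"] == AFTER, ["PC1", "PC2"]].to_numpy()
        p_val = np.nan
        if len(a) >= 4 and len(b) >= 4:
            try:
                p_val = manova_two_group(a, b).pvalue
            except ValueError:
                pass
        detections.append(
            DetectionResult(
                compound=comp,
                concentration=conc,
                unit=unit,
                distance=dist,
                threshold=thr,
                addiction_like=bool(dist > thr),
                manova_p=p_val,
            )
        )

    calls = _compound_calls(detections, labels or {})
    return ClassificationReport(
        detections=detections,
        threshold=thr,
        vehicle_compound=vehicle_compound,
        threshold_mode=threshold_mode,
        compound_calls=calls,
    )


def _compound_calls(detections: list[DetectionResult], labels: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    by_comp: dict[str, list[DetectionResult]] = {}
    for d in detections:
        by_comp.setdefault(d.compound, []).append(d)
    for comp, ds in sorted(by_comp.items()):
        ds = sorted(ds, key=lambda d: d.concentration)
        positives = [d for d in ds if d.addiction_like]
        flags = [d.addiction_like for d in ds]
        # monotone = positives form a suffix of the concentration ladder
        first_true = flags.index(True) if any(flags) else len(flags)
        monotone = all(flags[first_true:])
        if positives:
            lowest = positives[0]
            summary = f">= {lowest.concentration:g} {lowest.unit}".strip()
        else:
            summary = "none"
        rows.append(
            {
                "compound": comp,
                "label": labels.get(comp, ""),
                "addiction_like": bool(positives),
                "n_positive": len(positives),
                "n_tested": len(ds),
                "lowest_positive": summary,
                "monotone": monotone,
            }
        )
    return pd.DataFrame(rows)
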