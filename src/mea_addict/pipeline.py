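"""End-to-end study runner: plates → features → subset search → detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .bursts import BurstDetectionConfig, FeatureTable, extract_features, normalize_to_vehicle
from .classify import ClassificationReport, classify
from .recording import PlateRecording
from .search import SearchResult, SelectionResult, search_subsets, select_parameter_set
from .simulate import StudyDesign, generate_study

__all__ = ["StudyResult", "run_study", "analyze_plates"]


@dataclass
class StudyResult:
    """Everything one full pipeline run produces."""

    features_raw: FeatureTable
    features: FeatureTable  # vehicle-normalized
    search: SearchResult
    selection: SelectionResult
    classification: ClassificationReport | None


def analyze_plates(
    plates: Iterable[PlateRecording],
    labels: dict[str, str],
    vehicle_compound: str = "DMSO",
    cfg: BurstDetectionConfig | None = None,
    alpha: float = 0.05,
    min_size: int = 2,
) -> StudyResult:
    """Run the full analysis on recorded (or simulated) plates.

    Extracts the 13 parameters per well per recording, normalizes to each
    well's vehicle step, searches all parameter subsets for the
    addictive-only phase-shift criterion, and — when a discriminating set
    exists — classifies every compound × concentration against the 2SD
    vehicle threshold.
    """
    raw = extract_features(plates, cfg=cfg)
    norm = normalize_to_vehicle(raw)
    search = search_subsets(norm, labels, min_size=min_size, alpha=alpha)
    selection = select_parameter_set(search, norm)
    report = None
    if selection.found:
        report = classify(norm, selection.model, labels, vehicle_compound=vehicle_compound)
    return StudyResult(
        features_raw=raw,
        features=norm,
        search=search,
        selection=selection,
        classification=report,
    )


def run_study(design: StudyDesign, cfg: BurstDetectionConfig | None = None) -> StudyResult:
    """Simulate a study from its design and analyze it end to end."""
    plates = generate_study(design)
    return analyze_plates(
        plates, design.labels, vehicle_compound=design.vehicle_name, cfg=cfg
    )
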