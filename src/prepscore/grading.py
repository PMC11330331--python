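"""Quantized error scoring, letter grades and the borderline-group cutoff.

Each of the seven readings is compared with its ideal value; every full
0.25 mm of deviation (over- or under-preparation alike) counts as one error
unit, and the tooth's raw error total is the sum over the seven readings.
For example a 2.00 mm wide distal isthmus against the 1.25 mm ideal is a
0.75 mm deviation and scores three error units, while an extension that
stops 0.25 mm short scores one.

Error totals map to a 0–100 score via a configurable per-error penalty
(default 2 points per error); the mapping from error counts to points is a
documented convention of this package, not a published rule, so
reproduction of any particular study's grade distribution is not claimed.
Letter bands: A 80–100, B 60–79.99, C 40–59.99, D 20–39.99, E below 20,
closed at their lower bound. Pass/fail uses the borderline-group cutoff
(mean score of examiner-designated borderline candidates; 44 by default),
with a score equal to the cutoff passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurement import MeasurementSet

__all__ = [
    "IdealSpec",
    "ErrorReport",
    "GradeRecord",
    "DEFAULT_CUTOFF",
    "error_units",
    "score_measurements",
    "errors_to_score",
    "letter_grade",
    "borderline_cutoff",
    "pass_fail",
    "grade_measurements",
]

#: Borderline-group pass/fail cutoff (mean score of the borderline group).
DEFAULT_CUTOFF = 44.0

#: Quantization guard: deviations within this of a unit boundary count the unit.
_EPS = 1e-9

LETTER_BANDS = (("A", 80.0), ("B", 60.0), ("C", 40.0), ("D", 20.0), ("E", 0.0))


@dataclass(frozen=True)
class IdealSpec:
    """Ideal prep geometry and the error quantization unit (all mm)."""

    ideal_depth: float = 1.50
    ideal_width: float = 1.25
    ideal_ridge_mesial: float = 2.0
    ideal_ridge_distal: float = 2.0
    error_unit: float = 0.25

    def __post_init__(self) -> None:
        for name in ("ideal_depth", "ideal_width", "ideal_ridge_mesial",
                     "ideal_ridge_distal", "error_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def ideal_for(self, reading_name: str) -> float:
        if reading_name.startswith("depth"):
            return self.ideal_depth
        if reading_name.startswith("width"):
            return self.ideal_width
        if reading_name == "ridge_mesial_remaining":
            return self.ideal_ridge_mesial
        if reading_name == "ridge_distal_remaining":
            return self.ideal_ridge_distal
        raise KeyError(reading_name)


@dataclass
class ErrorReport:
    """Signed deviations, per-reading error units, and their sum."""

    deviations: dict[str, float]
    units: dict[str, int]
    total_errors: int

    def __post_init__(self) -> None:
        if self.total_errors != sum(self.units.values()):
            raise ValueError("total_errors inconsistent with per-reading units")


@dataclass(frozen=True)
class GradeRecord:
    score_0_100: float
    letter: str
    passed: bool
    cutoff_used: float


def error_units(measured: float, ideal: float, unit: float = 0.25) -> int:
    """Number of whole ``unit``-sized steps in |measured − ideal|.

    floor(|dev|/unit + eps): a deviation of exactly one unit counts one
    error; anything short of a full unit counts none.
    """
    if unit <= 0:
        raise ValueError("unit must be positive")
    if not (np.isfinite(measured) and np.isfinite(ideal)):
        raise ValueError("non-finite measurement")
    return int(np.floor(abs(measured - ideal) / unit + _EPS))


def score_measurements(m: MeasurementSet, spec: IdealSpec | None = None) -> ErrorReport:
    """Quantize each of the seven readings against its ideal and sum."""
    spec = spec or IdealSpec()
    deviations: dict[str, float] = {}
    units: dict[str, int] = {}
    for name in MeasurementSet.READING_NAMES:
        measured = getattr(m, name)
        ideal = spec.ideal_for(name)
        deviations[name] = float(measured - ideal)
        units[name] = error_units(measured, ideal, spec.error_unit)
    return ErrorReport(deviations=deviations, units=units, total_errors=sum(units.values()))


def errors_to_score(total_errors: int, penalty_per_error: float = 2.0) -> float:
    """Map an error total to a 0–100 score: max(0, 100 − penalty × errors)."""
    if total_errors < 0:
        raise ValueError("total_errors must be >= 0")
    if penalty_per_error <= 0:
        raise ValueError("penalty_per_error must be > 0")
    return float(max(0.0, 100.0 - penalty_per_error * total_errors))


def letter_grade(score: float) -> str:
    """Letter band of a 0–100 score (bands closed at their lower bound)."""
    if not np.isfinite(score) or not (0.0 <= score <= 100.0):
        raise ValueError(f"score must be in [0, 100], got {score}")
    for letter, lower in LETTER_BANDS:
        if score >= lower:
            return letter
    return "E"  # unreachable; E's lower bound is 0


def borderline_cutoff(borderline_scores) -> float:
    """Pass/fail cutoff by the borderline-group method: the mean score of the
    candidates the examiners judged borderline."""
    scores = np.asarray(list(borderline_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("borderline group is empty")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite borderline score")
    return float(scores.mean())


def pass_fail(score: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Pass iff score >= cutoff (a score exactly at the cutoff passes)."""
    return bool(score >= cutoff)


def grade_measurements(
    m: MeasurementSet,
    spec: IdealSpec | None = None,
    penalty_per_error: float = 2.0,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[ErrorReport, GradeRecord]:
    """Full pipeline: readings → error units → score → letter → pass/fail."""
    report = score_measurements(m, spec)
    score = errors_to_score(report.total_errors, penalty_per_error)
    record = GradeRecord(
        score_0_100=score,
        letter=letter_grade(score),
        passed=pass_fail(score, cutoff),
        cutoff_used=cutoff,
    )
    return report, record
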