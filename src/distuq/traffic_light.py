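"""Traffic-light uncertainty categories and the two-step text report.

A case's distance to its nearest predicted-class training example is placed
against the training cohort's within-group distance distribution for that
class: at or below the green-upper percentile is GREEN (uncertainty low),
between the two thresholds AMBER (uncertainty medium — exercise caution),
above the amber-upper percentile RED (uncertainty high).  The (50, 75)
percentile pair is the documented illustration, not a universal default —
thresholds are context-dependent and should be tuned per model and clinic,
so the config is a mandatory argument everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distances import DistanceSummary
from .errors import ContractError
from .io import INDETERMINATE, CaseReport

GREEN, AMBER, RED = "GREEN", "AMBER", "RED"

PHRASES = {
    GREEN: "uncertainty low",
    AMBER: "uncertainty medium—exercise caution",
    RED: "uncertainty high",
}

#: What distance population the thresholds are percentiles of.
REFERENCES = ("within-group-distance", "uq-score")


@dataclass(frozen=True)
class TrafficLightConfig:
    """Percentile thresholds against the predicted class's training distances."""

    green_upper_percentile: float = 50.0
    amber_upper_percentile: float = 75.0
    reference: str = "within-group-distance"

    def __post_init__(self) -> None:
        if not 0.0 < self.green_upper_percentile < self.amber_upper_percentile < 100.0:
            raise ContractError(
                "require 0 < green_upper < amber_upper < 100, got "
                f"({self.green_upper_percentile}, {self.amber_upper_percentile})"
            )
        if self.reference not in REFERENCES:
            raise ContractError(f"unknown reference {self.reference!r}")


def categorize_value(
    value: float,
    green_upper_value: float,
    amber_upper_value: float,
) -> str:
    """Place a value against two upper-inclusive thresholds."""
    if value < 0 and not math.isinf(value):
        raise ContractError(f"value must be nonnegative, got {value}")
    if value <= green_upper_value:
        return GREEN
    if value <= amber_upper_value:
        return AMBER
    return RED


def categorize(
    distance_to_predicted_label: float,
    summary: DistanceSummary,
    predicted_label: str,
    config: TrafficLightConfig,
) -> str:
    """Traffic-light category for one case.

    The categorized quantity is the distance to the nearest training example
    of the predicted class, compared against percentiles of that class's
    within-group training distances.  Boundaries are upper-inclusive: a
    distance exactly at the green threshold is GREEN.
    """
    green_val = summary.percentile_value(predicted_label, config.green_upper_percentile)
    amber_val = summary.percentile_value(predicted_label, config.amber_upper_percentile)
    return categorize_value(distance_to_predicted_label, green_val, amber_val)


def categorize_against_population(
    value: float,
    population: np.ndarray,
    config: TrafficLightConfig,
) -> str:
    """Category for a value against an arbitrary reference population
    (e.g. training-set uncertainty scores in the uq-score mode)."""
    population = np.asarray(population, dtype=float)
    if population.size == 0:
        raise ContractError("empty reference population")
    green_val = float(np.percentile(population, config.green_upper_percentile, method="linear"))
    amber_val = float(np.percentile(population, config.amber_upper_percentile, method="linear"))
    return categorize_value(value, green_val, amber_val)


def _fmt(value: float) -> str:
    return "inf" if math.isinf(value) else f"{value:.2f}"


def render_two_step_report(report: CaseReport) -> str:
    """Human-readable two-step report for one case.

    Step 1 states the classifier's call and its probability; step 2 states
    the distance-based uncertainty evidence and the traffic-light phrase.
    """
    lines = [
        f"Case {report.case_id}",
        "Step 1 - Model prediction:",
        (
            f"  Predicted risk class: {report.predicted_class} "
            f"(probability of positive class: {report.probability_positive * 100:.0f}%)"
        ),
        "Step 2 - Uncertainty assessment:",
        (
            f"  Distance to nearest negative example: {_fmt(report.distance_to_nearest_negative)}; "
            f"to nearest positive example: {_fmt(report.distance_to_nearest_positive)}"
        ),
        (
            f"  UQ score (negative): {_fmt(report.uq_negative)}; "
            f"UQ score (positive): {_fmt(report.uq_positive)}"
        ),
    ]
    if report.final_class == INDETERMINATE:
        lines.append(
            "  Final risk class: INDETERMINATE (the two uncertainty scores tie exactly)"
        )
    else:
        lines.append(f"  Final risk class: {report.final_class}")
    if report.traffic_light is not None:
        lines.append(
            f"  Traffic light: {report.traffic_light} ({PHRASES[report.traffic_light]})"
        )
    if report.final_class not in (INDETERMINATE, report.predicted_class):
        lines.append(
            "  Note: the uncertainty-based final class disagrees with the "
            "classifier's prediction; review this case."
        )
    return "\n".join(lines) + "\n"
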