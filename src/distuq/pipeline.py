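"""End-to-end per-case scoring pipeline and run configuration.

``run_score`` chains the whole method for a batch of test cases: optional
feature scaling fitted on the training cohort, a positive-class probability
(supplied or fitted), the prevalence-calibrated class call, per-label
nearest-neighbour distances, the per-label uncertainty scores with the
argmin final class, and the traffic-light category.  Cases where the
classifier's call and the uncertainty-based final class disagree — the
cases the method exists to surface — are logged at WARNING, as are
flagged-infinite scores.  No test case is ever dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import distances, scoring, traffic_light
from .classifier import DecisionConfig, calibrate_threshold, fit_reference_classifier, predict_class
from .errors import ContractError, SchemaError
from .io import CaseRecord, CaseReport, LabeledCohort, apply_scaling, fit_scaling
from .traffic_light import TrafficLightConfig

logger = logging.getLogger("distuq")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of one scoring run.

    ``quantile_definition`` selects which within-group distance population
    (``all-pairs`` or ``nearest-only``) backs the summary and the
    traffic-light percentiles; it is always echoed in outputs.  When
    ``threshold`` is None the decision cut-off is calibrated to the
    training event rate.
    """

    metric_p: float = 1.0
    k: int = 1
    uq_variant: str = "opposite-label"
    scaling: str = "none"
    threshold: float | None = None
    quantile_definition: str = "all-pairs"
    traffic_light: TrafficLightConfig = field(default_factory=TrafficLightConfig)
    tie_break_with_prediction: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traffic_light"] = dataclasses.asdict(self.traffic_light)
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def run_summarize(
    cohort: LabeledCohort,
    config: RunConfig,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> distances.DistanceSummary:
    """Compute (and optionally export) the training-set distance summary."""
    cohort = fit_scaling(cohort, config.scaling)
    summary = distances.summarize_distances(
        cohort, config.quantile_definition, p=config.metric_p
    )
    distances.write_summary(summary, csv_path=csv_path, json_path=json_path)
    return summary


def _training_uq_scores(
    cohort: LabeledCohort, label: str, config: RunConfig
) -> np.ndarray:
    """Leave-one-out uncertainty scores of the training members of ``label``
    for their own label — the reference population of the uq-score
    traffic-light mode."""
    scores = []
    for case in cohort.members(label):
        nd = distances.neighbor_distances(case, cohort, k=config.k, p=config.metric_p)
        result = scoring.score_case(nd, config.uq_variant, cohort.label_names)
        scores.append(result.uq_negative if label == cohort.negative_label
                      else result.uq_positive)
    return np.array(scores)


def run_score(
    train: LabeledCohort,
    test_cases: Sequence[CaseRecord],
    config: RunConfig,
    probabilities: Mapping[str, float] | None = None,
) -> list[CaseReport]:
    """Score every test case against the training cohort.

    ``probabilities`` maps case_id to a precomputed positive-class
    probability; when absent, the reference logistic classifier is fitted on
    the training cohort.  Every input case yields exactly one report.
    """
    if not test_cases:
        raise ContractError("no test cases supplied")
    for case in test_cases:
        if case.feature_names != train.feature_names:
            raise SchemaError(
                f"case {case.case_id!r} features {case.feature_names} do not "
                f"match training features {train.feature_names}"
            )

    train = fit_scaling(train, config.scaling)
    test_cases = apply_scaling(test_cases, train.feature_scaling)

    if config.threshold is not None:
        decision = DecisionConfig(
            threshold=config.threshold,
            calibration_rule="fixed",
            positive_label=train.positive_label,
        )
    else:
        decision = calibrate_threshold(train.labels(), train.positive_label)

    if probabilities is None:
        model = fit_reference_classifier(train, seed=config.seed)
        prob_of = {c.case_id: model.predict_proba(c) for c in test_cases}
    else:
        missing = [c.case_id for c in test_cases if c.case_id not in probabilities]
        if missing:
            raise ContractError(f"no probability supplied for cases {missing}")
        prob_of = {c.case_id: float(probabilities[c.case_id]) for c in test_cases}

    summary = distances.summarize_distances(
        train, config.quantile_definition, p=config.metric_p
    )
    uq_populations: dict[str, np.ndarray] | None = None
    if config.traffic_light.reference == "uq-score":
        uq_populations = {
            label: _training_uq_scores(train, label, config)
            for label in train.label_names
        }

    reports = []
    for case in test_cases:
        predicted = predict_class(prob_of[case.case_id], decision, train.negative_label)
        nd = distances.neighbor_distances(case, train, k=config.k, p=config.metric_p)
        result = scoring.score_case(nd, config.uq_variant, train.label_names)
        final = result.final_class
        if final == scoring.INDETERMINATE and config.tie_break_with_prediction:
            final = predicted

        if config.traffic_light.reference == "uq-score":
            own_score = (result.uq_negative if predicted == train.negative_label
                         else result.uq_positive)
            category = traffic_light.categorize_against_population(
                own_score, uq_populations[predicted], config.traffic_light
            )
        else:
            d_pred = (nd.d_negative if predicted == train.negative_label
                      else nd.d_positive)
            category = traffic_light.categorize(
                d_pred, summary, predicted, config.traffic_light
            )

        if math.isinf(result.uq_negative) or math.isinf(result.uq_positive):
            logger.warning(
                "case %s: flagged-infinite UQ score (case coincides with an "
                "opposite-label training example)", case.case_id
            )
        if final not in (predicted, scoring.INDETERMINATE):
            logger.warning(
                "case %s: classifier predicts %s but the UQ final class is %s",
                case.case_id, predicted, final,
            )

        reports.append(CaseReport(
            case_id=case.case_id,
            predicted_class=predicted,
            probability_positive=prob_of[case.case_id],
            distance_to_nearest_negative=nd.d_negative,
            distance_to_nearest_positive=nd.d_positive,
            uq_negative=result.uq_negative,
            uq_positive=result.uq_positive,
            final_class=final,
            traffic_light=category,
        ))
    return reports
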