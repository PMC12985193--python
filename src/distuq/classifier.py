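"""Binary probabilistic classifier contract and prevalence-calibrated threshold.

The UQ layer is classifier-agnostic: any map from feature vector to a
positive-class probability will do, and users may supply precomputed
probabilities, bypassing fitting entirely.  What this module pins down is
the decision rule — in imbalanced cohorts a 0.5 cut-off systematically
under-calls the minority class, so the threshold can instead be calibrated
to the positive-class event rate of the training labels (e.g. a cohort with
36% high-risk cases yields a cut-off of 0.36).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError
from .io import CaseRecord, LabeledCohort

CALIBRATION_RULES = ("event-rate", "fixed")


@dataclass(frozen=True)
class DecisionConfig:
    """Probability cut-off for calling the positive (high-risk) class."""

    threshold: float
    calibration_rule: str = "fixed"
    positive_label: str = "HR"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ContractError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.calibration_rule not in CALIBRATION_RULES:
            raise ContractError(f"unknown calibration rule {self.calibration_rule!r}")


def calibrate_threshold(
    labels: Sequence[str],
    positive_label: str = "HR",
) -> DecisionConfig:
    """Event-rate calibration: threshold = positive-class fraction of labels."""
    labels = list(labels)
    if not labels:
        raise ContractError("empty label list")
    n_pos = sum(1 for lab in labels if lab == positive_label)
    if n_pos == 0 or n_pos == len(labels):
        raise ContractError(
            f"labels contain a single class ({n_pos}/{len(labels)} positive); "
            "event-rate calibration needs both classes"
        )
    return DecisionConfig(
        threshold=n_pos / len(labels),
        calibration_rule="event-rate",
        positive_label=positive_label,
    )


def predict_class(
    probability_positive: float,
    config: DecisionConfig,
    negative_label: str = "LR",
) -> str:
    """Apply the cut-off; the boundary is inclusive on the positive side."""
    if not 0.0 <= probability_positive <= 1.0:
        raise ContractError(f"probability {probability_positive} outside [0, 1]")
    if probability_positive >= config.threshold:
        return config.positive_label
    return negative_label


class ReferenceClassifier:
    """A fitted linear-in-features logistic model returning P(positive).

    A deterministic reference implementation of the classifier contract,
    intended for demonstrations and synthetic scenarios; any external
    probability source satisfies the same contract.
    """

    def __init__(self, model, feature_names: tuple[str, ...], label_names: tuple[str, str]):
        self._model = model
        self.feature_names = feature_names
        self.label_names = label_names

    def predict_proba(self, case: CaseRecord | Mapping[str, float]) -> float:
        if isinstance(case, CaseRecord):
            if case.feature_names != self.feature_names:
                raise ContractError(
                    f"case {case.case_id!r} features do not match the fitted model"
                )
            x = case.vector()
        else:
            x = np.array([case[n] for n in self.feature_names], dtype=float)
        return float(self._model.predict_proba(x[None, :])[0, 1])

    def predict_proba_many(self, cases: Iterable[CaseRecord]) -> list[float]:
        return [self.predict_proba(c) for c in cases]


def fit_reference_classifier(
    cohort: LabeledCohort,
    seed: int = 0,
) -> ReferenceClassifier:
    """Fit the reference logistic regression on a labelled cohort.

    The fit is deterministic: identical input and seed give identical
    probabilities.  Constant features are rejected — the log-odds fit is
    unidentifiable in that direction.
    """
    from sklearn.linear_model import LogisticRegression

    for label in cohort.label_names:
        if len(cohort.members(label)) < 2:
            raise ContractError(f"label {label!r} needs >= 2 cases to fit a classifier")
    X = cohort.matrix()
    if np.any(X.std(axis=0) == 0.0):
        constant = [n for n, s in zip(cohort.feature_names, X.std(axis=0)) if s == 0.0]
        raise ContractError(f"degenerate constant features {constant}")
    y = np.array([1 if lab == cohort.positive_label else 0 for lab in cohort.labels()])
    model = LogisticRegression(random_state=seed, max_iter=1000)
    model.fit(X, y)
    return ReferenceClassifier(model, cohort.feature_names, cohort.label_names)
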