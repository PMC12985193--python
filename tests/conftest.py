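from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from distuq import CaseRecord, LabeledCohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_random_cohort(
    rng: np.random.Generator,
    n_cases: int = 20,
    n_features: int = 3,
    label_names: tuple[str, str] = ("LR", "HR"),
) -> LabeledCohort:
    """A random labelled cohort with at least three members per label."""
    assert n_cases >= 6
    labels = list(label_names) * 3
    labels += [label_names[int(rng.integers(2))] for _ in range(n_cases - 6)]
    X = rng.normal(scale=float(rng.uniform(0.5, 3.0)), size=(n_cases, n_features))
    names = [f"f{i}" for i in range(n_features)]
    cases = [
        CaseRecord(
            case_id=f"c{i:03d}",
            features=dict(zip(names, map(float, X[i]))),
            true_label=labels[i],
        )
        for i in range(n_cases)
    ]
    return LabeledCohort(cases=tuple(cases), label_names=label_names)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def small_cohort() -> LabeledCohort:
    """Hand-placed 2-feature cohort with distances checkable by hand.

    LR cases sit near the origin, HR cases near (3, 3).
    """
    points = {
        "LR": [(0.0, 0.0), (0.5, 0.0), (0.0, 1.0)],
        "HR": [(3.0, 3.0), (3.5, 3.0), (3.0, 4.0)],
    }
    cases = []
    for label, coords in points.items():
        for i, (x1, x2) in enumerate(coords):
            cases.append(CaseRecord(
                case_id=f"{label}{i}",
                features={"f1": x1, "f2": x2},
                true_label=label,
            ))
    return LabeledCohort(cases=tuple(cases))
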