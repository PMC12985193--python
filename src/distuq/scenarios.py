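"""Seeded synthetic cohort generator for two-class feature-space scenarios.

Real radiomics cohorts are rarely shareable, so every regime the distance
diagnostics are meant to distinguish is reproduced synthetically:

* ``EVEN_COVERAGE`` — both classes share the same within-class spread, so
  the two within-group median distances agree: the feature space is covered
  evenly and nearest-neighbour distances carry little class-specific signal.
* ``CLUSTERED_NEG_SPARSE_POS`` — the negative class forms a tight cluster
  while the positive class is dispersed; the positive class leaves empty
  feature space around its members.
* ``TWO_SEPARATED_CLUSTERS`` — two equally tight clusters far apart, with
  empty space between them: inter-group nearest distances dominate both
  intra-group means.
* ``NONLINEAR_BOUNDARY`` — two interleaved half-moon arcs, where no straight
  decision boundary separates the classes.

Default class sizes are 85 negative / 47 positive (a realistic imbalanced
single-centre rare-tumour cohort scale).  Generation is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import nearest_label_distance, within_group_quantiles
from .errors import ContractError
from .io import CaseRecord, LabeledCohort

SCENARIO_KINDS = (
    "EVEN_COVERAGE",
    "CLUSTERED_NEG_SPARSE_POS",
    "TWO_SEPARATED_CLUSTERS",
    "NONLINEAR_BOUNDARY",
)

BOUNDARY_CASE_KINDS = ("IN_CLUSTER", "NEAR_BOUNDARY", "OUTLIER_EMPTY_SPACE")

#: Per-scenario default (negative, positive) cluster centre offsets and spreads.
_SCENARIO_DEFAULTS = {
    "EVEN_COVERAGE": {"centers": (0.0, 1.5), "spreads": (1.0, 1.0)},
    "CLUSTERED_NEG_SPARSE_POS": {"centers": (0.0, 1.5), "spreads": (0.3, 1.2)},
    "TWO_SEPARATED_CLUSTERS": {"centers": (0.0, 8.0), "spreads": (0.4, 0.4)},
}

#: Construction tolerance for NEAR_BOUNDARY cases: relative per-label
#: distance imbalance |d_neg - d_pos| / max(d_neg, d_pos) stays below this.
NEAR_BOUNDARY_TOLERANCE = 0.05


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic two-class cohort."""

    scenario_kind: str
    n_negative: int = 85
    n_positive: int = 47
    n_features: int = 2
    centers: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    spreads: tuple[float, float] | None = None
    noise_family: str = "gaussian"
    label_names: tuple[str, str] = ("LR", "HR")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_kind not in SCENARIO_KINDS:
            raise ContractError(
                f"unknown scenario {self.scenario_kind!r}; choose from {SCENARIO_KINDS}"
            )
        if self.n_negative < 2 or self.n_positive < 2:
            raise ContractError("need >= 2 cases per label")
        if self.n_features < 1:
            raise ContractError("n_features must be >= 1")
        if self.noise_family not in ("gaussian", "uniform"):
            raise ContractError(f"unknown noise family {self.noise_family!r}")
        if self.scenario_kind == "NONLINEAR_BOUNDARY" and self.n_features != 2:
            raise ContractError("NONLINEAR_BOUNDARY is a 2-feature scenario")
        if self.spreads is not None and any(s <= 0 for s in self.spreads):
            raise ContractError("spreads must be positive")
        if self.centers is not None and any(
            len(c) != self.n_features for c in self.centers
        ):
            raise ContractError("each center must have n_features coordinates")

    def resolved_centers(self) -> tuple[np.ndarray, np.ndarray]:
        if self.centers is not None:
            return tuple(np.asarray(c, dtype=float) for c in self.centers)  # type: ignore[return-value]
        offsets = _SCENARIO_DEFAULTS[self.scenario_kind]["centers"]
        return tuple(np.full(self.n_features, o) for o in offsets)  # type: ignore[return-value]

    def resolved_spreads(self) -> tuple[float, float]:
        if self.spreads is not None:
            return self.spreads
        return _SCENARIO_DEFAULTS[self.scenario_kind]["spreads"]  # type: ignore[return-value]


def _cluster_noise(rng: np.random.Generator, n: int, dim: int,
                   spread: float, family: str) -> np.ndarray:
    if family == "gaussian":
        return rng.normal(0.0, spread, size=(n, dim))
    # uniform: same per-coordinate standard deviation as the gaussian family
    half_width = spread * np.sqrt(3.0)
    return rng.uniform(-half_width, half_width, size=(n, dim))


def generate_cohort(spec: ScenarioSpec) -> LabeledCohort:
    """Generate a labelled cohort realizing the spec's scenario."""
    rng = np.random.default_rng(spec.seed)
    neg_name, pos_name = spec.label_names
    feature_names = [f"f{i + 1}" for i in range(spec.n_features)]

    if spec.scenario_kind == "NONLINEAR_BOUNDARY":
        from sklearn.datasets import make_moons

        X, y = make_moons(
            n_samples=(spec.n_negative, spec.n_positive),
            noise=(spec.spreads[0] if spec.spreads else 0.15),
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        neg_points = X[y == 0]
        pos_points = X[y == 1]
    else:
        centers = spec.resolved_centers()
        spreads = spec.resolved_spreads()
        neg_points = centers[0] + _cluster_noise(
            rng, spec.n_negative, spec.n_features, spreads[0], spec.noise_family
        )
        pos_points = centers[1] + _cluster_noise(
            rng, spec.n_positive, spec.n_features, spreads[1], spec.noise_family
        )

    cases = []
    for label, points in ((neg_name, neg_points), (pos_name, pos_points)):
        for i, row in enumerate(points):
            cases.append(CaseRecord(
                case_id=f"{label}-{i + 1:03d}",
                features=dict(zip(feature_names, (float(v) for v in row))),
                true_label=label,
            ))
    return LabeledCohort(cases=tuple(cases), label_names=spec.label_names)


def _max_within_group_distance(cohort: LabeledCohort, p: float = 1.0) -> float:
    return max(
        within_group_quantiles(cohort, label, "all-pairs", p=p).maximum
        for label in cohort.label_names
    )


def _bisect_equidistant(
    start: np.ndarray, end: np.ndarray, cohort: LabeledCohort,
    feature_names: Sequence[str], p: float = 1.0,
) -> np.ndarray:
    """Point on the segment [start, end] whose nearest-negative and
    nearest-positive distances (against the cohort) agree.

    ``start`` sits in negative territory and ``end`` in positive territory,
    so the signed gap d_neg - d_pos changes sign along the segment; plain
    bisection converges to machine precision in ~60 steps."""
    def gap(t: float) -> float:
        point = start + t * (end - start)
        probe = CaseRecord("probe", dict(zip(feature_names, (float(v) for v in point))))
        d_neg = nearest_label_distance(probe, cohort, cohort.negative_label, p=p)
        d_pos = nearest_label_distance(probe, cohort, cohort.positive_label, p=p)
        return d_neg - d_pos

    lo, hi = 0.0, 1.0
    if gap(lo) > 0 or gap(hi) < 0:  # segment endpoints not in their territory
        lo, hi = hi, lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return start + 0.5 * (lo + hi) * (end - start)


def generate_boundary_cases(
    cohort: LabeledCohort,
    kind: str,
    n: int,
    seed: int = 0,
) -> list[CaseRecord]:
    """Generate unlabelled test cases in a chosen relation to the cohort.

    * ``IN_CLUSTER`` — small jitter around a random training case, staying
      inside that label's cluster (low uncertainty expected).
    * ``NEAR_BOUNDARY`` — on the segment between a random negative and a
      random positive training case, bisected until the two per-label
      nearest distances agree within ``NEAR_BOUNDARY_TOLERANCE``.
    * ``OUTLIER_EMPTY_SPACE`` — beyond the cohort in a random direction, far
      enough that the distance to every training case exceeds the cohort's
      maximum within-group distance.
    """
    if kind not in BOUNDARY_CASE_KINDS:
        raise ContractError(f"unknown case kind {kind!r}; choose from {BOUNDARY_CASE_KINDS}")
    if n <= 0:
        raise ContractError("n must be positive")
    rng = np.random.default_rng(seed)
    names = cohort.feature_names
    dim = len(names)
    neg = cohort.matrix(cohort.negative_label)
    pos = cohort.matrix(cohort.positive_label)

    points: list[np.ndarray] = []
    if kind == "IN_CLUSTER":
        local_scale = {
            label: within_group_quantiles(cohort, label, "nearest-only").median
            if len(cohort.members(label)) >= 2 else 0.1
            for label in cohort.label_names
        }
        all_cases = cohort.cases
        for _ in range(n):
            anchor = all_cases[rng.integers(len(all_cases))]
            jitter = rng.normal(0.0, 0.25 * local_scale[anchor.true_label] / dim, size=dim)
            points.append(anchor.vector() + jitter)
    elif kind == "NEAR_BOUNDARY":
        for _ in range(n):
            a = neg[rng.integers(len(neg))]
            b = pos[rng.integers(len(pos))]
            points.append(_bisect_equidistant(a, b, cohort, names))
    else:  # OUTLIER_EMPTY_SPACE
        X = cohort.matrix()
        centroid = X.mean(axis=0)
        max_within = _max_within_group_distance(cohort)
        for _ in range(n):
            direction = rng.normal(size=dim)
            direction /= np.abs(direction).sum()  # unit L1 length
            radius = float(np.abs(X - centroid).sum(axis=1).max()) + max_within + 1.0
            candidate = centroid + radius * direction
            while np.abs(X - candidate).sum(axis=1).min() <= max_within:
                radius *= 2.0
                candidate = centroid + radius * direction
            points.append(candidate)

    return [
        CaseRecord(
            case_id=f"{kind}-{i + 1:03d}",
            features=dict(zip(names, (float(v) for v in point))),
        )
        for i, point in enumerate(points)
    ]
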