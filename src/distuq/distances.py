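"""Manhattan / Minkowski distances, per-label nearest neighbours, summaries.

All distances are computed in the cohort's feature space with the Minkowski
p-metric; p = 1 (Manhattan, the sum of absolute coordinate differences) is
the default throughout.  Cohorts here are small (order 10^2 cases), so every
operation is exact brute force over :func:`scipy.spatial.distance` matrices —
no approximate indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd

from .errors import ContractError
from .io import CaseRecord, LabeledCohort

PAIRWISE_DEFINITIONS = ("all-pairs", "nearest-only")


@dataclass(frozen=True)
class NeighborDistances:
    """Per-label distance from one case to its nearest training examples.

    With k = 1 each field is the distance to the single nearest training
    case of that label; with k > 1 it is the arithmetic mean of the k
    smallest such distances.
    """

    case_id: str
    d_negative: float
    d_positive: float
    k: int = 1

    def __post_init__(self) -> None:
        if self.d_negative < 0 or self.d_positive < 0:
            raise ContractError("neighbour distances must be nonnegative")
        if self.k < 1:
            raise ContractError("k must be a positive integer")


@dataclass(frozen=True)
class GroupQuantiles:
    """Five-number summary (min, 25%, median, 75%, max) of a distance set."""

    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float

    def __post_init__(self) -> None:
        ordered = (self.minimum, self.q25, self.median, self.q75, self.maximum)
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            raise ContractError(f"quantiles out of order: {ordered}")

    def at_percentile(self, p: float) -> float:
        """Value at one of the stored grid percentiles {0, 25, 50, 75, 100}."""
        grid = {0.0: self.minimum, 25.0: self.q25, 50.0: self.median,
                75.0: self.q75, 100.0: self.maximum}
        if float(p) not in grid:
            raise ContractError(
                f"percentile {p} unavailable; stored grid is (0, 25, 50, 75, 100)"
            )
        return grid[float(p)]

    @classmethod
    def from_population(cls, values: np.ndarray) -> "GroupQuantiles":
        q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
        return cls(*(float(v) for v in q))


@dataclass(frozen=True)
class DistanceSummary:
    """Training-set distance summary: within-group quantiles per label plus
    the directed mean nearest-distance matrix over ordered label pairs.

    The directed means use each source member's distance to its *nearest*
    target-group member, so the matrix need not be symmetric: a tight
    cluster is near to a sparse one even when the reverse is false.
    ``populations`` retains the raw within-group distance values so that
    off-grid percentiles can be evaluated downstream.
    """

    label_names: tuple[str, str]
    quantiles: dict[str, GroupQuantiles]
    directed_means: dict[tuple[str, str], float]
    pairwise_definition: str
    metric_p: float = 1.0
    populations: dict[str, np.ndarray] | None = None

    def percentile_value(self, label: str, p: float) -> float:
        """Within-group distance value at percentile ``p`` for ``label``.

        Uses the retained raw population (linear interpolation) when
        available, otherwise falls back to the stored quantile grid.
        """
        if label not in self.quantiles:
            raise ContractError(f"no quantiles for label {label!r}")
        if not 0.0 <= p <= 100.0:
            raise ContractError(f"percentile {p} outside [0, 100]")
        if self.populations is not None and label in self.populations:
            return float(np.percentile(self.populations[label], p, method="linear"))
        return self.quantiles[label].at_percentile(p)


def _vector(case: CaseRecord | Mapping[str, float]) -> tuple[tuple[str, ...], np.ndarray]:
    if isinstance(case, CaseRecord):
        return case.feature_names, case.vector()
    names = tuple(case)
    return names, np.array([case[n] for n in names], dtype=float)


def minkowski_distance(
    u: CaseRecord | Mapping[str, float],
    v: CaseRecord | Mapping[str, float],
    p: float = 1.0,
) -> float:
    """Minkowski p-distance between two feature vectors (p >= 1)."""
    if p < 1:
        raise ContractError(f"Minkowski order must be >= 1, got {p}")
    names_u, x = _vector(u)
    names_v, y = _vector(v)
    if names_u != names_v:
        raise ContractError(
            f"mismatched feature sets: {names_u} vs {names_v}"
        )
    return float(ssd.minkowski(x, y, p=p))


def manhattan_distance(
    u: CaseRecord | Mapping[str, float],
    v: CaseRecord | Mapping[str, float],
) -> float:
    """Manhattan (L1) distance: sum over features of |u_i - v_i|."""
    return minkowski_distance(u, v, p=1.0)


def _distances_to_members(
    case: CaseRecord,
    cohort: LabeledCohort,
    label: str,
    p: float,
) -> np.ndarray:
    """Distances from ``case`` to every cohort member with ``label``,
    excluding the case itself (matched by case_id) if it is a member."""
    members = [m for m in cohort.members(label) if m.case_id != case.case_id]
    if case.feature_names != cohort.feature_names:
        raise ContractError(
            f"case {case.case_id!r} features {case.feature_names} do not match "
            f"cohort features {cohort.feature_names}"
        )
    if not members:
        return np.empty(0)
    M = np.array([m.vector() for m in members], dtype=float)
    return ssd.cdist(case.vector()[None, :], M, metric="minkowski", p=p)[0]


def nearest_label_distance(
    case: CaseRecord,
    cohort: LabeledCohort,
    label: str,
    k: int = 1,
    p: float = 1.0,
) -> float:
    """Distance to the nearest training case of ``label`` (mean of k nearest).

    k = 1 gives the plain nearest-neighbour distance of the base metric;
    k > 1 averages the k smallest distances, damping the influence of a
    single atypical training example.
    """
    if k < 1:
        raise ContractError("k must be a positive integer")
    d = _distances_to_members(case, cohort, label, p)
    if d.size < k:
        raise ContractError(
            f"label {label!r} has {d.size} usable members, fewer than k={k}"
        )
    return float(np.mean(np.sort(d)[:k]))


def neighbor_distances(
    case: CaseRecord,
    cohort: LabeledCohort,
    k: int = 1,
    p: float = 1.0,
) -> NeighborDistances:
    """Per-label nearest-neighbour distances for one case."""
    return NeighborDistances(
        case_id=case.case_id,
        d_negative=nearest_label_distance(case, cohort, cohort.negative_label, k=k, p=p),
        d_positive=nearest_label_distance(case, cohort, cohort.positive_label, k=k, p=p),
        k=k,
    )


def _within_group_population(
    cohort: LabeledCohort, label: str, definition: str, p: float
) -> np.ndarray:
    members = cohort.members(label)
    if len(members) < 2:
        raise ContractError(f"label {label!r} has {len(members)} members; need >= 2")
    X = np.array([m.vector() for m in members], dtype=float)
    if definition == "all-pairs":
        return ssd.pdist(X, metric="minkowski", p=p)
    if definition == "nearest-only":
        D = ssd.squareform(ssd.pdist(X, metric="minkowski", p=p))
        np.fill_diagonal(D, np.inf)
        return D.min(axis=1)
    raise ContractError(
        f"unknown pairwise definition {definition!r}; choose from {PAIRWISE_DEFINITIONS}"
    )


def within_group_quantiles(
    cohort: LabeledCohort,
    label: str,
    definition: str,
    p: float = 1.0,
) -> GroupQuantiles:
    """Five-number summary of within-group distances for one label.

    ``definition`` selects the distance population and is deliberately a
    required argument: ``all-pairs`` uses every unordered within-label pair
    once; ``nearest-only`` uses each member's distance to its nearest
    same-label neighbour (self excluded).  The two populations answer
    different questions (overall spread vs local density) and can differ
    by an order of magnitude on clustered data.
    """
    return GroupQuantiles.from_population(
        _within_group_population(cohort, label, definition, p)
    )


def mean_nearest_cross_distance(
    cohort: LabeledCohort,
    from_label: str,
    to_label: str,
    p: float = 1.0,
) -> float:
    """Mean over ``from_label`` members of the distance to the nearest
    ``to_label`` member (self excluded when the labels coincide).

    Directed: A -> B averages over A's members, B -> A over B's, so the two
    directions generally differ.
    """
    sources = cohort.members(from_label)
    targets = cohort.members(to_label)
    if from_label == to_label:
        if len(sources) < 2:
            raise ContractError(f"label {from_label!r} needs >= 2 members for intra-group means")
        X = np.array([m.vector() for m in sources], dtype=float)
        D = ssd.squareform(ssd.pdist(X, metric="minkowski", p=p))
        np.fill_diagonal(D, np.inf)
        return float(D.min(axis=1).mean())
    if not targets:
        raise ContractError(f"target group {to_label!r} is empty")
    S = np.array([m.vector() for m in sources], dtype=float)
    T = np.array([m.vector() for m in targets], dtype=float)
    D = ssd.cdist(S, T, metric="minkowski", p=p)
    return float(D.min(axis=1).mean())


def summarize_distances(
    cohort: LabeledCohort,
    definition: str,
    p: float = 1.0,
) -> DistanceSummary:
    """Full training-set distance summary: per-label within-group quantiles
    plus the four directed mean nearest distances."""
    neg, pos = cohort.label_names
    populations = {
        label: _within_group_population(cohort, label, definition, p)
        for label in (neg, pos)
    }
    quantiles = {
        label: GroupQuantiles.from_population(populations[label])
        for label in (neg, pos)
    }
    directed = {
        (a, b): mean_nearest_cross_distance(cohort, a, b, p=p)
        for a in (neg, pos)
        for b in (neg, pos)
    }
    return DistanceSummary(
        label_names=cohort.label_names,
        quantiles=quantiles,
        directed_means=directed,
        pairwise_definition=definition,
        metric_p=p,
        populations=populations,
    )


def summary_to_frame(summary: DistanceSummary) -> pd.DataFrame:
    """Summary as a table: five quantile rows per label plus the four
    directed mean nearest-distance rows."""
    neg, pos = summary.label_names
    rows = []
    for stat, attr in (("min", "minimum"), ("25%", "q25"), ("50% (median)", "median"),
                       ("75%", "q75"), ("max", "maximum")):
        rows.append({
            "section": "within-group distance distribution",
            "metric": stat,
            neg: getattr(summary.quantiles[neg], attr),
            pos: getattr(summary.quantiles[pos], attr),
        })
    for a, b in ((neg, neg), (neg, pos), (pos, neg), (pos, pos)):
        kind = "intra" if a == b else "inter"
        rows.append({
            "section": "mean nearest intra-/inter-group distances",
            "metric": f"{a} -> {b} ({kind}-group)",
            neg: summary.directed_means[(a, b)] if b == neg else np.nan,
            pos: summary.directed_means[(a, b)] if b == pos else np.nan,
        })
    return pd.DataFrame(rows)


def write_summary(summary: DistanceSummary, csv_path: str | Path | None = None,
                  json_path: str | Path | None = None) -> None:
    """Export a summary as CSV (table-shaped) and/or JSON."""
    if csv_path is not None:
        summary_to_frame(summary).to_csv(csv_path, index=False)
    if json_path is not None:
        neg, pos = summary.label_names
        payload = {
            "label_names": list(summary.label_names),
            "pairwise_definition": summary.pairwise_definition,
            "metric_p": summary.metric_p,
            "quantiles": {
                label: {
                    "min": q.minimum, "q25": q.q25, "median": q.median,
                    "q75": q.q75, "max": q.maximum,
                }
                for label, q in summary.quantiles.items()
            },
            "directed_mean_nearest": {
                f"{a}->{b}": v for (a, b), v in summary.directed_means.items()
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
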