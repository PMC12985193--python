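"""Independent brute-force reference implementations used only by tests.

Everything here is pure-Python loops over feature dicts — deliberately
sharing no code path with the package's scipy-based implementations.
"""

from __future__ import annotations

import numpy as np


def manhattan(u: dict[str, float], v: dict[str, float]) -> float:
    return sum(abs(u[name] - v[name]) for name in u)


def minkowski(u: dict[str, float], v: dict[str, float], p: float) -> float:
    return sum(abs(u[name] - v[name]) ** p for name in u) ** (1.0 / p)


def nearest_label_distance(case, cohort, label, k=1, p=1.0) -> float:
    dists = sorted(
        minkowski(case.features, member.features, p)
        for member in cohort.members(label)
        if member.case_id != case.case_id
    )
    return float(np.mean(dists[:k]))


def all_pairs_population(cohort, label, p=1.0) -> list[float]:
    members = cohort.members(label)
    return [
        minkowski(members[i].features, members[j].features, p)
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]


def nearest_only_population(cohort, label, p=1.0) -> list[float]:
    members = cohort.members(label)
    return [
        min(
            minkowski(a.features, b.features, p)
            for b in members if b.case_id != a.case_id
        )
        for a in members
    ]


def mean_nearest_cross(cohort, from_label, to_label, p=1.0) -> float:
    sources = cohort.members(from_label)
    targets = cohort.members(to_label)
    mins = [
        min(
            minkowski(s.features, t.features, p)
            for t in targets if t.case_id != s.case_id
        )
        for s in sources
    ]
    return float(np.mean(mins))


def quantiles(population) -> tuple[float, float, float, float, float]:
    q = np.percentile(np.asarray(population, dtype=float), [0, 25, 50, 75, 100])
    return tuple(float(v) for v in q)
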