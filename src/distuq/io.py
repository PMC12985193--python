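"""Tabular case I/O, domain containers, and feature scaling.

The central containers are :class:`CaseRecord` (one patient as a point in
feature space), :class:`LabeledCohort` (the training set every distance is
measured against) and :class:`CaseReport` (one row of the two-step clinical
report).  Tables are read and written through :mod:`pandas`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, SchemaError, ValidationError

INDETERMINATE = "INDETERMINATE"

#: Fixed column order of a serialized report row.
REPORT_COLUMNS = (
    "case_id",
    "predicted_class",
    "probability_positive",
    "distance_to_nearest_negative",
    "distance_to_nearest_positive",
    "uq_negative",
    "uq_positive",
    "final_class",
    "traffic_light",
)


@dataclass(frozen=True)
class CaseRecord:
    """A single case: an id, an ordered feature map and an optional label."""

    case_id: str
    features: dict[str, float]
    true_label: str | None = None

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"case {self.case_id!r}: feature {name!r} is not finite ({value!r})"
                )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.features)

    def vector(self) -> np.ndarray:
        """Feature values as a 1-D float array in declaration order."""
        return np.array(list(self.features.values()), dtype=float)


@dataclass(frozen=True)
class FeatureScaling:
    """Descriptor of a per-feature affine scaling ``(x - offset) / scale``.

    ``method`` is one of ``none``, ``min-max`` or ``z-score``; for ``none``
    the parameter maps are empty.  Parameters are always fitted on the
    training cohort only and applied unchanged to test cases.
    """

    method: str = "none"
    offsets: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("none", "min-max", "z-score"):
            raise ContractError(f"unknown scaling method {self.method!r}")

    def transform(self, case: CaseRecord) -> CaseRecord:
        if self.method == "none":
            return case
        features = {
            name: (value - self.offsets[name]) / self.scales[name]
            for name, value in case.features.items()
        }
        return replace(case, features=features)


@dataclass(frozen=True)
class LabeledCohort:
    """A fully labelled training cohort — the reference set for all distances.

    ``label_names`` is the ordered pair (negative_name, positive_name); by
    convention the positive class is the high-risk one.
    """

    cases: tuple[CaseRecord, ...]
    label_names: tuple[str, str] = ("LR", "HR")
    feature_scaling: FeatureScaling = field(default_factory=FeatureScaling)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        if not self.cases:
            raise ValidationError("cohort is empty")
        _check_uniform_features(self.cases)
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate case ids: {dupes}")
        negative, positive = self.label_names
        counts = {negative: 0, positive: 0}
        for case in self.cases:
            if case.true_label not in counts:
                raise ValidationError(
                    f"case {case.case_id!r} has label {case.true_label!r}; "
                    f"expected one of {self.label_names}"
                )
            counts[case.true_label] += 1
        for name, count in counts.items():
            if count < 1:
                raise ValidationError(f"cohort has no case with label {name!r}")

    @property
    def negative_label(self) -> str:
        return self.label_names[0]

    @property
    def positive_label(self) -> str:
        return self.label_names[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.cases[0].feature_names

    def members(self, label: str) -> tuple[CaseRecord, ...]:
        if label not in self.label_names:
            raise ContractError(f"unknown label {label!r}; cohort labels are {self.label_names}")
        return tuple(c for c in self.cases if c.true_label == label)

    def matrix(self, label: str | None = None) -> np.ndarray:
        cases = self.cases if label is None else self.members(label)
        return np.array([c.vector() for c in cases], dtype=float)

    def labels(self) -> list[str]:
        return [c.true_label for c in self.cases]  # type: ignore[misc]


@dataclass(frozen=True)
class CaseReport:
    """One row of the two-step report: prediction, distances, UQ, category."""

    case_id: str
    predicted_class: str
    probability_positive: float
    distance_to_nearest_negative: float
    distance_to_nearest_positive: float
    uq_negative: float
    uq_positive: float
    final_class: str
    traffic_light: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_positive <= 1.0:
            raise ValidationError(
                f"case {self.case_id!r}: probability {self.probability_positive} not in [0, 1]"
            )
        if self.traffic_light not in (None, "GREEN", "AMBER", "RED"):
            raise ValidationError(f"invalid traffic light {self.traffic_light!r}")


@dataclass(frozen=True)
class TableSchema:
    """Names of the id/label/feature columns of a feature table."""

    id_column: str = "case_id"
    label_column: str | None = "label"
    feature_columns: tuple[str, ...] | None = None
    negative_label: str = "LR"
    positive_label: str = "HR"

    @property
    def label_names(self) -> tuple[str, str]:
        return (self.negative_label, self.positive_label)

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if not isinstance(data, dict):
            raise SchemaError(f"schema config {path} must be a mapping")
        known = {
            "id_column", "label_column", "feature_columns",
            "negative_label", "positive_label",
        }
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        if data.get("feature_columns") is not None:
            data["feature_columns"] = tuple(data["feature_columns"])
        return cls(**data)


def _check_uniform_features(cases: Sequence[CaseRecord]) -> None:
    names = cases[0].feature_names
    for case in cases[1:]:
        if case.feature_names != names:
            raise ValidationError(
                f"case {case.case_id!r} has feature set {case.feature_names}, "
                f"expected {names}"
            )


def read_feature_table(
    path: str | Path,
    schema: TableSchema | None = None,
    *,
    sep: str = ",",
) -> list[CaseRecord]:
    """Read a CSV/TSV feature table into a list of :class:`CaseRecord`.

    Feature columns default to every column other than the id and label
    columns.  Non-numeric or missing feature cells and duplicate ids are
    rejected with an error naming the offending rows.
    """
    schema = schema or TableSchema()
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={schema.id_column: str})
    if schema.id_column not in df.columns:
        raise SchemaError(f"{path}: missing id column {schema.id_column!r}")
    has_labels = schema.label_column is not None and schema.label_column in df.columns
    if schema.feature_columns is not None:
        missing = [c for c in schema.feature_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing feature columns {missing}")
        feature_cols = list(schema.feature_columns)
    else:
        reserved = {schema.id_column, schema.label_column}
        feature_cols = [c for c in df.columns if c not in reserved]
    if not feature_cols:
        raise SchemaError(f"{path}: no feature columns found")

    ids = df[schema.id_column].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate case ids {dupes}")

    numeric = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        bad_ids = df.loc[bad, schema.id_column].tolist()
        raise ValidationError(
            f"{path}: non-numeric or missing feature values in rows {bad_ids}"
        )

    records = []
    for i, case_id in enumerate(ids):
        features = {c: float(numeric.iloc[i][c]) for c in feature_cols}
        label = None
        if has_labels:
            raw = df.iloc[i][schema.label_column]
            if not (isinstance(raw, float) and math.isnan(raw)):
                label = str(raw)
        records.append(CaseRecord(case_id=str(case_id), features=features, true_label=label))
    return records


def read_labeled_cohort(
    path: str | Path,
    schema: TableSchema | None = None,
    *,
    sep: str = ",",
) -> LabeledCohort:
    """Read a feature table that must be fully labelled, as a cohort."""
    schema = schema or TableSchema()
    records = read_feature_table(path, schema, sep=sep)
    unlabeled = [r.case_id for r in records if r.true_label is None]
    if unlabeled:
        raise ValidationError(f"{path}: unlabelled rows {unlabeled}; a cohort requires labels")
    return LabeledCohort(cases=tuple(records), label_names=schema.label_names)


def write_feature_table(
    cases: Iterable[CaseRecord],
    path: str | Path,
    schema: TableSchema | None = None,
    *,
    sep: str = ",",
) -> None:
    schema = schema or TableSchema()
    cases = list(cases)
    if not cases:
        raise ContractError("no cases to write")
    _check_uniform_features(cases)
    rows = []
    for case in cases:
        row: dict[str, object] = {schema.id_column: case.case_id}
        row.update(case.features)
        if case.true_label is not None:
            row[schema.label_column or "label"] = case.true_label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _render_number(value: float, precision: int) -> str:
    if math.isinf(value):
        return "inf"
    return f"{value:.{precision}f}"


def write_reports(
    reports: Sequence[CaseReport],
    path: str | Path,
    fmt: str = "csv",
    *,
    precision: int = 2,
) -> None:
    """Serialize reports as CSV or JSON-lines in the fixed column order.

    Numeric fields are rendered at ``precision`` decimals; flagged-infinite
    UQ scores are written as the literal token ``inf``.
    """
    if not reports:
        raise ContractError("no reports to write")
    if fmt not in ("csv", "jsonl"):
        raise ContractError(f"unknown report format {fmt!r}")
    path = Path(path)
    rows = []
    for r in reports:
        rows.append({
            "case_id": r.case_id,
            "predicted_class": r.predicted_class,
            "probability_positive": _render_number(r.probability_positive, precision),
            "distance_to_nearest_negative": _render_number(r.distance_to_nearest_negative, precision),
            "distance_to_nearest_positive": _render_number(r.distance_to_nearest_positive, precision),
            "uq_negative": _render_number(r.uq_negative, precision),
            "uq_positive": _render_number(r.uq_positive, precision),
            "final_class": r.final_class,
            "traffic_light": "" if r.traffic_light is None else r.traffic_light,
        })
    if fmt == "csv":
        pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def read_reports(path: str | Path, fmt: str = "csv") -> list[CaseReport]:
    """Read back a report file written by :func:`write_reports`."""
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = df.to_dict(orient="records")
    elif fmt == "jsonl":
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
    else:
        raise ContractError(f"unknown report format {fmt!r}")
    reports = []
    for row in rows:
        reports.append(CaseReport(
            case_id=str(row["case_id"]),
            predicted_class=str(row["predicted_class"]),
            probability_positive=float(row["probability_positive"]),
            distance_to_nearest_negative=float(row["distance_to_nearest_negative"]),
            distance_to_nearest_positive=float(row["distance_to_nearest_positive"]),
            uq_negative=float(row["uq_negative"]),
            uq_positive=float(row["uq_positive"]),
            final_class=str(row["final_class"]),
            traffic_light=(str(row["traffic_light"]) or None),
        ))
    return reports


def fit_scaling(cohort: LabeledCohort, method: str) -> LabeledCohort:
    """Fit a feature scaling on the cohort and return the scaled cohort.

    ``min-max`` maps each feature's training range onto [0, 1]; ``z-score``
    centres on the training mean and divides by the training standard
    deviation.  Constant features cannot be scaled.
    """
    if method == "none":
        return cohort
    from sklearn.preprocessing import MinMaxScaler, StandardScaler

    names = cohort.feature_names
    X = cohort.matrix()
    if method == "min-max":
        scaler = MinMaxScaler().fit(X)
        offsets = dict(zip(names, scaler.data_min_))
        scales = dict(zip(names, scaler.data_max_ - scaler.data_min_))
    elif method == "z-score":
        scaler = StandardScaler().fit(X)
        offsets = dict(zip(names, scaler.mean_))
        scales = dict(zip(names, np.sqrt(scaler.var_)))
    else:
        raise ContractError(f"unknown scaling method {method!r}")
    constant = [n for n, s in scales.items() if s == 0.0]
    if constant:
        raise ContractError(f"cannot scale constant features {constant}")
    scaling = FeatureScaling(method=method, offsets=offsets, scales=scales)
    scaled = tuple(scaling.transform(c) for c in cohort.cases)
    return LabeledCohort(cases=scaled, label_names=cohort.label_names, feature_scaling=scaling)


def apply_scaling(cases: Iterable[CaseRecord], scaling: FeatureScaling) -> list[CaseRecord]:
    """Apply a fitted scaling to (test) cases."""
    return [scaling.transform(c) for c in cases]
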