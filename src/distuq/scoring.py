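"""The distance-ratio uncertainty score and final-class selection.

For a case y and a candidate label x, the score is

    Uncertainty(y, x) = D_x(y) * (D_x(y) / a) = D_x(y)^2 / a

where D_x(y) is the distance from y to the nearest training example carrying
label x, and the reference distance a is the distance to the nearest training
example that does NOT carry label x (the ``opposite-label`` variant, the
default).  The first factor measures how far y is from x-territory in
absolute terms; the ratio measures it relative to the competing label.  A
score of 0 means the training set contains an example of label x with
exactly y's features — maximal certainty for that label.

An alternative ``global-min`` variant sets a = min(D_neg(y), D_pos(y)) for
both labels; it is retained because it is a defensible reading of the score,
but under it the label nearest to y always scores exactly its own distance,
which blunts the relative comparison — worked two-class examples only
reproduce under the opposite-label reading (see the package docs).

The final risk class is the label whose score is closer to 0; exact ties
yield the explicit sentinel ``INDETERMINATE`` rather than a silent default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .distances import NeighborDistances
from .errors import ContractError
from .io import INDETERMINATE

UQ_VARIANTS = ("opposite-label", "global-min")


@dataclass(frozen=True)
class UQResult:
    """Per-label uncertainty scores and the resulting final class."""

    case_id: str
    uq_negative: float
    uq_positive: float
    reference_distance_negative: float
    reference_distance_positive: float
    final_class: str
    formula_variant: str


def uq_score(d_own: float, d_reference: float) -> float:
    """Uncertainty score for one candidate label: d_own^2 / d_reference.

    ``d_own`` is the distance to the nearest training case of the candidate
    label; ``d_reference`` is the reference distance a.  An exact training
    duplicate (d_own = 0) scores 0 regardless of the reference — even when
    the reference is also 0.  d_own > 0 with d_reference = 0 means the case
    sits exactly on a training example of the *other* label: the score is
    flagged infinite (maximal uncertainty for this label).
    """
    if d_own < 0 or d_reference < 0:
        raise ContractError(
            f"distances must be nonnegative, got d_own={d_own}, d_reference={d_reference}"
        )
    if d_own == 0.0:
        return 0.0
    if d_reference == 0.0:
        return math.inf
    return d_own * (d_own / d_reference)


def score_case(
    nd: NeighborDistances,
    variant: str = "opposite-label",
    label_names: tuple[str, str] = ("LR", "HR"),
) -> UQResult:
    """Score both candidate labels for one case and pick the final class.

    variant="opposite-label": each label's reference a is the other label's
    nearest distance.  variant="global-min": a = min of the two distances,
    shared by both labels.  The final class is the label with the strictly
    smaller score; an exact tie gives INDETERMINATE.
    """
    if variant not in UQ_VARIANTS:
        raise ContractError(f"unknown variant {variant!r}; choose from {UQ_VARIANTS}")
    d_neg, d_pos = nd.d_negative, nd.d_positive
    if variant == "opposite-label":
        ref_neg, ref_pos = d_pos, d_neg
    else:
        ref_neg = ref_pos = min(d_neg, d_pos)
    score_neg = uq_score(d_neg, ref_neg)
    score_pos = uq_score(d_pos, ref_pos)
    if math.isinf(score_neg) and math.isinf(score_pos):
        raise ContractError(
            f"case {nd.case_id!r}: both scores flagged infinite — degenerate cohort"
        )
    negative, positive = label_names
    if score_neg < score_pos:
        final = negative
    elif score_pos < score_neg:
        final = positive
    else:
        final = INDETERMINATE
    return UQResult(
        case_id=nd.case_id,
        uq_negative=score_neg,
        uq_positive=score_pos,
        reference_distance_negative=ref_neg,
        reference_distance_positive=ref_pos,
        final_class=final,
        formula_variant=variant,
    )
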