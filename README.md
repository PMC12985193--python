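# distuq

Distance-based epistemic uncertainty quantification for binary risk
classifiers on tabular feature data.

## The problem

Clinical risk models — for example a radiomics model grading thymic
epithelial tumours into WHO low-risk (LR) and high-risk (HR) classes from
two CT features — report a class probability, but not how well the training
data supports the prediction for *this* patient. When a new case falls into
a region of feature space the training cohort never covered, the probability
can be confidently wrong. `distuq` quantifies that epistemic (data-coverage)
uncertainty with a deliberately simple, fully transparent mechanism: how far
is the new case from the nearest labelled training examples?

For a case *y* and candidate label *x*, with `D_x(y)` the Manhattan (L1)
distance from *y* to the nearest training example of label *x* and `a` the
distance to the nearest training example *not* of label *x*,

```
Uncertainty(y, x) = D_x(y) · (D_x(y) / a) = D_x(y)² / a
```

A score of 0 means the training set contains an example of label *x* with
exactly *y*'s features; the larger the score, the less the training data
supports calling *y* an *x*. The label with the smaller score is the
distance-based **final class**, reported alongside — never reconciled
with — the classifier's probability-based call. A per-case **traffic
light** (GREEN / AMBER / RED) places the case's distance to its predicted
class against percentiles of that class's within-group training distances,
so "high uncertainty" is always relative to the model's own cohort. The
probability cut-off can be calibrated to the training event rate (e.g. 0.36
in a cohort with 36% positive cases) to counter class imbalance.

The library also ships a seeded scenario generator (even coverage, tight
negatives vs dispersed positives, two separated clusters, interleaved
nonlinear arcs) so every component is testable without patient data, plus
distance summaries of the training set (within-group quantiles and directed
mean nearest-neighbour distances between groups — which are asymmetric, and
diagnose empty feature space).

## Worked example

```sh
distuq simulate --scenario CLUSTERED_NEG_SPARSE_POS --seed 7 -o train.csv
distuq summarize train.csv --definition all-pairs -o summary
distuq score --train train.csv --test test.csv --calibrate-event-rate -o reports.csv
distuq report reports.csv
```

with `test.csv` holding three probe cases (one inside the negative cluster,
one equidistant from both classes, one far outside the cohort) produces:

```
case_id,predicted_class,probability_positive,distance_to_nearest_negative,distance_to_nearest_positive,uq_negative,uq_positive,final_class,traffic_light
IN_CLUSTER-001,LR,0.09,0.01,0.57,0.00,35.51,LR,GREEN
NEAR_BOUNDARY-001,HR,0.54,0.46,0.46,0.46,0.46,HR,GREEN
OUTLIER_EMPTY_SPACE-001,LR,0.35,14.87,11.64,19.00,9.11,HR,RED
```

Reading the rows: the in-cluster case sits 0.01 from its nearest LR
neighbour — UQ ≈ 0, GREEN, trust the prediction. The boundary case is
exactly 0.46 from both classes, so both scores collapse to 0.46 and the two
labels are nearly indistinguishable. The outlier is 11.64 from even its
nearest neighbour — far beyond the training cohort's maximum within-group
distance — so it is flagged RED, and the distance-based final class (HR)
contradicts the classifier's call (LR), which the pipeline logs as a
warning. `distuq report` renders each row as a two-step clinical report
(step 1: predicted class + probability; step 2: distances, UQ scores,
traffic-light phrase).

The same pipeline is available as a library (`distuq.run_score`,
`distuq.run_summarize`, `distuq.uq_score`, ...); precomputed probabilities
from any external classifier can be supplied via `--prob-column`, making the
uncertainty layer classifier-agnostic.

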