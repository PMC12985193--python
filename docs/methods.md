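# Methods

## The model of uncertainty

`distuq` treats epistemic uncertainty as a geometric question: a binary
classifier's prediction for a case is only as trustworthy as the training
examples near that case in feature space. Each case is a point whose
coordinates are the model's input features (e.g. two radiomics features such
as sphericity and a 90th-percentile intensity). The package never inspects
the classifier; it works purely from the labelled training cohort and the
case's features, which is what makes it applicable to any probabilistic
binary model.

The primitive quantity is the per-label nearest-neighbour distance
`D_x(y)`: the Minkowski p-distance (default p = 1, Manhattan) from case `y`
to the nearest training example with label `x`, or, with `k > 1`, the
arithmetic mean of the `k` smallest such distances (averaging damps the
influence of a single atypical training point; `k = 1` is always a lower
bound of the `k > 1` value). If the case is itself a cohort member, matched
by id, self-pairing is excluded.

The per-label uncertainty score is

    Uncertainty(y, x) = D_x(y)^2 / a

with the reference distance `a` chosen by the `opposite-label` variant
(default): `a` is the nearest distance to the *other* label. The first
factor `D_x(y)` is absolute remoteness from label-x territory; the ratio
`D_x(y)/a` is remoteness relative to the competing label. The score is 0
exactly when `D_x(y) = 0` (an exact training duplicate — maximal certainty,
even when the opposite label also has a coincident example); it is flagged
infinite when `D_x(y) > 0` but `a = 0` (the case coincides with an
opposite-label training example). A `global-min` variant with
`a = min(D_neg, D_pos)` shared by both labels is retained as an explicit
option: it is a defensible alternative reading, but under it the nearer
label always scores exactly its own distance, which blunts the relative
comparison — two-class worked examples only reproduce under the
opposite-label reading, which is why that is the default.

The **final class** is the argmin of the two scores. Exact ties return the
sentinel `INDETERMINATE` rather than silently preferring a label; the
pipeline can optionally break ties with the classifier's own prediction
(`tie_break_with_prediction` / `--tie-break-predicted`). A disagreement
between the classifier's call and the distance-based final class is
reported and logged at WARNING, never reconciled automatically — surfacing
exactly those cases is the point of the method.

Useful properties, all enforced by tests: the score is strictly increasing
in `D_x` and strictly decreasing in `a`; multiplying all distances by
`c > 0` multiplies both scores by `c` and never changes the final class
(so the final class is invariant to the overall scale of the feature
space, though *not* to per-feature rescaling — see scaling below); and the
final class always equals the label nearer in feature space.

## Decision threshold

The classifier contract is a map from features to P(positive) in [0, 1].
Probabilities may be supplied per case, or fitted by the built-in reference
logistic regression (deterministic under a fixed seed; constant features
rejected as unidentifiable). The class call uses a cut-off that is either
fixed or calibrated to the training event rate — threshold = positive-class
fraction of the training labels — which counteracts the minority-class
under-calling of a 0.5 cut-off in imbalanced cohorts. The boundary is
inclusive on the positive side (probability exactly at the threshold is
called positive). The threshold is always computed from training labels,
never from test cases.

## Distance summaries of the training set

Two families of summary describe the cohort's geometry:

* **Within-group quantiles** (min, 25%, median, 75%, max) of a label's
  internal distances. Two populations are implemented and the choice is a
  *required* parameter recorded in every output, never a hidden default:
  `all-pairs` (every unordered within-label pair once — overall spread) and
  `nearest-only` (each member's distance to its nearest same-label
  neighbour — local density). The two can differ by an order of magnitude
  on clustered data and answer different questions, and published summary
  tables rarely state which was used, so the package refuses to guess.
* **Directed mean nearest distances** over ordered label pairs: the mean,
  over members of the source group, of each member's distance to its
  nearest target-group member. The per-member *minimum* (not the all-pairs
  mean) is used deliberately: it is the only definition under which the
  matrix is asymmetric, and the asymmetry is diagnostic — a tight cluster
  lies near a dispersed one while the reverse direction is dominated by the
  dispersed group's far members, revealing empty feature space between
  groups.

Quantiles use linear interpolation between order statistics
(`numpy.percentile` default). The raw distance populations are retained on
the summary object so that off-grid percentiles remain evaluable
downstream; a summary reconstructed from five printed quantiles alone
supports only the (0, 25, 50, 75, 100) grid and raises a contract error for
anything else.

## Feature scaling

Whether distances should be computed on raw or normalised features is
genuinely open — distance magnitudes are only comparable across features
when the features share a scale. The package therefore supports optional
`min-max` or `z-score` scaling, fitted on the training cohort only and
applied unchanged to test cases, with `none` as the default; the choice and
fitted parameters are recorded on the cohort and echoed in the resolved run
config written next to every report file. Missing feature values are
rejected, not imputed: the distance metric has no defined behaviour for
them.

## Traffic light

The categorized quantity is the case's distance to its nearest
predicted-class training example, placed against percentiles of the
predicted class's within-group training distance distribution: at or below
the green-upper percentile → GREEN ("uncertainty low"), at or below the
amber-upper percentile → AMBER ("uncertainty medium—exercise caution"),
above → RED ("uncertainty high"). Boundaries are upper-inclusive; with any
valid config the three categories partition [0, ∞) and are monotone in
distance. The (50, 75) pair is a documented illustration — thresholds are
context-dependent (disease, misclassification cost, institution) and the
config is mandatory in the API precisely so that no generic threshold gets
baked in. An alternative mode (`reference="uq-score"`) categorizes the
case's uncertainty score against the leave-one-out score distribution of
the training members of the predicted class, for users who prefer
uncertainty-relative-to-average-uncertainty semantics. Whether the AMBER
band's lower edge should include a value exactly at the green threshold is
ambiguous in prose formulations like "50–75%"; the upper-inclusive
convention is a documented choice, under which a distance just above the
median with a sparse quantile grid categorizes AMBER.

## Synthetic scenarios

The generator emulates the qualitative feature-space regimes the method is
meant to distinguish, not any real cohort's feature distributions:

| scenario | construction (defaults) | defining property |
|---|---|---|
| `EVEN_COVERAGE` | both classes Gaussian, spread 1.0, centres 1.5 apart per axis | within-group medians agree (within 20%) |
| `CLUSTERED_NEG_SPARSE_POS` | negative spread 0.3, positive spread 1.2 | negative median < positive median |
| `TWO_SEPARATED_CLUSTERS` | equal spread 0.4, centres 8.0 apart per axis | both directed inter-group means exceed both intra-group means |
| `NONLINEAR_BOUNDARY` | two interleaved half-moon arcs (noise 0.15) | a linear boundary demonstrably misclassifies part of each arc |

Default class sizes are 85 negative / 47 positive — a realistic imbalanced
single-centre rare-disease cohort scale, and the scale at which the demo
outputs are produced. Within-cluster dispersion is independent symmetric
per-feature noise; Gaussian by default, with a uniform family (matched
per-coordinate standard deviation) as the documented alternative, since
nothing in the method depends on the noise family's tails. Generation is a
pure function of (spec, seed); identical specs yield byte-identical tables.
The defining orderings above are statistical, holding in ≥95% of seeded
replicates rather than every draw.

Probe-case generation: `IN_CLUSTER` jitters a random training point by a
quarter of its label's median nearest-neighbour spacing; `NEAR_BOUNDARY`
bisects the segment between a random negative and a random positive
training point until the two per-label nearest distances agree within 5%
(the signed gap is continuous along the segment and changes sign, so plain
bisection converges); `OUTLIER_EMPTY_SPACE` walks outward from the cohort
centroid in a random direction, doubling the radius until the distance to
every training case exceeds the cohort's maximum within-group distance.

What passing tests on these scenarios shows: that each pipeline stage
computes its defined quantity correctly and that the score separates
covered from uncovered regions of feature space under controlled geometry.
What it does not show: performance on real radiomics features, whose
distributions, correlations and measurement noise the generator makes no
attempt to emulate — the metric addresses only epistemic (coverage)
uncertainty and ignores aleatoric noise entirely.

## Numerical choices and limitations

* Distances via `scipy.spatial.distance` (`pdist`/`cdist`); cohorts are
  small, so everything is exact brute force — no approximate
  nearest-neighbour indexing. Tests cross-check every distance operation
  against independent pure-Python enumeration at tolerance 1e-12.
* Ties among k-th nearest neighbours are harmless: only the k smallest
  scalar distances enter a mean, which is permutation-stable.
* Reports render numbers at 2 decimals (full precision in JSON); the
  round-trip reader restores values to that precision, and flagged-infinite
  scores serialize as the literal token `inf`.
* Known limitations, inherent to the metric: a case far from *all*
  training data but clearly nearer one class still gets a low score for
  that class (outliers in the direction of a class are not flagged by the
  score itself — the traffic light, which compares against within-group
  distances, is the mitigation); no aleatoric uncertainty; no weighted or
  learned metric.
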