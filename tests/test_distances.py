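import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from distuq import (
    CaseRecord,
    ContractError,
    LabeledCohort,
    manhattan_distance,
    mean_nearest_cross_distance,
    minkowski_distance,
    nearest_label_distance,
    neighbor_distances,
    summarize_distances,
    within_group_quantiles,
)
from distuq.distances import GroupQuantiles, summary_to_frame, write_summary

from . import oracles
from .conftest import make_random_cohort

coordinate = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)
vector5 = st.lists(coordinate, min_size=5, max_size=5)


def _fv(values):
    return {f"f{i}": float(v) for i, v in enumerate(values)}


class TestManhattan:
    def test_identity(self):
        u = _fv([1.2, -3.4])
        assert manhattan_distance(u, u) == 0.0

    def test_by_definition(self):
        assert manhattan_distance(_fv([0, 0]), _fv([1, 2])) == 3.0

    @settings(deadline=None, max_examples=50)
    @given(vector5, vector5)
    def test_matches_per_coordinate_oracle(self, u, v):
        fu, fv = _fv(u), _fv(v)
        assert manhattan_distance(fu, fv) == pytest.approx(
            oracles.manhattan(fu, fv), rel=1e-12, abs=1e-12
        )

    @settings(deadline=None, max_examples=50)
    @given(vector5, vector5, vector5)
    def test_metric_axioms(self, u, v, w):
        fu, fv, fw = _fv(u), _fv(v), _fv(w)
        duv = manhattan_distance(fu, fv)
        assert duv >= 0.0
        assert duv == pytest.approx(manhattan_distance(fv, fu))
        if u == v:
            assert duv == 0.0
        elif duv == 0.0:
            assert u == v
        assert duv <= (
            manhattan_distance(fu, fw) + manhattan_distance(fw, fv)
        ) * (1 + 1e-9) + 1e-9

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ContractError, match="mismatched"):
            manhattan_distance({"a": 1.0}, {"b": 1.0})

    def test_minkowski_p2_is_euclidean(self):
        assert minkowski_distance(_fv([0, 0]), _fv([3, 4]), p=2) == pytest.approx(5.0)

    def test_minkowski_order_below_one_rejected(self):
        with pytest.raises(ContractError):
            minkowski_distance(_fv([0]), _fv([1]), p=0.5)


class TestNearestLabelDistance:
    def test_exact_training_duplicate_gives_zero(self, small_cohort):
        case = CaseRecord("new", dict(small_cohort.cases[0].features))
        assert nearest_label_distance(case, small_cohort, "LR", k=1) == 0.0

    def test_self_pairing_excluded_for_cohort_members(self, small_cohort):
        member = small_cohort.cases[0]
        assert nearest_label_distance(member, small_cohort, "LR", k=1) > 0.0

    def test_k1_matches_exhaustive_minimum(self, rng):
        for _ in range(20):
            cohort = make_random_cohort(rng, n_cases=20)
            case = CaseRecord("probe", _fv(rng.normal(size=3)))
            for label in cohort.label_names:
                assert nearest_label_distance(case, cohort, label, k=1) == pytest.approx(
                    oracles.nearest_label_distance(case, cohort, label, k=1), rel=1e-12
                )

    def test_k3_matches_mean_of_three_smallest(self, rng):
        cohort = make_random_cohort(rng, n_cases=20)
        case = CaseRecord("probe", _fv(rng.normal(size=3)))
        for label in cohort.label_names:
            assert nearest_label_distance(case, cohort, label, k=3) == pytest.approx(
                oracles.nearest_label_distance(case, cohort, label, k=3), rel=1e-12
            )

    def test_k1_lower_bounds_larger_k(self, rng):
        for _ in range(10):
            cohort = make_random_cohort(rng, n_cases=15)
            case = CaseRecord("probe", _fv(rng.normal(size=3)))
            for label in cohort.label_names:
                d1 = nearest_label_distance(case, cohort, label, k=1)
                d3 = nearest_label_distance(case, cohort, label, k=3)
                assert d1 <= d3 + 1e-12

    def test_too_few_members_names_label(self, small_cohort):
        case = CaseRecord("probe", {"f1": 0.0, "f2": 0.0})
        with pytest.raises(ContractError, match="HR"):
            nearest_label_distance(case, small_cohort, "HR", k=5)

    def test_neighbor_distances_bundles_both_labels(self, small_cohort):
        case = CaseRecord("probe", {"f1": 0.0, "f2": 0.0})
        nd = neighbor_distances(case, small_cohort)
        assert nd.d_negative == 0.0  # coincides with LR0
        assert nd.d_positive == 6.0  # |3-0| + |3-0|
        assert nd.k == 1


class TestWithinGroupQuantiles:
    @pytest.mark.parametrize("definition", ["all-pairs", "nearest-only"])
    def test_two_member_group_collapses_to_single_distance(self, definition):
        cases = (
            CaseRecord("a", {"f1": 0.0}, "LR"),
            CaseRecord("b", {"f1": 1.5}, "LR"),
            CaseRecord("c", {"f1": 9.0}, "HR"),
            CaseRecord("d", {"f1": 9.5}, "HR"),
        )
        cohort = LabeledCohort(cases=cases)
        q = within_group_quantiles(cohort, "LR", definition)
        assert (q.minimum, q.q25, q.median, q.q75, q.maximum) == (1.5,) * 5

    def test_all_pairs_matches_pair_enumeration(self, rng):
        cohort = make_random_cohort(rng, n_cases=12)
        for label in cohort.label_names:
            q = within_group_quantiles(cohort, label, "all-pairs")
            expected = oracles.quantiles(oracles.all_pairs_population(cohort, label))
            assert (q.minimum, q.q25, q.median, q.q75, q.maximum) == pytest.approx(expected)

    def test_nearest_only_matches_per_member_minimum(self, rng):
        cohort = make_random_cohort(rng, n_cases=12)
        for label in cohort.label_names:
            q = within_group_quantiles(cohort, label, "nearest-only")
            expected = oracles.quantiles(oracles.nearest_only_population(cohort, label))
            assert (q.minimum, q.q25, q.median, q.q75, q.maximum) == pytest.approx(expected)

    def test_single_member_group_rejected(self):
        cases = (
            CaseRecord("a", {"f1": 0.0}, "LR"),
            CaseRecord("b", {"f1": 1.0}, "LR"),
            CaseRecord("c", {"f1": 2.0}, "HR"),
        )
        with pytest.raises(ContractError, match="HR"):
            within_group_quantiles(LabeledCohort(cases=cases), "HR", "all-pairs")

    def test_unknown_definition_rejected(self, small_cohort):
        with pytest.raises(ContractError, match="definition"):
            within_group_quantiles(small_cohort, "LR", "median-of-medians")

    def test_quantile_ordering_enforced(self):
        with pytest.raises(ContractError, match="out of order"):
            GroupQuantiles(1.0, 0.5, 2.0, 3.0, 4.0)


class TestMeanNearestCrossDistance:
    def test_singleton_groups_are_symmetric(self):
        cases = (
            CaseRecord("a", {"f1": 0.0, "f2": 0.0}, "LR"),
            CaseRecord("b", {"f1": 2.0, "f2": 1.0}, "HR"),
        )
        cohort = LabeledCohort(cases=cases)
        assert mean_nearest_cross_distance(cohort, "LR", "HR") == 3.0
        assert mean_nearest_cross_distance(cohort, "HR", "LR") == 3.0

    def test_tight_cluster_vs_outlier_is_asymmetric(self):
        # five tight LR points near 0; HR has one near point and one far outlier
        cases = tuple(
            CaseRecord(f"l{i}", {"f1": 0.1 * i}, "LR") for i in range(5)
        ) + (
            CaseRecord("h0", {"f1": 1.0}, "HR"),
            CaseRecord("h1", {"f1": 50.0}, "HR"),
        )
        cohort = LabeledCohort(cases=cases)
        lr_to_hr = mean_nearest_cross_distance(cohort, "LR", "HR")
        hr_to_lr = mean_nearest_cross_distance(cohort, "HR", "LR")
        # every LR's nearest HR is h0: mean of 1.0, 0.9, 0.8, 0.7, 0.6
        assert lr_to_hr == pytest.approx(0.8)
        # h0's nearest LR is 0.6 away; h1's is 49.6 away
        assert hr_to_lr == pytest.approx((0.6 + 49.6) / 2)
        assert lr_to_hr != hr_to_lr

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            cohort = make_random_cohort(rng, n_cases=18)
            for a in cohort.label_names:
                for b in cohort.label_names:
                    assert mean_nearest_cross_distance(cohort, a, b) == pytest.approx(
                        oracles.mean_nearest_cross(cohort, a, b), rel=1e-12
                    )

    def test_intra_group_needs_two_members(self):
        cases = (
            CaseRecord("a", {"f1": 0.0}, "LR"),
            CaseRecord("b", {"f1": 1.0}, "LR"),
            CaseRecord("c", {"f1": 2.0}, "HR"),
        )
        with pytest.raises(ContractError):
            mean_nearest_cross_distance(LabeledCohort(cases=cases), "HR", "HR")


class TestSummary:
    def test_summary_collects_quantiles_and_directed_means(self, small_cohort):
        summary = summarize_distances(small_cohort, "all-pairs")
        assert set(summary.quantiles) == {"LR", "HR"}
        assert len(summary.directed_means) == 4
        assert summary.pairwise_definition == "all-pairs"
        # the clusters are 6 apart but only ~1 wide: inter >> intra
        assert summary.directed_means[("LR", "HR")] > summary.directed_means[("LR", "LR")]

    def test_percentile_value_interpolates_population(self, small_cohort):
        summary = summarize_distances(small_cohort, "all-pairs")
        pop = summary.populations["LR"]
        assert summary.percentile_value("LR", 60.0) == pytest.approx(
            float(np.percentile(pop, 60.0))
        )

    def test_percentile_off_grid_without_population_rejected(self, small_cohort):
        q = within_group_quantiles(small_cohort, "LR", "all-pairs")
        with pytest.raises(ContractError, match="unavailable"):
            q.at_percentile(60.0)

    def test_exports_csv_and_json(self, small_cohort, tmp_path):
        summary = summarize_distances(small_cohort, "all-pairs")
        frame = summary_to_frame(summary)
        assert len(frame) == 9  # five quantile rows + four directed means
        write_summary(summary, csv_path=tmp_path / "s.csv", json_path=tmp_path / "s.json")
        assert (tmp_path / "s.csv").exists()
        text = (tmp_path / "s.json").read_text()
        assert "LR->HR" in text and "pairwise_definition" in text
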