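
import pytest

from nilcontrast.contrasts import (
    ContrastSet,
    annotation_matched_set,
    baseline_biased_set,
    exclusive_set,
    shared_response_sets,
    specific_response_sets,
    strong_subset,
    subset_profile,
)
from nilcontrast.data_model import AnnotationTable
from nilcontrast.datasets import condition_mean_frame, table1, table2, table3
from nilcontrast.simulate import GeneratorConfig, PlantedBlock, generate_dataset


def _cset(hid, members):
    return ContrastSet(hid, frozenset(members))


class TestExclusiveSet:
    def test_published_l_exclusive_rows_all_retained(self, table1_df):
        means = condition_mean_frame(table1_df)
        result = exclusive_set(means, "L")
        assert result.members == set(table1_df.index)
        assert result.parameters["high"] == 25

    def test_published_h_exclusive_rows_all_retained(self, table2_df):
        means = condition_mean_frame(table2_df)
        result = exclusive_set(means, "H")
        assert result.members == set(table2_df.index)

    def test_empty_matrix_empty_set(self, table1_df):
        means = condition_mean_frame(table1_df).iloc[:0]
        assert exclusive_set(means, "L").members == set()

    def test_high_must_exceed_low(self, table1_df):
        with pytest.raises(ValueError, match="high"):
            exclusive_set(condition_mean_frame(table1_df), "L", high=5, low=5)

    def test_l_and_h_sets_disjoint_for_any_thresholds(self, table1_df, table2_df):
        means = condition_mean_frame(table1_df, table2_df)
        for high, low in [(25, 5), (10, 9), (50, 1)]:
            got_l = exclusive_set(means, "L", high, low).members
            got_h = exclusive_set(means, "H", high, low).members
            assert not (got_l & got_h)

    def test_idempotent_on_own_output(self, table1_df, table2_df):
        means = condition_mean_frame(table1_df, table2_df)
        first = exclusive_set(means, "L")
        again = exclusive_set(means.loc[sorted(first.members)], "L")
        assert again.members == first.members


class TestSetAlgebra:
    def test_specific_sets_are_differences(self):
        up_l, up_h = _cset("u", {"a", "b", "c"}), _cset("u", {"b"})
        down_l, down_h = _cset("d", set()), _cset("d", {"x"})
        only_l_up, only_h_up, only_l_down, only_h_down = specific_response_sets(
            up_l, up_h, down_l, down_h
        )
        assert only_l_up.members == {"a", "c"}
        assert only_h_up.members == set()
        assert only_h_down.members == {"x"}

    def test_disjoint_inputs_pass_through(self):
        up_l, up_h = _cset("u", {"a"}), _cset("u", {"b"})
        only_l_up, only_h_up, *_ = specific_response_sets(
            up_l, up_h, _cset("d", set()), _cset("d", set())
        )
        assert only_l_up.members == {"a"}
        assert only_h_up.members == {"b"}

    def test_shared_sets_are_intersections(self):
        shared_up, shared_down = shared_response_sets(
            _cset("u", {"a", "b"}), _cset("u", {"b", "c"}),
            _cset("d", {"p"}), _cset("d", {"q"}),
        )
        assert shared_up.members == {"b"}
        assert shared_down.members == set()

    def test_partition_property(self):
        up_l, up_h = _cset("u", {"a", "b", "s1", "s2"}), _cset("u", {"c", "s1", "s2"})
        down = _cset("d", set())
        only_l, only_h, *_ = specific_response_sets(up_l, up_h, down, down)
        shared_up, _ = shared_response_sets(up_l, up_h, down, down)
        parts = [only_l.members, only_h.members, shared_up.members]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (parts[i] & parts[j])
        assert parts[0] | parts[1] | parts[2] == up_l.members | up_h.members


class TestStrongSubset:
    def test_asymmetric_induction_retained(self):
        shared = _cset("H7_shared_up", {"g"})
        result = strong_subset(shared, {"g": 160.0}, {"g": 9.0})
        assert result.members == {"g"}  # ratio ~17.8 >= 10

    def test_symmetric_induction_excluded(self):
        shared = _cset("H7_shared_up", {"g"})
        assert strong_subset(shared, {"g": 12.0}, {"g": 12.0}).members == set()

    def test_all_published_nas_rows_favor_l(self, table3_df):
        # every NAS contig is more induced in the L line than in H
        shared = _cset("H7_shared_up", set(table3_df.index))
        fc_l = table3_df["fc_L"].to_dict()
        fc_h = table3_df["fc_H"].to_dict()
        result = strong_subset(shared, fc_l, fc_h, ratio_threshold=1.000001)
        assert result.members == set(table3_df.index)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            strong_subset(_cset("s", set()), {}, {}, ratio_threshold=1.0)

    def test_missing_fold_change_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            strong_subset(_cset("s", {"g"}), {"g": 2.0}, {})


class TestSubsetProfile:
    def test_singleton_profile_equals_row(self, table3_df):
        means = condition_mean_frame(table3_df)
        prof = subset_profile(
            ["contig26634"], means,
            table3_df["fc_L"].to_dict(), table3_df["fc_H"].to_dict(),
        )
        assert prof.mean_ctrl_L == pytest.approx(7.8)
        assert prof.mean_treated_H == pytest.approx(240.7)
        assert prof.mean_fc_L == pytest.approx(77.1)

    def test_missing_member_named(self, table3_df):
        means = condition_mean_frame(table3_df)
        with pytest.raises(ValueError, match="ghost"):
            subset_profile(["ghost"], means, {}, {})


class TestBaselineBiased:
    @staticmethod
    def _matrix():
        cfg = GeneratorConfig(
            (
                PlantedBlock("exclusive_L", 3, (100.0, 100.0, 10.0, 10.0)),
                PlantedBlock("housekeeping", 3, (20.0, 20.0, 20.0, 20.0)),
                PlantedBlock("induced_L_only", 3, (100.0, 100.0, 95.0, 95.0)),
                PlantedBlock("null_background", 40, (8.0,) * 4, base_spread=0.6),
            ),
            noise_sigma=0.01, seed=6,
        )
        return generate_dataset(cfg)

    def test_recovers_strong_baseline_bias(self):
        matrix, truth = self._matrix()
        result = baseline_biased_set(matrix, "L")
        want = set(truth.assignments.index[truth.assignments == "exclusive_L"])
        assert result.members == want

    def test_background_level_gene_excluded(self):
        # 20 vs 20 FPKM: fails the 5x background gate
        matrix, truth = self._matrix()
        members = baseline_biased_set(matrix, "L").members
        flat = set(truth.assignments.index[truth.assignments == "housekeeping"])
        assert not (members & flat)

    def test_small_difference_excluded(self):
        # 100 vs 95 FPKM: abundant but fails the 2-fold/significance rule
        matrix, truth = self._matrix()
        members = baseline_biased_set(matrix, "L").members
        close = set(truth.assignments.index[truth.assignments == "induced_L_only"])
        assert not (members & close)

    def test_invalid_background(self):
        matrix, _ = self._matrix()
        with pytest.raises(ValueError):
            baseline_biased_set(matrix, "L", background=0.0)


class TestAnnotationMatched:
    def test_matches_terms_and_descriptions(self):
        ann = AnnotationTable.from_mapping(
            {
                "a": ("basic helix-loop-helix bHLH38", None, {"TF"}),
                "b": ("peroxidase", None, {"oxidoreductase"}),
                "c": ("unknown", None, set()),
            }
        )
        shared = _cset("H7_shared_up", {"a", "b", "c"})
        got = annotation_matched_set(shared, ann, ["bHLH", "TF"])
        assert got.members == {"a"}
        got2 = annotation_matched_set(shared, ann, ["oxidoreductase"])
        assert got2.members == {"b"}
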