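import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nilcontrast.data_model import DataModelError
from nilcontrast.diffexp import (
    bh_adjust,
    call_differential,
    expressed_contigs,
    fold_change,
    welch_t_test,
)
from nilcontrast.datasets import tables_expression_matrix, table1
from nilcontrast.simulate import GeneratorConfig, PlantedBlock, generate_dataset


class TestFoldChange:
    @pytest.mark.parametrize(
        "ref,alt,floor,expected",
        [
            (10.0, 40.0, 0.01, 4.0),
            (0.0, 50.0, 0.01, 5000.0),
            (2.0, 1.0, 0.01, 0.5),
        ],
    )
    def test_examples(self, ref, alt, floor, expected):
        assert fold_change(ref, alt, floor) == pytest.approx(expected)

    def test_printed_naat_ratio_within_5_percent(self):
        # published row: control 0.7 -> treated 246.9, printed FC 356.6
        # (the printed FC derives from unrounded FPKM)
        assert fold_change(0.7, 246.9) == pytest.approx(356.6, rel=0.05)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 5.0)
        with pytest.raises(ValueError):
            fold_change(1.0, 5.0, floor=0.0)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_textbook_example(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert t > 0  # group_b larger -> positive t

    def test_degenerate_zero_variance_equal_means(self):
        _, _, p = welch_t_test([0, 0, 0], [0, 0, 0])
        assert p == 1.0

    def test_degenerate_zero_variance_unequal_means(self):
        t, _, p = welch_t_test([1, 1, 1], [2, 2, 2])
        assert p == 0.0
        assert t == np.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2, 3])

    @pytest.mark.parametrize("na,nb", [(3, 3), (3, 5), (4, 8)])
    def test_matches_scipy_oracle(self, na, nb):
        rng = np.random.default_rng(123)
        for _ in range(25):
            a = rng.normal(0, 1, na)
            b = rng.normal(0.5, 2, nb)
            t, df, p = welch_t_test(a, b)
            ref = stats.ttest_ind(b, a, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,q",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_worked_examples(self, p, q):
        np.testing.assert_allclose(bh_adjust(p), q)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_preserves_input_order_and_bounds(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        # monotone in p: sorting p must sort q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref)


def _two_block_matrix(sigma=0.05, seed=0, base_alt=(6.0, 630.0, 6.0, 630.0)):
    cfg = GeneratorConfig(
        (
            PlantedBlock("induced_both_strongL", 1, base_alt),
            PlantedBlock("null_background", 60, (20.0,) * 4, base_spread=0.8),
        ),
        noise_sigma=sigma,
        seed=seed,
    )
    return generate_dataset(cfg)


class TestCallDifferential:
    def test_planted_induction_flagged_up(self):
        matrix, truth = _two_block_matrix()
        result = call_differential(matrix, ("L", "control"), ("L", "cadmium"))
        planted = truth.assignments.index[truth.assignments == "induced_both_strongL"]
        assert (result.loc[planted, "direction"] == "up").all()

    def test_null_false_positive_rate_near_zero(self):
        # flat genes under noise: essentially none reach q < 0.001 plus 2-fold
        hits = 0
        total = 0
        for seed in range(5):
            matrix, truth = _two_block_matrix(seed=seed)
            result = call_differential(matrix, ("L", "control"), ("L", "cadmium"))
            nulls = truth.assignments.index[truth.assignments == "null_background"]
            hits += int(result.loc[nulls, "is_deg"].sum())
            total += len(nulls)
        assert hits / total <= 0.001

    def test_min_fpkm_filter_blocks_low_abundance(self):
        cfg = GeneratorConfig(
            (PlantedBlock("induced_L_only", 4, (0.2, 2.0, 0.2, 0.2)),),
            noise_sigma=0.01, seed=3,
        )
        matrix, _ = generate_dataset(cfg)
        result = call_differential(matrix, ("L", "control"), ("L", "cadmium"))
        assert (result["fold_change"] > 2).all()
        assert not result["is_deg"].any()

    def test_deg_flags_monotone_in_thresholds(self):
        matrix, _ = _two_block_matrix(sigma=0.2, seed=9)
        strict = call_differential(
            matrix, ("L", "control"), ("L", "cadmium"),
            q_threshold=0.001, fc_threshold=2,
        )
        relaxed = call_differential(
            matrix, ("L", "control"), ("L", "cadmium"),
            q_threshold=0.01, fc_threshold=1.5,
        )
        assert (relaxed["is_deg"] | ~strict["is_deg"]).all()

    def test_q_never_below_p(self):
        matrix, _ = _two_block_matrix(sigma=0.3, seed=4)
        result = call_differential(matrix, ("H", "control"), ("H", "cadmium"))
        assert (result["q_value"] >= result["p_value"] - 1e-12).all()

    def test_single_replicate_contrast_rejected(self, tables_matrix):
        with pytest.raises(DataModelError, match="2 replicates"):
            call_differential(tables_matrix, ("L", "control"), ("L", "cadmium"))


class TestExpressedContigs:
    def test_published_exclusive_table_all_expressed(self):
        matrix = tables_expression_matrix(table1())
        assert expressed_contigs(matrix) == set(table1().index)

    def test_all_zero_matrix_empty(self):
        cfg = GeneratorConfig(
            (PlantedBlock("null_background", 10, (0.0,) * 4),), seed=0
        )
        matrix, _ = generate_dataset(cfg)
        assert expressed_contigs(matrix) == set()

    def test_threshold_is_strict(self):
        cfg = GeneratorConfig(
            (PlantedBlock("null_background", 3, (5.0,) * 4),),
            noise_sigma=0.0, seed=0,
        )
        matrix, _ = generate_dataset(cfg)
        assert expressed_contigs(matrix, threshold=5.0) == set()
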