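"""Screening pipeline: filters, tests, classification, reshuffling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primescreen.expression import (
    ComparisonSpec,
    ScreenResult,
    bh_fdr,
    classify_dynamics,
    classify_ld_response,
    fold_change,
    fold_change_filter,
    present_call_filter,
    reshuffle_analysis,
    run_screen,
    screen_comparisons,
    select_nontrivial,
    welch_test,
    welch_test_matrix,
)
from conftest import toy_matrix


def _two_condition_matrix(a_vals, b_vals, conds=("LD", "Control")):
    data, conditions = {}, {}
    for i, v in enumerate(a_vals, 1):
        name = f"{conds[0]}_r{i}"
        data[name] = v if isinstance(v, list) else [v]
        conditions[name] = conds[0]
    for i, v in enumerate(b_vals, 1):
        name = f"{conds[1]}_r{i}"
        data[name] = v if isinstance(v, list) else [v]
        conditions[name] = conds[1]
    return toy_matrix(data, conditions)


class TestPresentCallFilter:
    def test_all_absent_probe_removed_single_present_kept(self):
        mat = toy_matrix(
            {"Control_r1": [10, 10, 10], "Control_r2": [10, 10, 10]},
            calls={"Control_r1": ["A", "P", "A"], "Control_r2": ["A", "A", "A"]},
        )
        out = present_call_filter(mat)
        assert list(out.probes) == ["p1"]

    def test_no_calls_is_identity_with_warning(self, caplog):
        mat = toy_matrix({"Control_r1": [10], "Control_r2": [11]})
        with caplog.at_level("WARNING"):
            out = present_call_filter(mat)
        assert out is mat
        assert "filter skipped" in caplog.text

    def test_planted_absent_count(self, small_dataset):
        mat, truth = small_dataset
        out = present_call_filter(mat)
        assert len(out.probes) == len(mat.probes) - len(truth.absent)
        assert not out.probes.isin(truth.absent).any()


class TestFoldChange:
    def test_simple_ratio(self):
        mat = _two_condition_matrix([250, 250], [100, 100])
        fc = fold_change(mat, ComparisonSpec("LD", "Control"))
        assert fc["fc"].iloc[0] == pytest.approx(2.5)
        assert fc["direction"].iloc[0] == 1

    def test_identity_and_reciprocal_symmetry(self):
        mat = _two_condition_matrix([120, 80], [90, 110])
        f1 = fold_change(mat, ComparisonSpec("LD", "Control"))["fc"]
        f2 = fold_change(mat, ComparisonSpec("Control", "LD"))["fc"]
        assert (f1 * f2).iloc[0] == pytest.approx(1.0)
        same = _two_condition_matrix([100, 100], [100, 100])
        assert fold_change(same, ComparisonSpec("LD", "Control"))["fc"].iloc[
            0
        ] == pytest.approx(1.0)


class TestWelch:
    def test_identical_groups_give_p_one_t_zero(self):
        assert welch_test([10, 11, 9], [10, 11, 9]) == pytest.approx(1.0)

    def test_matches_hand_computed_welch_satterthwaite(self):
        """Oracle: the textbook formula computed step by step."""
        a, b = [10.1, 10.2, 9.9], [12.0, 12.3, 11.8]
        la, lb = np.log2(a), np.log2(b)
        va, vb = la.var(ddof=1) / 3, lb.var(ddof=1) / 3
        t = (la.mean() - lb.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_test(a, b) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_under_group_swap(self):
        a, b = [10.0, 12.0, 11.0], [20.0, 22.0, 19.0]
        assert welch_test(a, b) == pytest.approx(welch_test(b, a))

    def test_degenerate_variances(self, caplog):
        assert welch_test([5, 5], [5, 5]) == 1.0
        with caplog.at_level("WARNING"):
            assert welch_test([5, 5], [8, 8]) == 0.0
        assert "zero variance" in caplog.text

    def test_matrix_version_agrees_with_scalar(self, small_dataset):
        mat, _ = small_dataset
        sub = mat.subset(mat.probes[:40])
        p_vec = welch_test_matrix(sub, "LD", "Control")
        for probe in sub.probes[:10]:
            a = sub.condition_values("LD").loc[probe].to_numpy()
            b = sub.condition_values("Control").loc[probe].to_numpy()
            assert p_vec[probe] == pytest.approx(welch_test(a, b), rel=1e-9)

    def test_null_pvalues_uniform(self):
        """Planted null genes give Welch p uniform on [0,1] (KS check)."""
        rng = np.random.default_rng(99)
        n = 2000
        a = 2.0 ** (8 + 0.2 * rng.standard_normal((n, 3)))
        b = 2.0 ** (8 + 0.2 * rng.standard_normal((n, 3)))
        p = np.array([welch_test(a[i], b[i]) for i in range(n)])
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_hand_computed_step_up(self):
        """p(i) * m / i with cumulative minimum from the largest rank."""
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        # worked second case: adjusted = cummin(p * m / rank)
        p = [0.001, 0.01, 0.03, 0.8]
        expect = [0.004, 0.02, 0.04, 0.8]
        assert np.allclose(bh_fdr(p), expect)

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_invalid_rejected(self):
        p = np.array([0.001, 0.5, 0.04, 0.9])
        assert (bh_fdr(p) >= p).all()
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestScreen:
    def test_nontrivial_set_excludes_planted_nulls(self, small_dataset):
        mat, truth = small_dataset
        detected = present_call_filter(mat)
        candidates = fold_change_filter(detected)
        screen = screen_comparisons(candidates)
        nontrivial = select_nontrivial(candidates, screen)
        planted = set(truth.nontrivial)
        assert len(set(nontrivial) - planted) <= 0.1 * len(nontrivial)
        assert len(planted & set(nontrivial)) / len(planted) >= 0.9

    def test_dropping_significance_clause_enlarges_selection(
        self, small_dataset
    ):
        mat, _ = small_dataset
        candidates = fold_change_filter(present_call_filter(mat))
        screen = screen_comparisons(candidates)
        with_stats = set(select_nontrivial(candidates, screen))
        # FC-only variant: treat every test as significant
        relaxed_table = screen.table.copy()
        for name in screen.specs:
            fc = relaxed_table[(name, "fc")]
            relaxed_table[(name, "significant")] = (fc >= 2) | (fc <= 0.5)
        fc_only = set(
            select_nontrivial(
                candidates, ScreenResult(relaxed_table, screen.specs)
            )
        )
        assert with_stats <= fc_only

    def test_classifications_deterministic(self, small_dataset):
        mat, _ = small_dataset
        s1 = run_screen(mat)
        s2 = run_screen(mat)
        pd.testing.assert_frame_equal(s1.classification, s2.classification)


class TestClassification:
    def test_dynamics_cells_of_the_two_by_two(self):
        idx = pd.Index(["early", "late", "persistent", "silent"])
        cols = {}
        for name, (s3, s24) in {
            "HD3_vs_Control": ([True, False, True, False], None),
            "HD24_vs_Control": ([False, True, True, False], None),
        }.items():
            cols[(name, "significant")] = pd.Series(s3, index=idx)
        table = pd.DataFrame(cols)
        specs = {"HD3_vs_Control": None, "HD24_vs_Control": None}
        out = classify_dynamics(ScreenResult(table, specs), "HD")
        assert list(out) == ["early", "late", "persistent", "silent"]

    def test_ld_classes_and_dynamics_recover_ground_truth(
        self, small_dataset
    ):
        mat, truth = small_dataset
        summary = run_screen(mat)
        cl = summary.classification
        for klass in ("LD-induced", "LD-reduced"):
            found = set(cl.index[cl["ld_class"] == klass])
            true = set(truth.ld_class.index[truth.ld_class == klass])
            assert len(found & true) / len(true) >= 0.9
            assert len(found - true) <= 0.1 * max(len(found), 1)

    def test_readouts_recovered(self, small_dataset):
        mat, truth = small_dataset
        summary = run_screen(mat)
        cl = summary.classification
        strict = set(cl.index[cl["readout_strict"]])
        relaxed = set(cl.index[cl["readout_relaxed"]])
        assert set(truth.readouts) <= strict
        assert strict <= relaxed  # strict tier implies relaxed tier


class TestReshuffle:
    def test_identical_classifications_give_diagonal_matrix(self):
        c = pd.Series(
            ["early", "late", "silent", "persistent"],
            index=["a", "b", "c", "d"],
        )
        res = reshuffle_analysis(c, c)
        assert res.transition.to_numpy().sum() == 4
        assert np.trace(res.transition.to_numpy()) == 4
        assert len(res.reshuffled) == 0

    def test_row_sums_equal_hd_group_sizes(self, small_dataset):
        mat, _ = small_dataset
        summary = run_screen(mat)
        res = summary.reshuffle
        cl = summary.classification
        for klass in res.transition.index:
            assert res.transition.loc[klass].sum() == (
                cl["dynamics_HD"] == klass
            ).sum()

    def test_planted_reshufflers_recovered(self, small_dataset):
        mat, truth = small_dataset
        summary = run_screen(mat)
        found = set(summary.reshuffle.reshuffled)
        planted = set(truth.reshufflers)
        assert planted <= found
        extra = found - planted
        assert len(extra) <= 0.1 * max(len(found), 1)
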