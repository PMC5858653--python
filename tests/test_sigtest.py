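import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrkit import (
    CtTable,
    delta_ct_by_row,
    hodges_lehmann,
    rank_sum_interval,
    two_group_test,
)

from conftest import make_group_table


class TestDeltaCtByRow:
    def test_row_wise_difference(self, ct1):
        d = delta_ct_by_row(ct1, "GAPDH")
        assert d.loc[0, "delta_ct"] == pytest.approx(30.72 - 23.70)
        assert len(d) == 12
        assert set(d["group"]) == {"brain", "kidney"}

    def test_identical_genes_give_zeros(self):
        t = make_group_table({"a": [0.0, 0.0], "b": [0.0, 0.0]})
        assert (delta_ct_by_row(t, "ref")["delta_ct"] == 0).all()

    def test_missing_row_dropped_with_warning(self):
        t = CtTable(
            pd.DataFrame({"t": [25.0, np.nan, 24.0], "r": [20.0, 20.0, 20.0]}),
            group=["a", "a", "b"],
        )
        with pytest.warns(UserWarning, match="missing"):
            d = delta_ct_by_row(t, "r")
        assert len(d) == 2


def hl_bruteforce(x, y):
    diffs = sorted(yi - xj for yi in y for xj in x)
    return float(np.median(diffs))


class TestHodgesLehmann:
    def test_small_examples(self):
        assert hodges_lehmann([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)
        assert hodges_lehmann([1, 2, 3], [1, 2, 3]) == 0.0
        assert hodges_lehmann([0], [5]) == 5.0

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_bruteforce_enumeration(self, x, y):
        assert hodges_lehmann(x, y) == pytest.approx(hl_bruteforce(x, y), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hodges_lehmann([], [1.0])


SPEC_CTRL = [6.0, 6.2, 5.8]
SPEC_TRT = [5.0, 5.2, 4.8]


class TestTwoGroupTest:
    @pytest.mark.parametrize("method", ["t_test", "wilcoxon", "linear_model"])
    def test_balanced_shift_estimated_identically(self, method):
        t = make_group_table({"control": SPEC_CTRL, "treatment": SPEC_TRT})
        (res,) = two_group_test(t, "ref", "control", method)
        assert res.estimate == pytest.approx(-1.0, abs=1e-9)
        assert res.lower <= res.estimate <= res.upper
        assert 0 <= res.p_value <= 1

    def test_t_and_lm_pvalues_agree_on_balanced_equal_variance_design(self):
        t = make_group_table({"control": SPEC_CTRL, "treatment": SPEC_TRT})
        (tt,) = two_group_test(t, "ref", "control", "t_test")
        (lm,) = two_group_test(t, "ref", "control", "linear_model")
        assert tt.p_value == pytest.approx(lm.p_value, abs=1e-10)
        assert tt.estimate == pytest.approx(lm.estimate, abs=1e-12)

    def test_identical_groups_are_null(self):
        vals = [5.1, 5.4, 4.9, 5.0]
        t = make_group_table({"a": vals, "b": vals})
        for method in ["t_test", "wilcoxon", "linear_model"]:
            (res,) = two_group_test(t, "ref", "a", method)
            assert res.estimate == pytest.approx(0.0, abs=1e-12)
            assert res.p_value > 0.9

    def test_lm_coefficient_equals_group_mean_difference(self):
        rng = np.random.default_rng(3)
        ctrl, trt = rng.normal(5.2, 0.4, 10), rng.normal(4.5, 0.4, 10)
        t = make_group_table({"control": list(ctrl), "treatment": list(trt)})
        (lm,) = two_group_test(t, "ref", "control", "linear_model")
        assert lm.estimate == pytest.approx(trt.mean() - ctrl.mean(), abs=1e-10)
        assert lm.term == "group[T.treatment]"

    def test_wilcoxon_matches_frozen_r_oracle(self):
        # wilcox.test(y, x, conf.int=TRUE, exact=TRUE) in R 4.3.3:
        # estimate -0.9, p 0.00793651, CI (-1.2, -0.5)
        x = [6.0, 6.2, 5.8, 6.1, 5.9]
        y = [5.0, 5.3, 4.8, 5.1, 5.4]
        t = make_group_table({"control": x, "treatment": y})
        (res,) = two_group_test(t, "ref", "control", "wilcoxon")
        assert res.estimate == pytest.approx(-0.9, abs=1e-9)
        assert res.p_value == pytest.approx(0.00793651, abs=1e-6)
        assert res.lower == pytest.approx(-1.2, abs=1e-9)
        assert res.upper == pytest.approx(-0.5, abs=1e-9)

    def test_welch_t_matches_frozen_r_oracle(self):
        # t.test(y, x) in R 4.3.3: p 0.00024628, CI (-1.183327, -0.576673)
        x = [6.0, 6.2, 5.8, 6.1, 5.9]
        y = [5.0, 5.3, 4.8, 5.1, 5.4]
        t = make_group_table({"control": x, "treatment": y})
        (res,) = two_group_test(t, "ref", "control", "t_test")
        assert res.estimate == pytest.approx(-0.88, abs=1e-9)
        assert res.p_value == pytest.approx(0.00024628, abs=1e-6)
        assert res.lower == pytest.approx(-1.183327, abs=1e-5)
        assert res.upper == pytest.approx(-0.576673, abs=1e-5)

    def test_wilcoxon_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        ctrl, trt = rng.normal(5, 0.4, 8), rng.normal(4.6, 0.4, 8)
        t1 = make_group_table({"c": list(ctrl), "t": list(trt)})
        t2 = make_group_table({"c": list(np.exp(ctrl / 3)), "t": list(np.exp(trt / 3))})
        (a,) = two_group_test(t1, "ref", "c", "wilcoxon")
        (b,) = two_group_test(t2, "ref", "c", "wilcoxon")
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_multi_group_requires_linear_model(self):
        t = make_group_table({"a": [1.0, 1.1], "b": [2.0, 2.1], "c": [3.0, 3.1]})
        with pytest.raises(ValueError, match="exactly 2"):
            two_group_test(t, "ref", "a", "t_test")
        res = two_group_test(t, "ref", "a", "linear_model")
        assert len(res) == 2
        assert {r.term for r in res} == {"group[T.b]", "group[T.c]"}
        by_term = {r.term: r for r in res}
        assert by_term["group[T.b]"].estimate == pytest.approx(1.0, abs=1e-10)
        assert by_term["group[T.c]"].estimate == pytest.approx(2.0, abs=1e-10)

    def test_zero_variance_both_groups_rejected(self):
        t = make_group_table({"a": [5.0, 5.0], "b": [4.0, 4.0]})
        with pytest.raises(ValueError, match="zero variance"):
            two_group_test(t, "ref", "a", "t_test")

    def test_bh_adjustment_across_genes(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "g1": np.r_[rng.normal(25, 0.3, 6), rng.normal(24, 0.3, 6)],
                "g2": np.r_[rng.normal(25, 0.3, 6), rng.normal(25, 0.3, 6)],
                "ref": np.r_[rng.normal(20, 0.3, 6), rng.normal(20, 0.3, 6)],
            }
        )
        t = CtTable(df, group=["c"] * 6 + ["t"] * 6)
        raw = two_group_test(t, "ref", "c", "t_test")
        adj = two_group_test(t, "ref", "c", "t_test", adjust_p=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15


class TestRankSumInterval:
    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        est, lo, hi = rank_sum_interval(x, y)
        assert lo <= est <= hi

    def test_asymptotic_branch_consistent_with_exact(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 19), rng.normal(0.8, 1, 19)  # n*m = 361 exact
        est_e, lo_e, hi_e = rank_sum_interval(x, y, 0.95)
        import qpcrkit.sigtest as sg

        old = sg.EXACT_LIMIT
        try:
            sg.EXACT_LIMIT = 0
            est_a, lo_a, hi_a = rank_sum_interval(x, y, 0.95)
        finally:
            sg.EXACT_LIMIT = old
        assert est_e == est_a
        assert lo_a == pytest.approx(lo_e, abs=0.2)
        assert hi_a == pytest.approx(hi_e, abs=0.2)
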