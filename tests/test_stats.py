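import math

import numpy as np
import pytest
from scipy import stats as sps

from soil2leaf.stats import (
    correlation_matrix,
    games_howell,
    strength_label,
    studentized_range_sf,
    welch_anova,
)


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df",
        [(3.0, 3, 10), (2.0, 4, 5), (4.5, 5, 30), (1.0, 2, 3), (6.0, 3, 100), (3.5, 2, 7.3)],
    )
    def test_matches_scipy_oracle(self, q, k, df):
        assert studentized_range_sf(q, k, df) == pytest.approx(
            sps.studentized_range.sf(q, k, df), abs=1e-6
        )

    def test_infinite_df(self):
        assert studentized_range_sf(3.0, 3, math.inf) == pytest.approx(
            sps.studentized_range.sf(3.0, 3, 1e7), abs=1e-4
        )

    def test_degenerate_q(self):
        assert studentized_range_sf(0.0, 3, 10) == 1.0


class TestWelchAnova:
    def test_identical_groups_give_f_zero(self):
        res = welch_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equals_squared_welch_t(self):
        a, b = [1.0, 2, 3, 4], [2.0, 3, 4, 5]
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        groups = [rng.normal(m, s, n) for m, s, n in [(0, 1, 8), (0.5, 2, 12), (1, 0.5, 6)]]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [8, 12, 6]),
            }
        )
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        res = welch_anova(groups)
        assert res.f_stat == pytest.approx(ref["F"].iloc[0], rel=1e-9)
        assert res.df2 == pytest.approx(ref["ddof2"].iloc[0], rel=1e-9)
        assert res.p == pytest.approx(ref["p_unc"].iloc[0], rel=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(1, 2, 9), rng.normal(-1, 0.5, 7)]
        base = welch_anova(groups)
        shifted = welch_anova([g + 13.7 for g in groups])
        scaled = welch_anova([g * 4.1 for g in groups])
        assert shifted.f_stat == pytest.approx(base.f_stat, rel=1e-9)
        assert scaled.f_stat == pytest.approx(base.f_stat, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_anova([[1.0, 1.0, 1.0], [1, 2, 3]])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1, 2, 3]])


class TestGamesHowell:
    def test_identical_groups_null(self):
        (c,) = games_howell([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert c.mean_diff == 0.0
        assert c.p == pytest.approx(1.0)
        assert c.sig_code == "ns"

    def test_k2_reduces_to_welch_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 3, 11)
        (c,) = games_howell([a, b])
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert c.p == pytest.approx(ref.pvalue, abs=1e-6)
        assert c.q_stat == pytest.approx(abs(ref.statistic) * math.sqrt(2), rel=1e-12)

    def test_p_monotone_in_mean_diff(self):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        p_prev = 1.1
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            (c,) = games_howell([base, base + shift])
            assert c.p <= p_prev + 1e-12
            p_prev = c.p

    def test_familywise_error_near_alpha(self):
        # null simulation oracle: 3 equal-mean normal groups
        rng = np.random.default_rng(1)
        n_reps, n, k = 4000, 10, 3
        rejections = 0
        data = rng.normal(size=(n_reps, k, n))
        for rep in range(n_reps):
            comps = games_howell(list(data[rep]))
            if any(c.p < 0.05 for c in comps):
                rejections += 1
        fwer = rejections / n_reps
        assert abs(fwer - 0.05) <= 0.015  # ~4.3 binomial sigma at 4000 reps

    def test_labels_and_symmetry(self):
        comps = games_howell([[1.0, 2, 3], [4.0, 5, 7], [0.0, 1, 2]], labels=["a", "b", "c"])
        assert [(c.group_a, c.group_b) for c in comps] == [("a", "b"), ("a", "c"), ("b", "c")]
        ab = comps[0]
        ba = games_howell([[4.0, 5, 7], [1.0, 2, 3]])[0]
        assert ba.mean_diff == pytest.approx(-ab.mean_diff)


class TestCorrelationMatrix:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        cm = correlation_matrix(np.column_stack([x, 2 * x + 1]))
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.strength[0, 1] == "strong"
        assert cm.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_zero_mean(self):
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        cm = correlation_matrix(np.column_stack([x, y]))
        assert cm.r[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert cm.strength[0, 1] == "none"

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        n = 5
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        cm = correlation_matrix(np.column_stack([x, y]))
        assert cm.r[0, 1] == pytest.approx(num / den, rel=1e-12)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert cm.r[0, 1] == pytest.approx(ref_r, rel=1e-12)
        assert cm.p[0, 1] == pytest.approx(ref_p, rel=1e-9)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        data = rng.normal(size=(30, 4))
        data[3, 1] = data[5, 1]  # force a tie -> midranks
        sp = correlation_matrix(data, method="spearman")
        ranked = np.column_stack([sps.rankdata(data[:, j]) for j in range(4)])
        pe = correlation_matrix(ranked, method="pearson")
        np.testing.assert_allclose(sp.r, pe.r, atol=1e-12)

    def test_constant_variable_undefined(self):
        data = np.column_stack([np.ones(5), np.arange(5.0)])
        cm = correlation_matrix(data)
        assert np.isnan(cm.r[0, 1])
        assert cm.strength[0, 1] == "undefined"

    def test_pairwise_complete_deletion(self):
        data = np.array([[1.0, 2.0], [2, 4], [3, 6], [np.nan, 8], [5, 10]])
        cm = correlation_matrix(data)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_diagonal(self, rng):
        cm = correlation_matrix(rng.normal(size=(20, 5)))
        np.testing.assert_allclose(cm.r, cm.r.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(cm.r), 1.0)
        assert np.all(np.abs(cm.r) <= 1.0)


@pytest.mark.parametrize(
    "r,label",
    [(0.1, "none"), (0.2, "weak"), (0.39, "weak"), (0.4, "moderate"),
     (0.6, "moderate"), (0.61, "strong"), (-0.8, "strong"), (float("nan"), "undefined")],
)
def test_strength_labels(r, label):
    assert strength_label(r) == label
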