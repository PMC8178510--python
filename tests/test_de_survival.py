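"""Differential expression, Cox/Kaplan-Meier screens, 2x2 odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirqtl import (
    CoxPHModel,
    TwoByTwo,
    bh_fdr,
    cox_fit,
    differential_test,
    km_logrank,
    or_2x2,
)
from mirqtl.datasets import LUAD_NDUFS1_CLINICAL, clinical_or_table


def expr_frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"f{j}" for j in range(arr.shape[1])],
    )


def group_series(n_tumor, n_normal):
    return pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal,
        index=[f"S{i}" for i in range(n_tumor + n_normal)],
    )


class TestDifferentialTest:
    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(6, 1, (60, 10_000))
        res, _ = differential_test(
            expr_frame(vals), group_series(30, 30), group_max_absent=60
        )
        rate = (res["p"] < 0.05).mean()
        assert abs(rate - 0.05) <= 0.01

    def test_planted_shift_recovered_unbiased(self):
        shift = 1.04
        rng = np.random.default_rng(1)
        fcs = []
        for _ in range(100):
            vals = rng.normal(6, 1, (400, 1))
            vals[:200, 0] += shift
            res, _ = differential_test(
                expr_frame(vals), group_series(200, 200), group_max_absent=400
            )
            fcs.append(res["log2fc"].iloc[0])
        assert np.mean(fcs) == pytest.approx(shift, abs=0.05)

    def test_group_absence_rule(self):
        vals = np.full((60, 2), 8.0)
        vals[30:41, 0] = 0.0  # absent in 11 normal samples
        res, excluded = differential_test(
            expr_frame(vals + np.random.default_rng(2).normal(0, 0.1, (60, 2))
                       * (vals > 0)),
            group_series(30, 30),
            group_max_absent=10,
        )
        assert list(excluded["feature_id"]) == ["f0"]
        assert list(res["feature_id"]) == ["f1"]

    def test_q_values_reproduce_bh(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(6, 1, (40, 50))
        res, _ = differential_test(expr_frame(vals), group_series(20, 20),
                                   group_max_absent=40)
        np.testing.assert_allclose(res["q"], bh_fdr(res["p"]), atol=1e-15)

    def test_de_call_requires_both_fc_and_fdr(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(6, 0.05, (200, 2))
        vals[:100, 0] += 0.5  # significant but below fold-change 2
        vals[:100, 1] += 2.0  # significant and large
        res, _ = differential_test(expr_frame(vals), group_series(100, 100),
                                   group_max_absent=200)
        res = res.set_index("feature_id")
        assert not res.loc["f0", "de"]
        assert res.loc["f1", "de"]


def sim_survival(rng, n, loghr=0.0, censor_scale=3.0):
    grp = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0, n) * np.exp(-loghr * grp)
    c = rng.uniform(0, censor_scale, n)
    return grp, pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int)})


class TestCox:
    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        grp, surv = sim_survival(rng, 300, loghr=0.5)
        surv["time"] = np.round(surv["time"], 1) + 0.05  # force ties
        r = cox_fit(grp, surv)
        df = pd.DataFrame({"t": surv["time"], "e": surv["event"], "x": grp})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert r.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert r.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_null_hr_near_one(self):
        rng = np.random.default_rng(6)
        inside = 0
        for _ in range(100):
            grp, surv = sim_survival(rng, 500, censor_scale=5.0)
            r = cox_fit(grp, surv)
            inside += 0.8 <= r.hr <= 1.25
        assert inside >= 95

    def test_protective_hr_recovered(self):
        rng = np.random.default_rng(7)
        hrs = []
        for _ in range(100):
            grp, surv = sim_survival(rng, 1000, loghr=np.log(0.46))
            hrs.append(cox_fit(grp, surv).hr)
        assert np.mean(hrs) == pytest.approx(0.46, rel=0.10)

    def test_relabeling_inverts_hr(self):
        rng = np.random.default_rng(8)
        grp, surv = sim_survival(rng, 400, loghr=0.7)
        a = cox_fit(grp, surv)
        b = cox_fit(1 - grp, surv)
        assert b.hr == pytest.approx(1 / a.hr, rel=1e-6)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-6)

    def test_no_censoring_approaches_rate_ratio(self):
        rng = np.random.default_rng(9)
        n = 5000
        grp = rng.integers(0, 2, n).astype(float)
        rate = np.where(grp == 1, 2.0, 1.0)
        t = rng.exponential(1.0 / rate)
        surv = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int)})
        r = cox_fit(grp, surv)
        assert r.hr == pytest.approx(2.0, rel=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            CoxPHModel([0.0, 1.0, 0.0], [1.0, 2.0, 3.0], [0, 0, 0])

    def test_separation_flagged_and_capped(self):
        # group 1 all dies immediately, group 0 all censored late
        grp = np.array([1.0] * 10 + [0.0] * 10)
        time = np.array([0.1] * 10 + [10.0] * 10)
        event = np.array([1] * 10 + [0] * 10)
        r = CoxPHModel(grp, time, event).fit()
        assert r.separation
        assert abs(r.beta) <= CoxPHModel.BETA_CAP


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        surv = pd.DataFrame(
            {"time": time + time, "event": [1, 1, 0, 1, 1] * 2}
        )
        chi2, p, _ = km_logrank(["a"] * 5 + ["b"] * 5, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_logrank_table(self):
        # 10 subjects, unique event times, no censoring
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        event = np.ones(10, dtype=int)
        labels = np.array(["a", "b"] * 5)
        # hand computation: at each event time, O-E and hypergeometric variance
        o_minus_e = 0.0
        var = 0.0
        at_risk = np.ones(10, dtype=bool)
        for i in np.argsort(time):
            n_tot = at_risk.sum()
            n_a = (at_risk & (labels == "a")).sum()
            e_a = n_a / n_tot
            o_a = 1.0 if labels[i] == "a" else 0.0
            o_minus_e += o_a - e_a
            if n_tot > 1:
                var += e_a * (1 - n_a / n_tot) * (n_tot - 1) / (n_tot - 1)
            at_risk[i] = False
        expected_chi2 = o_minus_e**2 / var
        chi2, p, _ = km_logrank(labels, pd.DataFrame({"time": time, "event": event}))
        assert chi2 == pytest.approx(expected_chi2, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), abs=1e-6)

    def test_km_without_censoring_is_empirical_survival(self):
        time = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 1.5, 2.5, 3.5])
        surv = pd.DataFrame({"time": time, "event": np.ones(8, dtype=int)})
        _, _, curves = km_logrank(["a"] * 4 + ["b"] * 4, surv)
        km = curves["a"].iloc[:, 0]
        t_a = np.sort(time[:4])
        for i, t in enumerate(t_a):
            assert km.loc[t] == pytest.approx(1 - (i + 1) / 4)

    def test_single_group_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            km_logrank(["a", "a"], surv)


class TestOddsRatio:
    def test_worked_examples(self):
        assert or_2x2(TwoByTwo(16, 4, 6, 13)).odds_ratio == pytest.approx(8.667, abs=5e-4)
        assert or_2x2(TwoByTwo(16, 4, 8, 11)).odds_ratio == pytest.approx(5.50, abs=5e-3)
        assert or_2x2(TwoByTwo(1, 1, 1, 1)).odds_ratio == pytest.approx(1.0)

    def test_double_swap_invariance_and_single_swap_inversion(self):
        t = TwoByTwo(12, 5, 7, 9)
        base = or_2x2(t).odds_ratio
        swapped_both = or_2x2(TwoByTwo(t.d, t.c, t.b, t.a))
        assert swapped_both.odds_ratio == pytest.approx(base)
        row_swapped = or_2x2(TwoByTwo(t.c, t.d, t.a, t.b))
        assert row_swapped.odds_ratio == pytest.approx(1 / base)

    @given(st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
    def test_matches_logistic_regression_slope(self, cells):
        import statsmodels.api as sm

        a, b, c, d = cells
        exposure = np.array([1] * (a + c) + [0] * (b + d))
        outcome = np.array([1] * a + [0] * c + [1] * b + [0] * d)
        X = sm.add_constant(exposure.astype(float))
        fit = sm.GLM(outcome, X, family=sm.families.Binomial()).fit()
        assert or_2x2(TwoByTwo(a, b, c, d)).odds_ratio == pytest.approx(
            float(np.exp(fit.params[1])), rel=1e-6
        )

    def test_zero_cell_flagged_without_correction(self):
        res = or_2x2(TwoByTwo(0, 3, 4, 5))
        assert res.zero_cell and res.odds_ratio == 0.0
        res = or_2x2(TwoByTwo(3, 0, 4, 5))
        assert res.zero_cell and res.odds_ratio == np.inf

    def test_haldane_correction_optional(self):
        res = or_2x2(TwoByTwo(0, 3, 4, 5), haldane=True)
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (3.5 * 4.5))


class TestClinicalTable:
    PRINTED = {
        "Age": 1.091,
        "Sex": 1.671,
        "Stage": 4.121,
        "T stage": 1.429,
        "N stage": 5.500,
        "Differentiation": 0.225,
        "ki67": 2.571,
        "Tumor maximum diameter": 4.000,
        "Lymphatic and vascular invasion": 8.667,
        "Nerve invasion": 2.182,
    }

    def test_all_characteristic_ors_match_published_values(self):
        table = clinical_or_table().set_index("characteristic")
        for name, printed in self.PRINTED.items():
            assert round(table.loc[name, "odds_ratio"], 3) == pytest.approx(printed)

    def test_counts_sum_to_cohort_margins(self):
        for rec in LUAD_NDUFS1_CLINICAL:
            assert sum(rec["high"]) == 20
            assert sum(rec["low"]) == 19
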