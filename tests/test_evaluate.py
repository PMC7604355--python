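"""Scoring, cutoffs and the survival evaluation layer against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from pairsig.datatypes import GenePair, PrognosticSignature, RiskScoreTable
from pairsig.evaluate import (
    assign_groups,
    compute_risk_scores,
    concordance_index,
    cox_regression,
    evaluate_cohort,
    km_logrank_compare,
    select_cutoff,
    stratified_analysis,
    td_auc,
)

from .conftest import make_expr, make_surv


def _scores(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{j}" for j in range(len(values))]
    return RiskScoreTable(pd.DataFrame({"score": values}, index=ids))


class TestComputeRiskScores:
    def test_no_indicator_set_scores_zero(self, irgp23):
        from .conftest import topological_values

        vals = topological_values(irgp23.pairs, ascending=True)
        expr = make_expr(
            np.array([[vals[g]] for g in sorted(vals)]), genes=sorted(vals), samples=["S0"]
        )
        assert compute_risk_scores(expr, irgp23).score[0] == 0.0

    def test_monotone_transform_leaves_scores_identical(self, small_cohort, irgp23):
        _, expr, _, _ = small_cohort
        sig = PrognosticSignature(
            [(GenePair(expr.gene_symbols[i], expr.gene_symbols[i + 1]), 0.5 - 0.1 * i)
             for i in range(0, 10, 2)]
        )
        logged = make_expr(np.log(expr.values), genes=expr.gene_symbols, samples=expr.sample_ids)
        assert (compute_risk_scores(expr, sig).score == compute_risk_scores(logged, sig).score).all()

    def test_missing_gene_aborts_under_error_policy(self, irgp23, small_cohort):
        _, expr, _, _ = small_cohort
        with pytest.raises(KeyError):
            compute_risk_scores(expr, irgp23, missing_policy="error")

    def test_drop_pairs_policy_scores_with_remaining_pairs(self, irgp23):
        # only the APOBEC3G/IKBKE pair is scorable; indicator is 1
        expr = make_expr([[2.0], [1.0]], genes=["APOBEC3G", "IKBKE"], samples=["S0"])
        scores = compute_risk_scores(expr, irgp23, missing_policy="drop_pairs")
        assert scores.score[0] == pytest.approx(-0.511310011, abs=1e-12)

    def test_all_pairs_missing_rejected(self, irgp23):
        expr = make_expr([[1.0], [2.0]], genes=["X1", "X2"])
        with pytest.raises(ValueError, match="missing"):
            compute_risk_scores(expr, irgp23, missing_policy="drop_pairs")


class TestCutoffsAndGroups:
    def test_median_of_three(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        assert select_cutoff(_scores([1, 2, 3]), surv, "median") == 2.0

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="all risk scores equal"):
            select_cutoff(_scores([1.0, 1.0]), None, "median")

    def test_perfect_separation_youden_has_j_of_one(self):
        time = np.array([10.0, 20, 30, 400, 500, 600])
        event = np.array([1, 1, 1, 0, 0, 0])
        scores = _scores([5, 6, 7, 1, 2, 3])
        surv = make_surv(time, event)
        roc = td_auc(scores, surv, 100.0)
        j = roc.sensitivity + roc.specificity - 1.0
        assert j.max() == pytest.approx(1.0)
        cut = select_cutoff(scores, surv, "roc_youden", t=100.0)
        assert 3 <= cut < 5

    def test_youden_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(4)
        n = 120
        time = rng.exponential(200, n)
        event = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        surv = make_surv(time, event)
        scores = _scores(x)
        t = float(np.quantile(time, 0.5))
        cut = select_cutoff(scores, surv, "roc_youden", t=t)
        roc = td_auc(scores, surv, t)
        # brute-force scan over all observed thresholds using the same weights
        from pairsig.evaluate import _case_control_weights

        wc, wv = _case_control_weights(time, event, t)
        best = max(
            ((wc[x > c].sum() / wc.sum()) + (wv[x <= c].sum() / wv.sum()) - 1.0, c) for c in x
        )
        got_j = (wc[x > cut].sum() / wc.sum()) + (wv[x <= cut].sum() / wv.sum()) - 1.0
        assert got_j == pytest.approx(best[0], abs=1e-12)

    def test_group_assignment_boundary_is_strict(self):
        grouped = assign_groups(_scores([1.0, 2.0, 3.0]), 2.0)
        assert list(grouped.group) == ["low", "low", "high"]

    def test_cutoff_below_min_warns_all_high(self):
        with pytest.warns(UserWarning, match="empty"):
            grouped = assign_groups(_scores([1.0, 2.0]), 0.0)
        assert set(grouped.group) == {"high"}


class TestKMLogrank:
    def test_identical_groups_p_is_one(self):
        surv = make_surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.sample_ids)
        _, p = km_logrank_compare(groups, surv)
        assert p == pytest.approx(1.0)

    def test_uncensored_km_equals_empirical_survival(self):
        time = np.array([1.0, 2, 2, 3, 5])
        surv = make_surv(np.concatenate([time, time + 100]), [1] * 10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=surv.sample_ids)
        curves, _ = km_logrank_compare(groups, surv)
        km = curves["a"].set_index("time")["survival"]
        for t in np.unique(time):
            assert km.loc[t] == pytest.approx((time > t).mean())

    def test_all_censored_group_flat_at_one(self):
        surv = make_surv([1, 2, 3, 4], [0, 0, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"], index=surv.sample_ids)
        curves, _ = km_logrank_compare(groups, surv)
        assert (curves["a"]["survival"] == 1.0).all()

    def test_single_group_rejected(self):
        surv = make_surv([1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            km_logrank_compare(pd.Series(["a", "a"], index=surv.sample_ids), surv)


class TestConcordance:
    def test_perfectly_ordered_scores(self):
        surv = make_surv([5, 4, 3, 2, 1], [1] * 5)
        c, _ = concordance_index(_scores([1, 2, 3, 4, 5]), surv)
        assert c == 1.0

    def test_anti_ordered_scores(self):
        surv = make_surv([5, 4, 3, 2, 1], [1] * 5)
        c, _ = concordance_index(_scores([5, 4, 3, 2, 1]), surv)
        assert c == 0.0

    def test_censored_six_subject_case_matches_enumeration(self):
        time = np.array([3.0, 5, 7, 2, 8, 4])
        event = np.array([1, 0, 1, 1, 0, 0])
        x = np.array([2.0, 1, 1, 3, 0, 2])
        c, _ = concordance_index(_scores(x), make_surv(time, event))
        nc = nd = nt = 0
        for i in range(6):
            for j in range(6):
                if time[j] < time[i] and event[j] == 1:
                    nc += x[j] > x[i]
                    nd += x[j] < x[i]
                    nt += x[j] == x[i]
        assert c == pytest.approx((nc + 0.5 * nt) / (nc + nd + nt))

    def test_no_comparable_pairs_rejected(self):
        surv = make_surv([1, 2], [0, 0])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(_scores([1, 2]), surv)


class TestTimeDependentAUC:
    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 1000
        surv = make_surv(rng.exponential(100, n), rng.integers(0, 2, n))
        roc = td_auc(_scores(rng.normal(size=n)), surv, 80.0)
        assert abs(roc.auc - 0.5) < 0.05

    def test_score_equal_to_negative_time_is_perfect(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(100, 50)
        surv = make_surv(time, [1] * 50)
        roc = td_auc(_scores(-time), surv, float(np.median(time)) + 1e-9)
        assert roc.auc == pytest.approx(1.0)

    def test_no_events_by_horizon_rejected(self):
        surv = make_surv([100.0, 200.0], [1, 1])
        with pytest.raises(ValueError, match="no events"):
            td_auc(_scores([1, 2]), surv, 50.0)


class TestCoxRegression:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(2)
        n = 1000
        surv = make_surv(rng.exponential(100, n), [1] * n)
        cov = pd.DataFrame({"z": rng.normal(size=n)}, index=surv.sample_ids)
        res = cox_regression(surv, cov, mode="univariate")
        assert 0.8 <= res.frame.loc["z", "hr"] <= 1.25

    def test_rate_ratio_two_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        g = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / (0.01 * 2.0**g))
        surv = make_surv(time, [1] * n)
        cov = pd.DataFrame({"g": g.astype(float)}, index=surv.sample_ids)
        res = cox_regression(surv, cov, mode="multivariate")
        assert 1.8 <= res.frame.loc["g", "hr"] <= 2.2

    def test_five_subject_coefficient_matches_brute_force(self):
        time = np.array([1.0, 2.5, 3.1, 4.7, 6.2])
        event = np.array([1, 1, 0, 1, 1])
        z = np.array([0.5, -1.2, 0.3, 2.0, -0.7])
        surv = make_surv(time, event)
        res = cox_regression(surv, pd.DataFrame({"z": z}, index=surv.sample_ids), "univariate")

        def neg_pl(beta):
            lp = beta * z
            return -sum(
                lp[i] - np.log(np.exp(lp[time >= time[i]]).sum())
                for i in range(5)
                if event[i]
            )

        oracle = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded").x
        assert np.log(res.frame.loc["z", "hr"]) == pytest.approx(oracle, abs=1e-4)

    def test_sex_and_stage_encoding(self):
        rng = np.random.default_rng(5)
        n = 300
        surv = make_surv(rng.exponential(100, n), [1] * n)
        cov = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], n),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
            },
            index=surv.sample_ids,
        )
        res = cox_regression(surv, cov, mode="multivariate")
        assert set(res.frame.index) == {"sex", "stage"}
        assert (res.frame["hr"] > 0).all()


class TestStratifiedAnalysis:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 300
        age = rng.integers(40, 90, n).astype(float)
        risk = rng.integers(0, 2, n)
        # planted effect only in the older stratum
        hazard = 0.01 * np.exp(np.where(age > 65, 1.2 * risk, 0.0))
        surv = make_surv(rng.exponential(1 / hazard), [1] * n, age=age)
        scores = assign_groups(_scores(risk.astype(float), ids=surv.sample_ids), 0.5)
        return scores, surv

    def test_effect_confined_to_planted_stratum(self):
        scores, surv = self._cohort(seed=8)
        out = stratified_analysis(scores, surv, strata=("age",))
        assert out["age"]["age>65"]["logrank_p"] < 0.05
        assert out["age"]["age<=65"]["logrank_p"] > 0.05

    def test_stratum_sizes_cover_cohort(self):
        scores, surv = self._cohort(seed=9)
        out = stratified_analysis(scores, surv, strata=("age",))
        assert sum(level["n"] for level in out["age"].values()) == len(surv.sample_ids)

    def test_unknown_stratum_rejected(self):
        scores, surv = self._cohort()
        with pytest.raises(ValueError, match="unknown stratum"):
            stratified_analysis(scores, surv, strata=("ethnicity",))

    def test_missing_covariate_column_rejected(self):
        scores, surv = self._cohort()
        with pytest.raises(ValueError, match="lacks covariate"):
            stratified_analysis(scores, surv, strata=("stage",))


class TestEvaluateCohort:
    def test_report_fields_consistent(self, small_cohort):
        _, expr, surv, truth = small_cohort
        sig = PrognosticSignature(
            [(p, b) for p, b in zip(truth.signal_pairs, truth.true_coefficients)]
        )
        scores = compute_risk_scores(expr, sig)
        report = evaluate_cohort(scores, surv, horizons=(1, 3))
        assert report.n_samples == len(surv.sample_ids)
        assert 0 <= report.logrank_p <= 1
        assert report.c_index_ci[0] <= report.c_index <= report.c_index_ci[1]
        assert set(report.auc) <= {1, 3}
        d = report.to_dict()
        assert d["c_index"] == report.c_index
        for curve in report.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
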