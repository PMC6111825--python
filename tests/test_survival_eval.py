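import math

import numpy as np
import pandas as pd
import pytest

from subpathsig.activity_search import ActivityMatrix
from subpathsig.signature import HIGH, LOW, RiskScoreTable
from subpathsig.survival_eval import (
    activity_correlation,
    compare_auc,
    km_curve,
    logrank,
    multivariate_cox_backward,
    stratified_evaluate,
    td_roc,
)

from conftest import make_clinical


def risk_table(samples, groups, scores=None):
    scores = scores if scores is not None else np.zeros(len(samples))
    return RiskScoreTable(pd.DataFrame(
        {"score": scores, "group": groups}, index=samples
    ))


def logrank_oracle(t1, e1, t2, e2):
    """Textbook O-E/V log-rank chi-square (hypergeometric tie variance)."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for t in times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        times = [3, 5, 8, 12]
        events = [1, 0, 1, 1]
        clin = make_clinical(times * 2, events * 2,
                             samples=[f"s{j}" for j in range(8)])
        table = risk_table(clin.samples, [HIGH] * 4 + [LOW] * 4)
        chi2, p = logrank(table, clin)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_built_oe_table(self):
        # A: deaths at 1,2,3; B: deaths at 4,5,6 -> chi2 = 5.0517
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1] * 6,
                             samples=list("abcdef"))
        table = risk_table(clin.samples, [HIGH] * 3 + [LOW] * 3)
        chi2, _ = logrank(table, clin)
        oracle = logrank_oracle([1, 2, 3], [1] * 3, [4, 5, 6], [1] * 3)
        assert chi2 == pytest.approx(oracle, abs=1e-9)
        assert chi2 == pytest.approx(5.0517, abs=1e-3)

    def test_oracle_agreement_on_random_small_cohorts(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 11))
            t = rng.integers(1, 20, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            g = rng.integers(0, 2, size=n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            clin = make_clinical(t, e, samples=[f"s{j}" for j in range(n)])
            table = risk_table(clin.samples,
                               np.where(g == 1, HIGH, LOW))
            chi2, _ = logrank(table, clin)
            oracle = logrank_oracle(t[g == 1], e[g == 1],
                                    t[g == 0], e[g == 0])
            assert chi2 == pytest.approx(oracle, abs=1e-8)

    def test_time_rescaling_invariance(self):
        clin1 = make_clinical([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1],
                              samples=list("abcdef"))
        clin2 = make_clinical([10, 20, 30, 40, 50, 60], [1, 0, 1, 1, 0, 1],
                              samples=list("abcdef"))
        table = risk_table(list("abcdef"), [HIGH, LOW] * 3)
        assert logrank(table, clin1) == pytest.approx(logrank(table, clin2))

    def test_empty_group_rejected(self):
        clin = make_clinical([1, 2], [1, 1], samples=["a", "b"])
        with pytest.raises(ValueError, match="non-empty"):
            logrank(risk_table(["a", "b"], [HIGH, HIGH]), clin)


class TestKaplanMeier:
    def test_distinct_events_step_down_by_1_over_n(self):
        curve = km_curve([1, 2, 3, 4, 5], [1] * 5)
        steps = curve.survival[np.isin(curve.times, [1, 2, 3, 4, 5])]
        np.testing.assert_allclose(steps, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_all_censored_flat_no_median(self):
        curve = km_curve([4, 8, 15], [0, 0, 0])
        np.testing.assert_allclose(curve.survival, 1.0)
        assert curve.median is None

    def test_median_is_earliest_time_at_or_below_half(self):
        # times (1,2,3,4) all events: S = .75,.5,.25,0 -> median 2
        assert km_curve([1, 2, 3, 4], [1] * 4).median == 2

    def test_censoring_between_events(self):
        # product-limit by hand: d@1 of 4 -> .75; censor@2; d@3 of 2 -> .375
        curve = km_curve([1, 2, 3, 4], [1, 0, 1, 0])
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(3) == pytest.approx(0.375)


class TestMultivariateCoxBackward:
    def test_noise_dropped_prognostic_kept(self, rng):
        n = 400
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        lam0 = math.log(2) / 80
        t = rng.exponential(1 / (lam0 * np.exp(1.0 * x)))
        c = rng.uniform(0, 400, size=n)
        clin = make_clinical(
            np.maximum(np.minimum(t, c), 1e-3), (t <= c).astype(int),
            signature=x, noise=noise,
        )
        out = multivariate_cox_backward(clin, ["signature", "noise"])
        assert "signature" in out.index
        assert "noise" not in out.index

    def test_all_null_mostly_empty(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(6000 + seed)
            n = 150
            t = rng.exponential(80, size=n)
            clin = make_clinical(
                np.maximum(t, 1e-3), np.ones(n, dtype=int),
                a=rng.normal(size=n), b=rng.normal(size=n),
            )
            out = multivariate_cox_backward(clin, ["a", "b"])
            if len(out) == 0:
                hits += 1
        assert hits >= 8

    def test_single_significant_covariate_retained(self, rng):
        n = 300
        x = rng.normal(size=n)
        lam0 = math.log(2) / 80
        t = rng.exponential(1 / (lam0 * np.exp(x)))
        clin = make_clinical(np.maximum(t, 1e-3), np.ones(n, dtype=int), x=x)
        out = multivariate_cox_backward(clin, ["x"])
        assert list(out.index) == ["x"]
        assert out.loc["x", "p"] <= 0.05


class TestTimeDependentRoc:
    def test_perfect_ordering_auc_one(self):
        # cases (events before horizon) all score above controls
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 0, 0, 0]
        scores = [9.0, 8.0, 7.0, 1.0, 2.0, 3.0]
        clin = make_clinical(times, events,
                             samples=[f"s{j}" for j in range(6)])
        assert td_roc(np.array(scores), clin, horizon=5.0) == 1.0

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(77)
        n = 2000
        t = rng.exponential(80, size=n)
        e = np.ones(n, dtype=int)
        scores = rng.normal(size=n)
        clin = make_clinical(np.maximum(t, 1e-3), e,
                             samples=[f"s{j}" for j in range(n)])
        auc = td_roc(scores, clin, horizon=float(np.median(t)))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_equals_mann_whitney_without_censoring(self, rng):
        n = 60
        t = rng.exponential(50, size=n)
        scores = 0.5 * t.max() / (t + 1) + rng.normal(scale=0.1, size=n)
        clin = make_clinical(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                             samples=[f"s{j}" for j in range(n)])
        horizon = float(np.median(t))
        auc = td_roc(scores, clin, horizon)
        cases = t <= horizon
        controls = t > horizon
        # direct counting oracle (concordant pairs, ties half)
        sc, so = scores[cases][:, None], scores[controls][None, :]
        mw = ((sc > so).sum() + 0.5 * (sc == so).sum()) / (
            cases.sum() * controls.sum())
        assert auc == pytest.approx(mw, abs=1e-12)

    def test_matches_independent_ipcw_implementation(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        n = 400
        risk = rng.normal(size=n)
        lam0 = math.log(2) / 60
        t = rng.exponential(1 / (lam0 * np.exp(risk)))
        c = rng.uniform(0, 250, size=n)
        times = np.maximum(np.minimum(t, c), 1e-3)
        events = (t <= c).astype(int)
        clin = make_clinical(times, events,
                             samples=[f"s{j}" for j in range(n)])
        horizon = float(np.quantile(times, 0.4))
        ours = td_roc(risk, clin, horizon)
        y = np.array(list(zip(events.astype(bool), times)),
                     dtype=[("event", bool), ("time", float)])
        ref_auc, _ = sksurv_metrics.cumulative_dynamic_auc(
            y, y, risk, [horizon])
        assert ours == pytest.approx(float(ref_auc[0]), abs=0.02)

    def test_no_cases_at_horizon_rejected(self):
        clin = make_clinical([10, 12, 14], [0, 0, 0],
                             samples=["a", "b", "c"])
        with pytest.raises(ValueError, match="cases|controls"):
            td_roc(np.array([1.0, 2.0, 3.0]), clin, horizon=11.0)

    def test_horizon_outside_range_rejected(self):
        clin = make_clinical([10, 12], [1, 1], samples=["a", "b"])
        with pytest.raises(ValueError, match="horizon"):
            td_roc(np.array([1.0, 2.0]), clin, horizon=100.0)


class TestCompareAuc:
    def test_informative_beats_noise(self, rng):
        n = 300
        risk = rng.normal(size=n)
        lam0 = math.log(2) / 60
        t = rng.exponential(1 / (lam0 * np.exp(1.5 * risk)))
        clin = make_clinical(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                             samples=[f"s{j}" for j in range(n)])
        noise = rng.normal(size=n)
        delta, p = compare_auc(risk, noise, clin,
                               horizon=float(np.median(t)),
                               n_boot=200, seed=4)
        assert delta > 0
        assert p < 0.05

    def test_score_against_itself_null(self, rng):
        n = 200
        t = rng.exponential(60, size=n)
        clin = make_clinical(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                             samples=[f"s{j}" for j in range(n)])
        s = rng.normal(size=n)
        delta, p = compare_auc(s, s, clin, horizon=float(np.median(t)),
                               n_boot=100, seed=5)
        assert delta == 0.0
        assert p == 1.0


class TestActivityCorrelation:
    def act(self, vals, ids):
        return ActivityMatrix(pd.DataFrame(
            np.asarray(vals, dtype=float), index=ids,
            columns=[f"s{j}" for j in range(np.shape(vals)[1])]
        ))

    def test_self_and_negation(self):
        row = [1.0, 2.0, 4.0, 3.0]
        act = self.act([row, [-x for x in row]], ["a", "b"])
        corr = activity_correlation(act)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(123)
        act = self.act(rng.normal(size=(2, 1000)), ["a", "b"])
        corr = activity_correlation(act)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_zero_variance_row_flagged_nan(self):
        act = self.act([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "ok"])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = activity_correlation(act)
        assert np.isnan(corr.loc["flat", "ok"])

    def test_single_member_rejected(self):
        act = self.act([[1.0, 2.0]], ["a"])
        with pytest.raises(ValueError):
            activity_correlation(act)


class TestStratifiedEvaluate:
    def setup_cohort(self, rng, n=80):
        er = np.where(rng.random(n) < 0.5, "positive", "negative")
        risk = rng.normal(size=n)
        lam0 = math.log(2) / 80
        t = rng.exponential(1 / (lam0 * np.exp(risk)))
        clin = make_clinical(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                             samples=[f"s{j}" for j in range(n)], er=er)
        groups = risk_table(clin.samples,
                            np.where(risk > 0, HIGH, LOW), scores=risk)
        return clin, groups

    def test_empty_stratum_rejected(self, rng):
        clin, groups = self.setup_cohort(rng)
        with pytest.raises(ValueError, match="empty"):
            stratified_evaluate(lambda df: df["er"] == "unknown",
                                groups, clin)

    def test_trivial_predicate_matches_unstratified(self, rng):
        clin, groups = self.setup_cohort(rng)
        res = stratified_evaluate(lambda df: df["er"].notna(), groups, clin)
        chi2, p = logrank(groups, clin)
        assert res["logrank_chi2"] == pytest.approx(chi2)
        assert res["logrank_p"] == pytest.approx(p)

    def test_complementary_strata_partition_cohort(self, rng):
        clin, groups = self.setup_cohort(rng)
        pos = stratified_evaluate(lambda df: df["er"] == "positive",
                                  groups, clin)
        neg = stratified_evaluate(lambda df: df["er"] == "negative",
                                  groups, clin)
        assert pos["n"] + neg["n"] == len(clin.samples)
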