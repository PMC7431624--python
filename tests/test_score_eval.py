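import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synscore import (
    GeneSetCollection,
    SsgseaParams,
    SyntheticCohortConfig,
    adjusted_cox,
    cox_univariate,
    diag_roc,
    evaluate_signature,
    group_rank_tests,
    km_logrank,
    median_split,
    score_matrix,
    simulate_cohorts,
)

from conftest import make_clinical


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert set(labels[labels == "high"].index) == {"c", "d"}
        assert set(labels[labels == "low"].index) == {"a", "b"}

    def test_median_sample_goes_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert labels["b"] == "low"

    def test_order_invariance(self):
        s = pd.Series([3.0, 1.0, 4.0, 2.0], index=list("abcd"))
        a = median_split(s)
        b = median_split(s.sample(frac=1, random_state=0))
        assert a.sort_index().equals(b.sort_index())

    def test_balance_with_distinct_scores(self):
        rng = np.random.default_rng(0)
        for n in (10, 11, 50, 51):
            labels = median_split(pd.Series(rng.normal(size=n)))
            assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1

    def test_all_identical_errors(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([5.0, 8, 12, 20, 7, 9])
        event = np.array([1.0, 0, 1, 0, 1, 1])
        clin = make_clinical(
            np.concatenate([time, time]), np.concatenate([event, event]),
            [f"s{i}" for i in range(12)],
        )
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=clin.sample_ids)
        res = km_logrank(groups, clin)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(1)
        n = 60
        clin = make_clinical(rng.exponential(10, n), rng.integers(0, 2, n).astype(float))
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=clin.sample_ids)
        res = km_logrank(groups, clin)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)

    def test_halved_hazard_detected(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 200
            t_a = rng.exponential(10, n)
            t_b = rng.exponential(20, n)  # half the hazard
            c = rng.exponential(40, 2 * n)
            time = np.concatenate([t_a, t_b])
            event = (time <= c).astype(float)
            time = np.minimum(time, c)
            clin = make_clinical(time, event)
            groups = pd.Series(["low"] * n + ["high"] * n, index=clin.sample_ids)
            hits += km_logrank(groups, clin).p < 0.01
        assert hits == 3

    def test_group_without_events_errors(self):
        clin = make_clinical([1.0, 2, 3, 4], [1, 1, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=clin.sample_ids)
        with pytest.raises(ValueError, match="events"):
            km_logrank(groups, clin)


@pytest.fixture(scope="module")
def confounded():
    # grade correlated with program activity AND survival
    cohorts, _ = simulate_cohorts(
        SyntheticCohortConfig(n_samples=250, n_genes=50, term_size_range=(5, 15)), seed=5
    )
    _, clin = cohorts[0]
    return clin


class TestAdjustedCox:
    def test_none_reduces_to_univariate(self, confounded):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=len(confounded)), index=confounded.sample_ids)
        a = adjusted_cox(scores, confounded, adjustment="none")
        b = cox_univariate(scores, confounded)
        assert a.hr == pytest.approx(b.hr)
        assert a.p == pytest.approx(b.p)

    def test_grade_adjustment_shrinks_confounded_effect(self):
        shrunk = 0
        for seed in range(10):
            cohorts, truth = simulate_cohorts(
                SyntheticCohortConfig(
                    n_samples=300, n_genes=30, grade_link=2.0, term_size_range=(5, 10)
                ),
                seed=seed,
            )
            _, clin = cohorts[0]
            act = truth.activities["batch1"].loc[clin.sample_ids]
            # noisy surrogate of activity: correlated with grade through activity
            scores = act + np.random.default_rng(seed).normal(0, 1.0, size=len(act))
            un = adjusted_cox(scores, clin, adjustment="none")
            ad = adjusted_cox(scores, clin, adjustment="grade")
            shrunk += abs(np.log(ad.hr)) <= abs(np.log(un.hr))
        assert shrunk >= 8

    def test_categorical_grade_coding_runs(self, confounded):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=len(confounded)), index=confounded.sample_ids)
        res = adjusted_cox(scores, confounded, adjustment="grade", grade_coding="categorical")
        assert res.ok

    def test_missing_covariate_errors(self):
        clin = make_clinical([1.0, 2, 3, 4], [1, 1, 1, 0])
        scores = pd.Series([0.1, 0.5, 0.2, 0.9], index=clin.sample_ids)
        with pytest.raises(ValueError, match="missing"):
            adjusted_cox(scores, clin, adjustment="idh")


class TestGroupRankTests:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=40)
        scores = pd.Series(np.concatenate([vals, vals]))
        labels = pd.Series(["a"] * 40 + ["b"] * 40)
        res = group_rank_tests(scores, labels)
        assert res.loc[("a", "b"), "p"] > 0.9

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=60))
        labels = pd.Series(rng.choice(["x", "y", "z"], size=60))
        a = group_rank_tests(scores, labels)["p"]
        b = group_rank_tests(np.exp(scores * 2), labels)["p"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_too_small_group_errors(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        labels = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            group_rank_tests(scores, labels)


class TestDiagRoc:
    def test_perfect_separation(self):
        scores = pd.Series([1.0, 2, 3, 10, 11, 12])
        tissue = pd.Series(["tumor"] * 3 + ["normal"] * 3)
        assert diag_roc(scores, tissue).auc == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(np.concatenate([rng.normal(0, 1, 80), rng.normal(1, 1, 40)]))
        tissue = pd.Series(["tumor"] * 80 + ["normal"] * 40)
        roc = diag_roc(scores, tissue)
        u, _ = stats.mannwhitneyu(scores[tissue == "normal"], scores[tissue == "tumor"])
        assert roc.auc == pytest.approx(u / (80 * 40), abs=1e-12)

    def test_label_flip_complement(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=50))
        tissue = pd.Series(rng.choice(["tumor", "normal"], size=50))
        a = diag_roc(scores, tissue).auc
        flipped = tissue.map({"tumor": "normal", "normal": "tumor"})
        assert a + diag_roc(scores, flipped).auc == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            diag_roc(pd.Series([1.0, 2.0]), pd.Series(["tumor", "tumor"]))


class TestEvaluateSignature:
    def test_full_report_on_glioma_like_cohort(self, tiny_cohorts):
        cohorts, truth = tiny_cohorts
        expr, clin = cohorts[0]
        coll = GeneSetCollection()
        coll.add(truth.planted_set)
        scores = score_matrix(expr, coll, SsgseaParams(min_size=1)).es.iloc[0]
        rep = evaluate_signature(scores, clin)
        assert rep.km is not None and 0 <= rep.km.p <= 1
        assert set(rep.cox) == {"none", "grade", "idh", "codel"}
        for stat in rep.cox.values():
            assert stat.hr < 1  # protective program
        assert rep.roc is not None and rep.roc.auc > 0.5
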