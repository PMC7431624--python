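import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter

from synscore import bh_adjust, combine_batches, cox_univariate, screen_terms, screen_units
from synscore.cox import CoxError, fit_cox
from synscore.ssgsea import EnrichmentScoreMatrix, SsgseaParams
from synscore.survival_screen import BatchStat, rank_records

from _oracles import bh_reference
from conftest import make_clinical


def _simulate_survival(rng, score, beta, censor_scale=3.0, h0=0.1):
    t = rng.exponential(1.0 / (h0 * np.exp(beta * score)))
    c = rng.exponential(censor_scale / h0, size=score.size)
    return np.minimum(t, c), (t <= c).astype(float)


class TestCoxFitter:
    @pytest.mark.parametrize("with_covariate", [False, True])
    def test_agrees_with_lifelines(self, with_covariate):
        rng = np.random.default_rng(10)
        n = 250
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        time, event = _simulate_survival(rng, -0.8 * x + (0.4 * z if with_covariate else 0), 1.0)
        fit = fit_cox(x, time, event.astype(bool), covariates=z[:, None] if with_covariate else None)
        df = pd.DataFrame({"T": time, "E": event, "x": x})
        if with_covariate:
            df["z"] = z
        ref = CoxPHFitter().fit(df, "T", "E")
        assert fit.coef == pytest.approx(ref.params_.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_.to_numpy(), abs=1e-4)
        assert fit.p == pytest.approx(float(ref.summary.p.iloc[0]), rel=1e-3)

    def test_null_score_ci_coverage(self):
        # score independent of survival: 95% CI should cover HR=1 in >=90/100 runs
        rng = np.random.default_rng(11)
        covered = 0
        for _ in range(100):
            x = rng.normal(size=500)
            time, event = _simulate_survival(rng, 0.0 * x, 0.0)
            fit = fit_cox(x, time, event.astype(bool))
            lo, hi = fit.ci95
            covered += lo <= 1.0 <= hi
        assert covered >= 90

    def test_hr_recovery_protective_effect(self):
        # hazard proportional to exp(-1 * score): true HR = exp(-1) = 0.368
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        time, event = _simulate_survival(rng, -1.0 * x, 1.0)
        fit = fit_cox(x, time, event.astype(bool))
        assert 0.30 <= fit.hr <= 0.45

    def test_no_events_errors(self):
        rng = np.random.default_rng(13)
        with pytest.raises(CoxError, match="events"):
            fit_cox(rng.normal(size=50), rng.exponential(size=50), np.zeros(50, dtype=bool))

    def test_zero_variance_errors(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(size=50)
        with pytest.raises(CoxError, match="variance"):
            fit_cox(np.ones(50), t, np.ones(50, dtype=bool))


class TestCoxUnivariate:
    def test_complete_case_n_reported(self):
        rng = np.random.default_rng(15)
        n = 80
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        time = rng.exponential(10, n)
        time[:5] = np.nan  # incomplete survival
        clin = make_clinical(time, rng.integers(0, 2, n).astype(float), list(score.index))
        stat = cox_univariate(score, clin)
        assert stat.ok
        assert stat.n == n - 5

    def test_all_censored_flagged(self):
        rng = np.random.default_rng(16)
        score = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        clin = make_clinical(rng.exponential(10, 30), np.zeros(30), list(score.index))
        stat = cox_univariate(score, clin)
        assert not stat.ok and "events" in stat.reason

    def test_zero_variance_flagged(self):
        rng = np.random.default_rng(17)
        score = pd.Series(np.ones(30), index=[f"s{i}" for i in range(30)])
        clin = make_clinical(rng.exponential(10, 30), np.ones(30), list(score.index))
        stat = cox_univariate(score, clin)
        assert not stat.ok and "variance" in stat.reason


class TestBhAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_reference_and_never_decreases(self, ps):
        out = bh_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-15)
        assert np.all(out <= 1.0)
        assert out == pytest.approx(bh_reference(ps), abs=1e-12)


def _stat(hr, p, fdr, ok=True):
    return BatchStat(hr=hr, ci95=(hr / 2, hr * 2), p=p, n=100, fdr=fdr, ok=ok)


class TestCombineBatches:
    def test_product(self):
        cfdr, _, _, _ = combine_batches([_stat(0.5, 0.01, 0.1), _stat(0.6, 0.02, 0.2)])
        assert cfdr == pytest.approx(0.02)

    def test_identity_element(self):
        cfdr, _, _, _ = combine_batches([_stat(0.5, 0.5, 1.0), _stat(0.6, 0.02, 0.07)])
        assert cfdr == pytest.approx(0.07)

    def test_opposite_directions_inconsistent(self):
        _, _, consistent, _ = combine_batches([_stat(0.5, 0.01, 0.1), _stat(1.2, 0.01, 0.1)])
        assert not consistent

    def test_hr_exactly_one_inconsistent(self):
        _, _, consistent, _ = combine_batches([_stat(1.0, 0.5, 0.5), _stat(1.2, 0.1, 0.1)])
        assert not consistent

    def test_failed_batch_unrankable(self):
        _, _, _, rankable = combine_batches([_stat(0.5, 0.01, 0.1), _stat(np.nan, np.nan, np.nan, ok=False)])
        assert not rankable

    def test_three_batches_supported(self):
        cfdr, _, consistent, _ = combine_batches(
            [_stat(0.5, 0.01, 0.1), _stat(0.6, 0.02, 0.2), _stat(0.7, 0.03, 0.3)]
        )
        assert cfdr == pytest.approx(0.006)
        assert consistent


def _two_batch_scores(rng, n=150, beta=1.0):
    """Three protective score units of decreasing strength."""
    batches = []
    for _ in range(2):
        a = rng.normal(size=n)
        time, event = _simulate_survival(rng, -beta * a, 1.0)
        clin = make_clinical(time, event, [f"s{i}" for i in range(n)])
        scores = pd.DataFrame(
            {
                f"s{i}": [
                    a[i] + 0.3 * rng.normal(),
                    a[i] + 1.5 * rng.normal(),
                    a[i] + 4.0 * rng.normal(),
                ]
                for i in range(n)
            },
            index=["strong", "medium", "weak"],
        )
        batches.append((scores, clin))
    return [b[0] for b in batches], [b[1] for b in batches]


class TestScreening:
    def test_ranking_and_batch_order_invariance(self):
        scores, clin = _two_batch_scores(np.random.default_rng(20))
        rec = screen_units(scores, clin)
        ranked = rank_records(rec)
        assert ranked.index[0] == "strong"
        swapped = screen_units(scores[::-1], clin[::-1])
        assert np.allclose(
            rec["combined_fdr"].to_numpy(), swapped["combined_fdr"].to_numpy(), rtol=1e-12
        )
        assert list(rank_records(swapped).index) == list(ranked.index)

    def test_sample_order_invariance(self):
        scores, clin = _two_batch_scores(np.random.default_rng(21))
        perm = np.random.default_rng(0).permutation(scores[0].shape[1])
        scores2 = [scores[0].iloc[:, perm], scores[1]]
        clin2 = [clin[0].subset([scores[0].columns[i] for i in perm]), clin[1]]
        a = screen_units(scores, clin)["combined_fdr"]
        b = screen_units(scores2, clin2)["combined_fdr"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)

    def test_screen_terms_top_k_and_exclusions(self):
        scores, clin = _two_batch_scores(np.random.default_rng(22))
        es = [EnrichmentScoreMatrix(s, SsgseaParams()) for s in scores]
        ranked, selected = screen_terms(es, clin, top_k=2)
        assert selected[0] == "strong"
        # excluding the top unit pulls in replacements from further down
        _, sel2 = screen_terms(es, clin, top_k=2, exclusions=["strong"])
        assert sel2 == ["medium", "weak"]

    def test_direction_inconsistent_never_selected(self):
        rng = np.random.default_rng(23)
        n = 150
        batches, clins = [], []
        for sign in (+1.0, -1.0):
            a = rng.normal(size=n)
            time, event = _simulate_survival(rng, -1.0 * a, 1.0)
            clins.append(make_clinical(time, event, [f"s{i}" for i in range(n)]))
            # "flip" unit is strongly associated but with opposite sign per batch
            batches.append(
                pd.DataFrame(
                    {f"s{i}": [a[i] + 0.3 * rng.normal(), sign * a[i]] for i in range(n)},
                    index=["steady", "flip"],
                )
            )
        es = [EnrichmentScoreMatrix(b, SsgseaParams()) for b in batches]
        ranked, selected = screen_terms(es, clins, top_k=1)
        assert "flip" not in ranked.index  # filtered before ranking
        assert selected == ["steady"]
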