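import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import mcds
from mcds.validation import (auc, auc_ci_delong, bootstrap_auc_ci,
                             compare_auc_paired, km_estimate, logrank,
                             validation_report)
from tests.conftest import survival_frame


class TestAuc:
    def test_perfect_separation(self):
        r = auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_is_half(self):
        assert auc([3, 3, 3, 3], [0, 1, 0, 1]).auc == 0.5

    def test_pair_counting_example(self):
        # cases {3, 2}, controls {1, 2}: (3>1)+(3>2)+(2>1)+0.5*(2=2) = 3.5/4
        r = auc([3, 2, 1, 2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(3.5 / 4)
        assert r.auc == pytest.approx(roc_auc_score([1, 1, 0, 0], [3, 2, 1, 2]))
        assert (r.n_pos, r.n_neg) == (2, 2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(20, 200)
            score = rng.normal(size=n).round(1)  # ties on purpose
            outcome = rng.binomial(1, 0.3, n)
            if outcome.sum() in (0, n):
                continue
            assert auc(score, outcome).auc == pytest.approx(
                roc_auc_score(outcome, score), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=300)
        outcome = rng.binomial(1, 0.2, 300)
        a = auc(score, outcome).auc
        assert auc(np.exp(score), outcome).auc == pytest.approx(a)
        assert auc(3 * score - 7, outcome).auc == pytest.approx(a)


class TestDelongCi:
    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        score = rng.normal(size=500) + rng.binomial(1, 0.3, 500)
        outcome = rng.binomial(1, 0.3, 500)
        r = auc_ci_delong(score, outcome)
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0.0 <= r.ci_low and r.ci_high <= 1.0

    def test_perfect_auc_truncates_to_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = auc_ci_delong([1, 2, 9, 10], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.ci_high == 1.0

    def test_duplication_narrows_ci_keeps_estimate(self):
        rng = np.random.default_rng(3)
        score = rng.normal(size=200)
        outcome = rng.binomial(1, 0.4, 200)
        r1 = auc_ci_delong(score, outcome)
        r2 = auc_ci_delong(np.tile(score, 2), np.tile(outcome, 2))
        assert r2.auc == pytest.approx(r1.auc)
        assert (r2.ci_high - r2.ci_low) < (r1.ci_high - r1.ci_low)

    def test_null_coverage(self):
        # a score independent of the outcome: the 95% CI should cover 0.5 in
        # roughly 95% of draws
        rng = np.random.default_rng(4)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            score = rng.normal(size=300)
            outcome = rng.binomial(1, 0.25, 300)
            r = auc_ci_delong(score, outcome)
            covered += r.ci_low <= 0.5 <= r.ci_high
        assert 0.89 <= covered / n_rep <= 0.99

    def test_bootstrap_agrees_with_delong(self):
        rng = np.random.default_rng(5)
        score = rng.normal(size=400) + 0.8 * rng.binomial(1, 0.3, 400)
        outcome = rng.binomial(1, 0.3, 400)
        d = auc_ci_delong(score, outcome)
        b = bootstrap_auc_ci(score, outcome, n_boot=500, seed=5)
        assert b.auc == pytest.approx(d.auc)
        assert b.ci_low == pytest.approx(d.ci_low, abs=0.03)
        assert b.ci_high == pytest.approx(d.ci_high, abs=0.03)


class TestPairedComparison:
    def test_score_against_itself_is_zero(self):
        rng = np.random.default_rng(6)
        score = rng.normal(size=300)
        outcome = rng.binomial(1, 0.3, 300)
        chi2, p = compare_auc_paired(score, score, outcome)
        assert chi2 == 0.0 and p == 1.0

    def test_rank_invariance(self):
        rng = np.random.default_rng(7)
        score = rng.normal(size=300)
        outcome = rng.binomial(1, 0.3, 300)
        chi2, _ = compare_auc_paired(score, 2.0 * score, outcome)
        assert chi2 == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 400))
        outcome = rng.binomial(1, 0.3, 400)
        assert compare_auc_paired(a, b, outcome) == compare_auc_paired(b, a, outcome)

    def test_type_i_error_near_nominal(self):
        # two independent null scores: rejection at 5% should occur ~5% of runs
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 500))
            outcome = rng.binomial(1, 0.2, 500)
            _, p = compare_auc_paired(a, b, outcome)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        surv = survival_frame([365] * 10, [0] * 10)
        curves = km_estimate(surv, np.ones(10, dtype=int))
        assert curves[1]["survival"].iloc[-1] == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_fraction(self):
        times = [50, 100, 150, 200, 250, 300, 320, 340, 350, 360]
        surv = survival_frame(times, [1] * 10)
        curves = km_estimate(surv, np.ones(10, dtype=int))
        tbl = curves[1]
        # after the k-th death the estimate is 1 - k/10
        at_200 = tbl.loc[tbl["time"] <= 200, "survival"].iloc[-1]
        assert at_200 == pytest.approx(0.6)

    def test_single_death_product_limit(self):
        surv = survival_frame([100] + [365] * 9, [1] + [0] * 9)
        curves = km_estimate(surv, np.ones(10, dtype=int))
        assert curves[1]["survival"].iloc[-1] == pytest.approx(0.9)

    def test_curve_never_increases(self, small_bundle):
        surv = mcds.build_survival(small_bundle["cohort"], small_bundle["outcomes"])
        classes = np.ones(len(surv), dtype=int)
        tbl = km_estimate(surv, classes)[1]
        assert (np.diff(tbl["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_zero(self):
        base = survival_frame([100, 200, 365, 365], [1, 1, 0, 0])
        doubled = pd.concat([base, base], ignore_index=True)
        classes = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        chi2, df, p = logrank(doubled, classes)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_df_is_k_minus_one(self):
        rng = np.random.default_rng(10)
        surv = survival_frame(rng.integers(1, 365, 300),
                              rng.binomial(1, 0.5, 300))
        _, df, _ = logrank(surv, rng.integers(1, 5, 300))
        assert df == 3

    def test_power_against_strong_hazard_ratio(self):
        # two groups with hazard ratio 5: detection should be essentially sure
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(1 / 0.0002, 1000)
            t2 = rng.exponential(1 / 0.001, 1000)
            t = np.concatenate([t1, t2])
            surv = survival_frame(np.minimum(t, 365).astype(int) + 1,
                                  (t <= 365).astype(int))
            _, _, p = logrank(surv, np.repeat([1, 2], 1000))
            rejections += p < 0.001
        assert rejections == 10

    def test_single_class_rejected(self):
        surv = survival_frame([100, 365], [1, 0])
        with pytest.raises(ValueError):
            logrank(surv, np.array([1, 1]))


class TestReport:
    def test_report_structure_and_comparator(self, small_bundle):
        surv = mcds.build_survival(small_bundle["cohort"], small_bundle["outcomes"])
        truth = small_bundle["truth"].set_index("patient_id")
        weights = mcds.default_weights()
        profiles = truth[[c for c in truth.columns
                          if c not in ("linear_predictor", "death_day_uncensored")]]
        scores = mcds.score_profiles(profiles, weights)
        rng = np.random.default_rng(1)
        comparators = pd.DataFrame({
            "patient_id": scores["patient_id"],
            "noise_index": rng.normal(size=len(scores)),
        })
        report = validation_report(scores, surv, comparators)
        assert 0.0 <= report["auc"] <= 1.0
        assert report["ci_low"] <= report["auc"] <= report["ci_high"]
        assert report["logrank"]["df"] == scores["risk_class"].nunique() - 1
        comp = report["comparisons"]["noise_index"]
        assert comp["chi_square"] >= 0.0
        # an uninformative comparator should sit near 0.5
        assert abs(comp["auc"] - 0.5) < 0.1
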