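"""Logistic screen and random-forest comparison machinery.

Independent oracles: closed-form Welch statistic and the Mann-Whitney
identity for ROC AUC.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mirpipe.discrimination import (
    _metrics_from_confusion,
    fit_univariate_lr,
    lr_results_frame,
    resampled_roc_comparison,
    rf_cv_metrics,
    run_panel_lr,
    subgroup_view,
    validate_cohort,
)
from mirpipe.simulate import default_cohort_params, generate_cohort


def welch_oracle(x, y):
    """Closed-form Welch t statistic, dof and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    dof = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), dof)
    return t, dof, p


def mann_whitney_auc(y, scores):
    """AUC = U / (n_pos * n_neg), ties counted half."""
    y, scores = np.asarray(y), np.asarray(scores, float)
    pos, neg = scores[y == 1], scores[y == 0]
    u = 0.0
    for p in pos:
        u += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return u / (len(pos) * len(neg))


class TestOracles:
    def test_welch_ttest_matches_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0.8, 0.05, 100)
            y = rng.normal(0.81, 0.04, 100)
            t, dof, p = welch_oracle(x, y)
            res = stats.ttest_ind(x, y, equal_var=False)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-10)

    def test_roc_auc_matches_mann_whitney_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(60), 2)  # induce ties
            assert roc_auc_score(y, scores) == pytest.approx(
                mann_whitney_auc(y, scores), abs=1e-12
            )


class TestUnivariateLr:
    def test_planted_marker_detected_and_null_not_inflated(self, default_cohort):
        df, truth = default_cohort
        adj = fit_univariate_lr(df, "miR-21", adjusted=True)
        assert adj.p_adjusted < 0.05 and adj.coefficient > 0
        assert adj.n_used == len(df)

    def test_missing_calls_reduce_n_used(self):
        df, _ = generate_cohort(default_cohort_params(3, missing_rate=0.1))
        res = fit_univariate_lr(df, "miR-21", adjusted=False)
        assert res.n_used < len(df)
        assert res.n_used == int(df["miR-21"].notna().sum())

    def test_zero_variance_mir_is_an_error(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["miR-9"] = 1
        with pytest.raises(ValueError, match="zero variance"):
            fit_univariate_lr(df, "miR-9")

    def test_null_p_values_are_calibrated(self):
        # a mir independent of status: fraction of p<0.05 within 99% binomial
        # bounds of 0.05 (400 replicates on the unadjusted model)
        n_reps, hits = 400, 0
        for s in range(n_reps):
            df, _ = generate_cohort(
                default_cohort_params(
                    s, n_cases=200, n_controls=200, mir_odds_ratios={},
                    mir_panel=("miR-9",),
                )
            )
            r = fit_univariate_lr(df, "miR-9", adjusted=False)
            hits += r.p_unadjusted < 0.05
        rate = hits / n_reps
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half, rate

    def test_adjusted_fit_survives_constant_covariates_in_subgroups(self, default_cohort):
        # within a former-smokers-only view the smoking dummies are constant;
        # the adjusted model must drop them instead of failing on collinearity
        former = subgroup_view(default_cohort[0], "former")
        res = fit_univariate_lr(former, "miR-21", adjusted=True)
        assert res.reliable and res.p_adjusted is not None

    def test_separation_is_flagged_not_silent(self):
        df, _ = generate_cohort(default_cohort_params(5))
        df = df.copy()
        df["miR-9"] = (df["status"] == "case").astype(int)  # perfect separation
        res = fit_univariate_lr(df, "miR-9", adjusted=False)
        assert not res.reliable


class TestPanelLr:
    def test_empty_panel_gives_empty_results(self, default_cohort):
        assert run_panel_lr(default_cohort[0], panel=[]) == []

    def test_housekeeper_excluded_with_note(self, default_cohort, caplog):
        df, _ = default_cohort
        df = df.copy()
        df["miR-423-5p"] = df["miR-21"]
        with caplog.at_level("INFO"):
            res = run_panel_lr(df, panel=["miR-21", "miR-423-5p"])
        assert [r.mir_id for r in res] == ["miR-21"]
        assert any("housekeeper" in r.message for r in caplog.records)

    def test_degenerate_mir_does_not_abort_the_panel(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["miR-9"] = 0
        res = run_panel_lr(df, panel=["miR-9", "miR-21"])
        by_mir = {r.mir_id: r for r in res}
        assert not by_mir["miR-9"].reliable
        assert by_mir["miR-21"].p_adjusted is not None

    def test_results_frame_mirrors_two_p_columns(self, default_cohort):
        res = run_panel_lr(default_cohort[0], panel=["miR-21", "miR-33b"])
        frame = lr_results_frame(res)
        assert list(frame.columns[:3]) == ["miRNA", "p", "p.adj"]
        assert len(frame) == 2


class TestRfCv:
    def test_perfect_predictor_scores_perfectly(self, default_cohort):
        df, _ = default_cohort
        df = df.copy()
        df["miR-9"] = (df["status"] == "case").astype(int)
        cv = rf_cv_metrics(df, "mirs", n_repeats=2, seed=0, panel=["miR-9"], n_trees=25)
        for k in ("accuracy", "sensitivity", "specificity"):
            assert cv.metrics[k] == pytest.approx(1.0)

    def test_metric_identities_hold_on_every_fold(self, default_cohort):
        df, _ = default_cohort
        cv = rf_cv_metrics(df, "clinical", n_repeats=3, seed=1, n_trees=25)
        for fold in cv.per_fold:
            expected = _metrics_from_confusion(
                {k: fold[k] for k in ("tp", "tn", "fp", "fn")}
            )
            for k, v in expected.items():
                assert fold[k] == pytest.approx(v, nan_ok=True)
        assert fold["tp"] + fold["tn"] + fold["fp"] + fold["fn"] > 0

    def test_uninformative_features_score_near_chance(self):
        # label-independent features, balanced classes: accuracy ~ 0.5
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            df, _ = generate_cohort(
                default_cohort_params(
                    s, n_cases=150, n_controls=150, mir_odds_ratios={},
                    age_mean_case=56.40, pack_years_mean_case=19.21,
                    quit_years_mean_case=9.40,
                    smoking_probs_case=(0.205, 0.416, 0.379),
                    uld_probs_case=(0.45, 0.11, 0.44),
                    gender_male_prob_case=0.497,
                )
            )
            cv = rf_cv_metrics(df, "combined", n_repeats=2, seed=s, n_trees=50)
            hits += 0.40 <= cv.metrics["accuracy"] <= 0.60
        assert hits / n_seeds >= 0.95

    def test_reproducible_given_seed(self, default_cohort):
        df, _ = default_cohort
        a = rf_cv_metrics(df, "clinical", n_repeats=2, seed=7, n_trees=25)
        b = rf_cv_metrics(df, "clinical", n_repeats=2, seed=7, n_trees=25)
        assert a.metrics == b.metrics and a.per_fold == b.per_fold


class TestResampledComparison:
    def test_identical_feature_sets_show_no_difference(self):
        agree = 0
        n_seeds = 10
        for s in range(n_seeds):
            df, _ = generate_cohort(default_cohort_params(300 + s, mir_odds_ratios={}))
            c = resampled_roc_comparison(
                df, "clinical", "clinical", n_splits=20, seed=s, n_trees=100
            )
            agree += abs(c.auc_difference_pct) <= 0.5 and c.welch_p > 0.5
        assert agree / n_seeds >= 0.90

    def test_reproducible_auc_lists(self, default_cohort):
        df, _ = default_cohort
        a = resampled_roc_comparison(df, "clinical", "combined", n_splits=5, seed=3, n_trees=25)
        b = resampled_roc_comparison(df, "clinical", "combined", n_splits=5, seed=3, n_trees=25)
        assert a.auc_a == b.auc_a and a.auc_b == b.auc_b

    def test_planted_mir_signal_raises_combined_auc(self, default_cohort):
        df, _ = default_cohort
        c = resampled_roc_comparison(df, "clinical", "combined", n_splits=20, seed=0, n_trees=100)
        assert c.mean_auc_b > c.mean_auc_a
        assert c.auc_difference_pct == pytest.approx(
            100 * (np.mean(c.auc_b) - np.mean(c.auc_a))
        )
        assert all(0 <= a <= 1 for a in c.auc_a + c.auc_b)

    def test_welch_p_matches_oracle_on_the_reported_auc_vectors(self, default_cohort):
        df, _ = default_cohort
        c = resampled_roc_comparison(df, "clinical", "combined", n_splits=10, seed=1, n_trees=25)
        _, _, p = welch_oracle(np.array(c.auc_b), np.array(c.auc_a))
        assert c.welch_p == pytest.approx(p, abs=1e-10)


class TestSubgroups:
    def test_former_smoker_filter_applies_to_both_arms(self, default_cohort):
        sub = subgroup_view(default_cohort[0], "former")
        assert set(sub["smoking_status"]) == {"former"}
        assert set(sub["status"]) == {"case", "control"}

    def test_early_stage_keeps_all_controls(self, default_cohort):
        df, _ = default_cohort
        sub = subgroup_view(df, "early")
        cases = sub[sub["status"] == "case"]
        assert set(cases["stage"]) <= {"I", "II"}
        assert (sub["status"] == "control").sum() == (df["status"] == "control").sum()

    def test_empty_subgroup_is_an_error(self, default_cohort):
        with pytest.raises(ValueError, match="matched no subjects"):
            subgroup_view(default_cohort[0], lambda row: False)

    def test_unknown_name_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            subgroup_view(default_cohort[0], "sometimes")


class TestCohortContract:
    def test_validate_finds_mir_columns(self, default_cohort):
        df, _ = default_cohort
        mirs = validate_cohort(df)
        assert "miR-21" in mirs and "age" not in mirs

    def test_missing_required_column_rejected(self, default_cohort):
        df = default_cohort[0].drop(columns=["status"])
        with pytest.raises(ValueError, match="status"):
            validate_cohort(df)
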