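import itertools
import math

import numpy as np
import pandas as pd
import pytest

from arenanav import (
    FitError,
    binding_counts,
    cohens_f_from_F,
    fit_attractor_model,
    fit_binding_poisson,
    fit_error_mixed_anova,
    fit_logistic_diagnosis,
    fit_trial_polynomial_model,
    participant_cue_means,
    participant_switch_means,
    roc_youden,
)


class TestCohensF:
    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [
            (8.37, 1, 77, 0.33),  # published group effect
            (4.71, 1, 78, 0.25),  # published switching-model group effect
        ],
    )
    def test_published_conversions(self, F, df1, df2, expected):
        assert cohens_f_from_F(F, df1, df2) == pytest.approx(expected, abs=0.005)

    def test_zero_F_gives_zero_f(self):
        assert cohens_f_from_F(0.0, 1, 50) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cohens_f_from_F(-1.0, 1, 10)
        with pytest.raises(ValueError):
            cohens_f_from_F(1.0, 0, 10)

    def test_agrees_with_classical_anova_decomposition(self, rng):
        """For a balanced one-way ANOVA, f from the F statistic equals the
        between/within standard-deviation ratio computed directly."""
        a = rng.normal(0.0, 1.0, size=60)
        b = rng.normal(0.7, 1.0, size=60)
        y = np.concatenate([a, b])
        grand = y.mean()
        ss_b = 60 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_w = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        F = (ss_b / 1) / (ss_w / 118)
        f_direct = math.sqrt(ss_b / ss_w * 118 / 1) / math.sqrt(118)
        assert cohens_f_from_F(F, 1, 118) == pytest.approx(f_direct, rel=1e-9)


def synthetic_scores(rng, n_per_group=20, group_shift=0.0, cue_shift=0.0,
                     trial_slope=0.0, participant_sd=2.0, noise_sd=5.0):
    """Hand-built long score table with known ground truth."""
    rows = []
    for g, gname in ((0, "HC"), (1, "aMCI")):
        for i in range(n_per_group):
            pid = f"{gname}{i}"
            u = rng.normal(0, participant_sd)
            cues = ["ego", "allo"] * 8
            rng.shuffle(cues)
            for t, cue in enumerate(cues, start=1):
                y = (
                    20
                    + group_shift * g
                    + cue_shift * (cue == "ego")
                    + trial_slope * t
                    + u
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": gname,
                        "cue": cue,
                        "trial_index": t,
                        "object_id": ["cat", "chair", "bike", "carrot"][t % 4],
                        "error": y,
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_recovers_group_shift(self, rng):
        scores = synthetic_scores(rng, n_per_group=40, group_shift=3.0)
        res = fit_error_mixed_anova(scores)
        grp = res.ftest("group")
        assert grp["p"] < 0.05
        means = scores.groupby("group")["error"].mean()
        assert means["aMCI"] - means["HC"] > 0

    def test_group_df_match_split_plot(self, rng):
        scores = synthetic_scores(rng, n_per_group=40)
        res = fit_error_mixed_anova(scores)
        grp = res.ftest("group")
        assert grp["df_num"] == 1
        assert grp["df_den"] == 78  # 80 participants, 2 between parameters

    def test_f_column_is_internally_consistent(self, scored):
        res = fit_error_mixed_anova(scored)
        for _, row in res.ftests.iterrows():
            assert row["f"] == pytest.approx(
                cohens_f_from_F(row["F"], row["df_num"], row["df_den"])
            )

    def test_group_F_matches_pingouin_mixed_anova(self, rng):
        """Independent oracle: the between-participants F agrees with
        pingouin's split-plot mixed ANOVA on participant x cue means."""
        pingouin = pytest.importorskip("pingouin")
        scores = synthetic_scores(rng, n_per_group=25, group_shift=2.0, cue_shift=1.0)
        res = fit_error_mixed_anova(scores)
        agg = (
            scores.groupby(["participant_id", "group", "cue"], as_index=False)["error"]
            .mean()
        )
        pg = pingouin.mixed_anova(
            data=agg, dv="error", within="cue", subject="participant_id",
            between="group",
        )
        f_pg = float(pg.loc[pg["Source"] == "group", "F"].iloc[0])
        assert res.ftest("group")["F"] == pytest.approx(f_pg, rel=1e-6)

    def test_needs_two_participants_per_group(self, scored):
        one = scored[scored["participant_id"].isin(["HC001", "aMCI001"])]
        with pytest.raises(FitError):
            fit_error_mixed_anova(one)


class TestTrialPolynomial:
    def test_degree_zero_reduces_to_plain_anova(self, scored):
        base = fit_error_mixed_anova(scored)
        red = fit_trial_polynomial_model(scored, degree=0)
        pd.testing.assert_frame_equal(base.terms, red.terms)

    def test_recovers_linear_improvement(self, rng):
        scores = synthetic_scores(rng, n_per_group=30, trial_slope=-0.5)
        res = fit_trial_polynomial_model(scores, degree=2)
        lin = res.terms[res.terms["term"] == "trial_poly1"].iloc[0]
        assert lin["estimate"] < 0
        assert res.ftest("trial_poly1")["p"] < 0.05

    def test_no_trend_is_not_detected(self, rng):
        scores = synthetic_scores(rng, n_per_group=30)
        res = fit_trial_polynomial_model(scores, degree=2)
        assert res.ftest("trial_poly1")["p"] > 0.01


class TestAttractorModel:
    def test_group_contrast_sign_on_synthetic_cohort(self, scored):
        res = fit_attractor_model(scored, "landmark_index")
        assert res.ftests.iloc[0]["df_num"] == 1
        assert 0 <= res.ftests.iloc[0]["p"] <= 1


class TestBindingPoisson:
    def test_equal_counts_give_null_effects(self, arena):
        rows = [
            {"participant_id": f"p{i}", "group": g, "cue": c, "count": 3}
            for i, (g, c) in enumerate(
                itertools.product(["HC", "aMCI"] * 10, ["ego", "allo"])
            )
        ]
        res = fit_binding_poisson(pd.DataFrame(rows))
        for term in res.terms["term"]:
            if term != "Intercept":
                est = res.terms[res.terms["term"] == term]["estimate"].iloc[0]
                assert abs(est) < 1e-8

    def test_intercept_only_reproduces_log_mean(self, rng):
        counts = rng.poisson(3.0, size=40)
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "group": ["HC"] * 20 + ["aMCI"] * 20,
                "cue": ["ego", "allo"] * 20,
                "count": counts,
            }
        )
        import statsmodels.formula.api as smf
        import statsmodels.api as sm

        res = smf.glm("count ~ 1", df, family=sm.families.Poisson()).fit()
        assert res.params["Intercept"] == pytest.approx(np.log(counts.mean()), rel=1e-9)

    def test_recovers_rate_ratio_two(self, rng):
        rows = []
        for i in range(80):
            g = "HC" if i < 40 else "aMCI"
            lam = 2.0 if g == "HC" else 4.0
            for c in ("ego", "allo"):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "group": g,
                        "cue": c,
                        "count": rng.poisson(lam),
                    }
                )
        res = fit_binding_poisson(pd.DataFrame(rows))
        grp = res.term("C(group, Sum)")
        # Sum coding: the level effect is half the group log-difference
        assert 2 * abs(grp["estimate"]) == pytest.approx(np.log(2), abs=0.15)

    def test_from_score_table(self, scored):
        counts = binding_counts(scored)
        assert set(counts.columns) == {"participant_id", "group", "cue", "count"}
        assert counts["count"].between(0, 8).all()
        res = fit_binding_poisson(counts)
        assert (res.terms["rate_ratio"] > 0).all()


class TestLogistic:
    def test_or_equals_exp_beta_for_every_term(self, scored):
        cm = participant_cue_means(scored)
        res = fit_logistic_diagnosis(cm, predictors=["error_ego", "error_allo"])
        np.testing.assert_allclose(
            res.terms["or_"], np.exp(res.terms["estimate"]), rtol=1e-12
        )

    def test_independent_predictor_has_null_or(self, rng):
        df = pd.DataFrame(
            {
                "group": ["HC"] * 100 + ["aMCI"] * 100,
                "x": rng.normal(size=200),
            }
        )
        res = fit_logistic_diagnosis(df, predictors=["x"])
        assert res.term("x")["p"] > 0.01
        assert res.term("x")["or_"] == pytest.approx(1.0, abs=0.3)

    def test_sign_recovery_when_only_ego_differs(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "group": ["HC"] * n + ["aMCI"] * n,
                "error_ego": np.concatenate(
                    [rng.normal(20, 3, n), rng.normal(24, 3, n)]
                ),
                "error_allo": rng.normal(21, 3, 2 * n),
            }
        )
        res = fit_logistic_diagnosis(df, predictors=["error_ego", "error_allo"])
        assert res.term("error_ego")["estimate"] > 0
        assert res.term("error_ego")["p"] < 0.05
        assert abs(res.term("error_allo")["estimate"]) < res.term("error_ego")["estimate"]

    def test_separation_raises_with_penalized_fallback(self):
        df = pd.DataFrame(
            {
                "group": ["HC"] * 10 + ["aMCI"] * 10,
                "x": np.r_[np.zeros(10), np.ones(10)],
            }
        )
        with pytest.raises(FitError):
            fit_logistic_diagnosis(df, predictors=["x"])
        res = fit_logistic_diagnosis(df, predictors=["x"], penalized=True)
        assert res.notes and "penalized" in res.notes[0]

    def test_switch_means_predictors(self, scored):
        sw = participant_switch_means(scored)
        res = fit_logistic_diagnosis(
            sw,
            predictors=[
                "error_no_switch",
                "error_ego_to_allo",
                "error_allo_to_ego",
            ],
        )
        assert len(res.terms) == 4  # intercept + 3 switch predictors


def auc_by_concordance(scores, labels):
    """Exhaustive pairwise concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.youden == pytest.approx(1.0)

    def test_small_example_three_quarters(self):
        # concordant pairs: (2>1), (4>1), (4>3); discordant: (2<3)
        r = roc_youden([1, 3, 2, 4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_sign_reversal_flips_auc(self, rng):
        s = rng.normal(size=30)
        y = (rng.uniform(size=30) < 0.4).astype(int)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        assert roc_youden(-s, y).auc == pytest.approx(1 - roc_youden(s, y).auc)

    def test_matches_concordance_enumeration_small_n(self, rng):
        for trial in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 5, size=n).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            got = roc_youden(scores, labels)
            assert got.auc == pytest.approx(
                auc_by_concordance(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        s = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-s))).astype(int)
        got = roc_youden(s, y)
        assert got.auc == pytest.approx(sklearn_metrics.roc_auc_score(y, s), abs=1e-12)

    def test_youden_cutoff_attains_maximum(self, rng):
        s = rng.normal(size=50)
        y = (rng.uniform(size=50) < 0.5).astype(int)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        r = roc_youden(s, y)
        # brute force over a fine grid never beats the reported J
        grid = np.linspace(s.min() - 1, s.max() + 1, 2000)
        n_pos, n_neg = y.sum(), (1 - y).sum()
        js = [
            ((s >= c) & (y == 1)).sum() / n_pos
            + (~(s >= c) & (y == 0)).sum() / n_neg
            - 1
            for c in grid
        ]
        assert r.youden >= max(js) - 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1, 2, 3], [1, 1, 1])
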