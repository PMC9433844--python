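"""Mixed models: estimates, lme4 cross-checks, ladder, contrasts, outliers."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from musupp import models, synth


@pytest.fixture(scope="module")
def trial_table():
    return synth.simulate_trial_table(n_participants=20, n_videos=9, seed=42)


@pytest.fixture(scope="module")
def epoch_table():
    return synth.simulate_epoch_table(n_participants=10, n_videos=9,
                                      epochs_per_trial=30, seed=7)


def _run_r(script: str) -> str:
    res = subprocess.run(["Rscript", "-"], input=script, text=True,
                         capture_output=True, timeout=300)
    assert res.returncode == 0, res.stderr
    return res.stdout


class TestLmerCrossCheck:
    """The crossed-intercepts LMM must agree with lme4::lmer."""

    def test_reml_estimates_match_lmer(self, trial_table, tmp_path):
        path = tmp_path / "trial.csv"
        trial_table.to_csv(path, index=False)
        out = _run_r(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            d$condition <- relevel(factor(d$condition), ref="Audio-Video")
            m <- lmer(EA ~ S_C3 + S_C4 + S_O1 + S_O2 + condition
                      + (1|participant) + (1|video), data=d, REML=TRUE)
            co <- fixef(m); vc <- as.data.frame(VarCorr(m))
            cat(co[["S_C4"]], co[["(Intercept)"]],
                vc$vcov[1], vc$vcov[2], vc$vcov[3], sep=",")
        """))
        c4, intercept, tau_p, tau_v, sigma2 = map(float, out.strip().split(","))
        fit = models.fit_video_level(trial_table, reml=True)
        assert fit.params.loc["S_C4", "beta"] == pytest.approx(c4, abs=1e-5)
        assert fit.params.loc["(Intercept)", "beta"] == pytest.approx(intercept,
                                                                      abs=1e-5)
        assert fit.tau_participant == pytest.approx(tau_p, abs=1e-5)
        assert fit.tau_video == pytest.approx(tau_v, abs=1e-5)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-5)

    def test_ml_loglik_matches_lmer(self, trial_table, tmp_path):
        path = tmp_path / "trial.csv"
        trial_table.to_csv(path, index=False)
        out = _run_r(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            d$condition <- relevel(factor(d$condition), ref="Audio-Video")
            m <- lmer(EA ~ S_C3 + S_C4 + S_O1 + S_O2 + condition
                      + (1|participant) + (1|video), data=d, REML=FALSE)
            cat(logLik(m), AIC(m), sep=",")
        """))
        ll, aic = map(float, out.strip().split(","))
        fit = models.fit_video_level(trial_table, reml=False)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert fit.aic == pytest.approx(aic, abs=1e-3)

    def test_glmm_matches_glmer_laplace(self, epoch_table, tmp_path):
        path = tmp_path / "epoch.csv"
        epoch_table.to_csv(path, index=False)
        out = _run_r(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            d$condition <- relevel(factor(d$condition), ref="Audio-Video")
            g <- glmer(success ~ S_C3 + S_C4 + S_O1 + S_O2 + condition
                       + (1|participant) + (1|video), data=d, family=binomial)
            co <- fixef(g); se <- sqrt(diag(vcov(g)))
            cat(co[["S_C4"]], se[["S_C4"]], logLik(g), sep=",")
        """))
        c4, se_c4, ll = map(float, out.strip().split(","))
        fit = models.fit_epoch_level(epoch_table)
        assert fit.params.loc["S_C4", "beta"] == pytest.approx(c4, abs=2e-3)
        assert fit.params.loc["S_C4", "se"] == pytest.approx(se_c4, rel=0.02)
        assert fit.loglik == pytest.approx(ll, abs=0.01)


class TestVideoLevel:
    def test_sign_recovery_of_negative_c4_effect(self):
        hits = n = 0
        for s in range(30):
            df = synth.simulate_trial_table(n_participants=40, n_videos=9, seed=s)
            fit = models.fit_video_level(df)
            if fit.converged:
                n += 1
                hits += fit.params.loc["S_C4", "beta"] < 0
        assert n >= 28 and hits / n >= 0.9

    def test_zero_random_variance_recovers_near_zero_tau(self):
        df = synth.simulate_trial_table(n_participants=30, n_videos=9,
                                        tau_participant=0.0, tau_video=0.0,
                                        seed=3)
        fit = models.fit_video_level(df)
        assert fit.tau_participant < 0.01 and fit.tau_video < 0.01
        assert fit.singular

    def test_needs_two_participants_and_videos(self):
        df = synth.simulate_trial_table(n_participants=4, n_videos=3, seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            models.fit_video_level(df[df.participant == "P01"])

    def test_interaction_modes_add_expected_terms(self, trial_table):
        base = models.fit_video_level(trial_table)
        c4 = models.fit_video_level(trial_table, interaction="C4_only")
        full = models.fit_video_level(trial_table, interaction="all")
        assert len(c4.params) == len(base.params) + 2
        assert len(full.params) == len(base.params) + 8
        assert "S_C4:condition[Video-Only]" in c4.params.index


class TestEpochLevel:
    def test_slope_recovery_within_ci(self):
        hits = 0
        for s in range(20):
            df = synth.simulate_epoch_table(n_participants=20, n_videos=9,
                                            epochs_per_trial=40, seed=s)
            fit = models.fit_epoch_level(df)
            row = fit.params.loc["S_C4"]
            hits += row.ci_low <= -0.12 <= row.ci_high
        assert hits / 20 >= 0.9

    def test_single_class_outcome_raises_separation(self, epoch_table):
        df = epoch_table.copy()
        df["success"] = 1
        with pytest.raises(models.SeparationError):
            models.fit_epoch_level(df)


class TestLadder:
    def test_loglik_never_decreases_along_nested_ladder(self, trial_table):
        lad = models.hierarchical_compare(trial_table, level="video")
        ll = lad.steps["loglik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-6)

    def test_condition_effect_detected_at_right_step(self, trial_table):
        # generator plants strong condition effects and a modest C4 slope
        lad = models.hierarchical_compare(trial_table, level="video")
        assert lad.steps.loc[2, "p"] < 0.001          # +condition
        assert lad.steps.loc[3, "p"] > 0.05           # +interaction (none planted)

    def test_statistics_nonnegative_and_p_in_unit_interval(self, trial_table):
        lad = models.hierarchical_compare(trial_table, level="video",
                                          interaction="C4_only")
        steps = lad.steps.iloc[1:]
        assert (steps["stat"] >= 0).all()
        assert steps["p"].between(0, 1).all()

    def test_epoch_ladder_runs_and_is_nested(self, epoch_table):
        lad = models.hierarchical_compare(epoch_table, level="epoch",
                                          interaction="C4_only")
        assert list(lad.steps["step"]) == ["null", "+suppression",
                                           "+condition", "+interaction"]
        assert np.all(np.diff(lad.steps["loglik"].to_numpy()) >= -1e-4)
        assert lad.method == "LRT (ML)"


class TestContrasts:
    def test_three_contrasts_with_bonferroni_cap(self, trial_table):
        fit = models.fit_video_level(trial_table)
        res = models.condition_contrasts(fit)
        assert len(res.table) == 3
        t = res.table
        assert np.all(t["p_adj"] >= t["p_raw"] - 1e-15)
        assert np.all(t["p_adj"] <= 1.0)
        expect = np.minimum(1.0, 3.0 * t["p_raw"])
        assert np.allclose(t["p_adj"], expect)

    def test_contrast_equals_negated_treatment_coefficient(self, trial_table):
        """AV - VO at mean suppression == -beta[Video-Only] without interaction."""
        fit = models.fit_video_level(trial_table)
        res = models.condition_contrasts(fit).table
        av_vo = res.loc[res.contrast == "Audio-Video - Video-Only",
                        "estimate"].item()
        assert av_vo == pytest.approx(
            -fit.params.loc["condition[Video-Only]", "beta"])

    def test_planted_av_advantage_is_significant(self, trial_table):
        fit = models.fit_video_level(trial_table)
        res = models.condition_contrasts(fit).table
        row = res[res.contrast == "Audio-Video - Video-Only"].iloc[0]
        assert row.estimate > 0 and row.p_adj < 0.01

    def test_missing_condition_term_rejected(self, trial_table):
        fit = models.fit_video_level(trial_table, condition=False)
        with pytest.raises(ValueError, match="condition"):
            models.condition_contrasts(fit)


class TestOutlierRemoval:
    def test_single_far_outlier_removed(self):
        rng = np.random.default_rng(0)
        ea = np.concatenate([rng.normal(0.5, 0.02, 100), [-0.9]])
        df = pd.DataFrame({"participant": "P1", "video": [f"V{i}" for i in
                                                          range(101)], "EA": ea})
        out = models.remove_outlier_trials(df)
        assert len(out) == 100 and (-0.9 not in out["EA"].to_numpy())
        # single-pass oracle
        keep = np.abs(ea - ea.mean()) <= 2 * ea.std(ddof=1)
        assert np.array_equal(np.sort(out["EA"]), np.sort(ea[keep]))

    def test_equal_values_nothing_removed(self):
        df = pd.DataFrame({"EA": [0.4] * 10})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = models.remove_outlier_trials(df)
        assert len(out) == 10

    def test_infinite_k_is_identity(self):
        df = pd.DataFrame({"EA": np.linspace(-1, 1, 20)})
        assert len(models.remove_outlier_trials(df, k_sd=np.inf)) == 20

    def test_removal_is_single_pass(self):
        # values where iterated removal would drop more than one pass does
        ea = np.array([0.0] * 20 + [3.0, 10.0])
        df = pd.DataFrame({"EA": ea})
        out = models.remove_outlier_trials(df)
        keep = np.abs(ea - ea.mean()) <= 2 * ea.std(ddof=1)
        assert len(out) == keep.sum()
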