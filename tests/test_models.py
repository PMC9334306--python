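"""Mixed-effects models: identities, cross-checks, recovery behavior.

Independent oracles: statsmodels MixedLM for the uncensored time model and
R lme4 (glmer) for the random-intercept logistic model.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hardcog.behavior import DEFAULT_EFFECTS, EffectSpec, apply_exclusions, simulate_cohort
from hardcog.exceptions import SpecificationError
from hardcog.models import (
    AccuracyModel,
    CensoredTimeModel,
    ModelSpec,
    fit_accuracy,
    instance_r2,
    recovery_report,
)


def _sim_logistic(n_groups=15, n_per=60, beta=(-0.3, 1.2), sigma_u=0.6, seed=0):
    """Hand-rolled logistic random-intercept data with known truth."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma_u)
        x = rng.normal(0, 1, n_per)
        eta = beta[0] + beta[1] * x + u
        y = (rng.random(n_per) < 1 / (1 + np.exp(-eta))).astype(float)
        for xi, yi in zip(x, y):
            rows.append({"participant_id": f"g{g}", "x": xi, "correct": yi})
    return pd.DataFrame(rows)


def _sim_censored(n_groups=15, n_per=50, beta=(0.7, 0.12), sigma_e=0.15, sigma_u=0.08, seed=1, censor=True):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma_u)
        x = rng.integers(0, 2, n_per).astype(float)
        latent = beta[0] + beta[1] * x + u + rng.normal(0, sigma_e, n_per)
        for xi, li in zip(x, latent):
            cens = censor and li >= 1.0
            rows.append(
                {
                    "participant_id": f"g{g}",
                    "x": xi,
                    "time_prop": min(max(li, 0.01), 1.0) if censor else min(max(li, 0.01), 1.0),
                    "censored": bool(cens),
                }
            )
    return pd.DataFrame(rows)


class TestAccuracyModel:
    def test_intercept_zero_at_chance_accuracy(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"g{i}" for i in range(10)], 100),
                "correct": rng.integers(0, 2, 1000).astype(float),
            }
        )
        fit = AccuracyModel.from_frame(df, predictors=[]).fit("mle")
        assert fit.ci_lower["const"] < 0 < fit.ci_upper["const"]

    def test_recovers_known_effect(self):
        fit = AccuracyModel.from_frame(_sim_logistic(seed=3), ["x"]).fit("mle")
        assert fit.converged
        assert fit.ci_lower["x"] <= 1.2 <= fit.ci_upper["x"]
        assert abs(fit.sigma_u - 0.6) < 0.4

    def test_matches_r_lme4_glmer(self, tmp_path):
        """Coefficient agreement with lme4's Laplace-approximation GLMM fit
        on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _sim_logistic(n_groups=12, n_per=50, seed=4)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(correct ~ x + (1 | participant_id), data = d, family = binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))[1]), sep = ",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_const, r_x, r_sigma = (float(v) for v in out.stdout.strip().split(","))
        fit = AccuracyModel.from_frame(df, ["x"]).fit("mle")
        assert fit.median["const"] == pytest.approx(r_const, abs=0.05)
        assert fit.median["x"] == pytest.approx(r_x, abs=0.05)
        assert fit.sigma_u == pytest.approx(r_sigma, abs=0.1)

    def test_binary_outcome_enforced(self):
        df = _sim_logistic(seed=5)
        df.loc[0, "correct"] = 0.5
        with pytest.raises(SpecificationError):
            AccuracyModel.from_frame(df, ["x"])

    def test_mle_fit_is_reproducible(self):
        df = _sim_logistic(seed=6)
        f1 = AccuracyModel.from_frame(df, ["x"]).fit("mle")
        f2 = AccuracyModel.from_frame(df, ["x"]).fit("mle")
        pd.testing.assert_series_equal(f1.median, f2.median)


class TestCensoredTimeModel:
    def test_without_censoring_matches_mixedlm(self):
        """With no censored rows the likelihood coincides with an ordinary
        linear mixed model; estimates must match statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        df = _sim_censored(seed=7, censor=False)
        df["censored"] = False
        fit = CensoredTimeModel.from_frame(df, ["x"]).fit("mle")
        lmm = smf.mixedlm("time_prop ~ x", df, groups=df["participant_id"]).fit(reml=False)
        assert fit.median["const"] == pytest.approx(lmm.params["Intercept"], abs=1e-3)
        assert fit.median["x"] == pytest.approx(lmm.params["x"], abs=1e-3)

    def test_inactive_censor_bound_leaves_estimates_unchanged(self):
        df = _sim_censored(beta=(0.4, 0.05), seed=8)  # all data far below 1
        assert not df["censored"].any()
        fit_plain = CensoredTimeModel.from_frame(df, ["x"]).fit("mle")
        fit_flag = CensoredTimeModel.from_frame(df.assign(censored=False), ["x"]).fit("mle")
        pd.testing.assert_series_equal(fit_plain.median, fit_flag.median)

    def test_recovers_effect_under_censoring(self):
        df = _sim_censored(beta=(0.85, 0.12), seed=9)
        assert df["censored"].mean() > 0.05  # censoring actually active
        fit = CensoredTimeModel.from_frame(df, ["x"]).fit("mle")
        assert fit.ci_lower["x"] <= 0.12 <= fit.ci_upper["x"]

    def test_fully_censored_data_rejected(self):
        df = _sim_censored(seed=10)
        df["censored"] = True
        df["time_prop"] = 1.0
        with pytest.raises(SpecificationError):
            CensoredTimeModel.from_frame(df, ["x"])


class TestBayesBackend:
    def test_agrees_with_mle_on_well_separated_data(self):
        """Posterior medians and Wald estimates agree in sign and the
        intervals overlap."""
        df = _sim_logistic(n_groups=10, n_per=40, seed=11)
        mle = AccuracyModel.from_frame(df, ["x"]).fit("mle")
        bayes = AccuracyModel.from_frame(df, ["x"]).fit(
            "mcmc", seed=12, draws=500, burn=300
        )
        for name in ("const", "x"):
            assert np.sign(bayes.median[name]) == np.sign(mle.median[name])
            assert bayes.ci_lower[name] < mle.ci_upper[name]
            assert mle.ci_lower[name] < bayes.ci_upper[name]
        assert bayes.rhat is not None


class TestInstanceR2:
    def _fitted(self, sat3_design):
        rng = np.random.default_rng(13)
        trials = simulate_cohort(sat3_design, 20, DEFAULT_EFFECTS["sat3"], rng)
        kept, _ = apply_exclusions(trials)
        fit = fit_accuracy(kept, ModelSpec("accuracy", ("tcc_high",)))
        return fit, kept

    def test_r2_in_unit_interval_and_informative(self, sat3_design):
        fit, kept = self._fitted(sat3_design)
        r2 = instance_r2(fit, kept)
        assert 0.0 <= r2 <= 1.0

    def test_predictive_model_beats_intercept_only(self, sat3_design):
        fit, kept = self._fitted(sat3_design)
        null_fit = fit_accuracy(kept, ModelSpec("accuracy", ()))
        assert instance_r2(fit, kept) > instance_r2(null_fit, kept)

    def test_single_instance_rejected(self, sat3_design):
        fit, kept = self._fitted(sat3_design)
        one = kept[kept["instance_id"] == kept["instance_id"].iloc[0]]
        with pytest.raises(SpecificationError):
            instance_r2(fit, one)


class TestRecovery:
    def test_zero_effect_type_one_rate(self, sat3_design):
        """With no true TCC effect the interval excludes zero rarely
        (nominal 5%; allow <= 10% over 20 replicates)."""
        spec = EffectSpec(
            problem="sat3",
            accuracy_intercept=2.0,
            accuracy_coefs={"tcc_high": 0.0},
            participant_sd=0.5,
            miss_prob=0.0,
        )
        report = recovery_report(sat3_design, spec, 24, 20, seed=21)
        row = report.set_index("coefficient").loc["tcc_high"]
        assert row["significant_rate"] <= 0.10

    def test_more_participants_do_not_hurt_precision(self, sat3_design):
        spec = DEFAULT_EFFECTS["sat3"]
        small = recovery_report(sat3_design, spec, 8, 10, seed=22)
        large = recovery_report(sat3_design, spec, 32, 10, seed=22)
        rm_small = small.set_index("coefficient").loc["tcc_high", "rmse"]
        rm_large = large.set_index("coefficient").loc["tcc_high", "rmse"]
        assert rm_large <= rm_small * 1.25  # monotone precision up to noise
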