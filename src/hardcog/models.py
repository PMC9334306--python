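"""Mixed-effects models linking hardness metrics to performance.

Two model families, both with a Gaussian random intercept per participant:

* :class:`AccuracyModel` — logistic regression for the binary correctness
  outcome (a GLMM);
* :class:`CensoredTimeModel` — linear regression for time-on-task as a
  proportion of the trial limit, right-censored at 1.0 (a censored/Tobit
  mixed model).

The random intercept is integrated out of the likelihood exactly (up to
quadrature error) with Gauss-Hermite quadrature, so both backends share one
marginal likelihood:

* ``fit(method="mle")`` maximises it with scipy and reports Wald 95%
  intervals from the numerical Hessian — the fast backend;
* ``fit(method="mcmc")`` samples the posterior with an affine-invariant
  ensemble sampler (emcee) under weakly-informative priors (flat on
  slopes, Student-t(3) on the intercept, half-Student-t(3) on scale
  parameters), reporting posterior medians, 95% highest-density intervals
  and split-R-hat; a fit whose R-hat exceeds 1.01 on any reported parameter
  is flagged as failed and retried once with twice the draws.

An effect is called "significant" when its 95% interval excludes zero.
Results objects follow the statsmodels convention: ``fit`` returns a
:class:`MixedFitResults` with ``params``, ``conf_int()``, ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import FitError, SpecificationError

_GH_NODES = 25
_RHAT_GATE = 1.01
# log normalising constant of the Student-t(3) density at unit scale
_T3_NORM = float(
    special.gammaln(2.0) - special.gammaln(1.5) - 0.5 * np.log(3.0 * np.pi)
)


def _gh_rule(k: int = _GH_NODES) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(k)
    return nodes, weights / np.sqrt(np.pi)


class _RandomInterceptModel:
    """Shared scaffolding: design matrix, groups, quadrature likelihood."""

    #: names of the auxiliary (scale) parameters appended after the betas
    _aux_names: tuple[str, ...] = ()

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: Sequence[str],
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.exog) != len(self.endog):
            raise SpecificationError("exog must be 2-D and aligned with endog")
        if np.isnan(self.endog).any() or np.isnan(self.exog).any():
            raise SpecificationError("model data contain missing values")
        self.exog_names = list(exog_names)
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise SpecificationError("need at least 2 participants")
        self.group_codes = codes
        self.n_groups = len(uniques)
        self.k_beta = self.exog.shape[1]
        self._nodes, self._weights = _gh_rule()

    @property
    def param_names(self) -> list[str]:
        return self.exog_names + list(self._aux_names)

    # -- subclass hooks ----------------------------------------------------
    def _obs_loglik_matrix(self, params: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        """(n_obs, n_nodes) log-likelihoods at each random-intercept offset."""
        raise NotImplementedError

    def _sigma_u(self, params: np.ndarray) -> float:
        raise NotImplementedError

    def start_params(self) -> np.ndarray:
        raise NotImplementedError

    # -- marginal likelihood ----------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood, random intercepts integrated by GH."""
        sigma_u = self._sigma_u(params)
        offsets = np.sqrt(2.0) * sigma_u * self._nodes
        ll = self._obs_loglik_matrix(params, offsets)  # (n_obs, K)
        k_nodes = len(self._nodes)
        group_ll = np.empty((self.n_groups, k_nodes))
        for k in range(k_nodes):
            group_ll[:, k] = np.bincount(self.group_codes, ll[:, k], minlength=self.n_groups)
        log_w = np.log(self._weights)
        return float(special.logsumexp(group_ll + log_w[None, :], axis=1).sum())

    def _neg_loglike(self, params: np.ndarray) -> float:
        ll = self.loglike(params)
        return np.inf if not np.isfinite(ll) else -ll

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "mle", **kwargs) -> "MixedFitResults":
        if method == "mle":
            return self._fit_mle(**kwargs)
        if method == "mcmc":
            return self._fit_mcmc(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def _fit_mle(self, maxiter: int = 500) -> "MixedFitResults":
        from statsmodels.tools.numdiff import approx_hess

        x0 = self.start_params()
        res = optimize.minimize(
            self._neg_loglike, x0, method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-6},
        )
        params = res.x
        converged = bool(res.success or res.status == 2)  # 2: precision loss near optimum
        se = np.full(len(params), np.nan)
        try:
            hess = approx_hess(params, self._neg_loglike)
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(hess)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = np.sqrt(diag)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        # separation guard, scaled by each predictor's spread: a slope is
        # implausible when it moves the linear predictor by >15 logits per
        # standard deviation of its column
        scales = self.exog.std(axis=0)
        scales[scales < 1e-12] = 1.0  # constant column: raw threshold
        if np.any(np.abs(params[: self.k_beta]) * scales > 15):
            converged = False
        # small-sample critical value: t with group-based degrees of freedom
        # (Wald-z is anticonservative with a few dozen participants)
        crit = stats.t.ppf(0.975, max(self.n_groups - self.k_beta, 1))
        lo = params - crit * se
        hi = params + crit * se
        return MixedFitResults(
            model=self,
            backend="mle",
            median=pd.Series(params, index=self.param_names),
            ci_lower=pd.Series(lo, index=self.param_names),
            ci_upper=pd.Series(hi, index=self.param_names),
            se=pd.Series(se, index=self.param_names),
            rhat=None,
            converged=converged,
            n_obs=len(self.endog),
            loglike_value=-res.fun,
        )

    @staticmethod
    def _t3_logpdf(x: float, scale: float = 2.5) -> float:
        # Student-t with 3 df (closed form; avoids scipy call overhead)
        z = x / scale
        return float(_T3_NORM - np.log(scale) - 2.0 * np.log1p(z * z / 3.0))

    def _log_prior(self, params: np.ndarray) -> float:
        """Weakly-informative priors: flat slopes, t(3) intercept,
        half-t(3) on scales (parameterised on the log scale)."""
        lp = 0.0
        if "const" in self.exog_names:
            j = self.exog_names.index("const")
            lp += self._t3_logpdf(params[j])
        for j in range(self.k_beta, len(params)):
            sigma = np.exp(params[j])
            # half-t(3, 2.5) density on sigma plus log-scale Jacobian
            lp += self._t3_logpdf(sigma) + np.log(2.0) + params[j]
        return lp

    def _fit_mcmc(
        self,
        seed: int = 0,
        draws: int = 2000,
        burn: int = 1000,
        nwalkers: Optional[int] = None,
        _retry: bool = True,
    ) -> "MixedFitResults":
        import arviz as az
        import emcee

        start = self._fit_mle()
        x0 = start.median.to_numpy()
        ndim = len(x0)
        if nwalkers is None:
            nwalkers = max(4 * ndim, 16)
        rng = np.random.default_rng(seed)

        def log_prob(theta: np.ndarray) -> float:
            lp = self._log_prior(theta)
            ll = self.loglike(theta)
            return lp + ll if np.isfinite(ll) else -np.inf

        p0 = x0[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState(seed & 0x7FFFFFFF).get_state()
        sampler.run_mcmc(p0, burn + draws, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=burn)  # (draws, walkers, ndim)
        posterior = {
            name: np.swapaxes(chain[:, :, j], 0, 1) for j, name in enumerate(self.param_names)
        }
        idata = az.from_dict(posterior=posterior)
        rhat = az.rhat(idata).to_array().to_numpy().ravel()
        rhat = pd.Series(rhat, index=self.param_names)
        if (rhat > _RHAT_GATE).any() and _retry:
            return self._fit_mcmc(
                seed=seed + 1, draws=draws * 2, burn=burn * 2, nwalkers=nwalkers, _retry=False
            )
        flat = chain.reshape(-1, ndim)
        median = pd.Series(np.median(flat, axis=0), index=self.param_names)
        hdi = az.hdi(idata, hdi_prob=0.95)
        lo = pd.Series({n: float(hdi[n].sel(hdi="lower")) for n in self.param_names})
        hi = pd.Series({n: float(hdi[n].sel(hdi="higher")) for n in self.param_names})
        return MixedFitResults(
            model=self,
            backend="mcmc",
            median=median,
            ci_lower=lo[self.param_names],
            ci_upper=hi[self.param_names],
            se=pd.Series(flat.std(axis=0), index=self.param_names),
            rhat=rhat,
            converged=bool((rhat <= _RHAT_GATE).all()),
            n_obs=len(self.endog),
            loglike_value=float(self.loglike(median.to_numpy())),
        )


class AccuracyModel(_RandomInterceptModel):
    """Logistic mixed model for binary accuracy with participant intercepts.

    Parameters are the fixed-effect betas (logit scale) followed by
    ``log_sigma_u``, the log of the participant-intercept standard
    deviation.
    """

    _aux_names = ("log_sigma_u",)

    @classmethod
    def from_frame(
        cls,
        trials: pd.DataFrame,
        predictors: Sequence[str],
        outcome: str = "correct",
        group: str = "participant_id",
        add_const: bool = True,
    ) -> "AccuracyModel":
        missing = [c for c in (*predictors, outcome, group) if c not in trials.columns]
        if missing:
            raise SpecificationError(f"columns not in trial table: {missing}")
        y = trials[outcome].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise SpecificationError("outcome contains missing values; apply exclusions first")
        if not np.isin(y, (0.0, 1.0)).all():
            raise SpecificationError("accuracy outcome must be binary")
        X = trials[list(predictors)].to_numpy(dtype=float)
        names = list(predictors)
        if add_const:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["const"] + names
        return cls(y, X, trials[group].to_numpy(), names)

    def _sigma_u(self, params: np.ndarray) -> float:
        return float(np.exp(params[-1]))

    def _obs_loglik_matrix(self, params: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        eta = self.exog @ params[: self.k_beta]
        # log sigmoid((2y-1) eta), numerically stable
        z = (2.0 * self.endog - 1.0)[:, None] * (eta[:, None] + offsets[None, :])
        return -np.logaddexp(0.0, -z)

    def start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial()).fit()
            beta = np.clip(glm.params, -10, 10)
        except Exception:
            beta = np.zeros(self.k_beta)
        return np.concatenate([beta, [np.log(0.5)]])

    def predict_marginal(self, exog: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Population-averaged P(correct), intercept integrated out."""
        sigma_u = float(np.exp(params[-1]))
        eta = np.asarray(exog) @ params[: self.k_beta]
        probs = np.zeros(len(eta))
        for x, w in zip(*_gh_rule()):
            probs += w / (1.0 + np.exp(-(eta + np.sqrt(2.0) * sigma_u * x)))
        return probs


class CensoredTimeModel(_RandomInterceptModel):
    """Censored-Gaussian (Tobit) mixed model for time as proportion of limit.

    Right-censored at the trial limit (time_prop == 1).  Parameters: fixed
    effects, then ``log_sigma_e`` (residual) and ``log_sigma_u``
    (participant intercept).
    """

    _aux_names = ("log_sigma_e", "log_sigma_u")

    def __init__(self, endog, exog, groups, exog_names, censored) -> None:
        super().__init__(endog, exog, groups, exog_names)
        self.censored = np.asarray(censored, dtype=bool)
        if self.censored.all():
            raise SpecificationError("all observations censored; model is degenerate")

    @classmethod
    def from_frame(
        cls,
        trials: pd.DataFrame,
        predictors: Sequence[str],
        outcome: str = "time_prop",
        censor_col: str = "censored",
        group: str = "participant_id",
        add_const: bool = True,
    ) -> "CensoredTimeModel":
        missing = [c for c in (*predictors, outcome, censor_col, group) if c not in trials.columns]
        if missing:
            raise SpecificationError(f"columns not in trial table: {missing}")
        y = trials[outcome].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise SpecificationError("time outcome contains missing values")
        if np.any((y <= 0) | (y > 1)):
            raise SpecificationError("time_prop must lie in (0, 1]")
        X = trials[list(predictors)].to_numpy(dtype=float)
        names = list(predictors)
        if add_const:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["const"] + names
        return cls(y, X, trials[group].to_numpy(), names, trials[censor_col].to_numpy())

    def _sigma_u(self, params: np.ndarray) -> float:
        return float(np.exp(params[-1]))

    def _obs_loglik_matrix(self, params: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        sigma_e = np.exp(params[self.k_beta])
        mu = (self.exog @ params[: self.k_beta])[:, None] + offsets[None, :]
        z = (self.endog[:, None] - mu) / sigma_e
        ll = stats.norm.logpdf(z) - np.log(sigma_e)
        if self.censored.any():
            zc = (1.0 - mu[self.censored]) / sigma_e
            ll[self.censored] = stats.norm.logsf(zc)
        return ll

    def start_params(self) -> np.ndarray:
        mask = ~self.censored
        X, y = self.exog[mask], self.endog[mask]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma_e = max(float(resid.std()), 1e-3)
        return np.concatenate([beta, [np.log(sigma_e), np.log(max(sigma_e / 2, 1e-3))]])


@dataclass
class MixedFitResults:
    """Coefficient summaries for one mixed-model fit.

    ``median`` is the point estimate (posterior median for the MCMC backend,
    the maximum-likelihood estimate otherwise); the interval is a 95% HDI or
    Wald interval respectively.  ``converged`` is False when optimisation
    failed, the Hessian was not positive definite, separation is suspected,
    or any R-hat exceeded the 1.01 gate.
    """

    model: _RandomInterceptModel
    backend: str
    median: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    se: pd.Series
    rhat: Optional[pd.Series]
    converged: bool
    n_obs: int
    loglike_value: float

    @property
    def params(self) -> pd.Series:
        return self.median

    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.median["log_sigma_u"]))

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": self.ci_lower, "upper": self.ci_upper})

    @property
    def significant(self) -> pd.Series:
        """Effects whose 95% interval excludes zero (fixed effects only)."""
        names = self.model.exog_names
        return pd.Series(
            [(self.ci_lower[n] > 0) or (self.ci_upper[n] < 0) for n in names],
            index=names,
        )

    def summary(self) -> str:
        kind = type(self.model).__name__
        lines = [
            f"{kind} ({self.backend}); n_obs={self.n_obs}, "
            f"groups={self.model.n_groups}, loglik={self.loglike_value:.2f}, "
            f"converged={self.converged}",
            f"{'parameter':<16}{'estimate':>10}{'2.5%':>10}{'97.5%':>10}"
            + ("{:>8}".format("r_hat") if self.rhat is not None else ""),
        ]
        for name in self.median.index:
            row = (
                f"{name:<16}{self.median[name]:>10.3f}"
                f"{self.ci_lower[name]:>10.3f}{self.ci_upper[name]:>10.3f}"
            )
            if self.rhat is not None:
                row += f"{self.rhat[name]:>8.3f}"
            lines.append(row)
        lines.append(f"participant-intercept sd: {self.sigma_u:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "backend": self.backend,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "coefficients": {
                n: {
                    "median": float(self.median[n]),
                    "lower": float(self.ci_lower[n]),
                    "upper": float(self.ci_upper[n]),
                }
                for n in self.median.index
            },
        }
        if self.rhat is not None:
            out["rhat"] = {n: float(self.rhat[n]) for n in self.rhat.index}
        return out


@dataclass(frozen=True)
class ModelSpec:
    """Outcome + predictor list for one fitted model."""

    outcome: str  # "accuracy" or "time"
    predictors: tuple[str, ...]
    backend: str = "mle"
    seed: int = 0
    draws: int = 2000

    def __post_init__(self) -> None:
        if self.outcome not in ("accuracy", "time"):
            raise SpecificationError("outcome must be 'accuracy' or 'time'")


def fit_accuracy(trials: pd.DataFrame, spec: ModelSpec) -> MixedFitResults:
    """Fit the logistic mixed model named by a ModelSpec."""
    model = AccuracyModel.from_frame(trials, spec.predictors)
    if spec.backend == "mcmc":
        return model.fit("mcmc", seed=spec.seed, draws=spec.draws)
    return model.fit("mle")


def fit_time(trials: pd.DataFrame, spec: ModelSpec) -> MixedFitResults:
    """Fit the censored-Gaussian mixed model named by a ModelSpec."""
    model = CensoredTimeModel.from_frame(trials, spec.predictors)
    if spec.backend == "mcmc":
        return model.fit("mcmc", seed=spec.seed, draws=spec.draws)
    return model.fit("mle")


def instance_r2(results: MixedFitResults, trials: pd.DataFrame) -> float:
    """Variance in per-instance mean accuracy explained by the model.

    Squared Pearson correlation between observed per-instance mean accuracy
    and the model's population-averaged predicted probability.
    """
    if not isinstance(results.model, AccuracyModel):
        raise SpecificationError("instance_r2 is defined for accuracy models")
    if trials["instance_id"].nunique() < 2:
        raise SpecificationError("need at least 2 instances")
    model = results.model
    pred = model.predict_marginal(model.exog, results.median.to_numpy())
    df = pd.DataFrame(
        {
            "instance_id": trials["instance_id"].to_numpy(),
            "observed": model.endog,
            "predicted": pred,
        }
    )
    means = df.groupby("instance_id").mean()
    if means["predicted"].std() == 0 or means["observed"].std() == 0:
        return 0.0
    return float(np.corrcoef(means["observed"], means["predicted"])[0, 1] ** 2)


def recovery_report(
    instance_set,
    effect_spec,
    n_participants: int,
    n_replicates: int,
    seed: int,
    outcome: str = "accuracy",
    predictors: Optional[Sequence[str]] = None,
    min_accuracy: float = 0.6,
) -> pd.DataFrame:
    """Simulate cohorts, refit the matched model, and tabulate recovery.

    For each fixed-effect coefficient: mean estimate, bias against the
    generative truth, RMSE, 95%-interval coverage of the truth, and the rate
    at which the interval excludes zero on the correct side
    (``sign_recovery``).  Failed fits are counted, not silently dropped.
    """
    from .behavior import apply_exclusions, simulate_cohort

    truth_coefs = effect_spec.accuracy_coefs if outcome == "accuracy" else effect_spec.time_coefs
    intercept = (
        effect_spec.accuracy_intercept if outcome == "accuracy" else effect_spec.time_intercept
    )
    if predictors is None:
        predictors = tuple(truth_coefs)
    truth = {"const": intercept, **{p: truth_coefs.get(p, 0.0) for p in predictors}}

    rows = []
    n_failed = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        trials = simulate_cohort(instance_set, n_participants, effect_spec, rng)
        trials, _ = apply_exclusions(trials, min_accuracy=min_accuracy)
        try:
            if outcome == "accuracy":
                fit = AccuracyModel.from_frame(trials, predictors).fit("mle")
            else:
                fit = CensoredTimeModel.from_frame(trials, predictors).fit("mle")
        except (FitError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        for name in ("const", *predictors):
            beta = truth[name]
            rows.append(
                {
                    "replicate": rep,
                    "coefficient": name,
                    "truth": beta,
                    "estimate": fit.median[name],
                    "lower": fit.ci_lower[name],
                    "upper": fit.ci_upper[name],
                    "covered": fit.ci_lower[name] <= beta <= fit.ci_upper[name],
                    "sign_recovered": (
                        (fit.ci_lower[name] > 0 and beta > 0)
                        or (fit.ci_upper[name] < 0 and beta < 0)
                    ),
                    "significant": fit.ci_lower[name] > 0 or fit.ci_upper[name] < 0,
                }
            )
    long = pd.DataFrame(rows)
    if long.empty:
        raise FitError(f"all {n_replicates} replicate fits failed")
    summary = (
        long.groupby("coefficient")
        .agg(
            truth=("truth", "first"),
            mean_estimate=("estimate", "mean"),
            bias=("estimate", lambda s: s.mean()),
            coverage=("covered", "mean"),
            sign_recovery=("sign_recovered", "mean"),
            significant_rate=("significant", "mean"),
            rmse=("estimate", lambda s: np.nan),
            n_fits=("estimate", "size"),
        )
        .reset_index()
    )
    summary["bias"] = summary["mean_estimate"] - summary["truth"]
    rmse = (
        long.assign(sq=(long["estimate"] - long["truth"]) ** 2)
        .groupby("coefficient")["sq"]
        .mean()
        .pow(0.5)
    )
    summary["rmse"] = summary["coefficient"].map(rmse)
    summary.attrs["n_failed"] = n_failed
    summary.attrs["n_replicates"] = n_replicates
    return summary
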