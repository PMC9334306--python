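"""Synthetic trial-level participant behavior.

The simulator emits one row per participant x instance with the statistical
structure the downstream models assume:

* accuracy: Bernoulli with a logit-linear predictor over instance hardness
  metrics plus a Gaussian participant random intercept;
* time-on-task: measured as a proportion of the trial time limit, linear in
  the same predictors with its own participant intercept and Gaussian
  residual, right-censored at 1.0 (the limit) and floored at a small
  positive epsilon;
* clicks: negative-binomial count with rate increasing in hardness, hard
  cap of 20 clicks per trial;
* rare missing responses (no answer before the deadline) with a small
  configurable probability.

The knapsack task was not self-paced, so KP trials carry no time outcome.
Instance presentation order is randomized independently per participant.

Intercepts and dispersion parameters are *inputs*, not estimands: the
packaged defaults were fixed once so that cohort summary statistics land in
the regime the tasks were tuned for (mean accuracy roughly 0.85, mean time
fraction roughly 0.55-0.8).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import InstanceSet
from .exceptions import HardcogError, SpecificationError

TIME_LIMITS_S = {"sat3": 110.0, "tsp": 40.0, "kp": 25.0}
CLICK_CAP = 20


@dataclass
class EffectSpec:
    """Ground-truth generative parameters for one problem's cohort.

    Coefficient dictionaries map predictor column names (``tcc_high``,
    ``under``, ``over``, ``satisfiable``, ``ic``, ``witnesses``,
    ``ln_witnesses``, ``n_clauses``, ...) to effect sizes.  Accuracy effects
    are on the logit scale; time effects on the proportion-of-limit scale.
    """

    problem: str
    accuracy_intercept: float
    accuracy_coefs: dict[str, float] = field(default_factory=dict)
    participant_sd: float = 0.5
    has_time: bool = True
    time_intercept: float = 0.6
    time_coefs: dict[str, float] = field(default_factory=dict)
    time_residual_sd: float = 0.15
    time_participant_sd: float = 0.08
    censor_limit: float = 1.0
    time_floor: float = 0.01
    time_limit_s: float = 110.0
    miss_prob: float = 0.007
    click_log_rate: float = 2.0
    click_coefs: dict[str, float] = field(default_factory=dict)
    click_dispersion: float = 10.0
    click_cap: int = CLICK_CAP

    def __post_init__(self) -> None:
        if not 0 <= self.miss_prob <= 0.05:
            raise SpecificationError("miss probability must lie in [0, 0.05]")
        if self.time_residual_sd <= 0:
            raise SpecificationError("residual sd must be positive")
        if self.click_cap != CLICK_CAP:
            raise SpecificationError(f"click cap is fixed at {CLICK_CAP}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EffectSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


# Packaged defaults: the named slope magnitudes are the study's reported
# effects (TCC -> accuracy and TCC -> time per problem); intercepts and
# spreads were chosen once to match the cohort summary statistics.
DEFAULT_EFFECTS: dict[str, EffectSpec] = {
    "sat3": EffectSpec(
        problem="sat3",
        accuracy_intercept=2.9,
        accuracy_coefs={"tcc_high": -1.58},
        participant_sd=0.5,
        time_intercept=0.50,
        time_coefs={"tcc_high": 0.149},
        time_residual_sd=0.18,
        time_participant_sd=0.08,
        time_limit_s=TIME_LIMITS_S["sat3"],
        click_coefs={"tcc_high": 0.35},
    ),
    "tsp": EffectSpec(
        problem="tsp",
        accuracy_intercept=3.2,
        accuracy_coefs={"tcc_high": -2.10},
        participant_sd=0.5,
        time_intercept=0.74,
        time_coefs={"tcc_high": 0.118},
        time_residual_sd=0.12,
        time_participant_sd=0.06,
        time_limit_s=TIME_LIMITS_S["tsp"],
        click_coefs={"tcc_high": 0.35},
    ),
    "kp": EffectSpec(
        problem="kp",
        accuracy_intercept=2.6,
        accuracy_coefs={"tcc_high": -1.327},
        participant_sd=0.5,
        has_time=False,
        time_limit_s=TIME_LIMITS_S["kp"],
        click_coefs={"tcc_high": 0.35},
    ),
}


def predictor_frame(instance_set: InstanceSet) -> pd.DataFrame:
    """Instance-level predictor columns derived from the metric bundles.

    ``ln_witnesses`` is the natural log of the witness count (defined for
    satisfiable instances only; NaN otherwise) — the scale used for TSP
    witness counts downstream.
    """
    man = instance_set.manifest
    df = pd.DataFrame(
        {
            "instance_id": man["instance_id"],
            "alpha": man["alpha"],
            "tcc_high": (man["tcc"] == "high").astype(float),
            "under": (man["region"] == "underconstrained").astype(float),
            "over": (man["region"] == "overconstrained").astype(float),
            "satisfiable": man["satisfiable"].astype(float),
            "witnesses": man["witnesses"].astype(float),
            "ic": man["ic"],
        }
    )
    with np.errstate(divide="ignore"):
        df["ln_witnesses"] = np.where(
            man["witnesses"] > 0, np.log(man["witnesses"].astype(float)), np.nan
        )
    if instance_set.problem == "sat3":
        df["n_clauses"] = man["n_clauses"].astype(float)
    return df.set_index("instance_id", drop=False)


def _linear_predictor(frame: pd.DataFrame, coefs: dict[str, float], what: str) -> np.ndarray:
    eta = np.zeros(len(frame))
    for name, beta in coefs.items():
        if name not in frame.columns:
            raise SpecificationError(
                f"{what} predictor {name!r} is not available in the metric bundle"
            )
        col = frame[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise SpecificationError(
                f"{what} predictor {name!r} is undefined (NaN) for some instances"
            )
        eta = eta + beta * col
    return eta


def simulate_cohort(
    instance_set: InstanceSet,
    n_participants: int,
    effect_spec: EffectSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one cohort; returns a tidy trial table.

    Columns: participant_id, instance_id, trial_index, correct (0/1, NaN on
    missing trials), time_prop ((0, 1], NaN for KP and missing trials),
    censored, clicks, plus the instance predictor columns joined in.
    """
    if n_participants < 2:
        raise SpecificationError("need at least 2 participants")
    frame = predictor_frame(instance_set)
    n_inst = len(frame)
    truth = {rec.instance_id: rec.satisfiable for rec in instance_set.records}

    eta_acc = effect_spec.accuracy_intercept + _linear_predictor(
        frame, effect_spec.accuracy_coefs, "accuracy"
    )
    if effect_spec.has_time:
        eta_time = effect_spec.time_intercept + _linear_predictor(
            frame, effect_spec.time_coefs, "time"
        )
    log_rate = effect_spec.click_log_rate + _linear_predictor(
        frame, effect_spec.click_coefs, "clicks"
    )

    rows = []
    for p in range(n_participants):
        pid = f"p{p:03d}"
        u_acc = rng.normal(0.0, effect_spec.participant_sd)
        u_time = rng.normal(0.0, effect_spec.time_participant_sd)
        order = rng.permutation(n_inst)
        for t, j in enumerate(order):
            iid = frame["instance_id"].iloc[j]
            missing = rng.random() < effect_spec.miss_prob
            p_correct = 1.0 / (1.0 + np.exp(-(eta_acc[j] + u_acc)))
            correct = float(rng.random() < p_correct)
            if effect_spec.has_time:
                latent = eta_time[j] + u_time + rng.normal(0.0, effect_spec.time_residual_sd)
                censored = latent >= effect_spec.censor_limit
                time_prop = float(
                    np.clip(latent, effect_spec.time_floor, effect_spec.censor_limit)
                )
            else:
                censored = False
                time_prop = np.nan
            mu = np.exp(log_rate[j])
            r = effect_spec.click_dispersion
            clicks = int(min(rng.negative_binomial(r, r / (r + mu)), effect_spec.click_cap))
            if missing:
                correct = np.nan
                time_prop = np.nan
                censored = False
            rows.append(
                {
                    "participant_id": pid,
                    "instance_id": iid,
                    "trial_index": t,
                    "correct": correct,
                    "time_prop": time_prop,
                    "censored": bool(censored),
                    "clicks": clicks,
                    "truth_satisfiable": truth[iid],
                }
            )
    trials = pd.DataFrame(rows)
    return trials.merge(frame.reset_index(drop=True), on="instance_id", how="left")


def apply_exclusions(
    trials: pd.DataFrame,
    min_accuracy: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop missing-response trials and near-chance participants.

    Returns (kept trials, exclusion report).  The report has one row per
    excluded trial or participant with the rule that fired.  Raises if no
    participant survives.
    """
    report_rows = []
    missing = trials["correct"].isna()
    for _, row in trials[missing].iterrows():
        report_rows.append(
            {
                "rule": "missing_response",
                "participant_id": row["participant_id"],
                "instance_id": row["instance_id"],
                "detail": "no answer given",
            }
        )
    kept = trials[~missing].copy()
    acc = kept.groupby("participant_id")["correct"].mean()
    bad = acc[acc < min_accuracy].index
    for pid in bad:
        report_rows.append(
            {
                "rule": "near_chance_participant",
                "participant_id": pid,
                "instance_id": None,
                "detail": f"accuracy {acc[pid]:.3f} < {min_accuracy}",
            }
        )
    kept = kept[~kept["participant_id"].isin(bad)]
    if kept.empty or kept["participant_id"].nunique() == 0:
        raise HardcogError("all participants excluded")
    report = pd.DataFrame(report_rows, columns=["rule", "participant_id", "instance_id", "detail"])
    return kept.reset_index(drop=True), report
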