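"""Synthetic observers for the three norm-inference experiments.

The generator emulates participants who watch a group of four moving agents
and report probabilities on a 0–100% slider:

* Experiment 1 — 32 participants × 32 trials; the condition is the number of
  agents (1–4 of 4) exhibiting the norm-consistent behavior, no deviants.
* Experiment 2 — 48 trials; the condition is the proportion of
  norm-consistent behaviors (25/50/75/100%), the rest behaving deviantly.
* Experiment 3 — as Experiment 2, plus desire judgments and per-model
  conditional-probability elicitations for the IE/FC/DM causal networks.

Each synthetic participant is a noisy ideal observer: elicited priors are
drawn around 0.5, elicited conditional probabilities around the generating
model's true (condition-dependent) values, and the judgmental posterior is
the generating model's posterior *computed from the elicited values* plus
response noise.  All noise is truncated-normal on [0, 1] and every reported
value is rounded to the slider grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    MODEL_CPT_ENTRIES,
    NetworkSpec,
    bayes_posterior,
    desire_posterior,
    joint_table,
    network_posterior,
)

__all__ = [
    "ExperimentDesign",
    "ObserverParams",
    "TRIAL_COLUMNS",
    "default_design",
    "true_cpt",
    "derived_measure_truths",
    "generate_experiment",
    "aggregate_by_condition",
]

TRIAL_COLUMNS = ["participant", "experiment", "condition", "trial", "measure", "value"]

#: Number of moving agents whose behavior defines a condition.
N_AGENTS = 4


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural description of one experiment's trial table."""

    experiment_id: int
    n_participants: int = 32
    trials_per_condition: int | None = None
    conditions: tuple[float, ...] | None = None
    slider_step: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.experiment_id not in (1, 2, 3):
            raise ValueError("experiment_id must be 1, 2 or 3")
        if self.trials_per_condition is None:
            object.__setattr__(
                self, "trials_per_condition", 8 if self.experiment_id == 1 else 12
            )
        if self.conditions is None:
            default = (1, 2, 3, 4) if self.experiment_id == 1 else (0.25, 0.5, 0.75, 1.0)
            object.__setattr__(self, "conditions", tuple(default))
        conds = tuple(self.conditions)
        if any(b <= a for a, b in zip(conds, conds[1:])):
            raise ValueError("conditions must be strictly increasing")
        n_steps = 1.0 / self.slider_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("slider_step must divide 1 exactly")
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")

    @property
    def total_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    def proportion(self, condition: float) -> float:
        """Proportion of norm-consistent agents coded by a condition label.

        Experiment 1 codes conditions as counts (1-4 of 4 agents); the other
        experiments code them directly as proportions.
        """
        if self.experiment_id == 1:
            return condition / N_AGENTS
        return float(condition)


@dataclass(frozen=True)
class ObserverParams:
    """Noise model of the synthetic participants.

    ``generating_model`` names the network the observers actually use
    (BAYES, IE, FC or DM); ``true_cpt`` optionally overrides the default
    condition-dependent CPT (mapping condition -> entry dict).  The sigmas
    are truncated-normal standard deviations on the probability scale for
    prior elicitation, conditional-probability elicitation and the final
    slider judgment.
    """

    generating_model: str = "BAYES"
    true_cpt: Mapping[float, Mapping[str, float]] | None = None
    sigma_prior: float = 0.05
    sigma_elicit: float = 0.05
    sigma_response: float = 0.05

    def __post_init__(self):
        if self.generating_model not in ("BAYES", "IE", "FC", "DM"):
            raise ValueError(f"unknown generating model {self.generating_model!r}")
        for name in ("sigma_prior", "sigma_elicit", "sigma_response"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_design(experiment_id: int, seed: int = 0, **kwargs) -> ExperimentDesign:
    """The experiment's standard design (32 participants, 32 or 48 trials)."""
    return ExperimentDesign(experiment_id=experiment_id, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Generating-model truth
# ---------------------------------------------------------------------------

def true_cpt(model: str, proportion: float) -> dict[str, float]:
    """Default generating CPT for a condition with the given proportion of
    norm-consistent agents.

    Action probabilities rise linearly with the proportion and are larger
    under a norm than without one, so the likelihood ratio — and hence the
    ideal posterior — increases across conditions.  The Experiment 1 variant
    (no deviant behaviors) keeps every posterior above 0.5; the Experiment
    2/3 variant lets the 25% condition pull the posterior below 0.5, matching
    the qualitative pattern of the human judgments.
    """
    p = float(proportion)
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if model == "BAYES":
        return {
            "p_n": 0.5,
            "p_a_given_n": 0.10 + 0.85 * p,
            "p_a_given_notn": 0.75 - 0.55 * p,
        }
    action = {
        "p_a_given_n_d": 0.20 + 0.75 * p,
        "p_a_given_n_notd": 0.05 + 0.75 * p,
        "p_a_given_notn_d": 0.85 - 0.55 * p,
        "p_a_given_notn_notd": 0.60 - 0.55 * p,
    }
    if model == "IE":
        return {"p_n": 0.5, "p_d": 0.6, **action}
    if model == "FC":
        return {"p_n": 0.5, "p_d_given_n": 0.75, "p_d_given_notn": 0.35, **action}
    if model == "DM":
        return {
            "p_n": 0.5,
            "p_d_given_n": 0.8,
            "p_d_given_notn": 0.3,
            "p_a_given_d": 0.05 + 0.85 * p,
            "p_a_given_notd": 0.75 - 0.60 * p,
        }
    raise ValueError(f"unknown model {model!r}")


def _bayes_exp1_cpt(proportion: float) -> dict[str, float]:
    # Experiment 1 shows only norm-consistent movers (others static): evidence
    # is weaker but never negative, so P(A|N) starts at 0.5 for a single mover.
    p = float(proportion)
    return {
        "p_n": 0.5,
        "p_a_given_n": 0.35 + 0.60 * p,
        "p_a_given_notn": 0.45 - 0.20 * p,
    }


def _generating_cpt(design: ExperimentDesign, obs: ObserverParams, condition: float):
    if obs.true_cpt is not None:
        return dict(obs.true_cpt[condition])
    p = design.proportion(condition)
    if obs.generating_model == "BAYES" and design.experiment_id == 1:
        return _bayes_exp1_cpt(p)
    return true_cpt(obs.generating_model, p)


def derived_measure_truths(
    design: ExperimentDesign, obs: ObserverParams, condition: float
) -> dict[str, float]:
    """True values of every elicited measure, derived from the generating joint.

    A coherent observer's elicitations all reflect one underlying joint over
    (N, D, A): the two-variable conditionals ``P(A|N)``/``P(A|¬N)`` and each
    candidate network's CPT entries are read off the generating model's joint
    at this condition, so the per-model elicitations of Experiment 3 are
    mutually consistent up to noise.
    """
    cpt = _generating_cpt(design, obs, condition)
    truths: dict[str, float] = {"prior_norm": 0.5}
    if obs.generating_model == "BAYES":
        truths["p_a_given_n"] = cpt["p_a_given_n"]
        truths["p_a_given_notn"] = cpt["p_a_given_notn"]
        return truths

    spec = NetworkSpec(obs.generating_model, cpt)
    J = joint_table(spec)
    p_n = J[1].sum()
    p_d = J[:, 1].sum()

    def cond(num, den):
        return float(num / den) if den > 0 else 0.5

    # Two-variable likelihoods for the single Bayes update.
    truths["p_a_given_n"] = cond(J[1, :, 1].sum(), p_n)
    truths["p_a_given_notn"] = cond(J[0, :, 1].sum(), 1.0 - p_n)
    if design.experiment_id != 3:
        return truths

    truths["prior_desire"] = float(p_d)
    derived = {
        "p_d": float(p_d),
        "p_d_given_n": cond(J[1, 1].sum(), p_n),
        "p_d_given_notn": cond(J[0, 1].sum(), 1.0 - p_n),
        "p_a_given_n_d": cond(J[1, 1, 1], J[1, 1].sum()),
        "p_a_given_n_notd": cond(J[1, 0, 1], J[1, 0].sum()),
        "p_a_given_notn_d": cond(J[0, 1, 1], J[0, 1].sum()),
        "p_a_given_notn_notd": cond(J[0, 0, 1], J[0, 0].sum()),
        "p_a_given_d": cond(J[:, 1, 1].sum(), p_d),
        "p_a_given_notd": cond(J[:, 0, 1].sum(), 1.0 - p_d),
    }
    for model, entries in MODEL_CPT_ENTRIES.items():
        for entry in entries:
            if entry == "p_n":
                continue
            truths[f"cpt:{model.lower()}:{entry}"] = derived[entry]
    return truths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _truncnorm_noise(rng: np.random.Generator, mean, sigma: float):
    """Truncated-normal draw on [0, 1] centred on ``mean`` (exact at sigma=0)."""
    mean = np.asarray(mean, dtype=float)
    if sigma == 0:
        return mean.copy()
    a = (0.0 - mean) / sigma
    b = (1.0 - mean) / sigma
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sigma, random_state=rng)


def _snap(values, step: float):
    return np.clip(np.round(np.asarray(values, dtype=float) / step) * step, 0.0, 1.0)


def generate_experiment(design: ExperimentDesign, obs: ObserverParams) -> pd.DataFrame:
    """Simulate the full long-format trial table for one experiment.

    Deterministic given ``design.seed``.  Per trial the observer (1) reports a
    prior drawn around 0.5, (2) reports each required conditional probability
    drawn around its true derived value, and (3) reports the generating
    model's posterior computed from those elicited values, plus response
    noise.  Experiment 3 adds desire priors and posteriors from the
    generating network's ``P(D)`` / ``P(D|A)``.
    """
    if design.experiment_id != 3 and obs.generating_model != "BAYES":
        raise ValueError("network generating models require the Experiment 3 design")
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    step = design.slider_step
    gen = obs.generating_model
    records: list[tuple] = []

    for pid in range(1, design.n_participants + 1):
        trial_no = 0
        for condition in design.conditions:
            truths = derived_measure_truths(design, obs, condition)
            elicit_names = [m for m in truths if m not in ("prior_norm", "prior_desire")]
            T = design.trials_per_condition

            priors = _snap(
                _truncnorm_noise(rng, np.full(T, truths["prior_norm"]), obs.sigma_prior),
                step,
            )
            elicited = _snap(
                _truncnorm_noise(
                    rng,
                    np.tile([truths[m] for m in elicit_names], (T, 1)),
                    obs.sigma_elicit,
                ),
                step,
            )
            if "prior_desire" in truths:
                d_priors = _snap(
                    _truncnorm_noise(
                        rng, np.full(T, truths["prior_desire"]), obs.sigma_prior
                    ),
                    step,
                )

            # The judgmental posterior: the generating model applied to the
            # observer's own elicited numbers, then response noise.
            model_post = np.empty(T)
            d_post = np.empty(T)
            for t in range(T):
                row = dict(zip(elicit_names, elicited[t]))
                if gen == "BAYES":
                    model_post[t] = bayes_posterior(
                        (priors[t], row["p_a_given_n"], row["p_a_given_notn"])
                    )
                else:
                    prefix = f"cpt:{gen.lower()}:"
                    cpt = {"p_n": priors[t]}
                    cpt.update(
                        {e: row[prefix + e] for e in MODEL_CPT_ENTRIES[gen] if e != "p_n"}
                    )
                    spec = NetworkSpec(gen, cpt)
                    model_post[t] = network_posterior(spec)
                    # Even in IE, where desires are causally independent of
                    # norms, the desire judgment updates on the observed action.
                    d_post[t] = desire_posterior(spec)
            posts = _snap(_truncnorm_noise(rng, model_post, obs.sigma_response), step)
            if design.experiment_id == 3 and gen != "BAYES":
                d_posts = _snap(_truncnorm_noise(rng, d_post, obs.sigma_response), step)

            for t in range(T):
                trial_no += 1
                values = {"prior_norm": priors[t]}
                if "prior_desire" in truths:
                    values["prior_desire"] = d_priors[t]
                values.update(dict(zip(elicit_names, elicited[t])))
                values["posterior_norm"] = posts[t]
                if design.experiment_id == 3 and gen != "BAYES":
                    values["posterior_desire"] = d_posts[t]
                for measure, value in values.items():
                    records.append(
                        (pid, design.experiment_id, condition, trial_no, measure, float(value))
                    )

    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def aggregate_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant × condition × measure means of the trial values.

    Raises if any participant × condition cell is missing a measure that other
    cells have, rather than silently dropping it.
    """
    required = set(TRIAL_COLUMNS)
    missing = required - set(trials.columns)
    if missing:
        raise KeyError(f"trial table missing columns {sorted(missing)}")
    agg = (
        trials.groupby(["participant", "experiment", "condition", "measure"], sort=True)[
            "value"
        ]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_value"})
    )
    counts = agg.groupby(["experiment", "measure"])["mean_value"].count()
    cells = trials.groupby("experiment").apply(
        lambda g: g["participant"].nunique() * g["condition"].nunique(),
        include_groups=False,
    )
    bad = [
        (exp, measure)
        for (exp, measure), n in counts.items()
        if n != cells.loc[exp]
    ]
    if bad:
        raise ValueError(f"incomplete participant×condition cells for measures {bad}")
    return agg
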