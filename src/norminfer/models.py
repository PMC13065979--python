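"""Candidate cognitive models of group-norm inference.

An observer watches a small group of agents and judges the probability that an
injunctive norm ``N`` governs the group.  The candidate models map elicited
probabilities to a predicted posterior judgment:

* a single Bayes update ``P(N|A)`` from an elicited prior and the two
  likelihoods ``P(A|N)``, ``P(A|¬N)``;
* three discrete causal Bayesian networks over norm ``N``, desire ``D`` and
  action ``A`` — independent effects (IE: N→A←D), fully connected
  (FC: N→D, N→A, D→A) and desire mediation (DM: N→D→A) — solved by exact
  enumeration over the eight-cell joint;
* a frequency-tracking baseline that predicts the raw proportion of
  norm-consistent behaviors and integrates no prior at all.

Belief updating is quantified as the Kullback–Leibler divergence between the
two-point posterior and prior belief distributions, in nats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EPS",
    "BeliefPair",
    "ElicitedProbabilities",
    "NetworkSpec",
    "UpdateMetric",
    "DegenerateEvidenceError",
    "bayes_posterior",
    "kl_update",
    "kl_divergence",
    "network_posterior",
    "desire_posterior",
    "frequency_estimate",
    "joint_table",
    "marginal",
    "add_model_posteriors",
    "MODEL_CPT_ENTRIES",
]

#: Probabilities are clipped to [EPS, 1 - EPS] before logs and denominators;
#: sliders allow exact 0%/100% responses that would otherwise produce
#: infinities.
EPS = 1e-6

#: CPT entries each network structure requires (the norm prior P(N) included).
MODEL_CPT_ENTRIES: dict[str, tuple[str, ...]] = {
    "IE": (
        "p_n",
        "p_d",
        "p_a_given_n_d",
        "p_a_given_n_notd",
        "p_a_given_notn_d",
        "p_a_given_notn_notd",
    ),
    "FC": (
        "p_n",
        "p_d_given_n",
        "p_d_given_notn",
        "p_a_given_n_d",
        "p_a_given_n_notd",
        "p_a_given_notn_d",
        "p_a_given_notn_notd",
    ),
    "DM": (
        "p_n",
        "p_d_given_n",
        "p_d_given_notn",
        "p_a_given_d",
        "p_a_given_notd",
    ),
}


class DegenerateEvidenceError(ValueError):
    """Raised when the evidence has probability zero under every hypothesis."""


def _clip(p):
    return np.clip(p, EPS, 1.0 - EPS)


@dataclass(frozen=True)
class BeliefPair:
    """Prior and posterior probability that the norm exists, for one judgment."""

    prior: float
    posterior: float

    def __post_init__(self):
        for name in ("prior", "posterior"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ElicitedProbabilities:
    """Inputs of the single Bayes update.

    ``P(¬N)`` is always derived as ``1 - p_n`` and never stored.
    """

    p_n: float
    p_a_given_n: float
    p_a_given_notn: float

    def __post_init__(self):
        for name in ("p_n", "p_a_given_n", "p_a_given_notn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class UpdateMetric:
    """KL divergence of the posterior from the prior belief, in nats."""

    d_kl: float


@dataclass(frozen=True)
class NetworkSpec:
    """A causal model identifier plus the CPT entries its structure requires.

    ``model`` is one of ``IE``, ``FC``, ``DM`` (networks over N, D, A),
    ``BAYES`` (the two-variable update) or ``FREQ`` (the baseline, which
    needs no CPT).
    """

    model: str
    cpt: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.model in MODEL_CPT_ENTRIES:
            required = set(MODEL_CPT_ENTRIES[self.model])
            given = set(self.cpt)
            if given != required:
                missing = sorted(required - given)
                extra = sorted(given - required)
                raise ValueError(
                    f"{self.model} CPT mismatch: missing {missing}, unexpected {extra}"
                )
        elif self.model not in ("BAYES", "FREQ"):
            raise ValueError(f"unknown model {self.model!r}")
        for k, v in self.cpt.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CPT entry {k} must lie in [0, 1], got {v}")


def bayes_posterior(e: ElicitedProbabilities | tuple[float, float, float]) -> float:
    """Posterior probability that the norm exists after observing the action.

    Computes ``P(N|A) = P(N) P(A|N) / (P(N) P(A|N) + P(¬N) P(A|¬N))`` with the
    inputs clipped to ``[EPS, 1 - EPS]``.
    """
    if not isinstance(e, ElicitedProbabilities):
        e = ElicitedProbabilities(*e)
    p_n = _clip(e.p_n)
    num = p_n * _clip(e.p_a_given_n)
    den = num + (1.0 - p_n) * _clip(e.p_a_given_notn)
    if den <= 0.0:
        raise DegenerateEvidenceError("action has zero probability under both hypotheses")
    return float(num / den)


def kl_update(b: BeliefPair | tuple[float, float]) -> UpdateMetric:
    """KL divergence D(posterior ‖ prior) over the two-point belief distributions.

    Both probabilities are clipped to ``[EPS, 1 - EPS]`` before taking logs, so
    dogmatic 0/1 slider responses give a large but finite divergence.
    """
    if not isinstance(b, BeliefPair):
        b = BeliefPair(*b)
    p = _clip(b.posterior)
    q = _clip(b.prior)
    d = p * (np.log(p) - np.log(q)) + (1.0 - p) * (np.log(1.0 - p) - np.log(1.0 - q))
    return UpdateMetric(d_kl=float(max(d, 0.0)))


def kl_divergence(prior, posterior):
    """Vectorized two-point KL divergence D(posterior ‖ prior) in nats."""
    p = _clip(np.asarray(posterior, dtype=float))
    q = _clip(np.asarray(prior, dtype=float))
    d = p * (np.log(p) - np.log(q)) + (1.0 - p) * (np.log(1.0 - p) - np.log(1.0 - q))
    return np.maximum(d, 0.0)


def joint_table(spec: NetworkSpec) -> np.ndarray:
    """Joint distribution over (N, D, A) under the model's factorization.

    Returns an array ``J[n, d, a]`` indexed 0 = false, 1 = true, built from the
    model's CPT: IE as ``P(N)P(D)P(A|N,D)``, FC as ``P(N)P(D|N)P(A|N,D)`` and
    DM as ``P(N)P(D|N)P(A|D)``.
    """
    c = spec.cpt

    def pr(p, value):
        return p if value else 1.0 - p

    J = np.empty((2, 2, 2))
    for n, d, a in itertools.product((0, 1), repeat=3):
        p_n = pr(c["p_n"], n)
        if spec.model == "IE":
            p_d = pr(c["p_d"], d)
            p_a = pr(c[f"p_a_given_{'n' if n else 'notn'}_{'d' if d else 'notd'}"], a)
        elif spec.model == "FC":
            p_d = pr(c[f"p_d_given_{'n' if n else 'notn'}"], d)
            p_a = pr(c[f"p_a_given_{'n' if n else 'notn'}_{'d' if d else 'notd'}"], a)
        elif spec.model == "DM":
            p_d = pr(c[f"p_d_given_{'n' if n else 'notn'}"], d)
            p_a = pr(c[f"p_a_given_{'d' if d else 'notd'}"], a)
        else:
            raise ValueError(f"{spec.model} is not a causal network model")
        J[n, d, a] = p_n * p_d * p_a
    return J


def _conditional_on_action(J: np.ndarray, axis: int, action_observed: bool) -> float:
    a = 1 if action_observed else 0
    slice_a = J[:, :, a]
    total = slice_a.sum()
    if total <= 0.0:
        raise DegenerateEvidenceError("observed action has zero joint probability")
    return float(slice_a.sum(axis=1 - axis)[1] / total)


def network_posterior(spec: NetworkSpec, action_observed: bool = True) -> float:
    """Exact ``P(N | A = action_observed)`` by enumeration over the joint."""
    return _conditional_on_action(joint_table(spec), axis=0, action_observed=action_observed)


def desire_posterior(spec: NetworkSpec, action_observed: bool = True) -> float:
    """Exact ``P(D | A = action_observed)`` by enumeration over the joint."""
    return _conditional_on_action(joint_table(spec), axis=1, action_observed=action_observed)


def marginal(spec: NetworkSpec, variable: str) -> float:
    """Marginal probability of ``variable`` in {'n', 'd', 'a'} under the network."""
    axis = {"n": 0, "d": 1, "a": 2}[variable]
    J = joint_table(spec)
    return float(J.sum(axis=tuple(i for i in range(3) if i != axis))[1])


def frequency_estimate(k_consistent: int, n_moving: int) -> float:
    """Frequency-tracking baseline: the raw proportion ``k / n``.

    The model keeps no prior and applies no smoothing, so over a design with
    ``n`` moving agents it can only ever output the fixed grid
    ``{0, 1/n, ..., 1}``.
    """
    if n_moving <= 0:
        raise ValueError("n_moving must be positive")
    if not 0 <= k_consistent <= n_moving:
        raise ValueError("k_consistent must lie in [0, n_moving]")
    return k_consistent / n_moving


# ---------------------------------------------------------------------------
# Table-level API: per-trial model posteriors from elicited measures
# ---------------------------------------------------------------------------

def _require(wide: pd.DataFrame, cols: list[str], model: str) -> None:
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise KeyError(f"model {model} needs elicited measures {missing}")


def add_model_posteriors(
    trials: pd.DataFrame, models: list[str], n_agents: int = 4
) -> pd.DataFrame:
    """Compute per-trial model-derived posteriors from elicited measures.

    ``trials`` is the long table with columns ``participant, experiment,
    condition, trial, measure, value``.  Each trial's elicited values feed the
    requested models; the result is one row per participant × trial with a
    ``model_posterior:<name>`` column per model plus the judgmental measures
    carried through.
    """
    index = ["participant", "experiment", "condition", "trial"]
    wide = trials.pivot_table(index=index, columns="measure", values="value").reset_index()
    wide.columns.name = None

    for model in models:
        if model == "BAYES":
            _require(wide, ["prior_norm", "p_a_given_n", "p_a_given_notn"], model)
            out = [
                bayes_posterior((r.prior_norm, r.p_a_given_n, r.p_a_given_notn))
                for r in wide.itertuples()
            ]
        elif model == "FREQ":
            cond = wide["condition"].to_numpy(dtype=float)
            exp = wide["experiment"].to_numpy()
            # Experiment 1 codes conditions as counts of norm-consistent agents
            # (1..n_agents); the others as proportions. FREQ predicts k/n.
            out = np.where(exp == 1, cond / n_agents, cond)
        elif model in MODEL_CPT_ENTRIES:
            prefix = f"cpt:{model.lower()}:"
            entries = [e for e in MODEL_CPT_ENTRIES[model] if e != "p_n"]
            cols = [prefix + e for e in entries]
            _require(wide, ["prior_norm", *cols], model)
            out = []
            for row in wide.itertuples():
                cpt = {"p_n": getattr(row, "prior_norm")}
                for e, c in zip(entries, cols):
                    cpt[e] = wide.at[row.Index, c]
                out.append(network_posterior(NetworkSpec(model, cpt)))
        else:
            raise ValueError(f"unknown model {model!r}")
        wide[f"model_posterior:{model}"] = np.asarray(out, dtype=float)
    return wide
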