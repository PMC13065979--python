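"""Pipeline glue: trial-table IO, run configuration and end-to-end runners.

`run_experiment` reproduces one experiment's full analysis on synthetic
observers (or on an externally supplied trial table in the same long CSV
format): simulate -> aggregate -> descriptive ANOVA/t tests -> model-derived
posteriors -> hierarchical regressions (participant-only and the
condition-random-effect robustness variant) -> LOO model comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import models as _models
from . import observers as _obs
from . import regression as _reg
from . import comparison as _cmp
from . import stats as _stats

__all__ = ["RunConfig", "read_trials", "write_trials", "run_experiment"]

log = logging.getLogger("norminfer")

_REQUIRED = list(_obs.TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the long-format trial table as UTF-8 CSV with a header row."""
    trials.to_csv(path, index=False, columns=_REQUIRED, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Values may be stored as proportions (0-1) or percentages (0-100); the
    scale is auto-detected from the maximum value and percentages are
    converted to proportions.  Extra columns are dropped with a warning;
    missing required columns are an error.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise KeyError(f"trial table {path} is missing required columns {missing}")
    extra = [c for c in df.columns if c not in _REQUIRED]
    if extra:
        log.warning("ignoring extra columns %s in %s", extra, path)
        df = df[_REQUIRED].copy()
    vals = df["value"].to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 100:
        raise ValueError("values must lie in [0, 1] or [0, 100]")
    if np.nanmax(vals) > 1.5:
        log.info("values in %s look like percentages; rescaling to proportions", path)
        df["value"] = vals / 100.0
    return df


@dataclass
class RunConfig:
    """Everything needed to regenerate one experiment's full analysis."""

    experiment_id: int
    models: tuple[str, ...] = ("BAYES", "FREQ")
    design: dict[str, Any] = field(default_factory=dict)
    observer: dict[str, Any] = field(default_factory=dict)
    mcmc: dict[str, int] = field(
        default_factory=lambda: {"chains": 2, "iterations": 2000, "warmup": 500}
    )
    condition_random_effect: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        self.models = tuple(self.models)
        if not self.models:
            raise ValueError("at least one model must be evaluated")
        allowed = {"BAYES", "FREQ"} if self.experiment_id in (1, 2) else {
            "BAYES",
            "FREQ",
            "IE",
            "FC",
            "DM",
        }
        bad = set(self.models) - allowed
        if bad:
            raise ValueError(
                f"models {sorted(bad)} not available for experiment {self.experiment_id}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage_seed(seed: int, index: int) -> int:
    """Counter-based fan-out of the global seed into independent stage seeds."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def per_trial_table(trials: pd.DataFrame, config_models: list[str]) -> pd.DataFrame:
    """Wide per-trial frame with model posteriors and the per-trial D_KL."""
    wide = _models.add_model_posteriors(trials, list(config_models))
    wide["d_kl"] = _models.kl_divergence(wide["prior_norm"], wide["posterior_norm"])
    return wide


def aggregate_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Participant × condition means of every numeric per-trial column."""
    value_cols = [
        c
        for c in wide.columns
        if c not in ("participant", "experiment", "condition", "trial")
    ]
    return (
        wide.groupby(["participant", "condition"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def _descriptives(per_pc: pd.DataFrame, experiment_id: int):
    anova_rows, ttest_rows = [], []
    conditions = sorted(per_pc["condition"].unique())
    measures = ["prior_norm", "posterior_norm", "d_kl"]
    if "posterior_desire" in per_pc.columns:
        measures += ["prior_desire", "posterior_desire"]
    for measure in measures:
        pivot = per_pc.pivot(index="participant", columns="condition", values=measure)
        res = _stats.rm_anova(pivot)
        anova_rows.append({"measure": measure, **dataclasses.asdict(res)})
        try:
            for t in _stats.paired_posthoc(pivot):
                ttest_rows.append({"measure": measure, "kind": "paired", **dataclasses.asdict(t)})
        except ZeroDivisionError:
            log.warning("degenerate paired contrast for %s skipped", measure)
        mu = 0.0 if measure == "d_kl" else 0.5
        for cond in conditions:
            t = _stats.one_sample_t(
                pivot[cond], mu=mu, m=len(conditions), label=f"{cond} vs {mu}"
            )
            ttest_rows.append({"measure": measure, "kind": "one_sample", **dataclasses.asdict(t)})
    return pd.DataFrame(anova_rows), pd.DataFrame(ttest_rows)


def run_experiment(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """Run the full analysis pipeline for one experiment.

    Returns a bundle dict with the trial table, aggregated table, ANOVA and
    t-test reports, one regression summary per model and random-effect
    structure, the fitted results, and (when two or more models are compared)
    the LOO ranking table.  If ``config.out_dir`` is set, every stage output
    is also written there along with a JSON run log.
    """
    bundle: dict[str, Any] = {"config": config}

    stage = "simulate"
    try:
        if trials is None:
            design = _obs.ExperimentDesign(
                experiment_id=config.experiment_id,
                seed=_stage_seed(config.seed, 0),
                **config.design,
            )
            obs = _obs.ObserverParams(**config.observer)
            trials = _obs.generate_experiment(design, obs)
        bundle["trials"] = trials

        stage = "aggregate"
        bundle["aggregated_long"] = _obs.aggregate_by_condition(trials)
        wide = per_trial_table(trials, list(config.models))
        per_pc = aggregate_wide(wide)
        bundle["aggregated"] = per_pc

        stage = "descriptives"
        bundle["anova"], bundle["ttests"] = _descriptives(per_pc, config.experiment_id)

        stage = "regression"
        reg_rows, fits = [], {}
        for i, model in enumerate(config.models):
            x_col = f"model_posterior:{model}"
            variants = [("participant", False)]
            if config.condition_random_effect:
                variants.append(("participant+condition", True))
            for label, crossed in variants:
                fit = _reg.fit_hierarchical(
                    per_pc,
                    x_col=x_col,
                    y_col="posterior_norm",
                    seed=_stage_seed(config.seed, 10 + 2 * i + int(crossed)),
                    condition_random_effect=crossed,
                    **config.mcmc,
                )
                row = _reg.summarize(fit)
                reg_rows.append(
                    {"model": model, "random_effects": label, **row.to_dict()}
                )
                if not crossed:
                    fits[model] = fit
        bundle["regression"] = pd.DataFrame(reg_rows)
        bundle["fits"] = fits

        stage = "loo"
        if len(fits) >= 2:
            loos = [
                _cmp.psis_loo(fit.pointwise_loglik, model=m) for m, fit in fits.items()
            ]
            bundle["loo"] = _cmp.compare(loos)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: Mapping[str, Any], config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials(bundle["trials"], out / "trials.csv")
    bundle["aggregated"].to_csv(out / "aggregated.csv", index=False)
    bundle["anova"].to_csv(out / "anova.csv", index=False)
    bundle["ttests"].to_csv(out / "ttests.csv", index=False)
    bundle["regression"].to_csv(out / "regression.csv", index=False)
    if "loo" in bundle:
        bundle["loo"].to_csv(out / "loo.csv", index=False)
    for model, fit in bundle["fits"].items():
        # Columnar draws file: one array per parameter (chains x draws) plus
        # the pointwise log-likelihood (chains x draws x observations).
        np.savez_compressed(
            out / f"draws_{model}.npz",
            pointwise_loglik=fit.pointwise_loglik,
            **{k: v for k, v in fit.draws.items()},
        )
    import norminfer

    logpath = out / "run_log.json"
    with open(logpath, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": {
                    **dataclasses.asdict(config),
                    "models": list(config.models),
                },
                "seed": config.seed,
                "versions": {
                    "norminfer": norminfer.__version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            },
            fh,
            indent=2,
        )
    log.info("run bundle written to %s", out)
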