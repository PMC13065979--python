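import warnings

import pytest
from hypothesis import settings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import norminfer as ni
from norminfer.io import aggregate_wide, per_trial_table


@pytest.fixture(scope="session")
def exp1_tables():
    """Default-noise Experiment 1 synthetic data plus aggregated model posteriors."""
    design = ni.ExperimentDesign(experiment_id=1, seed=42)
    trials = ni.generate_experiment(design, ni.ObserverParams())
    per_pc = aggregate_wide(per_trial_table(trials, ["BAYES", "FREQ"]))
    return trials, per_pc


@pytest.fixture(scope="session")
def exp3_tables():
    """Default-noise Experiment 3 data generated by IE observers."""
    design = ni.ExperimentDesign(experiment_id=3, seed=7)
    trials = ni.generate_experiment(design, ni.ObserverParams(generating_model="IE"))
    per_pc = aggregate_wide(per_trial_table(trials, ["IE", "FC", "DM", "BAYES", "FREQ"]))
    return trials, per_pc


@pytest.fixture(scope="session")
def quick_fit(exp1_tables):
    """One reduced-size hierarchical fit shared across regression tests."""
    _, per_pc = exp1_tables
    return ni.fit_hierarchical(
        per_pc,
        x_col="model_posterior:BAYES",
        chains=2,
        iterations=2000,
        warmup=500,
        seed=1,
    )
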