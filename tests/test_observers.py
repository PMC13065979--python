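"""Synthetic-observer generator tests: determinism, grid/range invariants,
noise-free ideal-observer exactness and the monotone condition pattern."""

import numpy as np
import pandas as pd
import pytest

import norminfer as ni
from norminfer.io import aggregate_wide, per_trial_table
from norminfer.models import bayes_posterior
from norminfer.observers import derived_measure_truths


def noiseless(model="BAYES"):
    return ni.ObserverParams(
        generating_model=model, sigma_prior=0.0, sigma_elicit=0.0, sigma_response=0.0
    )


class TestDesign:
    def test_defaults_match_experiment_structure(self):
        d1 = ni.ExperimentDesign(experiment_id=1)
        assert d1.total_trials == 32 and d1.conditions == (1, 2, 3, 4)
        d2 = ni.ExperimentDesign(experiment_id=2)
        assert d2.total_trials == 48 and d2.conditions == (0.25, 0.5, 0.75, 1.0)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            ni.ExperimentDesign(experiment_id=1, conditions=(2, 1, 3, 4))
        with pytest.raises(ValueError):
            ni.ExperimentDesign(experiment_id=1, slider_step=0.03)
        with pytest.raises(ValueError):
            ni.ObserverParams(sigma_prior=-0.1)

    def test_network_generators_need_experiment_3(self):
        d1 = ni.ExperimentDesign(experiment_id=1)
        with pytest.raises(ValueError):
            ni.generate_experiment(d1, ni.ObserverParams(generating_model="IE"))


class TestGeneration:
    def test_seeded_determinism(self):
        design = ni.ExperimentDesign(experiment_id=2, seed=5)
        obs = ni.ObserverParams()
        a = ni.generate_experiment(design, obs)
        b = ni.generate_experiment(design, obs)
        pd.testing.assert_frame_equal(a, b)
        c = ni.generate_experiment(
            ni.ExperimentDesign(experiment_id=2, seed=6), obs
        )
        assert not a["value"].equals(c["value"])

    @pytest.mark.parametrize("experiment_id, model", [(1, "BAYES"), (3, "FC")])
    def test_values_on_slider_grid_and_in_range(self, experiment_id, model):
        design = ni.ExperimentDesign(experiment_id=experiment_id, n_participants=4, seed=2)
        trials = ni.generate_experiment(design, ni.ObserverParams(generating_model=model))
        v = trials["value"].to_numpy()
        assert ((0 <= v) & (v <= 1)).all()
        np.testing.assert_allclose(np.round(v / 0.01) * 0.01, v, atol=1e-12)

    def test_zero_prior_noise_gives_exact_half(self):
        design = ni.ExperimentDesign(experiment_id=1, n_participants=4, seed=3)
        obs = ni.ObserverParams(sigma_prior=0.0)
        trials = ni.generate_experiment(design, obs)
        priors = trials.loc[trials["measure"] == "prior_norm", "value"]
        assert (priors == 0.5).all()

    def test_noise_free_judgments_equal_bayes_update_exactly(self):
        design = ni.ExperimentDesign(experiment_id=1, n_participants=4, seed=4)
        trials = ni.generate_experiment(design, noiseless())
        wide = trials.pivot_table(
            index=["participant", "condition", "trial"], columns="measure", values="value"
        )
        for _, row in wide.iterrows():
            expected = bayes_posterior(
                (row["prior_norm"], row["p_a_given_n"], row["p_a_given_notn"])
            )
            # judgments are snapped to the 0.01 slider grid
            assert abs(row["posterior_norm"] - expected) <= 0.005 + 1e-12

    def test_exp3_includes_desire_and_per_model_cpt_measures(self):
        design = ni.ExperimentDesign(experiment_id=3, n_participants=2, seed=5)
        trials = ni.generate_experiment(design, ni.ObserverParams(generating_model="IE"))
        measures = set(trials["measure"])
        assert {"prior_desire", "posterior_desire", "cpt:ie:p_d",
                "cpt:fc:p_d_given_n", "cpt:dm:p_a_given_d"} <= measures

    def test_derived_truths_are_coherent_across_models(self):
        # FC's derived entries must reproduce the generating joint's
        # conditionals, whatever the generating model.
        design = ni.ExperimentDesign(experiment_id=3)
        obs = ni.ObserverParams(generating_model="DM")
        truths = derived_measure_truths(design, obs, 0.75)
        p_d = (
            truths["cpt:fc:p_d_given_n"] * 0.5 + truths["cpt:fc:p_d_given_notn"] * 0.5
        )
        assert truths["prior_desire"] == pytest.approx(p_d, abs=1e-12)

    def test_condition_means_monotone_over_seeds(self):
        # With the default CPTs the likelihood ratio rises with the condition,
        # so participant-mean judgments must be increasing, checked over seeds.
        for seed in range(20):
            design = ni.ExperimentDesign(experiment_id=1, n_participants=8, seed=seed)
            trials = ni.generate_experiment(design, ni.ObserverParams())
            means = (
                trials[trials["measure"] == "posterior_norm"]
                .groupby("condition")["value"]
                .mean()
                .reindex([1, 2, 3, 4])
            )
            assert means.is_monotonic_increasing


class TestAggregation:
    @pytest.mark.parametrize("values, expected", [([0.6] * 8, 0.6), ([0.5, 0.7], 0.6)])
    def test_cell_means(self, values, expected):
        rows = []
        for participant in (1, 2):
            for t, v in enumerate(values):
                rows.append((participant, 1, 1, t, "posterior_norm", v))
        trials = pd.DataFrame(rows, columns=ni.observers.TRIAL_COLUMNS)
        agg = ni.aggregate_by_condition(trials)
        np.testing.assert_allclose(agg["mean_value"], expected)

    def test_full_exp1_table_has_32x4_cells(self, exp1_tables):
        trials, per_pc = exp1_tables
        agg = ni.aggregate_by_condition(trials)
        counts = agg.groupby("measure").size()
        assert (counts == 32 * 4).all()
        assert len(per_pc) == 32 * 4

    def test_missing_cells_reported(self):
        trials = pd.DataFrame(
            [
                (1, 1, 1, 1, "posterior_norm", 0.5),
                (1, 1, 2, 2, "posterior_norm", 0.6),
                (2, 1, 1, 1, "posterior_norm", 0.4),
                # participant 2 lacks condition 2 entirely for this measure
                (2, 1, 2, 2, "prior_norm", 0.5),
                (1, 1, 1, 1, "prior_norm", 0.5),
                (1, 1, 2, 2, "prior_norm", 0.5),
                (2, 1, 1, 1, "prior_norm", 0.5),
            ],
            columns=ni.observers.TRIAL_COLUMNS,
        )
        with pytest.raises(ValueError, match="incomplete"):
            ni.aggregate_by_condition(trials)
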