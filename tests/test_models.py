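"""Cognitive-model unit and property tests.

Every network posterior is checked against an independent brute-force oracle
that builds the eight-cell joint from first principles, and the hand-derived
example values are frozen from direct evaluation of the formulas.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from norminfer.models import (
    MODEL_CPT_ENTRIES,
    DegenerateEvidenceError,
    NetworkSpec,
    bayes_posterior,
    desire_posterior,
    frequency_estimate,
    joint_table,
    kl_divergence,
    kl_update,
    network_posterior,
)

probs = st.floats(0.01, 0.99)


def brute_force_posterior(model, cpt, target, action=True):
    """Oracle: explicit joint built cell by cell, no shared code with joint_table."""
    total = {}
    for n, d, a in itertools.product([False, True], repeat=3):
        p = cpt["p_n"] if n else 1 - cpt["p_n"]
        if model == "IE":
            p *= cpt["p_d"] if d else 1 - cpt["p_d"]
        else:
            pd_ = cpt["p_d_given_n"] if n else cpt["p_d_given_notn"]
            p *= pd_ if d else 1 - pd_
        if model == "DM":
            pa = cpt["p_a_given_d"] if d else cpt["p_a_given_notd"]
        else:
            pa = cpt[f"p_a_given_{'n' if n else 'notn'}_{'d' if d else 'notd'}"]
        p *= pa if a else 1 - pa
        total[(n, d, a)] = p
    evid = sum(v for (n, d, a), v in total.items() if a == action)
    num = sum(
        v
        for (n, d, a), v in total.items()
        if a == action and (n if target == "n" else d)
    )
    return num / evid


class TestBayesPosterior:
    @pytest.mark.parametrize(
        "inputs, expected",
        [
            ((0.5, 0.8, 0.8), 0.5),        # uninformative likelihood
            ((1.0, 0.3, 0.9), 1.0),        # dogmatic prior (up to clipping)
            ((0.5, 0.9, 0.3), 0.75),       # 0.45 / 0.60 by hand
        ],
    )
    def test_hand_values(self, inputs, expected):
        assert bayes_posterior(inputs) == pytest.approx(expected, abs=1e-5)

    @given(p=probs, la=probs, lb=probs)
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_likelihoods(self, p, la, lb):
        base = bayes_posterior((p, la, lb))
        assert bayes_posterior((p, min(la + 0.01, 0.999), lb)) > base
        assert bayes_posterior((p, la, min(lb + 0.01, 0.999))) < base

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bayes_posterior((1.2, 0.5, 0.5))


class TestKlUpdate:
    def test_zero_when_equal(self):
        assert kl_update((0.7, 0.7)).d_kl == 0.0

    def test_hand_value(self):
        # 0.75 ln 1.5 + 0.25 ln 0.5
        assert kl_update((0.5, 0.75)).d_kl == pytest.approx(0.13081, abs=1e-5)

    def test_dogmatic_posterior_clipped_to_ln2(self):
        assert kl_update((0.5, 1.0)).d_kl == pytest.approx(np.log(2), abs=1e-4)

    @given(q=probs, delta=st.floats(0.0, 0.4))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_monotone_from_half(self, q, delta):
        assert kl_update((q, q)).d_kl == 0.0
        lo = kl_divergence(0.5, 0.5 + delta)
        hi = kl_divergence(0.5, min(0.5 + delta + 0.05, 0.999))
        assert 0.0 <= lo <= hi


class TestNetworkPosteriors:
    def test_ie_hand_value(self):
        spec = NetworkSpec(
            "IE",
            dict(
                p_n=0.5, p_d=0.5,
                p_a_given_n_d=0.9, p_a_given_n_notd=0.7,
                p_a_given_notn_d=0.6, p_a_given_notn_notd=0.1,
            ),
        )
        assert network_posterior(spec) == pytest.approx(0.8 / 1.15, abs=1e-12)

    def test_fc_hand_values(self):
        spec = NetworkSpec(
            "FC",
            dict(
                p_n=0.5, p_d_given_n=0.8, p_d_given_notn=0.3,
                p_a_given_n_d=0.9, p_a_given_n_notd=0.6,
                p_a_given_notn_d=0.7, p_a_given_notn_notd=0.1,
            ),
        )
        # P(A|N) = 0.84, P(A|notN) = 0.28 -> posterior 0.75
        assert network_posterior(spec) == pytest.approx(0.75, abs=1e-12)
        # P(D|A) = (0.5*0.8*0.9 + 0.5*0.3*0.7) / 0.56
        assert desire_posterior(spec) == pytest.approx(0.465 / 0.56, abs=1e-12)

    def test_dm_mediator_with_equal_desire_blocks_norm(self):
        spec = NetworkSpec(
            "DM",
            dict(p_n=0.37, p_d_given_n=0.6, p_d_given_notn=0.6,
                 p_a_given_d=0.9, p_a_given_notd=0.2),
        )
        assert network_posterior(spec) == pytest.approx(0.37, abs=1e-12)

    def test_dm_desire_hand_value(self):
        spec = NetworkSpec(
            "DM",
            dict(p_n=0.5, p_d_given_n=0.8, p_d_given_notn=0.3,
                 p_a_given_d=0.8, p_a_given_notd=0.1),
        )
        # P(D) = 0.55; P(D|A) = 0.44 / 0.485
        assert desire_posterior(spec) == pytest.approx(0.44 / 0.485, abs=1e-12)

    def test_ie_with_degenerate_desire_collapses_to_bayes(self):
        for p_d, row in [(1.0, "d"), (0.0, "notd")]:
            cpt = dict(
                p_n=0.4, p_d=p_d,
                p_a_given_n_d=0.85, p_a_given_n_notd=0.55,
                p_a_given_notn_d=0.35, p_a_given_notn_notd=0.15,
            )
            expected = bayes_posterior(
                (0.4, cpt[f"p_a_given_n_{row}"], cpt[f"p_a_given_notn_{row}"])
            )
            assert network_posterior(NetworkSpec("IE", cpt)) == pytest.approx(
                expected, abs=1e-9
            )

    def test_fc_with_desire_independent_action_equals_bayes(self):
        # P(D|N) = P(D|notN) and a D-independent action CPT reduce FC to Eq. 2.
        cpt = dict(
            p_n=0.45, p_d_given_n=0.6, p_d_given_notn=0.6,
            p_a_given_n_d=0.8, p_a_given_n_notd=0.8,
            p_a_given_notn_d=0.25, p_a_given_notn_notd=0.25,
        )
        assert network_posterior(NetworkSpec("FC", cpt)) == pytest.approx(
            bayes_posterior((0.45, 0.8, 0.25)), abs=1e-12
        )

    @pytest.mark.parametrize("model", ["IE", "FC", "DM"])
    @pytest.mark.parametrize("action", [True, False])
    def test_oracle_equivalence_random_cpts(self, model, action):
        rng = np.random.default_rng(hash((model, action)) % 2**31)
        for _ in range(200):
            cpt = {k: rng.uniform(0.02, 0.98) for k in MODEL_CPT_ENTRIES[model]}
            spec = NetworkSpec(model, cpt)
            assert network_posterior(spec, action) == pytest.approx(
                brute_force_posterior(model, cpt, "n", action), abs=1e-12
            )
            assert desire_posterior(spec, action) == pytest.approx(
                brute_force_posterior(model, cpt, "d", action), abs=1e-12
            )

    def test_missing_cpt_entry_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            NetworkSpec("IE", {"p_n": 0.5})

    def test_joint_sums_to_one(self):
        rng = np.random.default_rng(3)
        for model in MODEL_CPT_ENTRIES:
            cpt = {k: rng.uniform(0, 1) for k in MODEL_CPT_ENTRIES[model]}
            assert joint_table(NetworkSpec(model, cpt)).sum() == pytest.approx(1.0)

    def test_all_zero_joint_is_degenerate(self):
        spec = NetworkSpec(
            "DM",
            dict(p_n=0.5, p_d_given_n=0.5, p_d_given_notn=0.5,
                 p_a_given_d=0.0, p_a_given_notd=0.0),
        )
        with pytest.raises(DegenerateEvidenceError):
            network_posterior(spec, action_observed=True)


class TestFrequencyEstimate:
    @pytest.mark.parametrize("k, n, expected", [(4, 4, 1.0), (1, 4, 0.25), (0, 4, 0.0)])
    def test_proportions(self, k, n, expected):
        assert frequency_estimate(k, n) == expected

    def test_attainable_outputs_are_a_fixed_grid(self):
        # Over the 25/50/75/100% designs the model can only emit 4 values.
        outputs = {frequency_estimate(k, 4) for k in (1, 2, 3, 4)}
        assert outputs == {0.25, 0.5, 0.75, 1.0}

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            frequency_estimate(1, 0)
        with pytest.raises(ValueError):
            frequency_estimate(5, 4)
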