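"""Exact inference in the three causal networks over norm, desire and action.

IE: norms and desires independently cause actions (N -> A <- D).
FC: norms also shape desires (N -> D, N -> A, D -> A).
DM: norms act only through desires (N -> D -> A).
Each posterior is computed by enumeration over the eight-cell joint.
"""

from norminfer import NetworkSpec, desire_posterior, network_posterior

action_cpt = dict(
    p_a_given_n_d=0.9, p_a_given_n_notd=0.7,
    p_a_given_notn_d=0.6, p_a_given_notn_notd=0.1,
)

specs = {
    "IE": NetworkSpec("IE", dict(p_n=0.5, p_d=0.5, **action_cpt)),
    "FC": NetworkSpec("FC", dict(p_n=0.5, p_d_given_n=0.8, p_d_given_notn=0.3, **action_cpt)),
    "DM": NetworkSpec("DM", dict(p_n=0.5, p_d_given_n=0.8, p_d_given_notn=0.3,
                                 p_a_given_d=0.8, p_a_given_notd=0.1)),
}

print(f"{'model':5s} {'P(N|A)':>8s} {'P(D|A)':>8s}")
for name, spec in specs.items():
    print(f"{name:5s} {network_posterior(spec):8.4f} {desire_posterior(spec):8.4f}")
print()
print("After seeing the norm-consistent action, all three models raise the")
print("probability that a norm exists, but DM only transmits norm evidence")
print("through the desire node, so its norm posterior tracks P(D|A) closely.")
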