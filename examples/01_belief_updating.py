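"""Single Bayes update and KL-divergence belief updating.

An observer holds a prior that a group norm exists, elicits how likely the
observed behavior would be with and without a norm, and updates by Bayes'
rule; the size of the update is the KL divergence between the two-point
posterior and prior belief distributions (in nats).
"""

from norminfer import bayes_posterior, kl_update

prior = 0.5
p_behavior_given_norm = 0.9
p_behavior_given_no_norm = 0.3

post = bayes_posterior((prior, p_behavior_given_norm, p_behavior_given_no_norm))
dkl = kl_update((prior, post)).d_kl

print(f"prior P(N)              = {prior:.2f}")
print(f"posterior P(N|A)        = {post:.4f}")
print(f"belief update D_KL      = {dkl:.5f} nats")
print()
print("A posterior of 0.75 means the evidence (behavior 3x more likely under")
print("a norm) moves an undecided observer to 3:1 odds that the norm exists;")
print("0.131 nats is the corresponding amount of belief change.")
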