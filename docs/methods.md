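# Methods

## The inference problem

An observer watches a group of four agents; in each trial some number or
proportion of them exhibits a designated norm-consistent behavior.  The
observer judges, on a 0–100% slider, the probability that an injunctive
norm governs the group — once before the behavior is shown (the prior) and
once after (the posterior) — and also reports conditional probabilities
such as "how likely is this behavior if a norm exists?".  The scientific
question is which computation links those elicited inputs to the final
judgment.

Three experimental designs are supported: (1) 32 participants × 32 trials,
four conditions defined by the *number* of norm-consistent movers (1–4 of
4, the rest static); (2) 48 trials, conditions defined by the *proportion*
of norm-consistent movers (25/50/75/100%), the remainder behaving
deviantly; (3) as (2) with additional desire judgments and per-model
conditional-probability elicitations.

## Candidate models

- **Bayes update**: `P(N|A)` from the elicited prior and the two
  likelihoods (exact two-hypothesis Bayes rule).
- **IE / FC / DM causal networks** over norm `N`, desire `D`, action `A`
  with structures `N→A←D`, `{N→D, N→A, D→A}` and `N→D→A`.  Posteriors are
  computed by explicit enumeration of the eight-cell joint under each
  factorization — with three binary variables there is no reason to use
  approximate or message-passing inference, and enumeration is checked
  against an independently coded brute-force oracle to 1e−12 in the tests.
- **Frequency tracking**: the raw proportion `k/n` of norm-consistent
  movers, with no smoothing.  An unsmoothed proportion is the strictest
  form of a pure evidence-tally baseline: it integrates no prior and can
  only emit the fixed grid {0.25, 0.5, 0.75, 1.0} over these designs,
  which is exactly the coarseness the baseline is meant to exhibit.

Belief updating is quantified as `D_KL(posterior ‖ prior)` over the
two-point distributions, in nats (natural logarithm; "log" unqualified is
read as `ln`, the information-theoretic default).  Probabilities are
clipped to `[1e−6, 1 − 1e−6]` before logs and denominators, because the
slider permits exact 0%/100% answers that would otherwise produce
infinite divergences; with this clipping a dogmatic update from 0.5 to 1.0
yields ≈ ln 2 rather than ∞.

## Synthetic observers

Each simulated participant is a *noisy ideal observer* under a chosen
generating model:

1. the elicited prior is drawn around the true 0.5 (truncated normal on
   [0, 1], sd `sigma_prior`, default 0.05);
2. every elicited conditional probability is drawn around its true value
   (sd `sigma_elicit`, default 0.05), independently per trial, because the
   procedure elicits them within every trial;
3. the judgmental posterior is the generating model's posterior *computed
   from the observer's own elicited values*, plus truncated-normal response
   noise (sd `sigma_response`, default 0.05).

All reported values are snapped to the slider grid (step 0.01 — the
minimal faithful reading of a percent slider).  The defaults of 0.05 on
the probability scale are a conventional choice for slider noise in this
kind of simulation: large enough that model recovery is non-trivial,
small enough that condition effects of the size seen in the human data
survive aggregation over 8–12 trials.

The generating conditional probabilities are linear in the proportion `p`
of norm-consistent movers, e.g. for the Bayes generator in the deviant
designs `P(A|N) = 0.10 + 0.85p` and `P(A|¬N) = 0.75 − 0.55p`, chosen once
so that (a) the likelihood ratio — and hence the ideal posterior — rises
with the condition and (b) the noise-free posterior means (≈ 0.34 / 0.53 /
0.69 / 0.83) reproduce the qualitative pattern of the human condition
means, including a below-0.5 posterior when only a quarter of the group
complies.  The design-1 variant keeps all posteriors above 0.5, since no
deviant behavior is shown there.

For design 3 the truths of *every* elicited measure (the per-network CPT
entries and the two-variable likelihoods) are derived from the generating
network's joint at that condition, so a coherent observer underlies all
elicitations; each candidate network's entries are elicited with
independent noise, as separate slider questions would be.  Desire priors
and posteriors come from the generating network's `P(D)` and `P(D|A)`.

What the generator deliberately does not emulate: individual differences
in the generating CPTs, sequential (cross-trial) learning, anchoring or
response biases, and reaction times.  Passing recovery tests therefore
show that the *pipeline* identifies the generating computation under
realistic elicitation noise — not that human data are this clean.

## Hierarchical regression

The linking model is

    y_ij = (b0 + u0_j) + (b1 + u1_j) x_ij + e_ij,
    (u0_j, u1_j) ~ N(0, Σ_p),  e_ij ~ N(0, σ²),

with `x` the model-derived and `y` the judgmental posterior, averaged per
participant × condition.  Random intercept and slope are correlated.  The
robustness variant adds crossed random intercept/slope terms for the
condition, which is the stricter test under which a coarse predictor
(frequency tracking) loses its apparent precision.

Priors: Normal(0, 2.5) on intercept and slope (both variables live on
[0, 1], so this is weakly informative), half-Normal(0, 1) on all standard
deviations, Uniform(−1, 1) on correlations.

Sampling: the random effects are integrated out analytically — each
participant's 4-vector of responses is marginally multivariate normal — and
the remaining 6 (or 9) hyperparameters are sampled with an affine-invariant
ensemble sampler (emcee, differential-evolution moves), one independent
ensemble per chain, initialized in a small ball around the MAP found by
Nelder–Mead.  Sampling on (log sd, atanh ρ) with Jacobian corrections keeps
the geometry benign.  Each chain's draws are thinned to `iterations −
warmup` retained draws so the accounting matches the conventional
2-chain × 10⁴-iteration (2000 warmup) run; the test suite uses
2 × 2000 (500 warmup), which keeps one fit near three seconds on one CPU.
Convergence is monitored by split-R̂ per parameter; any value above 1.05
raises a `ConvergenceWarning` with the offending parameters rather than
passing silently.  The sampler is a means to an end: the contract is the
R̂ threshold, not the specific algorithm.

For every retained draw the random effects are then re-drawn *exactly*
from their Gaussian conditional given the hyperparameters and data, which
yields the per-observation log-likelihood matrix needed for LOO.  Reported
quantities: posterior-mean β, 95% equal-tailed CrI (HDI available),
Pr(β > 0), and δ_t = β / √(σ²_intercept + σ²_slope + σ²_residual) computed
per draw and averaged (the per-draw form was chosen over plugging in
posterior means; for well-identified fits the two agree to the second
decimal).

## Model comparison

Expected log predictive density under leave-one-out cross-validation is
estimated by Pareto-smoothed importance sampling (delegated to arviz, which
implements the standard tail-fraction recipe), reported as LOOIC =
−2·elpd_loo and ΔLOOIC relative to the best model; ties go to the
first-declared model so reports are deterministic.  Observations with
Pareto k > 0.7 are counted and exposed.  The tests validate PSIS against a
closed-form exact-LOO oracle on a conjugate normal-mean problem (every
leave-one-out predictive is available analytically), where the estimate
agrees to well under 0.5 elpd at 4000 draws.

## Frequentist layer

One-way repeated-measures ANOVA (pingouin's decomposition, cross-checked
in the tests against a first-principles sums-of-squares oracle) with
Greenhouse–Geisser correction applied when Mauchly's test rejects
sphericity at p < 0.05; partial η² = SS_effect/(SS_effect + SS_error);
corrected degrees of freedom ε(k−1) and ε(k−1)(n−1).  Post-hoc paired
t tests between adjacent conditions and one-sample t tests against 0.5
(probabilities) or 0 (KL divergences) are Bonferroni-corrected by
multiplying the raw p by the number of comparisons and capping at 1.00.

Cohen's d conventions: one-sample d = (mean − μ)/sd (= t/√n exactly);
paired d uses the *average of the two condition standard deviations* as
denominator rather than the difference-score sd — the latter is inflated
by within-participant correlation and is inconsistent with the magnitude
of published paired effect sizes in this paradigm.  Degenerate inputs are
errors, not infinities: a constant non-zero difference score or a
zero-variance sample raises, while exactly identical columns return
t = d = 0.

## Pipeline and reproducibility

`run_experiment` chains simulate → aggregate → descriptives → model
posteriors → regressions (both random-effect structures) → LOO comparison,
writing plain-CSV stage outputs, an `.npz` draws file per model (documented
columnar layout: one array per parameter, chains × draws, plus the
pointwise log-likelihood) and a JSON run log with seed and versions.  One
global seed fans out to per-stage seeds through `SeedSequence` spawn keys,
so stages are individually reproducible and mutually independent.  Trial
CSVs on either the 0–1 or 0–100 scale are accepted; the scale is detected
from the maximum value.

The package is library-shaped: the public functions plus the `examples/`
scripts are the interface, and no console entry point is installed.

## Known limitations

- The regression assumes Gaussian responses on the probability scale;
  judgments near the slider bounds are mildly censored, which the model
  ignores (as does the reference analysis style it follows).
- Exact enumeration is specific to the three-node binary networks; larger
  structures would need a general inference engine.
- The frequency baseline is within-trial; a cumulative cross-trial tally
  would require trial-order bookkeeping the designs do not vary.
- PSIS-LOO is computed on per-observation likelihoods conditional on the
  random effects (standard practice); leave-one-*participant*-out would
  require re-marginalization and is not implemented.
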