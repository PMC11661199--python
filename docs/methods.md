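# Methods

## Tasks and simulators

**Go/no-go.** Four fractal cues cross action (go / no-go) with valence
(win / avoid-loss); 160 interleaved trials, 40 per cue, no training phase.
Feedback is probabilistic: the "associated" (better) outcome of a cue's
pair follows a correct response 80% of the time. We schedule the
veridical/misleading flags as an exact 32-of-40 proportion per cue and
shuffle, rather than i.i.d. Bernoulli(0.8) draws, so design constants are
exact for every seed; an i.i.d. mode (`iid_feedback=True`) is available.
Win cues pay {+10, 0}, avoid cues {0, −10}. Presentation timings and
stimulus rendering are not modelled; the 1000 ms response window appears
only as an optional RT truncation bound in the simulator. Circle side is
recorded for data-format fidelity but has no effect on outcomes. Each
simulated subject-session gets its own seeded trial order.

**Ambiguous midpoint.** A 20-trial training phase (exactly 10 small, 10
large, seeded order) deterministically maps the small circle to the
low-reward key ($1) and the large circle to the high-reward key ($4). The
120-trial main phase presents 40 of each size; midpoint trials reward the
high key on exactly half of trials. One seeded order is shared by all
subjects within a session, as in the task itself.

**Agents.** Go/no-go agents draw choices from the model's p(go) and update
state from the realized feedback. Ambiguous-midpoint agents draw
(choice, RT) pairs from the Wiener first-passage distribution: the
midpoint drift is the subject's δ; trained sizes use drift ±3.0 toward the
trained key (a config constant chosen to give the near-ceiling accuracy
the deterministic mapping produces in practice), with the subject's own
boundary, bias and non-decision time. First-passage sampling is
rejection-free inverse-CDF sampling on a dense grid of the exact
first-passage density (0.2 ms spacing below 1 s of decision time, 1 ms
beyond; grid length set from the slowest eigenmode decay rate). The
sampler refuses to continue if more than 1e-4 of probability mass is
unaccounted for; tests confirm the sampled boundary fractions match the
closed-form absorption probabilities to < 0.005.

## Generating distributions

Subject-level parameters are drawn, per parameter, from a bivariate normal
across sessions on the unconstrained scale — probit scale for
unit-interval parameters (learning rate ε, lapse ξ, start bias β), log
scale for positive ones (sensitivities ρ, boundary α, non-decision time
τ), raw scale otherwise — with a configurable cross-session correlation
(default 0.7 for every parameter). Inducing the correlation on the
unconstrained scale matches the embedded model's assumption. Defaults
(see `defaults.py`, versioned) centre on values typical of published fits:
ε ≈ 0.21, b ≈ 0.3, Pavlovian biases ≈ 0.4, ρ ≈ 2.2, ξ ≈ 0.05; α ≈ 1.5,
β ≈ 0.5, δ ≈ 0.4 (SD 0.7), τ ≈ 0.33 s. They are configuration, not truth.
What the generator deliberately omits: non-responses and attentional
lapses in RT form, practice effects (session means are drawn from the same
group distribution), within-session drift of parameters, and any
questionnaire or demographic structure. Passing recovery and reliability
tests therefore show the pipeline is correct and well calibrated under the
models' own assumptions, not that real data satisfy those assumptions.

## Models

**Pavlovian-bias RL family.** Action weights
`W(go) = Q(go,s) + b + π_val·V(s)`, `W(nogo) = Q(nogo,s)`;
`p(go) = ξ/2 + (1−ξ)·logistic(W(go) − W(nogo))`. After feedback
r ∈ {−1, 0, +1} (points/10), the scaled outcome is `u = ρ_rew·r` for
rewards, `ρ_pun·r` for losses, and 0 for neutral feedback (no valence
scaling of zero outcomes); the taken action's Q and the stimulus V update
by `x += ε(u − x)`. The family ranges over five members from
(ε, ρ, ξ) to the winning 7-parameter model with split approach/avoid
biases and split sensitivities (`MODEL_FAMILY`). The "determinism"
parameter is the lapse ξ throughout; no inverse-temperature variant is
provided.

**Diffusion models.** The EZ estimator implements the closed form
with L = logit(Pc): `v = sign(Pc−½)·s·[L(L·Pc² − L·Pc + Pc − ½)/VRT]^¼`,
`a = s²L/v`, `Ter = MRT − (a/2v)·(1−e^(−va/s²))/(1+e^(−va/s²))`, scaling
constant s = 1 by default (0.1 available; reliability statistics are
scale-invariant). Degenerate accuracies are nudged half a trial (1/(2N))
off 0, ½ or 1 when edge correction is on, else raise. The 4-parameter
model evaluates the Wiener first-passage density by the standard dual
series (small-time and large-time expansions, switching by predicted
truncation effort, truncation error < 1e-10); the lower-boundary density
yields the upper by (δ, β) → (−δ, 1−β). Both fits use responded midpoint
trials with the high-reward key as the upper boundary, so positive drift
reads as optimism; p(upper) for δ≠0 is (1−e^(−2δαβ))/(1−e^(−2δα)).

## Hierarchical estimation

No probabilistic-programming backend is used; estimation is an in-package
adaptive Metropolis-within-Gibbs sampler (`hierarchical.py`). The
population model is normal on the unconstrained scale with priors
μ ~ N(0, 5²) and σ² ~ Inv-Gamma(1.5, 0.5). Each sweep combines:

* componentwise subject-level random walks (vectorised across subjects;
  per-coordinate step sizes adapt to 44% acceptance during warmup);
* a multivariate subject-level move along each subject's empirical
  posterior covariance (crosses within-subject trade-offs such as
  ε vs ρ);
* conjugate Gibbs draws of (μ_p, σ_p²);
* interweaving non-centred moves — translating μ_p together with all
  subject values, and rescaling deviations jointly with σ_p — which
  decouple group-level mixing from the subject-level random walk;
* a non-centred block move over all (μ, log σ) along their adapted joint
  covariance, crossing group-level ridges (e.g. lapse vs sensitivity).

Adaptation runs only during warmup (Robbins–Monro, diminishing rate).
Defaults: 2 chains, 400 warmup + 400 kept sweeps (heavier settings used
for the go/no-go recovery studies: 800 + 1000); convergence is summarised
by split-chain R̂ on group-level draws with a 1.05 reporting threshold;
non-converged fits are flagged and downstream consumers refuse them unless
forced. The engine's stationary distribution is verified by a
prior-recovery test (flat likelihood reproduces the priors). In the DDM
fit, τ carries a log map and draws with τ ≥ rt hit the density's numerical
floor (log 1e-300) rather than −∞, which keeps the support constraint
enforced without per-subject bounds. Model comparison uses WAIC on the
deviance scale (via arviz) computed from thinned pointwise log-likelihood
draws.

**Embedded two-session model.** Each parameter's subject-level pair is
bivariate normal across sessions with free per-session means and SDs
(practice effects allowed, so r is consistency-like) and correlation r_p
under a uniform prior — the LKJ(1) distribution restricted to a 2×2
block per parameter; we embed per-parameter blocks rather than one full
2P×2P matrix for identifiability at n = 58. The sampler adds a
re-correlation move: propose r′ and deterministically remap session-2
deviations so the whitened residuals are preserved; the prior ratio
cancels against the Jacobian, leaving only the session-2 likelihood and
the correlation prior, which makes r mix well (and exactly reproduces the
uniform prior under a flat likelihood — the marginal-equivalence test).

## Reliability statistics

Pearson r uses the t-transform p-value and Fisher-z 95% CI. ICCs come from
the two-way mean squares: ICC(C,1) = (MS_R−MS_E)/(MS_R+MS_E) and
ICC(A,1) = (MS_R−MS_E)/(MS_R+MS_E+(2/n)(MS_C−MS_E)) for k = 2, with
McGraw–Wong F-based intervals (Satterthwaite df for agreement) and the
psych/pingouin convention F = MS_R/MS_E for the test against zero —
cross-checked against pingouin and a brute-force ANOVA oracle to 1e-10.
Confidence level is fixed at 95%. No multiple-testing correction is
applied anywhere, matching the analysis this package implements. Band
labels: < 0.4 poor, 0.4–0.75 moderate-good, > 0.75 excellent. Excluded
subjects never enter reliability tables; pairs are complete-case per
measure.

**Transfer.** "Best-fitting parameters" are subject-level posterior means
on the native scale; the group-mean predictor is the arithmetic mean of
those (not the group hyper-mean). The DDM transfer likelihood uses the
choice probability only (marginal over RT) so the 0.5 chance baseline of
the t-tests is exact.

## Exclusion rules

A subject is removed if, in either session: go-to-win accuracy is zero; no
responses at all in a task; only one response key used in the
ambiguous-midpoint task; the high-reward key never chosen on responded
midpoint trials; or duplicate trial records exist. For go/no-go
accuracies a non-response counts as a no-go choice (the action space is
respond/withhold); p(high|mid) excludes non-responses from its denominator
and is flagged undefined (not 0) when nothing was responded.

## Problem sizes and numerical choices

Recovery and reliability studies run at the emulated study scale — 58
subjects, 160 go/no-go trials, 40 midpoint trials per session — with 2
chains per fit; the embedded coverage study uses 8 replicate cohorts, a
scale at which the pooled 95%-interval coverage estimate is informative
while the whole suite stays desk-sized. Ties and degenerate inputs:
undefined statistics (constant vectors, zero variance, no responded
trials) are returned as flagged NaN rather than 0; Pc edge handling in EZ
is logged; the Wiener sampler raises on unaccounted probability mass
rather than renormalising silently.

## Known limitations

* Reduced go/no-go family members are nested simplifications with a single
  learning rate; variants with multiple learning rates are not included.
* The diffusion model omits inter-trial variability parameters.
* The embedded model estimates per-parameter 2×2 correlation blocks, not
  the full cross-parameter matrix.
* The Metropolis-within-Gibbs sampler needs the interweaving moves to mix
  the weakly identified lapse parameter's group mean; occasional fits can
  still flag R̂ slightly above 1.05 and should be rerun with longer chains
  when that matters.
* Real-data ingestion is limited to the generic trials CSV schema.
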