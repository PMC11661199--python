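# affectbias

Test–retest reliability analysis of two computationally characterised
affective-bias tasks: an orthogonalized **go/no-go** task (Pavlovian bias in
approach/avoidance learning) and an **ambiguous-midpoint** task (optimistic
vs pessimistic interpretation of an ambiguous stimulus). The package is for
researchers who want to know how stable these tasks' measures are across
repeated sessions — the question that bounds their usefulness as endpoints
in randomized trials — and who want a fully simulated, end-to-end pipeline
to study that question under known ground truth.

## What it computes

For a two-session cohort (58 subjects by default, ≥2 weeks apart in the
emulated design):

1. **Task simulators** — exact trial schedules (160 go/no-go trials, 40 per
   cue, 80% veridical feedback; 20 training + 120 main ambiguous-midpoint
   trials, the midpoint rewarded 50/50) and generative agents playing them.
2. **Summary statistics** — per-cue accuracies and p(high|mid), with the
   study's participant-exclusion screens.
3. **Generative models** —
   * a Pavlovian-bias reinforcement-learning family for the go/no-go task;
     the winning 7-parameter model has action weights
     `W(go) = Q(go,s) + b + π_val·V(s)`, `W(nogo) = Q(nogo,s)` and choice
     rule `p(go) = ξ/2 + (1−ξ)·σ(W(go)−W(nogo))`, with delta-rule updates
     of `Q` and `V` on sensitivity-scaled outcomes (`ρ_rew`, `ρ_pun`);
   * both diffusion-model treatments of the ambiguous-midpoint task: the
     closed-form EZ estimator `(Pc, VRT, MRT) → (v, a, Ter)` and a
     4-parameter Wiener model `(α, β, δ, τ)` with the exact first-passage
     likelihood, the high-reward response coded as the upper boundary.
   Hierarchical Bayesian fits use an in-package adaptive
   Metropolis-within-Gibbs sampler with split-R̂ diagnostics.
4. **Reliability statistics** — Pearson r, ICC(A,1) and ICC(C,1) from the
   two-way ANOVA decomposition, with McGraw–Wong confidence intervals.
5. **Posterior-predictive transfer** — mean trialwise likelihood of one
   session's choices under the other session's parameters (chance = 0.5),
   with shrinkage checks against group-mean parameters.
6. **Embedded correlations** — a joint two-session model in which each
   parameter's subject-level pair is bivariate normal with a uniform prior
   on the cross-session correlation, yielding fully Bayesian reliability
   estimates that correct the attenuation of two-stage point-estimate
   correlations.

## Worked example

```python
from affectbias.synthetic_cohort import CohortConfig, simulate_cohort
from affectbias.summary_statistics import session_summaries
from affectbias.reliability import reliability_table

cohort = simulate_cohort(CohortConfig(task="gonogo", n_subjects=58,
                                      cross_session_r=0.7, seed=11))
summ = session_summaries(cohort)
tab = reliability_table(summ[summ.session == 1], summ[summ.session == 2],
                        measures=["acc_go_to_win", "acc_nogo_to_win"])
print(tab[["measure", "pearson_r", "icc_a1", "icc_c1", "band"]].round(3))
```

prints

```
           measure  pearson_r  icc_a1  icc_c1           band
0    acc_go_to_win      0.520   0.519   0.519  moderate-good
1  acc_nogo_to_win      0.569   0.572   0.568  moderate-good
```

i.e. with a generating cross-session parameter correlation of 0.7, the
observed accuracy summaries retest at r ≈ 0.52–0.57 — the behavioural summaries
are noisy readouts of the latent parameters, so their reliability sits
below the latent correlation. Fitting the generative models and embedding
the correlation inside the joint model (`affectbias.embedded_reliability`)
recovers estimates near the generating 0.7.

The same pipeline is scriptable from the shell:

```bash
affectbias simulate --task gonogo --n-subjects 58 --seed 11 --out trials.csv
affectbias summarise --trials trials.csv --out summaries.csv
affectbias pipeline --seed 11 --out runs/demo
```

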