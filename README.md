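# riskychoice

Prospect-theory modelling of risky choice on the 169-mixed-gambles task,
built for within-subject drug-manipulation studies (e.g. dopaminergic
medication ON/OFF designs in Parkinson's disease, with and without
depression).  The package covers the complete analysis path: task design,
choice model, hierarchical empirical-Bayes fitting, Bayesian model
comparison, behavioral exclusion screening, synthetic study cohorts, and
the group/correlation statistics battery — exposed as scikit-learn-style
estimators plus a small CLI.

## The model

Each trial offers a 50/50 gamble with a gain `G` (6–30 €, steps of 2) and a
loss `L` (3–15 €, steps of 1; 13 × 13 = 169 gambles per session).  Its
subjective utility is linear with loss aversion λ:

    SUG = 0.5·G − 0.5·L·λ

and the probability of accepting the gamble follows a biased softmax with
inverse temperature μ and a value-independent gambling bias c:

    p(accept) = 1 / (1 + exp(−(μ·SUG + c)))

λ > 1 means losses loom larger than gains; c > 0 is a tendency to gamble
regardless of value.  Parameters are bounded: λ, μ ∈ [0, 10], c ∈ [−10, 10].

Per subject-session parameters θₙ are estimated by hierarchical empirical
Bayes: every unit shares a diagonal normal prior N(Θ, Σ) whose moments are
iterated with the per-unit Laplace posteriors (MAP via box-constrained
L-BFGS-B with analytic gradients and Hessians) until convergence.  Model
variants (full vs. c ≡ 0) are compared by the negative log-model evidence

    NLME ≈ −Σₙ log P(Dₙ|θₙ) − Σₙ log N(θₙ|Θ,Σ) − ½mN·log 2π
           + ½Σₙ log|Hₙ| + m·log N

(lower is better; m free parameters per unit, N units, Hₙ the Hessian of
the negative log-posterior at θₙ).

## Worked example

```python
import riskychoice as rc

# a study-like synthetic cohort: 23 controls (one session),
# 22 + 21 patients tested ON and OFF
trials, clinical, truth = rc.generate_cohort(rc.CohortConfig(), seed=0)

# screen out non-utility-maximizers, then fit both model variants
kept = rc.UtilityMaximizerScreen().fit_transform(trials)
patients = kept[kept["group"] != "HC"]
full = rc.HierarchicalGambleModel(variant="full", seed=0).fit(patients)
reduced = rc.HierarchicalGambleModel(variant="no_bias", seed=0).fit(patients)
ev_f, ev_r = rc.evidence_for(full), rc.evidence_for(reduced)
print(round(ev_f.nlme, 1), round(ev_r.nlme, 1), rc.select_model(ev_f, ev_r))
print(full.prior_.mean.round(2))
```

prints

```
3455.2 3661.2 full
[ 1.44  1.   -1.08]
```

The full model wins the evidence comparison by ~206 NLME points — choices
in this cohort carry a real value-independent gambling bias — and the
estimated group means (λ ≈ 1.4, μ ≈ 1.0, c ≈ −1.1) recover the generating
distributions.  The whole pipeline (screen → fit → compare → metrics →
stats → report with a deterministic manifest) runs from a single call:

```bash
riskychoice run-all --out runs/demo --seed 0
```

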