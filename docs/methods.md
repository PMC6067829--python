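# Methods

## Choice model

A mixed gamble (gain `G`, loss magnitude `L`, both outcomes at probability
0.5) has subjective utility `SUG = 0.5·G − 0.5·L·λ` with a linear value
function and no probability weighting — a deliberate simplification that is
reasonable over the narrow 6–30 € / 3–15 € range of the task grid.
Acceptance probability is `p = logistic(μ·SUG + c)`.  The sign convention
places the gambling bias c additively on the logit, so c > 0 raises the
acceptance probability of every gamble; the reduced model variant
(`no_bias`) removes c from the model entirely rather than zeroing it after
fitting.

Parameters and bounds:

| parameter | meaning | bounds | typical value |
|---|---|---|---|
| λ | loss aversion (multiplicative weight on losses) | [0, 10] | ≈ 1–1.5 |
| μ | inverse temperature, 1/€ (choice consistency) | [0, 10] | ≈ 1 |
| c | value-independent gambling bias (logit offset) | [−10, 10] | ≈ −2–0 |

Probabilities are clamped to `[1e−12, 1 − 1e−12]` before logs; internal
likelihood code uses `log(1+e^z)` via `logaddexp` so saturated parameters
stay finite.

## Hierarchical empirical-Bayes fit

Each subject-session is one unit of the hierarchy, so ON and OFF
parameters of the same patient are separate draws from one shared diagonal
normal prior N(Θ, Σ).  The fit alternates:

1. **E-step** — per-unit MAP under the current prior, by L-BFGS-B with
   analytic gradient inside the box bounds; the unit posterior is
   approximated as normal with covariance `H⁻¹`, `H` the analytic Hessian
   of the negative log-posterior at the MAP.  Because the linear predictor
   is smooth in (λ, μ, c), the Hessian is available in closed form and is
   verified against central finite differences in the test suite.  At a
   box bound the analytic Hessian may be indefinite; eigenvalues are then
   floored at 1e−6 and the unit is flagged `at_boundary` (a Laplace
   approximation is not trustworthy there, and boundary units are surfaced
   by `screen_boundary` rather than silently used).
2. **M-step** — moment updates `Θ ← mean(θₙ)`,
   `Σ ← mean(θₙ² + diag(Hₙ⁻¹)) − Θ²`, floored elementwise at 1e−3.

Initialization: per-unit maximum likelihood under an effectively flat
prior (variance 1e6) with 5 seeded multi-starts, then 5%-trimmed moments
of those estimates.  Later E-steps warm-start each unit from its previous
MAP (plus the prior mean and one random start), which keeps iterations
cheap without changing the fixed point.  Convergence is declared when the
max absolute change of Θ and Σ drops below 1e−4 (cap 500 iterations);
non-convergence is flagged, never raised.

Two pooling strategies mirror the study design: `patients_only` (both
patient groups and both drug sessions under one prior, so group/session
contrasts cannot be artifacts of different regularization) and
`controls_plus_patients_per_session` (one fit per drug session, pooling
the controls' single session with that session's patients).

The per-iteration trace logs the Laplace approximation of the summed
per-unit log evidence.  It rises steeply and then may dip at the 1e−3
scale near the fixed point: once the normal approximation enters the
M-step, exact EM monotonicity is no longer guaranteed.  The suite asserts
near-monotonicity (no step loses more than 1% of the total rise) and that
the update deltas contract.

## Model evidence

`NLME = −Σ log P(Dₙ|θₙ) − Σ log N(θₙ|Θ,Σ) − ½mN log 2π + ½Σ log|Hₙ| + m log N`,
with the last term a BIC-style penalty for the 2m group parameters.  The
prior density is evaluated in native parameter space with the same
diagonal-normal object used during fitting.  Ties in model selection go to
the reduced model (parsimony).  On synthetic cohorts the comparison
recovers the generating model: cohorts with a real bias (|c| ≥ 2) select
the full model, bias-free cohorts select the reduced one.

## Exclusion screen

The utility-maximizer screen refits each session by maximum likelihood
with μ free in [−10, 10].  Verdicts:

* **inverted** — ML μ < 0 together with a significantly negative
  acceptance-versus-gain trend (the subject systematically prefers worse
  gambles);
* **random** — |ML μ| < 0.15, acceptance rate within [0.35, 0.65], and no
  significant gain or loss trend (Pearson trend tests, two-sided
  α = 0.05).  The μ gate sits at ≈3 standard errors of the sampling noise
  of the ML inverse temperature under truly random choice at 169 trials
  (SE ≈ 0.045); a tighter gate would miss genuine random responders purely
  through estimation noise.  The residual miss rate of the screen
  (~5–10%) is dominated by the α = 0.05 trend tests, which a random
  responder fails by chance in ≈1 − 0.95² of sessions;
* otherwise **include**.  All-accept/all-reject sessions are included
  with a degenerate-data warning since trends are undefined.

One excluded session removes the subject entirely, matching the study's
practice.  A false-exclusion control keeps well-behaved simulated agents
≥ 99% of the time.

## Behavioral metrics

Acceptance proportion per stratum, and loss-sensitivity curves: per loss
magnitude (gains pooled), `log((R + 0.5)/(A + 0.5))` with the
Haldane–Anscombe correction, against loss centered on the grid midpoint
(9 €); the least-squares slope of that curve rises with true λ.  The
per-level pooling (rather than a pairwise trial-difference construction)
is this package's pinned interpretation of "gains averaged out".

## Synthetic cohorts

The generator emulates the study design: 23 controls tested once, 22
nondepressed and 21 depression-history patients tested ON and OFF, 169
gambles per session, counterbalanced session order.  Defaults:

* λ ~ TruncNormal(1.3, 0.6²) on [0, 10]; μ ~ TruncNormal(1.0, 0.4²),
  constant within subject across sessions.
* c_OFF ~ Normal(m_g, 1.5²) clipped to [−10, 10], with per-group means
  m_g = −0.65 (controls), −2.0 (nondepressed PD), −1.7 (depression
  history), matching the reported OFF-session medians; ON adds a drug
  shift of +1.7 (nondepressed) or +0.4 (depression history) plus
  session noise (SD 0.5).
* BDI (OFF) per group: 3.1 (2.1), 4.0 (2.3), 9.9 (6.1), integer, floored
  at 0.  The ON score subtracts an improvement with group mean 0 / 2.0,
  slope 0.5 per OFF-BDI point above the group mean, and residual SD
  2.0 / 2.5 — patients with worse OFF-state depression improve more ON
  medication.
* Drug effect on λ: Δλ = −0.04·(BDI_OFF − group mean) + noise (SD 0.40).
  These two constants are the generator's causal coupling; with the
  group BDI spreads above they put the pooled Spearman correlation
  between OFF-state BDI and Δλ in the −0.3 to −0.4 regime and make the
  Δλ–ΔBDI correlation strong in the depression-history group and weak in
  the nondepressed group, i.e. the qualitative pattern the analysis is
  meant to detect, emerging from group differences in BDI variance
  rather than from separate per-group switches.

What the generator does **not** emulate: within-session learning or
fatigue (gambles are unresolved by design), response times, LED
pharmacokinetics, ICD symptom dynamics, antidepressant effects, and any
non-normal shape of the true parameter distributions.  Passing recovery
tests therefore show that the estimation machinery is correct under the
model's own assumptions — not that real patients satisfy them.

## Statistics battery

Shapiro–Wilk at α = 0.05 routes measures to parametric or nonparametric
branches.  Wilcoxon signed-rank (zero differences dropped; exact
enumeration up to n = 25 when tie-free, else continuity-corrected normal
approximation) for within-subject contrasts; Mann–Whitney U (same
exact/asymptotic policy) between groups; the Group × Drug interaction for
nonnormal parameters is computed as U on paired difference scores.  Mixed
(split-plot) ANOVA via pingouin for normally distributed measures, tested
against a from-scratch sums-of-squares oracle.  Correlations report
two-tailed p from `t = r·√((n−2)/(1−r²))` for both Pearson and Spearman
(midranks) — the approximation that reproduces printed study values at
n = 21–43.  Two independent correlations are compared by Fisher r-to-z.
Medians carry bootstrap standard errors (SD of the median over 10⁵
with-replacement resamples by default; seeded, chunked).  No
multiple-comparison correction is applied, matching the study's reporting;
reports flag this.

## Problem sizes

The default pipeline and the acceptance script fit the full 66-subject
design (86 patient units per variant).  Recovery suites use 40-subject
cohorts over 10 seeds, model recovery 20-subject cohorts over 10 seeds,
and screening reliability 100 seeded contaminants — sizes at which the
Monte-Carlo error of each checked quantity is comfortably below its
acceptance margin.

## Known limitations

* The group prior is diagonal; parameter covariances (e.g. μ–c trade-off)
  are captured per unit by the Laplace covariance but not at the group
  level.
* Laplace evidence is a large-data approximation; with 169 trials per
  unit it is accurate, but for much shorter sessions the BIC-style group
  penalty would dominate incorrectly.
* The screen's trend tests use linear (Pearson) association on binary
  outcomes; this is the conventional, slightly conservative choice.
* Exact rank tests switch to asymptotics in the presence of ties;
  fitted continuous parameters essentially never tie, so the exact branch
  is exercised mainly by the small-sample oracle tests.
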