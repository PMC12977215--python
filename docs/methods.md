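# Methods

## Outcome definitions

**Ventilator-free days (VFD) at day 28.** Days alive and free of invasive
ventilation between randomization and day 28, counted only when the
unassisted period lasted at least 24 consecutive hours. Death within 28
days, or ventilation extending to or beyond the 28-day horizon, scores 0.
The day-counting convention is half-open: day *k* is the interval
[*k*, *k*+1) from randomization and counts only if entirely unassisted.
Two points are under-determined by the verbal definition and are explicit
options of `compute_vfd`:

* *Mid-course windows.* An extubation–reintubation gap of ≥ 24 h
  contributes its whole days by default (`count_mid_course_windows=True`);
  note that a patient still ventilated at the horizon scores 0 regardless,
  so mid-course credit only ever applies to patients liberated before
  day 28.
* *Minimum window.* The 24-hour qualifier applies to every unassisted
  window, terminal or mid-course (`min_window_days=1.0`).

Both the implementation and its test oracle (an independent hour-grid
day-marking routine) implement this convention; partial days never count.

## Hierarchical models

All three models share: fixed treatment effect θ, hospital random
intercepts b_h ~ Normal(0, τ²), τ ~ Half-Normal(0, 0.5) ("mild
between-hospital heterogeneity": prior median ≈ 0.34 on the
linear-predictor scale).

| outcome | likelihood | effect scale | benefit |
| --- | --- | --- | --- |
| VFD | proportional-odds cumulative logistic, P(Y ≥ k) = logit⁻¹(θ·I + b_h − α_k) | log-OR | θ > 0 |
| 28-day mortality | logistic | log-OR | θ < 0 |
| duration (survivors) | linear, Normal residuals | days | θ < 0 |

The ordinal model keeps all 29 VFD categories. Nuisance priors, unstated
in the protocol, are deliberately much wider than any treatment prior so
that the registry priors dominate inference on θ: Normal(0, 5) on
intercepts and on each ordered cut-point, Half-Normal(0, 5) on the
residual SD. Cut-points for categories unobserved in a dataset remain
identified through their prior.

Subgroup analyses fit the dichotomous-outcome (mortality) model with a
subgroup main effect and a treatment-by-subgroup interaction, using the
protocol cut-offs (BMI > 30, PaO₂/FiO₂ ≤ 200, LIPS ≥ 4, APACHE ≥ 86,
cardiac arrest, surgical admission, primary respiratory failure). Rows
with a missing subgroup covariate are dropped (complete-case), with a
logged count.

## Prior registry

Every σ is solved from its stated constraint rather than copied:

* symmetric coverage — σ = bound / z₀.₉₇₅ (neutral priors: ln 2/1.96 =
  0.354 → printed 0.35; 2/1.96 = 1.020 → 1.02);
* opposite-tail mass — σ = |μ| / z₀.₇₀ (0.7/0.524 = 1.335 → printed 1.34;
  0.4/0.524 = 0.763 → 0.76; 0.16/0.524 = 0.305 → 0.3);
* elicited 95% intervals — σ = (hi − lo)/2 / z₀.₉₇₅, with risk-difference
  bounds first mapped to log-ORs by logit differences against the control
  risk, and SMD values mapped to log-ORs by the logistic-distribution
  factor π/√3 (0.07 → 0.127 → printed 0.13).

Asymmetric elicited intervals are collapsed to half their full width;
this is the only reading that reproduces the printed mortality survey σ
of 0.075 (the exact minimal-σ solution on the asymmetric interval is
0.0744 — the registry records full-precision values beside the printed
ones, and the unit tests check both). Two published inconsistencies are
carried, not resolved silently: the survey VFD prior is Normal(0.13,
0.35) by derivation but printed as Normal(0, 0.6) in the protocol table
(the derivation is the default, the table value is stored as
`printed_alternative`); the optimistic mortality centre is ln 0.84 =
−0.174 by derivation but printed as −0.16 (the printed value is
operational).

## Decision rules

* Probability of benefit: posterior mass on the benefit side of zero;
  superiority at ≥ 0.975 (inclusive — the boundary case is unit-tested),
  with a secondary report at 0.95.
* ROPE: (−0.1, +0.1) on the log-OR scale, the protocol's literal
  statement; the exact bounds (ln 0.9, ln 1.1) are available via
  `DecisionThresholds(literal_log_rope=False)`. No ROPE is defined for
  the duration outcome; asking for one raises.
* Practical equivalence: the *entire* 95% CrI inside the ROPE — the
  strictest common rule; the fraction of CrI width inside the ROPE is also
  reported so laxer rules can be applied post hoc.
* Severe harm: tail mass beyond OR 0.75 (VFD) or 1.25 (mortality); the
  protocol names the thresholds but no probability gate, so the
  superiority gate (0.975) is reused symmetrically and the raw tail mass
  is always reported.
* CrIs are equal-tailed quantile intervals with numpy's linear
  interpolation rule.

Classification order is fixed: superior → practically equivalent →
severe-harm signal → indeterminate.

## Posterior computation

Inference uses ensemble MCMC (emcee): 90% differential-evolution moves,
10% stretch moves, over an unconstrained parameterization — non-centred
hospital effects (b = τ·z), τ = |u| with u ~ Normal(0, s) (exactly
Half-Normal marginally, avoiding both the boundary at zero and a
log-scale tail), log residual SD with its Half-Normal prior plus
Jacobian, and ordinal cut-points as a free first cut-point plus log-gaps.
The snooker variant of the differential-evolution move was excluded after
it produced measurably under-dispersed marginals on a Gaussian
calibration target; the retained move set reproduces unit variance to
within sampling error in 16 and 43 dimensions.

Each fit runs `n_chains` fully independent ensembles (2·d + 6 walkers,
over-dispersed initialization at the prior scale of θ, τ and z).
Defaults: 4 chains, 1500 warm-up steps, thinning 10, with at least 1500
retained post-warm-up raw steps per ensemble. Flattened draws are strided
evenly across the whole post-warm-up window — a tail-only window is
coherent with the ensemble's slow "breathing" mode and under-represents
posterior spread. Split-R̂ is computed across the independent ensembles
and bulk ESS from per-walker autocorrelation (arviz); the convergence
gate is R̂ ≤ 1.01 and ESS ≥ 400 on both θ and τ, and fits failing it
carry `converged: False` plus a `ConvergenceWarning`.

Integrated autocorrelation times are roughly 55 raw steps for the
logistic/linear models (d ≈ 16) and 100–125 for the ordinal model
(d = 43), so the defaults give total ESS in the low thousands; a default
three-outcome fit takes on the order of 5–25 s on one CPU core.

## Synthetic trial generator

`simulate_trial` emulates the trial's structure: 969 patients, 13
hospitals (uniform assignment), 1:1 allocation by permutation, and three
outcome channels with independent hospital-effect vectors (the analysis
models treat hospitals independently per outcome, so the generator does
too).

* **Mortality** is drawn first from the hierarchical logistic model
  (baseline 0.42, default true OR 0.84 — the published arm rates 38.4%
  vs 42.0%).
* **VFD** follows a proportional-odds law on a frozen 29-cell baseline
  pmf whose zero cell (0.47) comprises deaths (0.42) plus ~5% ventilated
  beyond day 28, with survivor mass peaking at 23–27 days (short
  ventilation courses dominate in a non-ARDS population). Decedents are
  forced to VFD 0; survivors draw from the death-depleted conditional
  pmf, so the *marginal* VFD distribution is exactly the configured
  proportional-odds law whenever the per-patient zero cell exceeds the
  death probability (violations are floored and are rare at τ = 0.25).
  The default treatment shift is −0.18 on the cumulative log-odds,
  reproducing the published one-day deficit in mean VFD for lower PEEP.
* **Duration among survivors** is log-normal (median 3 days, log-scale SD
  0.8 — right-skewed, as observed ventilation durations are) plus an
  additive arm shift (default +0.4 days) and an additive hospital effect,
  floored just above zero. The additive shift makes the mean difference
  the exact estimand of the (misspecified-by-design) Normal-residual
  linear model.

One caveat is worth stating: the published arm-level summaries "mean VFD
17.7 vs 16.7" and "mortality 38.4% vs 42.0%" are jointly unattainable
under the zero-VFD-on-death rule (with 42% zeros the mean cannot exceed
28 × 0.58 = 16.2), so the generator anchors the mortality rates exactly
and yields arm means near 13–14 VFD; the one-day *difference* between
arms is preserved. Tests therefore check the mortality anchors sharply
and the VFD channel through its odds-ratio structure, not through those
published means.

What the generator does *not* emulate: correlation between a patient's
VFD and their ventilation duration (channels are conditionally
independent given arm and hospital), informative missingness (synthetic
outcomes are complete), non-proportional odds, and any time-varying
ventilation course beyond what `compute_vfd` consumes. Passing tests
demonstrate correct recovery of the generating model's parameters, not
robustness to these real-data features.

Randomness is organized as named substreams spawned from one master seed
(hospital effects, assignment, mortality, VFD, duration, covariates), so
identical seeds give byte-identical output tables regardless of draw
order within a block.

## Validation design

* Exact kernels: each model's unnormalized log posterior is compared to a
  naive per-patient implementation at random parameter points (1e−8, up
  to a constant).
* Prior recovery: with all patients in one arm the likelihood carries no
  information on θ, so the posterior must equal the prior; all 12
  registry priors are checked with Monte-Carlo standard errors estimated
  from independent-chain replicates (t-calibrated at the 3σ level).
* Parameter recovery: 20 simulated trials at full size (n = 969, 13
  hospitals, τ = 0.25); 95% CrIs must cover the generating θ at least
  17/20 times per model.
* Generator fidelity: law-of-large-numbers checks at n = 200 000
  (empirical mortality OR within ±0.02 of truth; cumulative VFD ORs
  uniform over cut-points), exchangeability under the null, and a rank
  test that between-hospital spread grows with τ.
* Determinism: one master seed reproduces the full 12-cell result bundle
  exactly at the summary level; every pipeline output is hash-manifested.

Sampler settings in replicate-heavy tests are scaled down (2 chains,
shorter warm-up) relative to production defaults; the problem sizes used
are stated in each test.

## Known limitations

* Ensemble MCMC mixes more slowly than gradient-based samplers on the
  43-parameter ordinal model; the defaults spend most of their budget
  there. For repeated large-scale simulation studies a gradient-based
  backend would be preferable.
* The ROPE/severe-harm machinery is deliberately specific to the two
  log-OR outcomes; no thresholds are invented for the duration outcome.
* The proportional-odds assumption is imposed, not tested; no
  non-proportional alternative is provided.
* Subgroup interaction models exist for the dichotomous outcome only,
  matching the analysis plan's stated form.
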