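# Methods

## Generative model

Every simulated trial follows the equal-variance type-II signal detection
observer that the estimators assume, so parameter recovery is a well-posed
check of the estimation machinery rather than a robustness exercise.

**Type-I stage.** The stimulus class (S1/S2) is equiprobable. Decision
evidence is x₁ ~ Normal(±d′/2, 1); the response is "S2" iff x₁ > c. With
the default c = 0 the observer is unbiased; accuracy at d′ = 0 is 50% by
construction (2AFC chance).

**Type-II stage.** Confidence cannot be read off x₁ directly, because the
meta level may be noisier than the decision level. Instead a second evidence
sample x₂ ~ Normal(±meta-d′/2, 1) is drawn, truncated to the
response-consistent side of the rescaled criterion meta-c = (c/d′)·meta-d′,
and binned by 2(K−1) ordered cutpoints (K−1 below meta-c for "S1"
responses, K−1 above for "S2" responses) into K ordinal confidence levels.
When meta-d′ = d′ this is distributionally identical to re-binning x₁
itself (an ideal metacognitive observer, Mratio = 1); meta-d′ < d′ produces
confidence that discriminates correct from incorrect trials less well than
the decisions warrant. At d′ = 0 the relative criterion c/d′ is undefined
and the raw c is carried over; only the (irrelevant) confidence labels are
affected.

**Default cutpoints.** The simulator places cutpoints at equal quantiles of
the response-conditional evidence distribution, yielding roughly uniform
usage of the confidence scale. Real raters do not use scales uniformly;
recovered cutpoints are free parameters in both estimators, so this choice
affects realism of the marginal confidence distribution, not validity.

**Group structure.** For a T-task group, each subject's vector of log
Mratios is drawn from N(μ, Σ) with Σ = diag(σ)·ρ·diag(σ). Per-subject,
per-task d′ is Uniform(0.5, 2.5) — heterogeneity spanning the range of mean
sensitivities typically observed across 2AFC batteries of memory, executive
and perceptual tasks. Defaults mirror the target study design: 4 tasks × 40
trials, an 11-level (0–100% in steps of 10) confidence scale, group Mratio
0.8, σ_logM = 0.5, and a common cross-task correlation of 0.6. A supplied
ρ is validated (unit diagonal, |ρ| ≤ 1, symmetric, PSD with tolerance
1e−8) and rejected rather than repaired, since silent repair would corrupt
recovery ground truth.

**What the generator does not emulate.** Response omissions, lapses,
sequential dependencies, response-time structure, scale-use idiosyncrasies
(end-aversion, category collapse), task-specific difficulty structure, and
criterion drift. Passing recovery tests therefore demonstrates correctness
of the estimation chain under the model's own assumptions, not robustness
of the model to real behavioral data.

## Estimators

**Type-I d′.** Hits are "S2" responses to S2 stimuli (the signal label is
arbitrary in 2AFC). The default `loglinear` correction adds 0.5/1 to
numerators/denominators unconditionally — the standard rule, avoiding the
selection discontinuity of correcting only degenerate rates; `none` raises
on a 0/1 rate rather than returning ±inf.

**AUROC2.** Trapezoidal area under the type-II ROC traced by cumulating
confidence distributions of correct vs incorrect trials from the top level
down. Invariant to monotone relabelings of the scale (property-tested);
requires at least one correct and one incorrect trial.

**Maximum-likelihood meta-d′.** The type-1 criterion is fixed at its
empirical relative position c′ = c/d′ (scaled by meta-d′) — the convention
of the standard meta-d′ fitting framework; the alternative of
jointly sampling type-1 parameters is not implemented. Cutpoints are
parameterized as log gaps walking away from meta-c, so ordering holds by
construction and no constrained solver is needed. The objective is the
response-conditional multinomial log-likelihood; L-BFGS-B from three starts
(empirical-quantile cutpoints; meta-d′ at 0.5×, 1×, 1.5× of d̂′). A
+1/(2K) cell padding is applied only when some stimulus × response family
is empty. Degenerate inputs (a single confidence level used) are returned
as flagged fits with meta-d′ = 0 rather than silently optimized, since the
likelihood is flat there. The optimizer is validated against an exhaustive
meta-d′ grid (step 0.005) with nested cutpoint optimization.

For the sparse-cell regime of 40-trial data, MLE fits default to collapsing
the 11-level scale to K′ = 4 equal-width bins (configurable, including no
collapsing).

## Hierarchical model

Subject-level: the same type-II likelihood, with meta-d′ = exp(m_st)·d̂′
and d̂′, ĉ fixed at their per-subject-task point estimates. Cutpoint log
gaps get independent Normal(τ̂₀, 1) priors centred on the subject's
empirical response-conditional quantiles. Group level: m_s· ~ N(μ, Σ) with
the printed priors μ_t ~ N(0,1), σ_t ~ InvSqrtGamma(0.001, 0.001) (i.e.
σ⁻² ~ Gamma(0.001, 0.001)), ρ_ij ~ Uniform(−1,1) element-wise with
non-PSD states rejected. Note that at T ≥ 3 the PSD restriction truncates
the element-wise uniform prior, so single-ρ marginals are no longer exactly
uniform; the prior-predictive uniformity check is exact only at T = 2.

**The hierarchical path fits the full confidence scale** (no collapsing):
the multinomial likelihood handles empty cells without edge correction, and
collapsing measurably weakens identification of (σ, ρ) at 40 trials/task.

**Sampler.** Metropolis-within-Gibbs, vectorized across subjects (which are
conditionally independent given the group level):

- subject log-Mratios: per-task random-walk updates with per-subject
  adaptive scales (target acceptance 0.44), plus an independence refresh of
  whole subject vectors proposed from the current MVN prior and accepted on
  the likelihood ratio alone (the proposal cancels the prior term) — this
  keeps subject draws decorrelated when the likelihood is weak;
- cutpoint log gaps: joint per-task random walks (target 0.25);
- μ: exact conjugate Gibbs draw;
- log σ: centred random walk *and* a non-centred move that rescales the
  subject deviations together with σ (the MVN prior change cancels against
  the Jacobian, leaving prior × likelihood) — the second move breaks the
  funnel coupling between σ and the subject-level spread in low-information
  regimes;
- each ρ entry: random walk with a 10% mixture of independence
  Uniform(−1,1) proposals; proposals leaving (−1,1) or breaking positive
  definiteness (Cholesky test) are rejected.

Proposal scales adapt only during burn-in (every 25 iterations,
Robbins-Monro style), so the kept draws target the exact posterior. log σ
is hard-truncated to [−7, 3] as a numerical guard; the likelihood keeps the
posterior far from these bounds in practice. Chains are initialised
overdispersed (μ, log σ, ρ jittered; subject parameters around the prior
mean and empirical cutpoints).

With the likelihood disabled (`prior_only=True`) the model factorizes, so
the "fit" draws exact iid samples from the joint prior ancestrally — the
reference distribution for prior-predictive checks.

**Diagnostics.** R̂ is the classic Gelman–Rubin factor from between/within
chain variances (cross-checked against arviz in the tests), computed for
every group-level and subject-level parameter; a fit warns when any exceeds
1.1. HDIs are exact narrowest-window intervals over sorted draws (leftmost
tie-break). Library defaults are 3 chains × 10,000 kept draws after 1,000
burn-in; the simulation studies below use shorter, explicitly configured
chains.

**Degenerate type-1 estimates.** A subject-task d̂′ below 0.05 is floored
at 0.05 (with a warning) so that c′ = c/d̂′ stays finite; the
nonhierarchical analysis path instead excludes subjects with d̂′ < 0.10 in
any task, mirroring the asymmetric treatment in the target analysis design
(the hierarchical path keeps all subjects).

## Recovery study

For each replicate: simulate a group (default 2 tasks × 100 subjects,
Mratio 0.8, σ = 0.5, ρ = 0.6), then estimate ρ two ways — the hierarchical
posterior mean, and the Pearson correlation of per-subject MLE Mratios
after the d′ exclusion rule — at 40 and 400 trials/task. Fits whose
group-level R̂ exceeds 1.1 are rerun with doubled chains (up to twice,
seeded deterministically); the study aborts if more than 20% of fits remain
unconverged. The expected pattern, which the acceptance suite verifies over
10 replicates, is that hierarchical shrinkage gives a markedly smaller mean
absolute error at 40 trials (noisy MLEs attenuate the nonhierarchical
correlation toward zero) and that the gap largely closes at 400 trials.

## Frequentist layer

Paired t-tests (scipy), Cohen's dz = mean(diff)/sd(diff) = t/√n, Bonferroni
thresholds α/m, Pearson r with 95% Fisher-z intervals (tanh(atanh r ±
1.96/√(n−3))), and regression-influence screening of paired samples via the
y-on-x simple regression: leverage > 2(k+1)/n, |externally studentized
residual| > 3, Cook's distance > 4/n, reported per test and as a union.
Under a homogeneous Gaussian sample these screens fire at their nominal
base rates (leverage ≈ 8%, Cook's ≈ 5%, residual ≪ 1%); they are screening
heuristics, not hypothesis tests. Metacognitive bias is the raw mean
confidence level (percent scale) without subtracting task performance —
subtracting percent correct would presume raters anchor 0% confidence at
chance, which the scale semantics do not guarantee.

## Problem sizes used in the test and acceptance runs

Chosen as the package's standard desk-scale configurations: ideal-observer
calibration at 50 subjects × 400 trials (3 chains × 800 kept / 600
burn-in); correlation recovery at 100 subjects × 400 trials (2 × 800/600);
the recovery study at 100 subjects, 10 replicates, 2 × 1200/1000 with
doubling retries; oracle equivalence on 20 random 60-trial, 3-level tables.
Group-level posterior means are stable at these lengths (R̂ ≲ 1.1); the
library defaults remain available for final analyses.

## Known limitations

- Type-1 parameters are point estimates, not jointly sampled; their
  sampling noise propagates into log-Mratio estimates (visible as mild
  attenuation of recovered ρ at 40 trials/task).
- Equal-variance SDT only; no response-specific meta-d′, unequal-variance,
  or continuous-rating variants.
- The element-wise uniform prior on ρ with PSD rejection is faithful to the
  printed model but is not uniform over correlation *matrices* at T ≥ 3
  (an LKJ-style parameterization would change the prior and is deliberately
  not the default).
- The random-walk sampler needs thousands of iterations for well-mixed ρ
  chains at 40 trials/task; R̂ should always be inspected, and the recovery
  driver's automatic rerun-on-warning is the recommended pattern.
- The preregistered-style bias score (confidence minus percent correct) is
  intentionally not implemented; mean confidence level is the bias measure.
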