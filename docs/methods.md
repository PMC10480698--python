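# Methods

This note documents the statistical models, the samplers, the synthetic-data
generator and the numerical choices behind `metacog`, including the places
where the design was genuinely open and what the packaged defaults commit to.

## Data model and recoding

A survey response is a single choice on a 6-point scale that couples the
truth judgement and its confidence. The scale is recoded bijectively:
responses 1–3 map to "respond true" with confidence 3, 2, 1 and responses
4–6 to "respond false" with confidence 1, 2, 3. Only three confidence levels
are modelled; the 2 (stimulus truth) × 2 (judgement) × 3 (confidence) count
table per respondent × domain is the sufficient statistic for every
signal-detection quantity downstream. Respondents with incomplete statement
sets are retained (counts simply sum fewer trials); respondents are only
dropped from the *hierarchical* fit when an entire domain is missing
(complete-case, reported on the result object).

Internal consistency of a domain's item set is summarised by Cronbach's
α over the binary item-correctness matrix (judgement matches label,
confidence ignored), α = K/(K−1)·(1 − Σᵢ varᵢ / var_total), computed on
respondents with complete item sets and undefined (signalled) when the total
score has zero variance.

## Type-1 model

Equal-variance Gaussian SDT with the *true statement* class as signal.
Hit and false-alarm rates are computed after adding a padding constant of
1/(2·3) = 1/6 to each of the 12 cells — the convention of the reference
meta-d′ implementations for three confidence levels — which keeps the normal
quantiles finite for respondents with empty margins. The cost of this
convention is a known attenuation of extreme d′ estimates when trials are
few (visible in the synthetic runs as mean estimated d′ ≈ 1.51 for a
generating mean of 1.67 at 14 trials); the hierarchical model's joint mode
(below) avoids inheriting that attenuation.

## Meta-d′ likelihood and MLE

The response-conditional meta-d′ model: meta-level evidence is
N(±meta-d′/2, 1), the meta-level judgement boundary is the shifted criterion
c′ = c·(meta-d′/d′), and four confidence criteria flank c′ (two on each
side). The likelihood of the count table is multinomial over confidence
*conditional on* each (stimulus, judgement) cell, so the type-1 margins
carry no information about meta-d′.

The single-subject MLE optimises meta-d′ and the four criteria with
L-BFGS-B from ≥ 3 jittered starts, keeping the best optimum. Criteria are
parameterised as log-increments away from c′, so their ordering holds by
construction for any parameter vector. Numerical choices:

* meta-d′ is bounded to [0, 10]; a fit at the bound is flagged.
* When any of the 12 cells is zero, the padding constant is added to every
  cell for the likelihood; otherwise raw counts are used.
* When d′ ≤ 0.05 the M-ratio is reported as missing (`NaN`) rather than as
  an exploding ratio; the fit itself still returns meta-d′.
* Degenerate tables (all confidence mass on one level) are flagged.

## Hierarchical within-subject model

For subject i and domain j ∈ (science, covid):

* counts_ij ~ response-conditional meta-d′ likelihood with
  meta-d′_ij = exp(λ_ij)·d′_ij and free criteria (log-increment
  parameterisation, independent N(−0.7, 1) priors on the increments);
* (λ_i,science, λ_i,covid) ~ bivariate normal with means
  (μ − δ/2, μ + δ/2), SDs (σ_s, σ_c), correlation ρ;
* μ ~ N(0, 1), δ ~ N(0, 0.4), σ ~ HalfNormal(1), ρ ~ Uniform(−1, 1).

δ is the domain difference in log M-ratio. Its prior is deliberately
informative and is always reported alongside the Bayes factor, which is
computed with the Savage–Dickey density ratio
BF₁₀ = p_prior(δ=0)/p_posterior(δ=0). The posterior ordinate uses a normal
approximation to the δ draws with a Gaussian-KDE cross-check; a discrepancy
above 20% is flagged on the result, and a vanishing posterior ordinate
yields an explicit lower bound instead of a point value. The ρ parameter can
be pinned (`rho_fixed`) to recover the no-correlation variant or a
single-domain model.

### Type-1 parameters: joint estimation vs plug-in

The conventional hierarchical meta-d′ setup fixes each subject's (d′, c) at
its padded point estimate. With ~14 statements per domain those estimates
carry sampling noise of roughly ±0.7 in d′ and ±0.4 in c, and conditioning
the confidence likelihood on mismeasured type-1 parameters acts like an
errors-in-variables problem: in controlled simulation (homogeneous cohort,
true M-ratio 1.0, 14 items, N = 1500) the plug-in recovers a population
M-ratio of ≈ 0.78 — an attenuation of about 20%, roughly half attributable
to noise in d̂′ and half to noise in ĉ, and absent when the true values are
supplied. The package therefore defaults to **joint estimation**
(`type1="joint"`): subject-level d′ and c are free parameters informed by
the binomial type-1 margins of the same tables, with hierarchical priors
d′_ij ~ TruncNormal(m_dj, s_dj, >0) and c_ij ~ N(m_cj, s_cj) and weak
hyperpriors on the domain-level means and SDs. Joint mode removes the
attenuation (same simulation recovers ≈ 0.97–1.00) and is what the recovery
tests exercise. `type1="plugin"` retains the conventional two-step for
comparability with analyses that used it; the two modes agree as the number
of statements grows.

### Sampler

Adaptive Metropolis-within-Gibbs, exploiting the conditional independence of
subjects given population parameters:

* λ, criteria increments and (d′, c) are updated with vectorised
  element-wise Metropolis steps across all subjects simultaneously, with
  per-subject step sizes adapted during burn-in (targets 0.44 for scalar
  updates, 0.30 for blocks);
* (μ, δ) has an exact conjugate Gibbs draw given the λ matrix and Σ;
* one joint *translation move* proposes a shift of (μ, δ) together with all
  subject λ's. The population prior is invariant under this move, so it is
  accepted on the likelihood and (μ, δ) prior alone; without it the
  population means inherit the slow random walk of 2N coupled subject
  parameters (this was the dominant mixing failure at 14 items/domain);
* (σ_s, σ_c, ρ) moves jointly on (log σ, atanh ρ) with an extra ρ-only
  step, since ρ mixes slowest; ρ's effective sample size is the weakest
  diagnostic at desk scale and its R-hat commonly exceeds 1.01 in the
  reduced presets — a convergence warning is attached to the result rather
  than silently ignored.

Chain geometry presets: `PAPER_MCMC` mirrors the published configuration
(3 chains, 30k post-burn-in iterations, 5k burn-in, thinning 9 → 9999
retained draws); `TEST_MCMC` (2 × 3000/1200, thin 3) is the desk-scale
default. Split R-hat and ESS are computed with arviz for every population
parameter; any R-hat ≥ 1.01 attaches a warning to the posterior.

## Ordinal outcome models

One Bayesian multilevel cumulative-logit model per question:
P(Y ≤ k) = logistic(κ_k − η), η = Xβ + Σ_g u_g[group], with

* continuous predictors centred and scaled by 2 SD (slopes then comparable
  with binary dummies); the scaling record is stored for inverse transforms;
* β ~ N(0, 1); random-intercept SDs τ_g ~ HalfCauchy(0, 1);
* cut points carrying the push-forward of a flat Dirichlet on the baseline
  category probabilities: q_k = logistic(κ_k) is uniform on the ordered
  simplex, so log p(κ) = Σ_k [log q_k + log(1 − q_k)] on ascending κ;
* categorical covariates with more than two levels enter as random
  intercepts, with missing values forming an explicit `"missing"` level (no
  imputation).

The sampler updates β and κ in small adaptive blocks (κ via its first value
and log-increments) and each grouping factor's intercepts with one
vectorised element-wise Metropolis step (the levels of a factor partition
the observations). Divergence counts do not exist for a Metropolis sampler;
the fit records `divergences=None` and relies on R-hat/ESS.

Derived quantities:

* **Odds ratios**: with 2-SD scaling, exp(β/2) is the odds change per 1 SD
  and exp(β) per 2 SD (also the raw OR for a binary dummy).
* **Marginal effects**: category-probability curves over a natural-scale
  grid (M-ratio values pass through log and the stored scaling), other
  continuous predictors at their mean, dummies at reference, random
  intercepts at zero; the default grid spans the 5th–95th percentile of
  individual M-ratio estimates.
* **Pseudo-R²**: latent-variance (McKelvey–Zavoina-style) definition
  R² = Var(Xβ)/(Var(Xβ) + Σ_g τ_g² + π²/3), averaged over draws, with the
  random-intercept variance counted as unexplained. The definition is a
  recorded configuration choice; alternative conventions attribute the
  group variance differently and yield different values for the same fit.

The "control" analysis (adding the science-domain log M-ratio as an extra
predictor) is the same fit path with one more column; no special code.

## Synthetic-cohort generator

The generator is the literal inverse of the fitted models, so recovery tests
are unconfounded by model mismatch:

* subject (λ_s, λ_c) bivariate normal; d′ truncated-normal at 0; c normal —
  all per domain, defaults shaped on the published study (d′ means
  1.05/1.67, SDs 0.85/1.0; M-ratios 0.98/0.82, log-SD 0.4, ρ 0.6; c ~
  N(0, 0.4); N = 1689; 14 statements per domain, half true);
* type-2 criteria placed at fixed offsets (0.6, 1.2) from the shifted
  criterion — a deterministic rule, so the ground truth is explicit;
* each statement's judgement is sampled from the type-1 response
  probabilities and confidence from the *exact* conditional type-2
  distribution, then encoded to the 6-point scale;
* attitude outcomes follow the cumulative-logit model with the subject's
  true log M-ratio and d′ (2-SD scaled within the cohort), age/gender/
  affected covariates (normal and Bernoulli), and multinomial group
  assignments with normal random intercepts.

What the generator does **not** emulate: quota/panel sampling, item-content
semantics (statements are exchangeable within truth × domain), response
styles such as scale-end avoidance, and any dependence of attitudes on
unmodelled demographics. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to the ways real survey data violate them.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at reduced scale, chosen so
each check exercises the full estimation path while completing in minutes:
hierarchical recovery uses N = 200 cohorts with 14 items/domain over 10
replicates (2 × 3000/1200 chains); Bayes-factor null calibration uses the
same cohorts with equal domain means and single 2400-iteration chains;
ordinal recovery uses n = 2000 with 2 × 2000/1500 chains; the acceptance
script runs a 300-respondent cohort end to end. At these sizes the Bayes
factor for the study-shaped preset is near 1 — the published-scale evidence
for a domain difference requires the full N ≈ 1700 cohort, which the same
code runs with the `paper` presets.

## Known limitations

* Equal-variance SDT only; no unequal-variance or probit variants.
* The meta-d′ model constrains meta-d′ ≥ 0 via the exp-link; genuinely
  counter-informative confidence (meta-d′ < 0) is truncated at 0.
* ρ mixes slowly in the reduced MCMC presets; treat its interval estimates
  from desk-scale runs as indicative.
* Ordinal models assume proportional odds (no category-specific effects).
* Subject-level M-ratio point estimates fed to the ordinal stage are
  posterior means and hence shrunken; regression coefficients on them are
  attenuated relative to the generating values at small item counts. This
  mirrors the two-step design of the original analysis rather than a joint
  model of both stages.
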