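# metacog

Signal-detection analysis of **metacognitive efficiency** for truth-judgement
surveys: how well does a respondent's *confidence* track the *accuracy* of
their knowledge, and does that metacognitive insight predict their attitudes
and behaviour?

The package was built for two-domain knowledge surveys of the kind used to
study the COVID-19 "infodemic": each respondent judges a set of true/false
statements from two knowledge domains (general science vs COVID-19) on a
6-point combined scale (from "extremely confident this is true" to "extremely
confident this is false"), then answers ordinal questions about attitudes,
behaviours and vaccination intention.

## The model

**Type-1 sensitivity.** Judging a statement is modelled as equal-variance
Gaussian signal detection: d′ = z(HR) − z(FAR) measures the ability to
discriminate true from false statements, and c = −(z(HR) + z(FAR))/2 the bias
towards answering "true".

**Metacognitive efficiency.** Confidence ratings are modelled with the
response-conditional meta-d′ observer: meta-d′ is the type-1 sensitivity a
counterfactual observer would need to produce the observed confidence
distributions, with confidence criteria flanking the shifted criterion
c′ = c·(meta-d′/d′). The **M-ratio** = meta-d′/d′ is efficiency: 1 means
confidence is as informative as the judgements themselves; values below 1
mean information is lost between knowing and knowing-that-you-know.

**Hierarchical within-subject model.** Subject log M-ratios for the two
domains follow a bivariate normal population with means (μ − δ/2, μ + δ/2);
δ is the domain difference in log M-ratio and carries an informative normal
prior, so the Savage–Dickey density ratio at δ = 0 yields a Bayes factor for
a *difference in metacognitive efficiency between domains*. Estimation is by
an adaptive Metropolis-within-Gibbs sampler; subject-level d′ and c can be
estimated jointly (default) or fixed at plug-in estimates (the convention of
the standard hierarchical meta-d′ toolboxes). See `docs/methods.md`.

**Ordinal outcome models.** Each attitude/behaviour question is analysed
with a Bayesian multilevel cumulative-logit model,
P(Y ≤ k) = logistic(κ_k − Xβ − Σ_g u_g), with 2-SD-scaled continuous
predictors (log M-ratio, d′, age), standard-normal slope priors,
HalfCauchy(0,1) random-intercept SDs and a flat-Dirichlet-induced prior on
the cut points. Derived quantities: odds ratios per 1 or 2 SD,
marginal-effect curves over an M-ratio grid, and a latent-variance pseudo-R².

A **synthetic-cohort generator** (`metacog.cohort`) draws complete studies
from this exact generative process with known ground truth, so every stage is
validated by parameter recovery without any real data.

## Worked example

```python
import dataclasses
import numpy as np
from metacog import cohort, survey_io, sdt_core, hmeta

# a small synthetic study: 200 respondents, 14 statements per domain,
# true population M-ratio 1.0 (science) and 0.8 (covid)
cfg = cohort.CohortConfig(
    n_subjects=200,
    population=cohort.PopulationConfig(logm_mean=(0.0, float(np.log(0.8)))),
    seed=3)
responses, attitudes, truth = cohort.generate_cohort(cfg)

counts = survey_io.tabulate_counts(responses)
type1 = {k: sdt_core.estimate_type1(cc.counts) for k, cc in counts.items()}

spec = hmeta.HierModelSpec(
    mcmc=dataclasses.replace(hmeta.TEST_MCMC, seed=11))
post = hmeta.fit_hierarchical(counts, type1, spec)
for domain, s in post.mratio_summary().items():
    print(domain, round(s["mean"], 3),
          [round(s["hdi_low"], 2), round(s["hdi_high"], 2)])
print("BF10 =", round(hmeta.savage_dickey_bf(post, spec).bf10, 2))
```

prints (seed-exact):

```
science 1.064 [0.85, 1.3]
covid 0.854 [0.73, 0.98]
delta -0.216 [-0.46, 0.03]
BF10 = 1.37
```

Both 95% HDIs cover their generating values; the posterior domain difference
has the generating sign (covid below science), and at this small sample the
Bayes factor is still near 1 — evidence for the difference accumulates with
cohort size.

The same analysis runs end to end from a config:

```bash
metacog run-all --config config.yaml --out results/
metacog report --manifest results/manifest.json
```

which writes per-respondent SDT fits, the hierarchical summary with the
Bayes factor and its δ prior, per-question ordinal summaries (odds-ratio
table, pseudo-R², marginal-effect curves), the conspiracy-endorser exclusion
refit, and a markdown report.

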