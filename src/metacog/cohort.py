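"""Synthetic survey cohorts with a known metacognitive ground truth.

The generator produces a full synthetic study — truth-judgement responses on
the 6-point combined scale plus ordinal attitude outcomes — from an explicit
generative process that is the literal inverse of the models fitted elsewhere
in the package, so every pipeline stage has a parameter-recovery test without
any real data:

* per subject, log M-ratios for the two domains are drawn from a bivariate
  normal population; d' is truncated-normal (at 0) and the type-1 criterion
  normal, independently per domain;
* each statement's judgement is sampled from the type-1 SDT response
  probabilities, and confidence from the *exact* response-conditional type-2
  distribution implied by meta-d' = exp(log M-ratio) * d';
* attitude outcomes are sampled from a cumulative-logit model whose linear
  predictor combines the subject's (true) log M-ratio, d', continuous/binary
  covariates and group random intercepts, with continuous predictors on the
  2-standard-deviation scale used by the fitting code.

Tuple-valued population parameters are ordered (science, covid) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import sdt_core
from .survey_io import AttitudeTable, ResponseTable, decode_response

__all__ = [
    "PopulationConfig",
    "AttitudeModelConfig",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "paper_shape_preset",
    "sample_ordinal",
]

DOMAIN_ORDER = ("science", "covid")


@dataclass(frozen=True)
class PopulationConfig:
    """Population distributions for the SDT/metacognition process.

    All pairs are (science, covid).  ``criterion_offsets`` place the two
    type-2 criteria on each side at fixed distances from the shifted type-1
    criterion c', in evidence units.
    """

    dprime_mean: tuple = (1.05, 1.67)
    dprime_sd: tuple = (0.85, 1.0)
    logm_mean: tuple = (float(np.log(0.98)), float(np.log(0.82)))
    logm_sd: tuple = (0.4, 0.4)
    rho: float = 0.6
    c_mean: float = 0.0
    c_sd: float = 0.4
    criterion_offsets: tuple = (0.6, 1.2)


@dataclass(frozen=True)
class AttitudeModelConfig:
    """Ground-truth cumulative-logit model for one ordinal outcome.

    ``beta`` are slopes on the 2-SD scale (continuous) or for 0/1 dummies;
    recognised predictor names: ``log_mratio``, ``d_prime`` (covid-domain
    subject truth), ``age``, ``gender``, ``affected``.  ``cutpoint_probs``
    are the baseline category probabilities at linear predictor 0; ``groups``
    maps a grouping variable to (n_levels, intercept SD).
    """

    outcome: str = "vaccine_intent"
    categories: tuple = ("very_unlikely", "fairly_unlikely", "fairly_likely", "very_likely")
    beta: dict = field(default_factory=lambda: {
        "log_mratio": 0.8, "d_prime": 0.3, "age": 0.2, "gender": -0.1, "affected": 0.3,
    })
    cutpoint_probs: tuple = (0.08, 0.07, 0.12, 0.73)
    groups: dict = field(default_factory=lambda: {"region": (11, 0.25), "income": (10, 0.25)})
    age_mean: float = 48.0
    age_sd: float = 16.0
    p_gender: float = 0.5
    p_affected: float = 0.4


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 200
    items_per_domain: int = 14  # half true, half false
    population: PopulationConfig = field(default_factory=PopulationConfig)
    attitude_model: AttitudeModelConfig = field(default_factory=AttitudeModelConfig)
    seed: int = 0

    def __post_init__(self):
        if self.items_per_domain % 2:
            raise ValueError("items_per_domain must be even (half true, half false)")
        pop = self.population
        if not (-1.0 <= pop.rho <= 1.0):
            raise ValueError("|rho| must be <= 1")
        if any(s < 0 for s in (*pop.dprime_sd, *pop.logm_sd)):
            raise ValueError("population SDs must be nonnegative")
        if abs(sum(self.attitude_model.cutpoint_probs) - 1.0) > 1e-8:
            raise ValueError("cutpoint_probs must sum to 1")


@dataclass
class GroundTruth:
    """Everything needed to score a recovery test on a generated cohort."""

    subjects: pd.DataFrame      # per-subject d', c, log M-ratio per domain
    population: dict
    attitude: dict              # beta, kappa, tau and u per group
    config: CohortConfig
    conspiracy_statement_id: str = "covid_false_1"

    def to_json(self, path) -> None:
        payload = {
            "population": self.population,
            "attitude": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.attitude.items()
            },
            "config": asdict(self.config),
            "subjects": self.subjects.to_dict(orient="list"),
            "conspiracy_statement_id": self.conspiracy_statement_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _cutpoints_from_probs(probs) -> np.ndarray:
    cum = np.cumsum(probs)[:-1]
    return np.log(cum / (1.0 - cum))


def sample_ordinal(rng, eta: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Sample ordinal categories (0-based) from P(Y<=k) = logistic(kappa_k - eta)."""
    cum = 1.0 / (1.0 + np.exp(-(kappa[None, :] - eta[:, None])))
    cum = np.hstack([cum, np.ones((len(eta), 1))])
    u = rng.random(len(eta))
    return (u[:, None] > cum).sum(axis=1)


def _two_sd_scale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / (2.0 * sd)


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[ResponseTable, AttitudeTable, GroundTruth]:
    """Generate one synthetic study; all randomness flows from one seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop = config.population
    n, k_items = config.n_subjects, config.items_per_domain

    # subject-level parameters
    z = rng.standard_normal((n, 2))
    lam = np.empty((n, 2))
    lam[:, 0] = pop.logm_mean[0] + pop.logm_sd[0] * z[:, 0]
    lam[:, 1] = pop.logm_mean[1] + pop.logm_sd[1] * (
        pop.rho * z[:, 0] + np.sqrt(max(0.0, 1 - pop.rho ** 2)) * z[:, 1]
    )
    dprime = np.empty((n, 2))
    for j in range(2):
        a = (0.0 - pop.dprime_mean[j]) / max(pop.dprime_sd[j], 1e-12)
        dprime[:, j] = truncnorm.rvs(
            a, np.inf, loc=pop.dprime_mean[j], scale=pop.dprime_sd[j],
            size=n, random_state=rng,
        )
    dprime = np.maximum(dprime, 1e-3)
    crit_c = rng.normal(pop.c_mean, pop.c_sd, size=(n, 2))

    w1, w2 = pop.criterion_offsets
    rows = []
    for j, domain in enumerate(DOMAIN_ORDER):
        meta_d = np.exp(lam[:, j]) * dprime[:, j]
        cprime = crit_c[:, j] * meta_d / dprime[:, j]
        t2 = np.stack(
            [cprime - w2, cprime - w1, cprime + w1, cprime + w2], axis=-1
        )
        cell = sdt_core.type2_cell_probabilities(
            meta_d, type2_criteria=t2, c=crit_c[:, j], d_prime=dprime[:, j]
        )  # (n, 2, 2, 3)
        cond = sdt_core.type2_conditional_probs(cell)
        # type-1 response probabilities
        p_true_given = np.stack([
            sdt_core.ndtr(dprime[:, j] / 2.0 - crit_c[:, j]),
            sdt_core.ndtr(-dprime[:, j] / 2.0 - crit_c[:, j]),
        ], axis=1)  # (n, stimulus)
        for t in range(k_items):
            stim = 0 if t < k_items // 2 else 1  # first half true
            truth = "true_statement" if stim == 0 else "false_statement"
            sid = f"{domain}_{'true' if stim == 0 else 'false'}_{t % (k_items // 2) + 1}"
            judge = (rng.random(n) >= p_true_given[:, stim]).astype(int)
            pc = cond[np.arange(n), stim, judge, :]  # (n, 3)
            cum = np.cumsum(pc, axis=1)
            conf = (rng.random(n)[:, None] > cum).sum(axis=1) + 1
            raw = np.array([
                decode_response("respond_true" if jj == 0 else "respond_false", cc)
                for jj, cc in zip(judge, conf)
            ])
            rows.append(pd.DataFrame({
                "respondent_id": np.arange(n),
                "statement_id": sid,
                "domain": domain,
                "truth": truth,
                "raw_response": raw,
            }))
    resp_df = pd.concat(rows, ignore_index=True)
    resp_df = resp_df.sort_values(["respondent_id", "domain", "statement_id"],
                                  kind="stable").reset_index(drop=True)
    responses = ResponseTable(df=resp_df)

    # attitude outcomes from the ground-truth ordinal model
    am = config.attitude_model
    kappa = _cutpoints_from_probs(am.cutpoint_probs)
    age = rng.normal(am.age_mean, am.age_sd, n)
    gender = rng.binomial(1, am.p_gender, n)
    affected = rng.binomial(1, am.p_affected, n)
    continuous = {
        "log_mratio": lam[:, 1],
        "d_prime": dprime[:, 1],
        "age": age,
    }
    binary = {"gender": gender, "affected": affected}
    eta = np.zeros(n)
    for name, beta in am.beta.items():
        if name in continuous:
            eta += beta * _two_sd_scale(continuous[name])
        elif name in binary:
            eta += beta * binary[name]
        else:
            raise ValueError(f"unknown attitude predictor {name!r}")
    group_assign, group_u = {}, {}
    for gname, (n_levels, tau) in am.groups.items():
        u = rng.normal(0.0, tau, n_levels)
        levels = rng.integers(0, n_levels, n)
        eta += u[levels]
        group_assign[gname] = levels
        group_u[gname] = u
    y = sample_ordinal(rng, eta, kappa)

    att_df = pd.DataFrame({
        "respondent_id": np.arange(n),
        am.outcome: np.asarray(am.categories, dtype=object)[y],
        "age": age, "gender": gender, "affected": affected,
    })
    for gname, levels in group_assign.items():
        att_df[gname] = pd.Series(levels).map(lambda i: f"{gname}_{i}")
    attitudes = AttitudeTable(
        df=att_df,
        outcomes={am.outcome: list(am.categories)},
        group_vars=list(am.groups),
    )

    subjects = pd.DataFrame({
        "respondent_id": np.arange(n),
        "d_prime_science": dprime[:, 0], "d_prime_covid": dprime[:, 1],
        "c_science": crit_c[:, 0], "c_covid": crit_c[:, 1],
        "log_mratio_science": lam[:, 0], "log_mratio_covid": lam[:, 1],
    })
    truth = GroundTruth(
        subjects=subjects,
        population={
            "logm_mean": list(pop.logm_mean), "logm_sd": list(pop.logm_sd),
            "rho": pop.rho, "dprime_mean": list(pop.dprime_mean),
            "dprime_sd": list(pop.dprime_sd),
            "delta": pop.logm_mean[1] - pop.logm_mean[0],
        },
        attitude={
            "beta": dict(am.beta), "kappa": kappa,
            "tau": {g: am.groups[g][1] for g in am.groups},
            "u": {g: group_u[g].tolist() for g in am.groups},
        },
        config=config,
    )
    return responses, attitudes, truth


def paper_shape_preset(n_subjects: int = 1689, seed: int = 0) -> CohortConfig:
    """A cohort config mimicking the published study's shape.

    1689 respondents, 14 statements per domain (half true), mean d' 1.05
    (science) and 1.67 (covid), population M-ratios 0.98 and 0.82.
    """
    return CohortConfig(n_subjects=n_subjects, items_per_domain=14, seed=seed)
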