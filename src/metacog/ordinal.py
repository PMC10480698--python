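"""Bayesian multilevel cumulative-logit (ordered logit) regression.

One model per ordinal outcome question:

    P(Y_n <= k) = logistic(kappa_k - eta_n),
    eta_n = x_n' beta + sum_g u_g[group_g(n)]

with ascending cut points kappa.  Priors follow a regularising convention for
survey regression: standard-normal slopes, HalfCauchy(0, 1) random-intercept
SDs, and cut points carrying the push-forward of a flat Dirichlet prior on the
baseline category probabilities (at eta = 0).  Continuous predictors are
centred and scaled by two standard deviations so their slopes are comparable
with binary dummies.

Estimation uses an adaptive Metropolis-within-Gibbs sampler: slopes and cut
points move in small adaptive blocks, and the random intercepts of each
grouping factor are updated with a single vectorised element-wise Metropolis
step (levels of one factor partition the observations, so they are
conditionally independent).  Derived quantities: odds ratios per 1 or 2 SD,
marginal-effect curves over a natural-scale predictor grid, and a
latent-variance pseudo-R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az
from scipy.special import expit

from .hmeta import MCMCConfig

__all__ = [
    "OrdinalModelSpec",
    "OrdinalFit",
    "ScalingRecord",
    "scale_predictors",
    "fit_ordinal",
    "odds_ratio",
    "marginal_effects",
    "pseudo_r2",
    "ORDINAL_TEST_MCMC",
    "ORDINAL_PAPER_MCMC",
]

#: The published run length for the ordinal models: 4 chains x 4k (2k burn-in).
ORDINAL_PAPER_MCMC = MCMCConfig(chains=4, samples=2000, burn=2000, thin=1)
ORDINAL_TEST_MCMC = MCMCConfig(chains=2, samples=1500, burn=1000, thin=1)


@dataclass(frozen=True)
class ScalingRecord:
    """Per-column (mean, sd) used for the 2-SD standardisation."""

    stats: dict  # name -> (mean, sd)

    def transform(self, name: str, x):
        m, s = self.stats[name]
        return (np.asarray(x, dtype=float) - m) / (2.0 * s)


@dataclass(frozen=True)
class OrdinalModelSpec:
    """Specification of one cumulative-logit model.

    ``fixed_effects`` name numeric columns of the design (continuous ones
    listed in ``scale_2sd`` get the 2-SD standardisation); ``random_groups``
    name categorical columns entering as random intercepts.
    """

    outcome: str
    categories: tuple
    fixed_effects: tuple = ()
    random_groups: tuple = ()
    scale_2sd: tuple = ()
    prior_slope_sd: float = 1.0
    prior_tau_scale: float = 1.0   # HalfCauchy(0, scale)
    mcmc: MCMCConfig = field(default_factory=lambda: ORDINAL_TEST_MCMC)

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError("need >= 2 outcome categories")
        unknown = set(self.scale_2sd) - set(self.fixed_effects)
        if unknown:
            raise ValueError(f"scale_2sd names not in fixed_effects: {unknown}")


def scale_predictors(df: pd.DataFrame, continuous) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre the named columns and divide by 2 SD; returns the scaling record."""
    out = df.copy()
    stats = {}
    for name in continuous:
        x = pd.to_numeric(out[name], errors="raise").to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {name!r} has zero standard deviation")
        stats[name] = (float(x.mean()), float(sd))
        out[name] = (x - x.mean()) / (2.0 * sd)
    return out, ScalingRecord(stats=stats)


@dataclass
class OrdinalFit:
    """Posterior draws and bookkeeping for one fitted ordinal model.

    ``draws`` holds ``beta`` (chains, draws, p), ``kappa`` (chains, draws,
    K-1), per-group ``tau_<g>`` (chains, draws) and ``u_<g>`` (chains, draws,
    levels).  ``eta_var`` is the per-draw variance of the fixed-effect linear
    predictor over the estimation sample, used by :func:`pseudo_r2`.
    """

    spec: OrdinalModelSpec
    draws: dict
    feature_names: tuple
    group_levels: dict
    scaling: ScalingRecord
    eta_var: np.ndarray
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    divergences: int | None = None  # not defined for a Metropolis sampler

    def flat(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def beta_draws(self, predictor: str) -> np.ndarray:
        try:
            j = self.feature_names.index(predictor)
        except ValueError:
            raise LookupError(f"unknown predictor {predictor!r}") from None
        return self.flat("beta")[:, j]


def _ordinal_loglik(y, eta, kappa):
    """Per-observation log-likelihood; y is 0-based, kappa ascending."""
    K = len(kappa) + 1
    kpad = np.concatenate([[-np.inf], kappa, [np.inf]])
    upper = expit(kpad[y + 1] - eta)
    lower = expit(kpad[y] - eta)
    return np.log(np.clip(upper - lower, 1e-300, None))


def _kappa_logprior(kappa):
    """Flat Dirichlet on baseline category probabilities, pushed to kappa.

    A flat Dirichlet on p is uniform over the ordered vector q_k = logistic
    (kappa_k); the change of variables contributes sum_k log q_k(1 - q_k).
    """
    if np.any(np.diff(kappa) <= 0):
        return -np.inf
    q = expit(kappa)
    return float(np.sum(np.log(q) + np.log1p(-q)))


def _halfcauchy_logpdf(tau, scale):
    if tau <= 0:
        return -np.inf
    return float(-np.log1p((tau / scale) ** 2) - np.log(scale))


def _design(spec: OrdinalModelSpec, data: pd.DataFrame):
    df = data.dropna(subset=[spec.outcome]).copy()
    cat_index = {cat: k for k, cat in enumerate(spec.categories)}
    y = df[spec.outcome].map(cat_index)
    if y.isna().any():
        raise ValueError("outcome contains undeclared categories")
    y = y.to_numpy(dtype=int)
    X = df.loc[:, list(spec.fixed_effects)].to_numpy(dtype=float) \
        if spec.fixed_effects else np.zeros((len(df), 0))
    groups = {}
    for g in spec.random_groups:
        levels = sorted(df[g].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"random group {g!r} has < 2 levels")
        idx = df[g].astype(str).map({lv: i for i, lv in enumerate(levels)})
        groups[g] = (idx.to_numpy(dtype=int), levels)
    return y, X, groups


def _run_ordinal_chain(y, X, groups, spec, seed):
    rng = np.random.default_rng(seed)
    n, p = X.shape
    K = len(spec.categories)
    mcfg = spec.mcmc

    beta = rng.normal(0, 0.1, p)
    base = np.bincount(y, minlength=K) + 0.5
    cum = np.cumsum(base / base.sum())[:-1]
    kappa = np.log(cum / (1 - cum)) + rng.normal(0, 0.05, K - 1)
    u = {g: rng.normal(0, 0.1, len(lv)) for g, (_, lv) in groups.items()}
    tau = {g: 0.5 for g in groups}

    def eta_from(u_):
        e = X @ beta
        for g, (idx, _) in groups.items():
            e = e + u_[g][idx]
        return e

    eta = eta_from(u)
    ll_obs = _ordinal_loglik(y, eta, kappa)

    step_beta, step_kappa, step_tau = 0.1, 0.1, 0.3
    step_u = {g: np.full(len(lv), 0.3) for g, (_, lv) in groups.items()}
    acc = {"beta": 0, "kappa": 0, "tau": 0}
    acc_u = {g: np.zeros(len(lv)) for g, (_, lv) in groups.items()}
    adapt_every = 50
    n_since = 0

    n_keep = mcfg.draws_per_chain
    out = {
        "beta": np.empty((n_keep, p)),
        "kappa": np.empty((n_keep, K - 1)),
        "eta_var": np.empty(n_keep),
    }
    for g in groups:
        out[f"tau_{g}"] = np.empty(n_keep)
        out[f"u_{g}"] = np.empty((n_keep, len(groups[g][1])))
    k_out = 0

    n_iter = mcfg.burn + mcfg.samples
    for t in range(n_iter):
        n_since += 1
        # slopes (joint random-walk block)
        if p:
            prop = beta + step_beta * rng.standard_normal(p)
            eta_p = eta + X @ (prop - beta)
            ll_new = _ordinal_loglik(y, eta_p, kappa)
            logr = (ll_new.sum() - ll_obs.sum()
                    - 0.5 * (prop @ prop - beta @ beta) / spec.prior_slope_sd ** 2)
            if np.log(rng.random()) < logr:
                beta, eta, ll_obs = prop, eta_p, ll_new
                acc["beta"] += 1

        # cut points (kappa_1 free, log-increments for the rest)
        z = np.concatenate([[kappa[0]], np.log(np.diff(kappa))]) \
            if K > 2 else np.array([kappa[0]])
        zp = z + step_kappa * rng.standard_normal(len(z))
        kap_p = np.concatenate([[zp[0]], zp[0] + np.cumsum(np.exp(zp[1:]))])
        ll_new = _ordinal_loglik(y, eta, kap_p)
        # Jacobian of the log-increment parameterisation: sum of log-increments
        jac_p = zp[1:].sum() if K > 2 else 0.0
        jac_c = z[1:].sum() if K > 2 else 0.0
        logr = (ll_new.sum() - ll_obs.sum()
                + _kappa_logprior(kap_p) - _kappa_logprior(kappa)
                + jac_p - jac_c)
        if np.log(rng.random()) < logr:
            kappa, ll_obs = kap_p, ll_new
            acc["kappa"] += 1

        # random intercepts: vectorised element-wise Metropolis per factor
        for g, (idx, levels) in groups.items():
            L = len(levels)
            prop_u = u[g] + step_u[g] * rng.standard_normal(L)
            eta_p = eta + (prop_u - u[g])[idx]
            ll_new = _ordinal_loglik(y, eta_p, kappa)
            delta_ll = np.bincount(idx, weights=ll_new - ll_obs, minlength=L)
            logr = delta_ll - 0.5 * (prop_u ** 2 - u[g] ** 2) / tau[g] ** 2
            acc_mask = np.log(rng.random(L)) < logr
            if acc_mask.any():
                new_u = np.where(acc_mask, prop_u, u[g])
                eta = eta + (new_u - u[g])[idx]
                u[g] = new_u
                ll_obs = _ordinal_loglik(y, eta, kappa)
            acc_u[g] += acc_mask

            # tau: Metropolis on log scale
            lt = np.log(tau[g]) + step_tau * rng.standard_normal()
            tau_p = np.exp(lt)
            ssq = u[g] @ u[g]
            logr = (
                -0.5 * ssq / tau_p ** 2 - L * np.log(tau_p)
                + _halfcauchy_logpdf(tau_p, spec.prior_tau_scale) + np.log(tau_p)
            ) - (
                -0.5 * ssq / tau[g] ** 2 - L * np.log(tau[g])
                + _halfcauchy_logpdf(tau[g], spec.prior_tau_scale) + np.log(tau[g])
            )
            if np.log(rng.random()) < logr:
                tau[g] = tau_p
                acc["tau"] += 1

        if t < mcfg.burn and n_since >= adapt_every:
            step_beta *= np.exp(np.clip(acc["beta"] / n_since - 0.3, -0.5, 0.5))
            step_kappa *= np.exp(np.clip(acc["kappa"] / n_since - 0.3, -0.5, 0.5))
            if groups:
                step_tau *= np.exp(np.clip(
                    acc["tau"] / (n_since * len(groups)) - 0.3, -0.5, 0.5))
            for g in groups:
                step_u[g] *= np.exp(np.clip(acc_u[g] / n_since - 0.44, -0.5, 0.5))
                acc_u[g][:] = 0
            acc = {k: 0 for k in acc}
            n_since = 0

        if t >= mcfg.burn and (t - mcfg.burn + 1) % mcfg.thin == 0 and k_out < n_keep:
            out["beta"][k_out] = beta
            out["kappa"][k_out] = kappa
            fixed_eta = X @ beta
            out["eta_var"][k_out] = fixed_eta.var() if p else 0.0
            for g in groups:
                out[f"tau_{g}"][k_out] = tau[g]
                out[f"u_{g}"][k_out] = u[g]
            k_out += 1

    return out


def fit_ordinal(spec: OrdinalModelSpec, data: pd.DataFrame) -> OrdinalFit:
    """Fit one multilevel cumulative-logit model.

    ``data`` must contain the outcome column (values from
    ``spec.categories``), numeric fixed-effect columns and categorical
    random-group columns.  Continuous predictors named in ``spec.scale_2sd``
    are standardised here and the scaling recorded on the fit.
    """
    df = data.copy()
    scaling = ScalingRecord(stats={})
    if spec.scale_2sd:
        df, scaling = scale_predictors(df, spec.scale_2sd)
    y, X, groups = _design(spec, df)

    mcfg = spec.mcmc
    chain_out = []
    for ch in range(mcfg.chains):
        seed = np.random.default_rng([mcfg.seed, ch]).integers(2**31)
        chain_out.append(_run_ordinal_chain(y, X, groups, spec, seed))
    draws = {k: np.stack([co[k] for co in chain_out]) for k in chain_out[0]}
    eta_var = draws.pop("eta_var")

    fit = OrdinalFit(
        spec=spec,
        draws=draws,
        feature_names=tuple(spec.fixed_effects),
        group_levels={g: lv for g, (_, lv) in groups.items()},
        scaling=scaling,
        eta_var=eta_var,
    )
    # convergence summaries on population-level parameters
    for name in ["beta", "kappa"] + [f"tau_{g}" for g in groups]:
        arr = draws[name]
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.shape[-1] == 0:
            continue
        ds = az.convert_to_dataset(arr)
        if mcfg.chains >= 2:
            fit.rhat[name] = np.atleast_1d(az.rhat(ds)["x"].values).max()
        fit.ess[name] = np.atleast_1d(az.ess(ds)["x"].values).min()
    bad = [k for k, v in fit.rhat.items() if v >= 1.01]
    if bad:
        fit.warnings.append(f"convergence warning: R-hat >= 1.01 for {bad}")
    return fit


def odds_ratio(fit: OrdinalFit, predictor: str, per: str = "1sd") -> dict:
    """Posterior odds ratio for a higher outcome category.

    With 2-SD-scaled continuous predictors, ``per="1sd"`` reports exp(beta/2)
    (the odds change for a 1 SD increase) and ``per="2sd"`` reports exp(beta)
    — the latter is also the raw odds ratio for a binary dummy.
    """
    b = fit.beta_draws(predictor)
    if per == "1sd":
        draws = np.exp(b / 2.0)
    elif per == "2sd":
        draws = np.exp(b)
    else:
        raise ValueError("per must be '1sd' or '2sd'")
    lo, hi = az.hdi(draws, hdi_prob=0.95)
    return {"mean": float(draws.mean()), "hdi_low": float(lo),
            "hdi_high": float(hi), "draws": draws}


def category_probabilities(kappa: np.ndarray, eta) -> np.ndarray:
    """Category probabilities under the cumulative-logit link; sums to 1."""
    eta = np.asarray(eta, dtype=float)
    cum = expit(kappa - eta[..., None])
    cum = np.concatenate([cum, np.ones(eta.shape + (1,))], axis=-1)
    return np.diff(cum, axis=-1, prepend=0.0)


def marginal_effects(
    fit: OrdinalFit,
    predictor: str,
    grid: np.ndarray,
    natural_transform=np.log,
) -> dict:
    """Category-probability curves over a natural-scale predictor grid.

    ``grid`` is on the natural scale (e.g. M-ratio values); it is mapped
    through ``natural_transform`` (log by default, identity if None) and the
    stored 2-SD scaling before entering the linear predictor.  All other
    continuous predictors sit at their mean (0 on the scaled design), binary
    dummies at reference 0 and random intercepts at 0.
    """
    if predictor not in fit.scaling.stats:
        raise ValueError(f"{predictor!r} is not a scaled continuous predictor")
    x_nat = np.asarray(grid, dtype=float)
    x_model = natural_transform(x_nat) if natural_transform is not None else x_nat
    x_scaled = fit.scaling.transform(predictor, x_model)

    b = fit.beta_draws(predictor)                      # (draws,)
    kappa = fit.flat("kappa")                          # (draws, K-1)
    eta = b[:, None] * x_scaled[None, :]               # (draws, grid)
    probs = category_probabilities(kappa[:, None, :], eta)  # (draws, grid, K)
    hdi = np.stack([
        az.hdi(np.ascontiguousarray(probs[None, :, i, :]), hdi_prob=0.95)
        for i in range(len(x_nat))
    ])                                                 # (grid, K, 2)
    return {
        "grid": x_nat,
        "mean": probs.mean(axis=0),
        "hdi_low": hdi[..., 0],
        "hdi_high": hdi[..., 1],
        "draws": probs,
    }


def pseudo_r2(fit: OrdinalFit) -> float:
    """Latent-variance pseudo-R^2 (McKelvey-Zavoina style, logistic residual).

    R^2 = Var(X beta) / (Var(X beta) + sum_g tau_g^2 + pi^2 / 3), averaged
    over posterior draws; the random-intercept variances count as unexplained.
    """
    v_fixed = fit.eta_var.reshape(-1)
    v_groups = np.zeros_like(v_fixed)
    for g in fit.group_levels:
        v_groups = v_groups + fit.flat(f"tau_{g}") ** 2
    r2 = v_fixed / (v_fixed + v_groups + np.pi ** 2 / 3.0)
    return float(r2.mean())
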