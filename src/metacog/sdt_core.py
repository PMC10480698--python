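"""Equal-variance signal detection theory for truth judgements with graded confidence.

Type-1 analysis treats each statement as a detection trial: the "signal" class is
a *true* statement, a "hit" is judging a true statement true, a "false alarm" is
judging a false statement true.  Sensitivity d' and criterion c follow the usual
Gaussian closed forms.

The type-2 (metacognitive) analysis is the response-conditional meta-d' model:
a counterfactual type-1 observer with sensitivity meta-d' generates the observed
confidence ratings.  Confidence criteria flank the *shifted* type-1 criterion
c' = c * (meta-d' / d'), and the likelihood of the 2x2x3 confidence-count table
is multinomial in each (stimulus, judgement) cell, conditional on the judgement.
meta-d' and the four confidence criteria are free; type-1 parameters stay fixed
at their point estimates.  The M-ratio meta-d'/d' is the efficiency measure:
1 means confidence carries all the information the judgement did, < 1 means loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "Type1Params",
    "MetadFit",
    "DEFAULT_PADDING",
    "estimate_type1",
    "type2_cell_probabilities",
    "type2_conditional_probs",
    "conditional_loglik",
    "fit_metad_mle",
]

#: Cell-padding constant 1/(2 * n_confidence_levels); the conventional correction
#: for empty cells with 3 confidence levels.
DEFAULT_PADDING = 1.0 / 6.0

# Minimum d' below which the M-ratio denominator is considered unstable.
MIN_DPRIME = 0.05


@dataclass(frozen=True)
class Type1Params:
    """First-order sensitivity and bias for one respondent x domain."""

    d_prime: float
    c: float
    hit_rate: float
    fa_rate: float


@dataclass(frozen=True)
class MetadFit:
    """Maximum-likelihood meta-d' fit for one respondent x domain.

    ``type2_criteria`` are the four confidence criteria in ascending order
    ``[c2_false_hi, c2_false_lo, c2_true_lo, c2_true_hi]``; the middle gap
    contains the shifted type-1 criterion c'.
    """

    meta_d: float
    m_ratio: float
    log_m_ratio: float
    type2_criteria: np.ndarray
    loglik: float
    flags: tuple = field(default_factory=tuple)


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-3:] != (2, 2, 3):
        raise ValueError(f"expected a (..., 2, 2, 3) count array, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return counts


def estimate_type1(counts: np.ndarray, padding: float = DEFAULT_PADDING) -> Type1Params:
    """Closed-form d' and c from a stimulus x judgement x confidence count table.

    ``padding`` is added to every one of the 12 cells before computing the hit
    and false-alarm rates, which keeps the normal quantiles finite when a
    respondent produces an empty margin.
    """
    counts = _validate_counts(counts)
    if counts.sum() == 0:
        raise ValueError("all-zero count table: type-1 parameters undefined")
    padded = counts + padding
    hit_rate = padded[0, 0].sum() / padded[0].sum()
    fa_rate = padded[1, 0].sum() / padded[1].sum()
    z_hr, z_far = ndtri(hit_rate), ndtri(fa_rate)
    return Type1Params(
        d_prime=float(z_hr - z_far),
        c=float(-(z_hr + z_far) / 2.0),
        hit_rate=float(hit_rate),
        fa_rate=float(fa_rate),
    )


def type2_cell_probabilities(
    meta_d: float | np.ndarray,
    type1: Type1Params | None = None,
    type2_criteria: np.ndarray | None = None,
    *,
    c: float | np.ndarray | None = None,
    d_prime: float | np.ndarray | None = None,
) -> np.ndarray:
    """Exact cell probabilities of the meta-d' observer.

    Returns an array of shape ``(..., 2, 2, 3)`` indexed
    ``[stimulus (true, false), judgement (true, false), confidence (1..3)]``;
    each stimulus slice sums to 1.  Evidence for the meta-level observer is
    N(+meta_d/2, 1) for true statements and N(-meta_d/2, 1) for false ones;
    the judgement boundary sits at the shifted criterion c' and the four
    ascending ``type2_criteria`` carve each side into confidence bands.

    Accepts either a :class:`Type1Params` or explicit ``c=.../d_prime=...``
    arrays (broadcastable against ``meta_d``), the latter form being what the
    hierarchical sampler uses.
    """
    if type1 is not None:
        c, d_prime = type1.c, type1.d_prime
    meta_d = np.asarray(meta_d, dtype=float)
    c = np.asarray(c, dtype=float)
    d_prime = np.asarray(d_prime, dtype=float)
    crit = np.asarray(type2_criteria, dtype=float)
    if crit.shape[-1] != 4:
        raise ValueError("type2_criteria must have 4 entries (ascending)")
    if np.any(np.abs(d_prime) < 1e-12):
        raise ValueError(
            "d' = 0: the shifted type-2 criterion c' = c * meta_d / d' is undefined"
        )
    cprime = c * meta_d / d_prime

    shape = np.broadcast_shapes(meta_d.shape, c.shape, crit.shape[:-1])
    # ascending thresholds: [cl2, cl1, c', ch1, ch2]
    thresh = np.empty(shape + (5,))
    thresh[..., 0] = crit[..., 0]
    thresh[..., 1] = crit[..., 1]
    thresh[..., 2] = cprime
    thresh[..., 3] = crit[..., 2]
    thresh[..., 4] = crit[..., 3]
    if np.any(np.diff(thresh, axis=-1) < 0):
        raise ValueError("type2_criteria must straddle c' in ascending order")

    out = np.empty(shape + (2, 2, 3))
    for s, sign in ((0, +1.0), (1, -1.0)):
        cum = ndtr(thresh - sign * np.broadcast_to(meta_d, shape)[..., None] / 2.0)
        # 6 ordered bands, leftmost = "false, extremely confident"
        bands = np.diff(cum, axis=-1, prepend=0.0, append=1.0)
        out[..., s, 0, :] = bands[..., 3:6]          # respond true, conf 1..3
        out[..., s, 1, :] = bands[..., 2::-1]        # respond false, conf 1..3
    return out


def type2_conditional_probs(cell_probs: np.ndarray) -> np.ndarray:
    """Confidence distribution conditional on (stimulus, judgement)."""
    side = cell_probs.sum(axis=-1, keepdims=True)
    return cell_probs / np.clip(side, 1e-300, None)


def conditional_loglik(
    counts: np.ndarray,
    meta_d,
    c,
    d_prime,
    type2_criteria,
) -> np.ndarray:
    """Response-conditional multinomial log-likelihood, broadcast over leading axes.

    ``counts`` has shape ``(..., 2, 2, 3)``; parameters broadcast against its
    leading axes.  Criteria that violate the ordering constraint yield -inf
    rather than raising, so samplers can treat them as rejected proposals.
    """
    counts = np.asarray(counts, dtype=float)
    meta_d = np.asarray(meta_d, dtype=float)
    c = np.asarray(c, dtype=float)
    d_prime = np.asarray(d_prime, dtype=float)
    crit = np.asarray(type2_criteria, dtype=float)

    cprime = c * meta_d / d_prime
    shape = np.broadcast_shapes(meta_d.shape, c.shape, crit.shape[:-1])
    thresh = np.empty(shape + (5,))
    thresh[..., 0] = crit[..., 0]
    thresh[..., 1] = crit[..., 1]
    thresh[..., 2] = cprime
    thresh[..., 3] = crit[..., 2]
    thresh[..., 4] = crit[..., 3]
    bad = np.any(np.diff(thresh, axis=-1) < 0, axis=-1)

    out = np.zeros(shape)
    for s, sign in ((0, +1.0), (1, -1.0)):
        cum = ndtr(thresh - sign * np.broadcast_to(meta_d, shape)[..., None] / 2.0)
        bands = np.diff(cum, axis=-1, prepend=0.0, append=1.0)
        cells = np.empty(shape + (2, 3))
        cells[..., 0, :] = bands[..., 3:6]
        cells[..., 1, :] = bands[..., 2::-1]
        cond = cells / np.clip(cells.sum(axis=-1, keepdims=True), 1e-300, None)
        out += np.sum(counts[..., s, :, :] * np.log(np.clip(cond, 1e-300, None)),
                      axis=(-2, -1))
    return np.where(bad, -np.inf, out)


def _unpack_theta(theta, cprime):
    meta_d = theta[0]
    a1, a2, b1, b2 = theta[1:]
    cl1 = cprime - np.exp(a1)
    cl2 = cl1 - np.exp(a2)
    ch1 = cprime + np.exp(b1)
    ch2 = ch1 + np.exp(b2)
    return meta_d, np.array([cl2, cl1, ch1, ch2])


def fit_metad_mle(
    counts: np.ndarray,
    type1: Type1Params,
    padding: float = DEFAULT_PADDING,
    n_starts: int = 4,
    seed: int = 0,
) -> MetadFit:
    """Maximum-likelihood meta-d' for one respondent x domain.

    Free parameters are meta-d' and the four type-2 criteria, the latter
    parameterised as log-increments away from the shifted criterion c' so the
    ordering holds by construction.  The optimiser (L-BFGS-B) restarts from
    ``n_starts`` jittered initial points and keeps the best optimum.  When any
    of the 12 cells is empty, ``padding`` is added to every cell for the
    likelihood (the same correction used for the type-1 rates), otherwise the
    raw counts are used.
    """
    counts = _validate_counts(counts)
    flags = []
    eff = counts
    if np.any(counts == 0):
        eff = counts + padding

    # degenerate: within every (stimulus, judgement) cell all mass on one level
    conf_totals = counts.sum(axis=(0, 1))
    if np.count_nonzero(conf_totals) <= 1:
        flags.append("degenerate_confidence")

    d, c = type1.d_prime, type1.c
    if abs(d) < 1e-3:
        # c' = c * meta_d / d' is unstable near d' = 0; clamp the denominator
        d = 1e-3 if d >= 0 else -1e-3
        flags.append("clamped_d_prime")

    def nll(theta):
        cpr = c * theta[0] / d
        md, crit = _unpack_theta(theta, cpr)
        return -conditional_loglik(eff, md, c, d, crit)

    rng = np.random.default_rng(seed)
    best = None
    x0_base = np.array([max(abs(d), 0.5), np.log(0.5), np.log(0.5),
                        np.log(0.5), np.log(0.5)])
    bounds = [(0.0, 10.0)] + [(-5.0, 3.0)] * 4
    for k in range(n_starts):
        x0 = x0_base if k == 0 else x0_base + rng.normal(0, 0.4, 5)
        x0[0] = np.clip(x0[0], 0.05, 9.0)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    meta_d, crit = _unpack_theta(best.x, c * best.x[0] / d)
    if best.x[0] <= 1e-6 or best.x[0] >= 10.0 - 1e-6:
        flags.append("boundary_meta_d")

    if abs(d) <= MIN_DPRIME:
        m_ratio = np.nan
        log_m = np.nan
        flags.append("unstable_d_prime")
    else:
        m_ratio = meta_d / d
        log_m = np.log(m_ratio) if m_ratio > 0 else -np.inf
    return MetadFit(
        meta_d=float(meta_d),
        m_ratio=float(m_ratio),
        log_m_ratio=float(log_m),
        type2_criteria=crit,
        loglik=float(-best.fun),
        flags=tuple(flags),
    )
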