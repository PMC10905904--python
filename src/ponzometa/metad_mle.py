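"""Single-subject maximum-likelihood meta-d' estimation.

meta-d' expresses metacognitive (type-2) sensitivity on the type-1 d' scale:
it is the sensitivity a hypothetical SDT-ideal observer would need in order
to produce the observed confidence-rating data.  The meta-level observer is
an equal-variance Gaussian observer with stimulus means at +/- meta_d'/2
whose type-1 criterion is constrained to be "response-bias matched",

    meta_C = C * (meta_d' / d'),

and whose four-point confidence ratings arise from three type-2 criteria on
each side of meta_C.  The fit maximizes the multinomial likelihood of the
confidence counts conditional on each (stimulus, response) cell, with the
type-1 response marginals fixed at their observed values.

Efficiency measures:

    M-ratio   = meta_d' / d'        (1   = metacognitively optimal)
    log M-ratio = ln(meta_d' / d')  (0   = optimal; < 0 inefficiency;
                                     > 0 "superefficiency")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .core_io import ConfidenceCountTable, N_CONFIDENCE_LEVELS
from .sdt_type1 import Type1Estimates

__all__ = [
    "MetaDFit",
    "fit_meta_d",
    "log_m_ratio",
    "conditional_probs",
    "joint_probs",
    "expected_count_table",
    "negative_log_likelihood",
    "brute_force_fit",
]

#: cell padding added before the MLE, 1/(2K) for K = 4 rating levels
CELL_PAD = 1.0 / (2 * N_CONFIDENCE_LEVELS)

_TINY = 1e-300


@dataclass
class MetaDFit:
    meta_d: float
    meta_c: float
    t2_criteria_s1: np.ndarray  # 3 ascending criteria below meta_c
    t2_criteria_s2: np.ndarray  # 3 ascending criteria above meta_c
    m_ratio: float
    log_m_ratio: float
    nll: float
    warnings: list[str] = field(default_factory=list)


def _boundaries(meta_c, t2s1, t2s2):
    """The 9 segment boundaries on the meta-level evidence axis."""
    return np.concatenate(([-np.inf], np.atleast_1d(t2s1), [meta_c],
                           np.atleast_1d(t2s2), [np.inf]))


def _segment_probs(mean: float, bounds: np.ndarray) -> np.ndarray:
    cdf = norm.cdf(bounds - mean)
    return np.clip(np.diff(cdf), _TINY, 1.0)


def conditional_probs(meta_d, meta_c, t2s1, t2s2):
    """P(confidence cell | stimulus, response) under the meta-level observer.

    Returns (p_s1, p_s2), each length 8 in the canonical cell order; within
    each response half the four entries sum to 1.
    """
    bounds = _boundaries(meta_c, t2s1, t2s2)
    out = []
    for mean in (-meta_d / 2.0, +meta_d / 2.0):
        seg = _segment_probs(mean, bounds)
        same = seg[:4] / seg[:4].sum()
        diff = seg[4:] / seg[4:].sum()
        out.append(np.concatenate([same, diff]))
    return out[0], out[1]


def joint_probs(d_prime, criterion_c, meta_d, t2s1, t2s2):
    """P(response, confidence | stimulus): meta-level confidence distribution
    combined with the *type-1* observer's response marginals."""
    meta_c = criterion_c * (meta_d / d_prime) if d_prime != 0 else criterion_c
    p1, p2 = conditional_probs(meta_d, meta_c, t2s1, t2s2)
    out = []
    for mean, p in ((-d_prime / 2.0, p1), (+d_prime / 2.0, p2)):
        p_diff = 1.0 - norm.cdf(criterion_c - mean)  # P(respond "different")
        joint = p.copy()
        joint[:4] *= 1.0 - p_diff
        joint[4:] *= p_diff
        out.append(joint)
    return out[0], out[1]


def expected_count_table(
    d_prime: float,
    criterion_c: float,
    meta_d: float,
    t2s1,
    t2s2,
    n_s1: float,
    n_s2: float,
) -> ConfidenceCountTable:
    """Expected (non-integer) cell counts of an ideal meta-level observer."""
    p1, p2 = joint_probs(d_prime, criterion_c, meta_d,
                         np.asarray(t2s1, float), np.asarray(t2s2, float))
    return ConfidenceCountTable(n_s1 * p1, n_s2 * p2)


def negative_log_likelihood(
    counts_s1: np.ndarray,
    counts_s2: np.ndarray,
    meta_d: float,
    meta_c: float,
    t2s1,
    t2s2,
) -> float:
    """Response-conditional multinomial NLL of the 16 confidence cells."""
    p1, p2 = conditional_probs(meta_d, meta_c, np.asarray(t2s1, float),
                               np.asarray(t2s2, float))
    return float(-(counts_s1 * np.log(p1)).sum() - (counts_s2 * np.log(p2)).sum())


def _unpack(x: np.ndarray, c_ratio: float):
    """x = [meta_d, w0..w5] -> (meta_d, meta_c, t2s1, t2s2).

    Type-2 criteria are parameterized as cumulative exp-increments away from
    meta_C on either side, which enforces strict ordering for any real w.
    """
    meta_d = x[0]
    meta_c = c_ratio * meta_d
    off1 = np.cumsum(np.exp(x[1:4]))
    off2 = np.cumsum(np.exp(x[4:7]))
    t2s1 = meta_c - off1[::-1]
    t2s2 = meta_c + off2
    return meta_d, meta_c, t2s1, t2s2


def fit_meta_d(
    table: ConfidenceCountTable,
    type1: Type1Estimates,
    pad: float = CELL_PAD,
) -> MetaDFit:
    """Maximum-likelihood meta-d' fit for one subject x condition.

    Free parameters are meta_d' and the six type-2 criteria; meta_C is
    constrained to C * meta_d'/d'.  Every cell count is padded by ``pad``
    (default 1/(2K)) before fitting to avoid zero-cell degeneracies; the
    padding never touches stored data.  The optimizer is L-BFGS-B from five
    deterministic starts, ties broken by lowest NLL then lowest meta_d'.
    """
    warns: list[str] = []
    d = type1.d_prime
    if not np.isfinite(d) or d <= 0:
        warns.append("d' <= 0 after correction: M-ratio undefined")
        warnings.warn(warns[-1], stacklevel=2)
        nan = float("nan")
        return MetaDFit(nan, nan, np.full(3, nan), np.full(3, nan),
                        nan, nan, nan, warns)
    c_ratio = type1.criterion_c / d
    c1 = table.s1 + pad
    c2 = table.s2 + pad

    def objective(x):
        meta_d, meta_c, t2s1, t2s2 = _unpack(x, c_ratio)
        return negative_log_likelihood(c1, c2, meta_d, meta_c, t2s1, t2s2)

    w0 = np.log(0.5)
    starts = [0.2, 0.5 * d, d, 1.5 * d, 2.0 * d]
    bounds = [(-5.0, 10.0)] + [(-5.0, 3.0)] * 6
    best = None
    for s in starts:
        x0 = np.array([s] + [w0] * 6)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        key = (round(res.fun, 9), res.x[0])
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    meta_d, meta_c, t2s1, t2s2 = _unpack(res.x, c_ratio)
    m_ratio = meta_d / d
    if m_ratio > 0:
        logm = float(np.log(m_ratio))
    else:
        logm = float("nan")
        warns.append("nonpositive M-ratio: log M-ratio undefined")
        warnings.warn(warns[-1], stacklevel=2)
    return MetaDFit(float(meta_d), float(meta_c), t2s1, t2s2,
                    float(m_ratio), logm, float(res.fun), warns)


def log_m_ratio(fit: MetaDFit, d_prime: float | None = None) -> float:
    """Natural log of meta_d'/d'; 0 iff meta_d' = d'."""
    if d_prime is None:
        ratio = fit.m_ratio
    else:
        ratio = fit.meta_d / d_prime
    if not np.isfinite(ratio) or ratio <= 0:
        warnings.warn("nonpositive M-ratio: log M-ratio undefined", stacklevel=2)
        return float("nan")
    return float(np.log(ratio))


# ---------------------------------------------------------------------------
# brute-force reference fit
# ---------------------------------------------------------------------------

def brute_force_fit(
    table: ConfidenceCountTable,
    type1: Type1Estimates,
    step: float = 0.01,
    meta_d_range: tuple[float, float] = (-2.0, 5.0),
    criterion_span: float = 4.0,
    pad: float = CELL_PAD,
    max_cycles: int = 60,
) -> MetaDFit:
    """Derivative-free exhaustive reference fit, for verification only.

    Scans one parameter at a time over a dense grid of raw positions at
    resolution ``step`` (meta_d' over ``meta_d_range``; each type-2 criterion
    over the interval between its ordered neighbours), cycling until no
    coordinate moves.  Independent of the gradient-based path in
    :func:`fit_meta_d`.
    """
    d = type1.d_prime
    if d <= 0:
        raise ValueError("brute_force_fit requires d' > 0")
    c_ratio = type1.criterion_c / d
    c1 = table.s1 + pad
    c2 = table.s2 + pad

    def nll_at(meta_d, crit):
        meta_c = c_ratio * meta_d
        t2s1, t2s2 = crit[:3], crit[3:]
        if not (t2s1[0] < t2s1[1] < t2s1[2] < meta_c < t2s2[0] < t2s2[1] < t2s2[2]):
            return np.inf
        return negative_log_likelihood(c1, c2, meta_d, meta_c, t2s1, t2s2)

    # start from an ordered spread around the constrained criterion
    meta_d = max(min(d, meta_d_range[1] - step), meta_d_range[0] + step)
    meta_c = c_ratio * meta_d
    crit = np.array([meta_c - 1.5, meta_c - 1.0, meta_c - 0.5,
                     meta_c + 0.5, meta_c + 1.0, meta_c + 1.5])
    current = nll_at(meta_d, crit)
    for _ in range(max_cycles):
        moved = False
        # meta_d scan; criteria keep their offsets from meta_C (rigid shift),
        # so the scan follows the natural ridge of the likelihood
        grid = np.arange(meta_d_range[0], meta_d_range[1] + step / 2, step)
        offs = crit - c_ratio * meta_d
        vals = np.array([nll_at(m, c_ratio * m + offs) for m in grid])
        j = int(np.argmin(vals))
        if vals[j] < current - 1e-12:
            meta_d, current, moved = float(grid[j]), float(vals[j]), True
            crit = c_ratio * meta_d + offs
        meta_c = c_ratio * meta_d
        # criterion scans, each bounded by its ordered neighbours
        anchors = np.concatenate(([crit[0] - criterion_span], crit, [crit[-1] + criterion_span]))
        for i in range(6):
            lo = anchors[i] + step if i != 3 else max(anchors[i] + step, meta_c + step)
            hi = anchors[i + 2] - step if i != 2 else min(anchors[i + 2] - step, meta_c - step)
            if hi < lo:
                continue
            grid = np.arange(lo, hi + step / 2, step)
            trial = crit.copy()
            best_v, best_x = current, crit[i]
            for x in grid:
                trial[i] = x
                v = nll_at(meta_d, trial)
                if v < best_v - 1e-12:
                    best_v, best_x = v, float(x)
            if best_x != crit[i]:
                crit[i], current, moved = best_x, best_v, True
            anchors = np.concatenate(([crit[0] - criterion_span], crit,
                                      [crit[-1] + criterion_span]))
        # auxiliary scan directions (still plain 1-D grid scans): a common
        # shift of all six criteria, and a common scale of their offsets
        # from meta_C — these follow the correlated directions on which
        # one-at-a-time moves stall
        shift_grid = np.arange(-1.0, 1.0 + step / 2, step)
        vals = np.array([nll_at(meta_d, crit + s) for s in shift_grid])
        j = int(np.argmin(vals))
        if vals[j] < current - 1e-12:
            crit, current, moved = crit + shift_grid[j], float(vals[j]), True
        offs = crit - meta_c
        scale_grid = np.arange(0.5, 2.0 + step / 2, step)
        vals = np.array([nll_at(meta_d, meta_c + g * offs) for g in scale_grid])
        j = int(np.argmin(vals))
        if vals[j] < current - 1e-12:
            crit, current, moved = meta_c + scale_grid[j] * offs, float(vals[j]), True
        if not moved:
            break
    meta_c = c_ratio * meta_d
    m_ratio = meta_d / d
    logm = float(np.log(m_ratio)) if m_ratio > 0 else float("nan")
    return MetaDFit(meta_d, float(meta_c), crit[:3].copy(), crit[3:].copy(),
                    float(m_ratio), logm, float(current))
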