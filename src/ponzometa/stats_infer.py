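"""Classical inference: t tests with Cohen's d, Spearman and partial Spearman.

Cohen's d for a one-sample test is (mean - mu0)/SD = t/sqrt(n); its CI uses
the normal approximation d +/- 1.96 * sqrt(1/n + d^2/(2n)).  Spearman
correlations are Pearson correlations of midranks; partial Spearman
residualizes the midranks on the covariates first.  p-values use the
t-approximation t = rho * sqrt((n - 2 - k)/(1 - rho^2)); confidence
intervals use a seeded percentile bootstrap over sample pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "CorrelationResult",
    "one_sample_t",
    "paired_diff_t",
    "spearman",
    "partial_spearman",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    effect_d: float
    effect_ci: tuple[float, float]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci: tuple[float, float]
    p: float
    partialled: list[str] = field(default_factory=list)


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    d = t / np.sqrt(n)
    half = 1.96 * np.sqrt(1.0 / n + d**2 / (2 * n))
    return TestResult(float(t), n - 1, float(p), float(d),
                      (float(d - half), float(d + half)))


def paired_diff_t(a, b) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _partial_residuals(r: np.ndarray, covs: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones(len(r)), covs])
    beta, *_ = np.linalg.lstsq(Z, r, rcond=None)
    return r - Z @ beta


def _rho_p_ci(x, y, covs, labels, n_boot, seed):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=3)
        return CorrelationResult(float("nan"), (float("nan"), float("nan")),
                                 float("nan"), labels)
    k = 0
    if covs is not None:
        covs = np.asarray(covs, dtype=float)
        if covs.ndim != 2 or covs.shape[0] != n:
            raise ValueError("covariates must be an (n, k) array")
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), covs])) < covs.shape[1] + 1:
            raise ValueError("covariates are rank deficient")
        k = covs.shape[1]

    def compute(xi, yi, ci):
        rx, ry = _rank(xi), _rank(yi)
        if ci is not None:
            rc = np.column_stack([_rank(c) for c in ci.T])
            rx = _partial_residuals(rx, rc)
            ry = _partial_residuals(ry, rc)
        sx, sy = rx.std(), ry.std()
        if sx == 0 or sy == 0:
            return float("nan")
        return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))

    rho = compute(x, y, covs)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    ci_lo = ci_hi = float("nan")
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = compute(x[idx], y[idx], covs[idx] if covs is not None else None)
        boots = boots[np.isfinite(boots)]
        if boots.size:
            ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(rho, (float(ci_lo), float(ci_hi)), p, labels)


def spearman(x, y, n_boot: int = 10_000, seed: int | None = None) -> CorrelationResult:
    """Spearman correlation with bootstrap CI (percentile, seeded)."""
    return _rho_p_ci(x, y, None, [], n_boot, seed)


def partial_spearman(x, y, covariates, labels: list[str] | None = None,
                     n_boot: int = 10_000, seed: int | None = None) -> CorrelationResult:
    """Partial Spearman: Pearson on midranks residualized on ranked covariates."""
    covs = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covs.shape[0] != len(np.asarray(x)):
        covs = covs.T
    return _rho_p_ci(x, y, covs, labels or [f"cov{i}" for i in range(covs.shape[1])],
                     n_boot, seed)
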