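"""Hierarchical Bayesian estimation of group and subject log M-ratio.

Generative model (subject s, with type-1 d'_s and C_s held fixed at their
conventional estimates — a deliberate "cut" so the type-1 values stay exactly
identical to the non-Bayesian ones):

    log M-ratio_s ~ Normal(mu [+ beta * x_s], sigma)
    meta_d'_s      = exp(log M-ratio_s) * d'_s
    meta_C_s       = C_s * meta_d'_s / d'_s          (bias-matched observer)
    confidence cells_s ~ multinomial over the response-conditional
                         probabilities of the meta-level Gaussian observer

Priors: mu ~ Normal(0, 1); sigma ~ Half-Normal(1); beta ~ Normal(0, 1);
type-2 criteria weakly informative Normal(0, 10), truncated to ordering via
a cumulative exp-increment parameterization.

The posterior is sampled with a vectorized Metropolis-within-Gibbs scheme:
per-subject blocks (log M-ratio + 6 criterion parameters) move by adaptive
random-walk Metropolis, all subjects in parallel; mu (and beta) are drawn
exactly from their conjugate conditional; sigma moves by random-walk
Metropolis on the log scale.  Step sizes adapt during burn-in only, keeping
the post-burn-in chain Markovian.  Convergence is monitored by split R-hat.

Group-level summaries are MAP (mode of a Gaussian KDE over pooled samples)
and 95% highest-density intervals.  M-ratio summaries exponentiate the
log M-ratio samples *before* summarizing, so the M-ratio MAP need not equal
exp(log-M-ratio MAP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from .core_io import ConfidenceCountTable, PipelineConfig
from .sdt_type1 import Type1Estimates

__all__ = [
    "HierPosterior",
    "PosteriorSummary",
    "fit_hierarchical",
    "fit_hierarchical_regression",
    "summarize_posterior",
]

_CRIT_PRIOR_SD = 10.0
_RHAT_LIMIT = 1.1


@dataclass
class PosteriorSummary:
    map: float
    hdi_low: float
    hdi_high: float
    mean: float


@dataclass
class HierPosterior:
    """MCMC draws (chains x draws) for the group model."""

    mu: np.ndarray                 # (chains, draws)
    sigma: np.ndarray              # (chains, draws)
    subject_logm: np.ndarray       # (chains, draws, n_subjects)
    subject_ids: list[str]
    beta: np.ndarray | None = None
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1) if arr.ndim == 2 else arr.reshape(-1, arr.shape[-1])

    def subject_posterior_means(self) -> np.ndarray:
        return self.subject_logm.mean(axis=(0, 1))

    def summary_mu(self, mass: float = 0.95) -> PosteriorSummary:
        return summarize_posterior(self.pooled("mu"), mass)

    def summary_m_ratio(self, mass: float = 0.95) -> PosteriorSummary:
        """Group M-ratio summary: exponentiate mu samples, then summarize."""
        return summarize_posterior(np.exp(self.pooled("mu")), mass)


# ---------------------------------------------------------------------------
# vectorized meta-observer likelihood
# ---------------------------------------------------------------------------

class _Data:
    def __init__(self, tables, type1s):
        self.s1 = np.stack([t.s1 for t in tables])          # (n, 8)
        self.s2 = np.stack([t.s2 for t in tables])
        self.d = np.array([t.d_prime for t in type1s])      # (n,)
        if np.any(self.d == 0) or np.any(~np.isfinite(self.d)):
            raise ValueError("every subject needs a finite nonzero d'")
        self.c_ratio = np.array([t.criterion_c for t in type1s]) / self.d
        self.n = len(type1s)


def _loglik(theta, w, data: _Data, fixed_criteria=None):
    """Summed log multinomial likelihood per subject; theta (n,), w (n, 6)."""
    meta_d = np.exp(theta) * data.d
    meta_c = data.c_ratio * meta_d
    if fixed_criteria is None:
        off1 = np.cumsum(np.exp(w[:, :3]), axis=1)
        off2 = np.cumsum(np.exp(w[:, 3:]), axis=1)
        t2s1 = meta_c[:, None] - off1[:, ::-1]
        t2s2 = meta_c[:, None] + off2
    else:
        t2s1 = fixed_criteria[:, :3]
        t2s2 = fixed_criteria[:, 3:]
    n = data.n
    bounds = np.empty((n, 9))
    bounds[:, 0] = -np.inf
    bounds[:, 1:4] = t2s1
    bounds[:, 4] = meta_c
    bounds[:, 5:8] = t2s2
    bounds[:, 8] = np.inf
    ll = np.zeros(n)
    for mean, counts in ((-meta_d / 2, data.s1), (+meta_d / 2, data.s2)):
        seg = np.diff(ndtr(bounds - mean[:, None]), axis=1)
        seg = np.clip(seg, 1e-300, 1.0)
        same = seg[:, :4] / seg[:, :4].sum(axis=1, keepdims=True)
        diff = seg[:, 4:] / seg[:, 4:].sum(axis=1, keepdims=True)
        p = np.concatenate([same, diff], axis=1)
        ll += (counts * np.log(p)).sum(axis=1)
    return ll


def _log_prior_subject(theta, w, m, sigma, data: _Data, fixed: bool):
    """log p(theta, criteria | mu, sigma) per subject (n,)."""
    lp = -0.5 * ((theta - m) / sigma) ** 2 - np.log(sigma)
    if not fixed:
        meta_c = data.c_ratio * np.exp(theta) * data.d
        off1 = np.cumsum(np.exp(w[:, :3]), axis=1)
        off2 = np.cumsum(np.exp(w[:, 3:]), axis=1)
        crit = np.concatenate([meta_c[:, None] - off1[:, ::-1],
                               meta_c[:, None] + off2], axis=1)
        lp += -0.5 * (crit / _CRIT_PRIOR_SD) ** 2 @ np.ones(6)
        lp += w.sum(axis=1)  # Jacobian of the exp-increment transform
    return lp


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def fit_hierarchical(
    tables: list[ConfidenceCountTable],
    type1: list[Type1Estimates],
    config: PipelineConfig | None = None,
    covariate: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    seed: int | None = None,
    fix_criteria: np.ndarray | None = None,
) -> HierPosterior:
    """Sample the hierarchical posterior over subject and group log M-ratio.

    ``covariate`` (optional) enables simultaneous regression,
    log M-ratio_s ~ Normal(mu + beta * x_s, sigma), with x standardized to
    zero mean and unit variance internally.  ``fix_criteria`` (n x 6 raw
    criterion positions) freezes the type-2 criteria, which is useful for
    grid-oracle verification.
    """
    if len(tables) != len(type1) or len(tables) < 1:
        raise ValueError("need matching, non-empty tables and type-1 estimates")
    if covariate is None and len(tables) < 2:
        pass  # single-subject fit allowed (prior-dominated checks)
    config = config or PipelineConfig()
    data = _Data(tables, type1)
    n = data.n
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(n)]

    has_beta = covariate is not None
    if has_beta:
        x = np.asarray(covariate, dtype=float)
        if x.shape != (n,):
            raise ValueError("covariate must have one value per subject")
        sd = x.std()
        if sd == 0:
            raise ValueError("constant covariate: regression slope unidentifiable")
        x = (x - x.mean()) / sd
        Z = np.column_stack([np.ones(n), x])
    else:
        Z = np.ones((n, 1))
    k = Z.shape[1]
    ZtZ = Z.T @ Z

    draws = config.samples - config.burn_in
    mu_out = np.empty((config.chains, draws))
    sigma_out = np.empty((config.chains, draws))
    beta_out = np.empty((config.chains, draws)) if has_beta else None
    theta_out = np.empty((config.chains, draws, n))

    seed = config.seed if seed is None else seed
    seeds = np.random.SeedSequence(seed).spawn(config.chains)

    # deterministic coarse initialization of theta per subject
    grid = np.arange(-2.5, 1.5001, 0.05)
    w_init = np.full((n, 6), np.log(0.5))
    ll_grid = np.stack([
        _loglik(np.full(n, g), w_init, data, fix_criteria) for g in grid
    ])
    theta_map0 = grid[np.argmax(ll_grid, axis=0)]

    for chain in range(config.chains):
        rng = np.random.default_rng(seeds[chain])
        theta = theta_map0 + 0.2 * rng.standard_normal(n)
        w = w_init + 0.1 * rng.standard_normal((n, 6))
        coef = np.zeros(k)
        coef[0] = theta.mean()
        sigma = max(theta.std(), 0.1)
        step = np.full(n, 0.15)
        sig_step = 0.3
        acc = np.zeros(n)
        sig_acc = 0

        m = Z @ coef
        fixed = fix_criteria is not None
        ll = _loglik(theta, w, data, fix_criteria)
        lp = _log_prior_subject(theta, w, m, sigma, data, fixed)

        for it in range(config.samples):
            # --- subject blocks: joint RW proposal on (theta, w) ----------
            th_prop = theta + step * rng.standard_normal(n)
            w_prop = w if fixed else w + step[:, None] * rng.standard_normal((n, 6))
            ll_prop = _loglik(th_prop, w_prop, data, fix_criteria)
            lp_prop = _log_prior_subject(th_prop, w_prop, m, sigma, data, fixed)
            log_alpha = (ll_prop + lp_prop) - (ll + lp)
            accept = np.log(rng.random(n)) < log_alpha
            theta = np.where(accept, th_prop, theta)
            if not fixed:
                w = np.where(accept[:, None], w_prop, w)
            ll = np.where(accept, ll_prop, ll)
            lp = np.where(accept, lp_prop, lp)
            acc += accept

            # --- mu (and beta): exact conjugate Gibbs draw ----------------
            A = ZtZ / sigma**2 + np.eye(k)        # prior Normal(0, 1) each
            b = Z.T @ theta / sigma**2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            coef = mean + np.linalg.solve(L.T, rng.standard_normal(k))
            m = Z @ coef

            # --- sigma: RW Metropolis on log sigma ------------------------
            resid2 = float(((theta - m) ** 2).sum())
            log_s = np.log(sigma)
            log_s_prop = log_s + sig_step * rng.standard_normal()
            s_prop = np.exp(log_s_prop)

            def sigma_logpost(s, ls):
                # likelihood of theta + Half-Normal(1) prior + log-Jacobian
                return (-n * ls - resid2 / (2 * s**2)) - s**2 / 2 + ls

            if np.log(rng.random()) < sigma_logpost(s_prop, log_s_prop) - \
                    sigma_logpost(sigma, log_s):
                sigma = s_prop
                sig_acc += 1
            lp = _log_prior_subject(theta, w, m, sigma, data, fixed)

            # --- adaptation (burn-in only) --------------------------------
            if it < config.burn_in and (it + 1) % 50 == 0:
                rate = acc / 50.0
                step *= np.exp(0.8 * (rate - 0.30))
                step = np.clip(step, 1e-3, 2.0)
                sig_step *= np.exp(0.8 * (sig_acc / 50.0 - 0.44))
                sig_step = float(np.clip(sig_step, 1e-3, 2.0))
                acc[:] = 0
                sig_acc = 0

            if it >= config.burn_in:
                j = it - config.burn_in
                mu_out[chain, j] = coef[0]
                sigma_out[chain, j] = sigma
                if has_beta:
                    beta_out[chain, j] = coef[1]
                theta_out[chain, j] = theta

    # --- diagnostics ------------------------------------------------------
    rhat: dict[str, float] = {}
    named = {"mu": mu_out, "sigma": sigma_out}
    if has_beta:
        named["beta"] = beta_out
    for name, arr in named.items():
        if config.chains >= 2 and draws >= 4:
            rhat[name] = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
        else:
            rhat[name] = float("nan")
    warns = []
    converged = True
    bad = {p: r for p, r in rhat.items() if np.isfinite(r) and r > _RHAT_LIMIT}
    if bad:
        converged = False
        warns.append(f"non-convergence: split R-hat above {_RHAT_LIMIT} for {bad}")
        warnings.warn(warns[-1], stacklevel=2)

    return HierPosterior(mu_out, sigma_out, theta_out, list(subject_ids),
                         beta_out, rhat, converged, warns)


def fit_hierarchical_regression(
    tables: list[ConfidenceCountTable],
    type1: list[Type1Estimates],
    covariate: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    subject_ids: list[str] | None = None,
) -> HierPosterior:
    """Hierarchical fit with a simultaneous subject-level regression slope."""
    return fit_hierarchical(tables, type1, config=config, covariate=covariate,
                            seed=seed, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def summarize_posterior(samples: np.ndarray, mass: float = 0.95) -> PosteriorSummary:
    """MAP (Gaussian-KDE mode, Silverman bandwidth) and shortest HDI.

    The HDI is the shortest contiguous interval containing ``mass`` of the
    pooled samples, found by a sorted-sample sweep.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly inside (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    if x.size == 0:
        raise ValueError("empty sample array")
    mean = float(x.mean())
    if x[0] == x[-1]:
        return PosteriorSummary(float(x[0]), float(x[0]), float(x[-1]), mean)
    try:
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x[0], x[-1], 2048)
        map_ = float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        # numerically zero spread (near-duplicate samples): mode ~ median
        map_ = float(np.median(x))
    n = x.size
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return PosteriorSummary(map_, float(x[i]), float(x[i + k - 1]), mean)
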