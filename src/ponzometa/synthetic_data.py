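"""Synthetic cohorts with the statistical structure the analysis assumes.

Trial generator
---------------
A subject is a Gaussian SDT observer: type-1 evidence ~ Normal(+/- d'/2, 1)
against criterion c.  Confidence comes from a second, partially decorrelated
meta-level evidence sample whose sensitivity is meta-d' =
exp(log M-ratio) * d', drawn *conditionally on agreeing with the type-1
response* (truncated at the bias-matched meta criterion) and cut by three
ordered type-2 criteria per side.  This is exactly the meta-level observer
that the MLE and hierarchical fitters assume, so generator <-> estimator
round trips are exact in expectation.  Filler trials (5% size steps) are
emitted at sensitivity 0 — near threshold — and flagged for exclusion.

Rating generator
----------------
52 scored item values arise from a 3-factor loading model plus Gaussian
noise, shifted by a small positive group superiority bias, then clipped to
[-1, 1] and snapped to the 0.05 VAS grid.  Undesirable items are emitted on
the raw (un-reversed) scale so downstream scoring exercises reverse-coding;
the 8 fillers are uniform grid noise.

Cohort defaults mirror the anatomy of the study population this pipeline is
built for: n = 37 subjects, high control-condition sensitivity (d' near 3),
near-zero sensitivity under the depth-cue illusion, group log M-ratio around
-0.3 with SD 0.2, and a modest positive mean superiority rating.  Optional
linkage coefficients couple the latent rating factors to the depth-condition
d' (hence the illusion-magnitude difference) and to log M-ratio, producing
cohorts whose latent architecture the full pipeline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .core_io import (
    Condition,
    ItemClass,
    RatingSheet,
    Response,
    Stimulus,
    TrialRecord,
    FILLER_WORDS,
    VAS_STEP,
    build_trial_schedule,
    trait_items,
)

__all__ = [
    "CohortSpec",
    "default_loading_matrix",
    "simulate_subject_trials",
    "simulate_cohort",
    "simulate_ratings",
    "simulate_study",
]


def default_loading_matrix(primaries: tuple[float, float, float] = (1.0, 0.7, 0.45)) -> np.ndarray:
    """52 x 3 block loading matrix: items 1-18, 19-35, 36-52 load on factors
    1, 2, 3.  Decreasing strengths mirror the clearly ordered component
    variances of real trait-rating data and keep the components identifiable."""
    L = np.zeros((52, 3))
    L[:18, 0] = primaries[0]
    L[18:35, 1] = primaries[1]
    L[35:, 2] = primaries[2]
    return L


@dataclass
class CohortSpec:
    """True-parameter distributions for a simulated cohort."""

    n_subjects: int = 37
    # type-1 sensitivity / bias distributions per condition
    d_control_mean: float = 2.8
    d_control_sd: float = 0.7
    d_depth_mean: float = 0.2
    d_depth_sd: float = 0.3
    d_floor: float | None = 0.05   # truncate true d' away from 0; None allows
                                   # below-chance depth-condition sensitivity
                                   # (a strong illusion can invert the percept)
    c_sd: float = 0.15
    # group metacognitive efficiency
    mu_log_m_ratio: float = -0.3
    sigma_log_m_ratio: float = 0.2
    # type-2 criterion spreads (mean increments away from meta_C per side)
    t2_increment: float = 0.5
    t2_jitter_sd: float = 0.15
    # rating factor model
    loading_matrix: np.ndarray = field(default_factory=default_loading_matrix)
    rating_noise_sd: float = 0.5
    rating_intercept: float = 0.08   # group-mean superiority bias
    rating_scale: float = 0.35       # latent-to-VAS scale before clipping
    # linkage: latent factors -> depth d' and log M-ratio (None = independent)
    link_d_depth: tuple[float, float, float] | None = None
    link_log_m: tuple[float, float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("d_control_sd", "d_depth_sd", "c_sd", "sigma_log_m_ratio",
                     "t2_jitter_sd", "rating_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        L = np.asarray(self.loading_matrix, dtype=float)
        if L.shape != (52, 3):
            raise ValueError("loading_matrix must be 52 x 3")
        if np.any(np.linalg.norm(L, axis=1) > 1.0 + 1e-9):
            raise ValueError("loading_matrix rows must have norm <= 1")

    @classmethod
    def linked(cls, **kw) -> "CohortSpec":
        """Cohort with the canonical latent architecture: factor 1 drives both
        outcomes negatively, factor 2 only the depth-condition d', factor 3
        only log M-ratio."""
        kw.setdefault("link_d_depth", (-0.7, -0.7, 0.0))
        kw.setdefault("link_log_m", (-0.35, 0.0, -0.35))
        kw.setdefault("sigma_log_m_ratio", 0.1)
        kw.setdefault("d_floor", None)
        return cls(**kw)


def _truncated_normal(rng, mean, sd, low, size=None):
    if sd == 0:
        return np.maximum(np.broadcast_to(mean, size or ()), low).astype(float)
    a = (low - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                         random_state=rng)


def simulate_subject_trials(
    d_prime: float,
    criterion: float,
    log_m_ratio: float,
    t2_offsets_s1: np.ndarray,
    t2_offsets_s2: np.ndarray,
    schedule: list[TrialRecord],
    rng: np.random.Generator,
    d_by_condition: dict[Condition, float] | None = None,
) -> list[TrialRecord]:
    """Fill a schedule's stubs with type-1 responses and confidence ratings.

    ``t2_offsets_*`` are the three positive increments away from meta_C on
    each side (strictly positive, else criteria would be unordered).
    ``d_by_condition`` optionally overrides d' per background condition
    (the usual illusion setup); ``d_prime`` is the fallback for both.
    """
    off1 = np.asarray(t2_offsets_s1, dtype=float)
    off2 = np.asarray(t2_offsets_s2, dtype=float)
    if np.any(off1 <= 0) or np.any(off2 <= 0):
        raise ValueError("type-2 criterion increments must be positive (ordered)")
    m_ratio = float(np.exp(log_m_ratio))
    n = len(schedule)
    d_all = np.array([
        (d_by_condition[Condition(s.condition)] if d_by_condition else d_prime)
        for s in schedule
    ])
    d_eff = np.where([s.is_filler for s in schedule], 0.0, d_all)
    sign = np.where([Stimulus(s.stimulus) == Stimulus.SAME for s in schedule],
                    -1.0, +1.0)
    x = rng.normal(sign * d_eff / 2.0, 1.0)
    respond_diff = x > criterion
    # meta-level evidence, conditioned to agree with the type-1 response:
    # inverse-CDF sampling from the Normal truncated at the matched meta_C
    meta_d = m_ratio * d_eff
    meta_c = criterion * m_ratio  # = C * meta_d / d'
    mean = sign * meta_d / 2.0
    p_cut = ndtr(meta_c - mean)
    u = rng.random(n)
    u_trunc = np.where(respond_diff, p_cut + u * (1.0 - p_cut), u * p_cut)
    y = mean + ndtri(np.clip(u_trunc, 1e-12, 1.0 - 1e-12))
    cuts_diff = meta_c + np.cumsum(off2)
    cuts_same = meta_c - np.cumsum(off1)[::-1]
    conf_diff = 1 + np.searchsorted(cuts_diff, y, side="right")
    conf_same = 4 - np.searchsorted(cuts_same, y, side="right")
    conf_all = np.where(respond_diff, conf_diff, conf_same)
    out: list[TrialRecord] = []
    for i, stub in enumerate(schedule):
        resp = Response.DIFFERENT if respond_diff[i] else Response.SAME
        conf = int(conf_all[i])
        out.append(
            TrialRecord(
                subject_id=stub.subject_id,
                condition=stub.condition,
                stimulus=stub.stimulus,
                size_ratio=stub.size_ratio,
                response=resp,
                confidence=conf,
                is_filler=stub.is_filler,
            )
        )
    return out


def _draw_subject_params(spec: CohortSpec, rng: np.random.Generator):
    n = spec.n_subjects
    factors = rng.standard_normal((n, 3))
    floor = spec.d_floor
    if floor is not None:
        d_control = _truncated_normal(rng, spec.d_control_mean,
                                      spec.d_control_sd, floor, n)
        d_depth = _truncated_normal(rng, spec.d_depth_mean, spec.d_depth_sd,
                                    floor, n)
    else:
        # control stays clearly above chance; depth may go below it
        d_control = _truncated_normal(rng, spec.d_control_mean,
                                      spec.d_control_sd, 0.5, n)
        d_depth = rng.normal(spec.d_depth_mean, spec.d_depth_sd, n)
    if spec.link_d_depth is not None:
        shift = factors @ np.asarray(spec.link_d_depth)
        d_depth = d_depth + shift
        if floor is not None:
            d_depth = np.maximum(d_depth, floor)
    c = rng.normal(0.0, spec.c_sd, n)
    logm = rng.normal(spec.mu_log_m_ratio, spec.sigma_log_m_ratio, n)
    if spec.link_log_m is not None:
        logm = logm + factors @ np.asarray(spec.link_log_m)
    off1 = np.exp(np.log(spec.t2_increment)
                  + spec.t2_jitter_sd * rng.standard_normal((n, 3)))
    off2 = np.exp(np.log(spec.t2_increment)
                  + spec.t2_jitter_sd * rng.standard_normal((n, 3)))
    return factors, d_control, d_depth, c, logm, off1, off2


def simulate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Simulate trials for a whole cohort.

    Returns ``(trials, manifest)`` where ``trials`` is a flat list of
    TrialRecord (n_subjects x 320) and ``manifest`` maps every true
    parameter, per subject, for recovery tests.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    factors, d_control, d_depth, c, logm, off1, off2 = _draw_subject_params(spec, rng)
    trials: list[TrialRecord] = []
    manifest: dict = {
        "subjects": [],
        "mu_log_m_ratio": spec.mu_log_m_ratio,
        "sigma_log_m_ratio": spec.sigma_log_m_ratio,
        "factors": factors,
    }
    for i in range(spec.n_subjects):
        sid = f"s{i:03d}"
        schedule = build_trial_schedule(int(rng.integers(2**31)), subject_id=sid)
        trials.extend(
            simulate_subject_trials(
                d_prime=d_control[i],
                criterion=c[i],
                log_m_ratio=logm[i],
                t2_offsets_s1=off1[i],
                t2_offsets_s2=off2[i],
                schedule=schedule,
                rng=rng,
                d_by_condition={Condition.CONTROL: d_control[i],
                                Condition.DEPTH: d_depth[i]},
            )
        )
        manifest["subjects"].append(
            {
                "subject_id": sid,
                "d_control": float(d_control[i]),
                "d_depth": float(d_depth[i]),
                "criterion": float(c[i]),
                "log_m_ratio": float(logm[i]),
                "t2_offsets_s1": off1[i].tolist(),
                "t2_offsets_s2": off2[i].tolist(),
            }
        )
    return trials, manifest


def _snap(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values / VAS_STEP) * VAS_STEP, -1.0, 1.0)


def simulate_ratings(
    spec: CohortSpec,
    factor_scores: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate rating sheets from the 3-factor model.

    Returns ``(sheets, factor_scores)``.  Pass the manifest's factor scores
    to couple ratings with an already-simulated trial cohort.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = spec.n_subjects
    if factor_scores is None:
        factor_scores = rng.standard_normal((n, 3))
    items = trait_items()
    L = np.asarray(spec.loading_matrix, dtype=float)
    latent = factor_scores @ L.T  # (n, 52) on the scored scale
    noise = spec.rating_noise_sd * rng.standard_normal((n, 52))
    scored = spec.rating_intercept + spec.rating_scale * (latent + noise)
    sheets: list[RatingSheet] = []
    for i in range(n):
        scores: dict[str, float] = {}
        classes: dict[str, ItemClass] = {}
        for j, (word, valence) in enumerate(zip(items["word"], items["valence"])):
            cls = ItemClass(valence)
            val = scored[i, j]
            raw = -val if cls == ItemClass.UNDESIRABLE else val
            scores[word] = float(_snap(np.asarray(raw)))
            classes[word] = cls
        for word in FILLER_WORDS:
            scores[word] = float(_snap(rng.uniform(-1, 1)))
            classes[word] = ItemClass.FILLER
        sheets.append(RatingSheet(f"s{i:03d}", scores, classes))
    return sheets, factor_scores


def simulate_study(spec: CohortSpec):
    """Trials + coupled ratings + truth manifest for one synthetic study."""
    rng = np.random.default_rng(spec.seed)
    trials, manifest = simulate_cohort(spec, rng)
    sheets, _ = simulate_ratings(spec, factor_scores=manifest["factors"], rng=rng)
    return trials, sheets, manifest
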