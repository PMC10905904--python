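"""Type-1 signal detection estimation: sensitivity d' and criterion C.

Under the equal-variance Gaussian SDT model the two stimulus classes project
evidence distributions N(-d'/2, 1) ("same", S1) and N(+d'/2, 1)
("different", S2); the observer answers "different" when evidence exceeds a
criterion.  With hit rate H = P("different" | S2) and false-alarm rate
F = P("different" | S1):

    d' = z(H) - z(F)          C = -(z(H) + z(F)) / 2

where z is the standard-normal quantile.  The illusion's strength is the
between-condition drop in d' (depth minus control; negative = stronger
illusion).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .core_io import ConfidenceCountTable

__all__ = ["Type1Estimates", "ConditionDiff", "compute_type1", "condition_difference"]


@dataclass(frozen=True)
class Type1Estimates:
    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    n_signal: int  # S2 ("different") trials
    n_noise: int   # S1 ("same") trials


@dataclass(frozen=True)
class ConditionDiff:
    measure: str
    value: float  # depth - control


_MEASURES = {"d_prime", "criterion_c", "hit_rate", "fa_rate"}


def _correct_extreme(p: float, n: int) -> float:
    # standard 1/(2N) replacement, applied only to exact 0/1 proportions
    if p <= 0.0:
        return 1.0 / (2 * n)
    if p >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def compute_type1(table: ConfidenceCountTable) -> Type1Estimates:
    """Estimate d' and C from a response-conditional confidence count table.

    Confidence levels are collapsed; only the type-1 response matters here.
    Extreme hit/false-alarm proportions of 0 or 1 are replaced by 1/(2N) and
    1 - 1/(2N) before the z-transform.
    """
    k = table.n_levels
    n_noise = int(round(table.n_s1))
    n_signal = int(round(table.n_s2))
    if n_noise == 0 or n_signal == 0:
        raise ValueError("empty stimulus class: cannot estimate type-1 SDT")
    fa = float(table.s1[k:].sum()) / n_noise
    hit = float(table.s2[k:].sum()) / n_signal
    fa = _correct_extreme(fa, n_noise)
    hit = _correct_extreme(hit, n_signal)
    zh, zf = norm.ppf(hit), norm.ppf(fa)
    return Type1Estimates(
        d_prime=float(zh - zf),
        criterion_c=float(-0.5 * (zh + zf)),
        hit_rate=hit,
        fa_rate=fa,
        n_signal=n_signal,
        n_noise=n_noise,
    )


def condition_difference(
    depth: Type1Estimates, control: Type1Estimates, measure: str = "d_prime"
) -> ConditionDiff:
    """Depth-minus-control difference of a named type-1 measure.

    A negative d' difference indicates a stronger illusion (depth cues degrade
    discrimination); a negative C difference, a more liberal criterion under
    the illusion.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {sorted(_MEASURES)}")
    return ConditionDiff(measure, float(getattr(depth, measure) - getattr(control, measure)))
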