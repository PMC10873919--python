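"""Sample-size and power for an unmatched case-control design.

The design question: how many animals are needed to detect a variant whose
allelic odds ratio is ``target_or``, when the event probability in the
unexposed (reference) group is ``p0``? The exposed-group probability follows
from the odds ratio, p1 = OR*p0 / (1 + p0*(OR-1)).

Power refers to the two-sided continuity-corrected chi-square test (Yates)
on the resulting 2x2 table. At the sample sizes this design produces
(single to low hundreds of animals) the rejection probability is computed
EXACTLY by enumerating the two binomial count distributions; the
closed-form two-proportion normal approximation with continuity correction
(Fleiss) provides the search starting point and the large-sample fallback.
``min_total_n`` returns the smallest total (even, for balanced arms) from
which the exact power stays at or above the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, chi2, norm

__all__ = ["PowerSpec", "derived_p1", "achieved_power", "min_total_n"]

_N_CAP = 2_000_000  # total-size search cap; reached only for OR ~ 1
_EXACT_MAX_CELLS = 4_000_000  # enumerate exactly while n1*n2 stays below this


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters: target allelic odds ratio (>1), reference-group
    event probability p0, desired power, two-sided alpha, and the
    controls-per-case ratio (1 = balanced)."""

    target_or: float
    p0: float
    power: float = 0.80
    alpha: float = 0.05
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.target_or <= 1.0:
            raise ValueError("target_or must exceed 1")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def derived_p1(spec: PowerSpec) -> float:
    """Exposed-group event probability implied by the odds ratio."""
    p1 = spec.target_or * spec.p0 / (1.0 + spec.p0 * (spec.target_or - 1.0))
    if p1 >= 1.0:
        raise ValueError(f"derived p1 = {p1} >= 1; configuration impossible")
    return p1


def _arm_sizes(spec: PowerSpec, n_total: int) -> tuple[int, int]:
    n1 = max(1, int(round(n_total / (1.0 + spec.ratio))))  # cases
    n2 = max(1, n_total - n1)  # controls
    return n1, n2


def _exact_power(p1: float, p0: float, n1: int, n2: int, alpha: float) -> float:
    """Exact rejection probability of the Yates-corrected chi-square test,
    by enumeration of the two independent binomial counts."""
    crit = chi2.ppf(1.0 - alpha, 1)
    a = np.arange(n1 + 1, dtype=float)[:, None]  # case events
    c = np.arange(n2 + 1, dtype=float)[None, :]  # control events
    b, d = n1 - a, n2 - c
    n_tot = float(n1 + n2)
    cross = np.abs(a * d - b * c) - n_tot / 2.0
    np.clip(cross, 0.0, None, out=cross)
    denom = (a + c) * (b + d) * float(n1) * float(n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n_tot * cross**2 / denom
    reject = np.where(denom > 0, stat, 0.0) > crit
    pmf1 = binom.pmf(np.arange(n1 + 1), n1, p1)
    pmf0 = binom.pmf(np.arange(n2 + 1), n2, p0)
    return float(pmf1 @ reject @ pmf0)


def _approx_power(p1: float, p0: float, n1: int, n2: int, alpha: float) -> float:
    """Fleiss-style normal approximation with continuity correction."""
    delta = abs(p1 - p0)
    pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
    z_a = norm.ppf(1.0 - alpha / 2.0)
    var_null = pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2)
    var_alt = p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n2
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    delta_c = max(delta - cc, 0.0)
    return float(norm.cdf((delta_c - z_a * math.sqrt(var_null)) / math.sqrt(var_alt)))


def achieved_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the continuity-corrected two-sided test at the given total
    sample size (cases = n_total / (1 + ratio)). Exact by enumeration up to
    a few thousand animals; normal approximation beyond."""
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    n1, n2 = _arm_sizes(spec, n_total)
    p1, p0 = derived_p1(spec), spec.p0
    if n1 * n2 <= _EXACT_MAX_CELLS:
        return _exact_power(p1, p0, n1, n2, spec.alpha)
    return _approx_power(p1, p0, n1, n2, spec.alpha)


def _fleiss_guess(spec: PowerSpec) -> int:
    """Closed-form starting point for the search (balanced-arm Fleiss with
    continuity correction, scaled to the requested ratio)."""
    p1, p0 = derived_p1(spec), spec.p0
    delta = abs(p1 - p0)
    r = spec.ratio
    pbar = (p1 + r * p0) / (1.0 + r)
    z_a = norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    m = (
        (
            z_a * math.sqrt((1.0 + 1.0 / r) * pbar * (1.0 - pbar))
            + z_b * math.sqrt(p1 * (1.0 - p1) + p0 * (1.0 - p0) / r)
        )
        / delta
    ) ** 2
    m_cc = m / 4.0 * (1.0 + math.sqrt(1.0 + 4.0 / (m * delta))) ** 2
    return max(2, int(math.ceil(m_cc * (1.0 + r) / (1.0 + r) * (1.0 + r))))


def min_total_n(spec: PowerSpec) -> int:
    """Smallest total sample size (even for balanced arms) from which power
    stays at or above the target.

    Exact power over discrete counts is mildly sawtoothed in n, so the
    returned n is the start of the contiguous block of sizes meeting the
    target that contains the upper bracket (a sustained crossing, not an
    isolated spike)."""
    step = 2 if spec.ratio == 1.0 else max(2, int(round(1.0 + spec.ratio)))
    guess = max(step, (_fleiss_guess(spec) // step) * step)
    hi = guess
    while achieved_power(spec, hi) < spec.power:
        hi += max(step, hi // 4 // step * step)
        if hi > _N_CAP:
            raise ValueError(f"no total below {_N_CAP} reaches power {spec.power}")
    n = hi
    while n - step >= step and achieved_power(spec, n - step) >= spec.power:
        n -= step
    return n
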