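"""Reliability- and correlation-precision sample-size planning.

Bonett's interval for Cronbach's alpha works on the log(1-alpha) scale
with variance 2k/((k-1)(n-2)); its half-width on the alpha scale at a
planning value ``alpha`` is

    (1 - alpha) * sinh( z * sqrt( 2k / ((k-1)(n-2)) ) ),

which shrinks in n and in alpha, so a precision requirement over a range
of plausible alphas is evaluated at the smallest (worst-case) value.
Correlation precision uses the Fisher-z interval,
tanh(atanh(r) +/- z / sqrt(n-3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PrecisionPlan",
    "bonett_halfwidth",
    "bonett_required_n",
    "fisher_halfwidth",
]


@dataclass(frozen=True)
class PrecisionPlan:
    k_items: int
    planning_alpha: float
    half_width: float
    level: float
    required_n: int


def bonett_halfwidth(planning_alpha: float, k: int, n: int, level: float = 0.95) -> float:
    """Half-width, on the alpha scale, of the Bonett interval at a planning
    alpha for k items and n respondents."""
    if n <= 2:
        raise ValueError("n must exceed 2")
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(2.0 * k / ((k - 1) * (n - 2)))
    return float((1.0 - planning_alpha) * np.sinh(z * se))


def bonett_required_n(
    k: int, planning_alpha: float, half_width: float, level: float = 0.95
) -> PrecisionPlan:
    """Smallest n whose Bonett interval half-width does not exceed the target.

    Solved in closed form on the transformed scale, then verified by direct
    search (the returned n satisfies the target and n-1 does not).
    """
    if not 0 < planning_alpha < 1:
        raise ValueError("planning_alpha must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    target = np.arcsinh(half_width / (1.0 - planning_alpha))
    n = int(np.ceil(2.0 * k * (z / target) ** 2 / (k - 1) + 2))
    n = max(n, 3)
    # direct verification against the half-width function
    while bonett_halfwidth(planning_alpha, k, n, level) > half_width:
        n += 1
    while n > 3 and bonett_halfwidth(planning_alpha, k, n - 1, level) <= half_width:
        n -= 1
    return PrecisionPlan(
        k_items=k, planning_alpha=planning_alpha,
        half_width=half_width, level=level, required_n=n,
    )


def fisher_halfwidth(r: float, n: int, level: float = 0.95) -> float:
    """Half-width on the correlation scale of the Fisher-z interval."""
    if not -1 < r < 1:
        raise ValueError("|r| must be below 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z = stats.norm.ppf(0.5 + level / 2)
    zr = np.arctanh(r)
    lo = np.tanh(zr - z / np.sqrt(n - 3))
    hi = np.tanh(zr + z / np.sqrt(n - 3))
    return float((hi - lo) / 2.0)
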