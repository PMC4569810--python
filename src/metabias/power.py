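"""Power and required sample size for two-group between-subject designs.

Uses the exact noncentral-t power function of the two-sample t-test with
noncentrality ``g * sqrt(n1 n2 / (n1 + n2))``. The headline sample-size
totals for standardized effects on the g scale are computed one-tailed at
alpha = 0.05 by default; the paper-style printed totals (e.g. 156
participants for g = 0.40 at 80% power) arise only under that convention,
and two-tailed calculation is available via ``tails="two"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import math

from scipy.stats import nct, t as t_dist

__all__ = ["PowerSpec", "power_two_sample", "required_total_n"]


@dataclass(frozen=True)
class PowerSpec:
    """Assumptions for a power calculation on the Hedges' g scale."""

    effect_g: float
    alpha: float = 0.05
    tails: Literal["one", "two"] = "one"
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.alpha < self.target_power < 1.0:
            raise ValueError(
                f"target_power must be in (alpha, 1), got {self.target_power}"
            )
        if self.tails not in ("one", "two"):
            raise ValueError(f"tails must be 'one' or 'two', got {self.tails!r}")


def power_two_sample(spec: PowerSpec, n1: int, n2: int) -> float:
    """Achieved power of the two-sample t-test at the spec's effect and alpha.

    ``df = n1 + n2 - 2``; the noncentrality parameter is
    ``g * sqrt(n1 n2 / (n1 + n2))``. For a one-tailed test the rejection
    region sits on the side of the assumed effect.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2, got n1={n1}, n2={n2}")
    df = n1 + n2 - 2
    ncp = abs(spec.effect_g) * math.sqrt(n1 * n2 / (n1 + n2))
    if spec.tails == "one":
        crit = t_dist.ppf(1.0 - spec.alpha, df)
        return float(nct.sf(crit, df, ncp))
    crit = t_dist.ppf(1.0 - spec.alpha / 2.0, df)
    return float(nct.sf(crit, df, ncp) + nct.cdf(-crit, df, ncp))


def required_total_n(spec: PowerSpec, max_total: int = 2_000_000) -> int:
    """Smallest even total N (1:1 allocation) reaching the target power.

    Power is monotone in the per-group size, so the search brackets the
    normal-approximation guess and walks to the boundary.

    Raises
    ------
    ValueError
        If the effect is zero or the target power is unreachable below
        ``max_total`` participants.
    """
    if spec.effect_g == 0:
        raise ValueError("effect_g must be nonzero for a sample-size search")
    g = abs(spec.effect_g)
    from scipy.stats import norm

    a = spec.alpha if spec.tails == "one" else spec.alpha / 2.0
    guess = 2.0 * (norm.ppf(1.0 - a) + norm.ppf(spec.target_power)) ** 2 / g**2
    n = max(2, int(guess))

    if power_two_sample(spec, n, n) >= spec.target_power:
        while n > 2 and power_two_sample(spec, n - 1, n - 1) >= spec.target_power:
            n -= 1
    else:
        while power_two_sample(spec, n, n) < spec.target_power:
            n += 1
            if 2 * n > max_total:
                raise ValueError(
                    f"target power {spec.target_power} unreachable for g={spec.effect_g} "
                    f"within a total of {max_total} participants"
                )
    return 2 * n
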