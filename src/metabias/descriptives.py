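"""Per-study confidence intervals and funnel-plot coordinates.

Wide per-study CIs whose lower bounds cluster just above zero are a textbook
signature of selective reporting; this module computes the forest-plot
summaries that make that pattern quantitative, plus the (SE, effect)
coordinates of the funnel plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import MetaDataset

__all__ = ["CiSummary", "study_cis", "funnel_coordinates", "write_funnel_csv"]


@dataclass(frozen=True)
class CiSummary:
    """Per-study CIs on the g scale plus forest-plot summary statistics."""

    lower: np.ndarray
    upper: np.ndarray
    level: float

    @property
    def per_study_ci(self) -> list[tuple[float, float]]:
        return list(zip(self.lower.tolist(), self.upper.tolist()))

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.widths))

    @property
    def mean_lower(self) -> float:
        """Element-wise mean of the lower bounds (secondary summary)."""
        return float(np.mean(self.lower))

    @property
    def mean_upper(self) -> float:
        """Element-wise mean of the upper bounds (secondary summary)."""
        return float(np.mean(self.upper))

    def frac_lower_in(self, a: float, b: float) -> float:
        """Fraction of studies whose CI lower bound lies in ``[a, b]``."""
        return float(np.mean((self.lower >= a) & (self.lower <= b)))

    def coverage_of(self, delta: float) -> float:
        """Fraction of per-study CIs containing ``delta``."""
        return float(np.mean((self.lower <= delta) & (delta <= self.upper)))


def study_cis(data: MetaDataset, level: float = 0.95) -> CiSummary:
    """Normal-approximation CIs ``g_i ± z_{(1+level)/2} * se_i`` per study.

    Per-study CIs in meta-analysis conventionally use normal quantiles, not
    t, because the SE is taken as known at the study level.
    """
    if data.k == 0:
        raise ValueError("cannot summarize an empty dataset")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 * (1.0 + level))
    g, se = data.g, data.se
    return CiSummary(lower=g - z * se, upper=g + z * se, level=level)


def funnel_coordinates(data: MetaDataset) -> list[tuple[float, float]]:
    """Funnel-plot coordinates: one ``(se, effect_g)`` pair per study, in file order.

    SE on the x-axis, effect on the y-axis. In the absence of selection the
    scatter is symmetric around the true effect at every SE; censoring of
    nonsignificant results induces a positive SE-effect correlation.
    """
    if data.k == 0:
        raise ValueError("cannot compute funnel coordinates of an empty dataset")
    return list(zip(data.se.tolist(), data.g.tolist()))


def write_funnel_csv(data: MetaDataset, path: str | Path) -> None:
    """Export plot-ready funnel coordinates (columns ``se``, ``g``)."""
    coords = funnel_coordinates(data)
    pd.DataFrame(coords, columns=["se", "g"]).to_csv(path, index=False)
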