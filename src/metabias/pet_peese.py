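"""PET-PEESE: precision-based meta-regressions correcting for publication bias.

PET (precision-effect test) regresses observed effects on their standard
errors with inverse-variance weights; its intercept is the effect of an
idealized zero-SE study and its slope indexes funnel asymmetry (it is the
weighted-least-squares form of Egger's regression test). PEESE replaces the
SE by its square, which behaves better when a true nonzero effect exists.
The conditional estimator reports the PET intercept unless that intercept is
significant, in which case it reports the PEESE intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .data_model import MetaDataset

__all__ = [
    "WlsFit",
    "PetPeeseResult",
    "CollinearityError",
    "wls_fit",
    "pet_fit",
    "peese_fit",
    "pet_peese",
    "inverse_variance_mean",
]


class CollinearityError(ValueError):
    """The predictor is constant, so slope and intercept are not identified."""


@dataclass(frozen=True)
class WlsFit:
    """A two-parameter weighted least-squares fit ``y = b0 + b1 x``.

    Weights are treated as known up to a proportionality constant; the
    residual scale is estimated from the weighted residual mean square
    (classical WLS), so inference is invariant to rescaling all weights.
    CIs and p-values use t quantiles with ``df = k - 2``.
    """

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    p_b0: float
    p_b1: float
    ci_b0: tuple[float, float]
    ci_b1: tuple[float, float]
    df: int


@dataclass(frozen=True)
class PetPeeseResult:
    """Both fits plus the conditional bias-corrected estimate."""

    pet: WlsFit
    peese: WlsFit
    selected_model: Literal["PET", "PEESE"]
    estimate: float
    alpha_gate: float
    publication_bias_flag: bool


def wls_fit(
    y: Sequence[float],
    x: Sequence[float],
    w: Sequence[float],
    ci_level: float = 0.95,
) -> WlsFit:
    """Weighted least squares of ``y`` on ``x`` with weights ``w``.

    Minimizes sum of ``w_i (y_i - b0 - b1 x_i)^2``; see :class:`WlsFit` for
    the inference conventions.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(y) == len(x) == len(w)):
        raise ValueError("y, x, w must have equal lengths")
    if len(y) < 3:
        raise ValueError(f"need at least 3 studies for a two-parameter fit, got {len(y)}")
    if np.any(w <= 0):
        raise ValueError("all weights must be > 0")
    if np.ptp(x) == 0:
        raise CollinearityError("predictor is constant across studies")

    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    ci = res.conf_int(alpha=1.0 - ci_level)
    return WlsFit(
        b0=float(res.params[0]),
        b1=float(res.params[1]),
        se_b0=float(res.bse[0]),
        se_b1=float(res.bse[1]),
        p_b0=float(res.pvalues[0]),
        p_b1=float(res.pvalues[1]),
        ci_b0=(float(ci[0, 0]), float(ci[0, 1])),
        ci_b1=(float(ci[1, 0]), float(ci[1, 1])),
        df=int(res.df_resid),
    )


def pet_fit(data: MetaDataset, ci_level: float = 0.95) -> WlsFit:
    """PET: regress effects on SE, weights ``1/se^2``.

    The intercept estimates the publication-bias-corrected effect; a
    significantly positive slope signals funnel asymmetry (Egger's test).
    """
    se = data.se
    if data.k >= 1 and np.ptp(se) == 0:
        raise CollinearityError("all studies have identical SEs; PET is not identified")
    return wls_fit(data.g, se, 1.0 / se**2, ci_level=ci_level)


def peese_fit(data: MetaDataset, ci_level: float = 0.95) -> WlsFit:
    """PEESE: regress effects on squared SE, weights ``1/se^2``."""
    se = data.se
    if data.k >= 1 and np.ptp(se) == 0:
        raise CollinearityError("all studies have identical SEs; PEESE is not identified")
    return wls_fit(data.g, se**2, 1.0 / se**2, ci_level=ci_level)


def pet_peese(data: MetaDataset, alpha_gate: float = 0.05) -> PetPeeseResult:
    """Conditional PET-PEESE estimate of the bias-corrected true effect.

    Report the PET intercept when it is non-significant at ``alpha_gate``
    (two-sided), otherwise the PEESE intercept. ``publication_bias_flag`` is
    True when the PET slope is significantly positive.
    """
    pet = pet_fit(data)
    peese = peese_fit(data)
    if pet.p_b0 >= alpha_gate:
        selected: Literal["PET", "PEESE"] = "PET"
        estimate = pet.b0
    else:
        selected = "PEESE"
        estimate = peese.b0
    return PetPeeseResult(
        pet=pet,
        peese=peese,
        selected_model=selected,
        estimate=estimate,
        alpha_gate=alpha_gate,
        publication_bias_flag=bool(pet.p_b1 < alpha_gate and pet.b1 > 0),
    )


def inverse_variance_mean(data: MetaDataset) -> tuple[float, float]:
    """Fixed-effect (inverse-variance weighted) mean and its SE.

    The naive pooled estimate that publication-bias corrections are compared
    against.
    """
    if data.k == 0:
        raise ValueError("cannot pool an empty dataset")
    w = 1.0 / data.se**2
    mean = float(np.sum(w * data.g) / np.sum(w))
    return mean, float(np.sqrt(1.0 / np.sum(w)))
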