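"""Synthetic meta-analytic literatures with a known truth and a file drawer.

The generator produces two-group studies one candidate at a time: draw
per-group sample sizes, draw the study-level true effect (optionally
heterogeneous around the grand mean), draw the observed effect from its
sampling distribution, then publish the study with probability given by the
selection model's weight function of the study's p-value. Generation
continues until the requested number of published studies has accumulated,
so the file-drawer size (candidates minus published) is part of the output.

By default the selection gate is directional: only significant results in
the hypothesized (positive) direction count as significant, and wrong-signed
results are treated as maximally nonsignificant (selection p-value 1). This
mirrors how a literature testing a directional hypothesis censors itself —
and it is what produces the classic funnel asymmetry: under extreme
censoring with a true effect of zero, published effects are all positive and
roughly proportional to their SE. Sign-symmetric censoring is available with
``direction="both"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bbc import BiasModel, no_bias, two_sided_p
from .data_model import MetaDataset, StudyRecord, se_from_groups

__all__ = ["SimConfig", "SimulationResult", "simulate_study", "generate_literature"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one synthetic literature.

    Per-group sample sizes are integer log-uniform on
    ``[n_min, n_max]`` (default [10, 100]), which at small effects spreads
    the SEs over roughly 0.14-0.45 — the x-range of a typical funnel plot.
    """

    k_published: int = 92
    delta: float = 0.0
    tau: float = 0.0
    selection: BiasModel = field(default_factory=no_bias)
    nuisance: float | None = None
    n_min: int = 10
    n_max: int = 100
    direction: Literal["positive", "both"] = "positive"
    seed: int = 0
    max_attempts: int = 1_000_000
    label: str = "simulated"

    def __post_init__(self) -> None:
        if self.k_published < 1:
            raise ValueError("k_published must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 2 <= self.n_min <= self.n_max:
            raise ValueError("need 2 <= n_min <= n_max")
        if self.selection.has_nuisance and self.nuisance is None:
            raise ValueError(f"selection model {self.selection.name} needs a nuisance value")


@dataclass(frozen=True)
class SimulationResult:
    """A generated literature plus file-drawer accounting."""

    dataset: MetaDataset
    n_candidates: int

    @property
    def acceptance_rate(self) -> float:
        return self.dataset.k / self.n_candidates


def _draw_group_size(rng: np.random.Generator, n_min: int, n_max: int) -> int:
    u = rng.uniform(math.log(n_min), math.log(n_max))
    return int(min(max(round(math.exp(u)), n_min), n_max))


def simulate_study(
    delta_i: float,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    study_id: str = "sim",
    subset: str | None = None,
) -> StudyRecord:
    """Draw one study's observed effect.

    The sampling SE is computed from the group sizes at the study's true
    effect, and the observed g is drawn from ``Normal(delta_i, se^2)``; the
    recorded SE is that sampling SE (the analyses treat it as known).
    """
    se = se_from_groups(delta_i, n1, n2)
    g = float(rng.normal(delta_i, se))
    return StudyRecord(study_id=study_id, effect_g=g, se=se, n1=n1, n2=n2, subset=subset)


def _selection_p(g: float, se: float, direction: str) -> float:
    p = two_sided_p(g, se)
    if direction == "positive" and g <= 0:
        return 1.0
    return p


def generate_literature(config: SimConfig) -> SimulationResult:
    """Generate candidate studies until ``k_published`` survive selection.

    Each candidate's true effect is drawn from ``Normal(delta, tau^2)``; the
    published flag is a Bernoulli draw with probability
    ``selection.weight(p_sel)`` where ``p_sel`` is the (possibly
    directional) selection p-value. Identical configs (including the seed)
    produce identical output.

    Raises
    ------
    RuntimeError
        If ``max_attempts`` candidates are exhausted first; the message
        reports the empirical acceptance rate.
    """
    rng = np.random.default_rng(config.seed)
    records: list[StudyRecord] = []
    n_candidates = 0
    while len(records) < config.k_published:
        if n_candidates >= config.max_attempts:
            raise RuntimeError(
                f"max_attempts={config.max_attempts} exhausted with "
                f"{len(records)}/{config.k_published} published "
                f"(acceptance rate {len(records) / n_candidates:.2e})"
            )
        n_candidates += 1
        n1 = _draw_group_size(rng, config.n_min, config.n_max)
        n2 = _draw_group_size(rng, config.n_min, config.n_max)
        delta_i = config.delta if config.tau == 0 else float(rng.normal(config.delta, config.tau))
        rec = simulate_study(delta_i, n1, n2, rng, study_id=f"study_{n_candidates:06d}")
        p_sel = _selection_p(rec.effect_g, rec.se, config.direction)
        w = float(config.selection.weight(p_sel, config.nuisance))
        if rng.uniform() < w:
            records.append(
                StudyRecord(
                    study_id=rec.study_id,
                    effect_g=rec.effect_g,
                    se=rec.se,
                    n1=rec.n1,
                    n2=rec.n2,
                    published_flag=True,
                )
            )
    dataset = MetaDataset(tuple(records), label=config.label)
    return SimulationResult(dataset=dataset, n_candidates=n_candidates)
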