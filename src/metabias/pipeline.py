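"""Full-analysis driver: descriptives, PET-PEESE and Bayesian bias correction
on one dataset, aggregated into a serializable report.

This layer never computes anything itself; every number in the report is the
output of exactly one library call, so CLI output and library output agree
by construction.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .bbc import BbcResult, QuadratureSpec, SpikeSlabPrior, bbc_analyze
from .data_model import MetaDataset, read_meta_csv
from .descriptives import CiSummary, study_cis
from .pet_peese import PetPeeseResult, inverse_variance_mean, pet_peese

__all__ = ["AnalysisConfig", "RunReport", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the full pipeline; every default is echoed in the report."""

    subset: str | None = None
    ci_level: float = 0.95
    alpha_gate: float = 0.05
    p_null: float = 0.5
    slab_sd: float = 2.0 / 3.0
    n_delta: int = 1201
    n_nuisance: int = 101

    def spike_slab(self) -> SpikeSlabPrior:
        return SpikeSlabPrior(p_null=self.p_null, slab_sd=self.slab_sd)

    def quadrature(self) -> QuadratureSpec:
        return QuadratureSpec(n_delta=self.n_delta, n_nuisance=self.n_nuisance)


@dataclass(frozen=True)
class RunReport:
    """Aggregated results of one full analysis run."""

    input_label: str
    k: int
    config: AnalysisConfig
    ci: CiSummary
    pooled_mean: float
    pooled_se: float
    pet_peese: PetPeeseResult
    bbc: BbcResult
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.UTC).isoformat())

    def to_dict(self, include_timestamp: bool = True) -> dict[str, Any]:
        pp = self.pet_peese
        d: dict[str, Any] = {
            "input": {"label": self.input_label, "k": self.k, "subset": self.config.subset},
            "config": {
                "ci_level": self.config.ci_level,
                "alpha_gate": self.config.alpha_gate,
                "p_null": self.config.p_null,
                "slab_sd": self.config.slab_sd,
                "n_delta": self.config.n_delta,
                "n_nuisance": self.config.n_nuisance,
            },
            "descriptives": {
                "mean_ci_width": self.ci.mean_width,
                "mean_ci_lower": self.ci.mean_lower,
                "mean_ci_upper": self.ci.mean_upper,
                "frac_lower_in_0_0.1": self.ci.frac_lower_in(0.0, 0.1),
                "pooled_mean": self.pooled_mean,
                "pooled_se": self.pooled_se,
            },
            "pet_peese": {
                "pet": _wls_dict(pp.pet),
                "peese": _wls_dict(pp.peese),
                "selected_model": pp.selected_model,
                "estimate": pp.estimate,
                "alpha_gate": pp.alpha_gate,
                "publication_bias_flag": pp.publication_bias_flag,
            },
            "bbc": {
                "scenarios": list(self.bbc.scenario_labels),
                "prior_probs": self.bbc.prior_probs.tolist(),
                "posterior_probs": self.bbc.posterior_probs.tolist(),
                "bf_01": self.bbc.bf_01,
                "point_mass_at_zero": self.bbc.point_mass_at_zero,
                "posterior_mean_nonnull": self.bbc.posterior_mean_nonnull,
                "modal_scenario": self.bbc.modal_scenario,
            },
            "version": self.version,
        }
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return d

    def to_json(self, include_timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(include_timestamp=include_timestamp), indent=2, sort_keys=True)


def _wls_dict(fit) -> dict[str, Any]:
    return {
        "b0": fit.b0,
        "b1": fit.b1,
        "se_b0": fit.se_b0,
        "se_b1": fit.se_b1,
        "p_b0": fit.p_b0,
        "p_b1": fit.p_b1,
        "ci_b0": list(fit.ci_b0),
        "ci_b1": list(fit.ci_b1),
        "df": fit.df,
    }


def run_full_analysis(
    source: str | Path | MetaDataset, config: AnalysisConfig = AnalysisConfig()
) -> RunReport:
    """Run descriptives, PET-PEESE and BBC on one dataset.

    ``source`` may be a CSV path or an in-memory :class:`MetaDataset`.
    """
    data = source if isinstance(source, MetaDataset) else read_meta_csv(source)
    if config.subset:
        data = data.subset(config.subset)
    ci = study_cis(data, level=config.ci_level)
    pooled_mean, pooled_se = inverse_variance_mean(data)
    pp = pet_peese(data, alpha_gate=config.alpha_gate)
    bbc = bbc_analyze(data, prior=config.spike_slab(), quad=config.quadrature())
    return RunReport(
        input_label=data.label,
        k=data.k,
        config=config,
        ci=ci,
        pooled_mean=pooled_mean,
        pooled_se=pooled_se,
        pet_peese=pp,
        bbc=bbc,
    )
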