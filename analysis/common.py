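"""Shared setup for the numbered analysis drivers.

Defines the three study conditions every driver works from — an unbiased
literature with a real effect, a pure-publication-bias literature with no
effect, and a realistically censored literature with a real effect — and
regenerates them deterministically when the CSVs are missing.
"""

from __future__ import annotations

from pathlib import Path

from metabias import (
    MetaDataset,
    SimConfig,
    constant_rate,
    extreme_censoring,
    generate_literature,
    no_bias,
    read_meta_csv,
    write_meta_csv,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONDITIONS: dict[str, SimConfig] = {
    # no selection, true effect 0.3: what an honest literature looks like
    "unbiased_d03": SimConfig(
        k_published=92, delta=0.3, selection=no_bias(), seed=101, label="unbiased_d03"
    ),
    # extreme censoring, no true effect: publication bias manufactures an effect
    "censored_d00": SimConfig(
        k_published=92, delta=0.0, selection=extreme_censoring(), seed=102, label="censored_d00"
    ),
    # constant-rate censoring (pi = 0.2), true effect 0.3: bias plus signal
    "censored_d03": SimConfig(
        k_published=92, delta=0.3, selection=constant_rate(), nuisance=0.2, seed=103,
        label="censored_d03",
    ),
}


def literature_csv(name: str) -> Path:
    return RESULTS / f"literature_{name}.csv"


def load_or_generate(name: str) -> MetaDataset:
    """Load a study-condition literature, generating it if needed."""
    path = literature_csv(name)
    if path.exists():
        return read_meta_csv(path)
    RESULTS.mkdir(exist_ok=True)
    ds = generate_literature(CONDITIONS[name]).dataset
    write_meta_csv(ds, path)
    return ds
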