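#!/usr/bin/env python
"""Bayesian bias correction on each study condition.

For every condition: the eight-scenario posterior (four selection processes
x effect/no-effect), the Bayes factor for the null, and the model-averaged
posterior for the effect. Writes the scenario tables and the posterior
density of the bias-plus-signal condition.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import CONDITIONS, RESULTS, load_or_generate

from metabias import bbc_analyze

tables = []
for name in CONDITIONS:
    ds = load_or_generate(name)
    res = bbc_analyze(ds)
    tab = res.scenario_table()
    tab.insert(0, "condition", name)
    tables.append(tab)
    print(f"{name}:")
    print(
        "  posterior over scenarios: "
        + ", ".join(
            f"{lab}={p:.3f}" for lab, p in zip(res.scenario_labels, res.posterior_probs)
        )
    )
    print(
        f"  modal scenario {res.modal_scenario}; BF01 = {res.bf_01:.3g}; "
        f"P(delta = 0 | data) = {res.point_mass_at_zero:.4f}; "
        f"E[delta | effect, data] = {res.posterior_mean_nonnull:+.3f}"
    )
    if name == "censored_d03":
        pd.DataFrame(
            {"delta": res.delta_grid, "density": res.posterior_density}
        ).to_csv(RESULTS / "04_posterior_density_censored_d03.csv", index=False)

pd.concat(tables).to_csv(RESULTS / "04_bbc_scenarios.csv", index=False)
print(
    "\nWith signal plus censoring the posterior concentrates on the "
    "constant-rate selection process with a real effect, and the point mass "
    "at zero vanishes; under pure bias the no-effect scenarios dominate."
)
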