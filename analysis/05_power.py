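#!/usr/bin/env python
"""Required sample sizes for adequately powered replication studies.

Computes the total two-group N needed for 80% power at the literature's
optimistic (uncorrected) effect estimate g = 0.40 and at the bias-corrected
prosocial estimate g = 0.18, plus the power a typical small study actually
had under each assumption.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS

from metabias import PowerSpec, power_two_sample, required_total_n

RESULTS.mkdir(exist_ok=True)
rows = []
for label, g in (("uncorrected_overall", 0.40), ("bias_corrected_prosocial", 0.18)):
    spec = PowerSpec(effect_g=g, alpha=0.05, tails="one", target_power=0.80)
    total = required_total_n(spec)
    achieved = power_two_sample(spec, total // 2, total // 2)
    typical = power_two_sample(spec, 25, 25)  # a common per-group size in the field
    rows.append(
        {
            "assumed_g": g,
            "scenario": label,
            "required_total_n": total,
            "power_at_required_n": round(achieved, 4),
            "power_at_n25_per_group": round(typical, 3),
        }
    )
    print(
        f"g = {g:.2f} ({label}): total N = {total} for 80% power "
        f"(achieved {achieved:.3f}); a 25-per-group study had power {typical:.2f}"
    )

pd.DataFrame(rows).to_csv(RESULTS / "05_power.csv", index=False)
print(
    "\nOne-tailed alpha = 0.05, 1:1 allocation, exact noncentral-t power. "
    "Typical studies in the simulated literatures are severely underpowered "
    "for either effect size."
)
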