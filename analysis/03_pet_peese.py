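#!/usr/bin/env python
"""Conditional PET-PEESE on each study condition, against the naive pooled mean.

The headline comparison: under pure publication bias (no true effect) the
naive inverse-variance mean is grossly inflated while the PET intercept sits
at zero with a large significant slope — the funnel-asymmetry signature.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import CONDITIONS, RESULTS, load_or_generate

from metabias import inverse_variance_mean, pet_peese

rows = []
for name in CONDITIONS:
    ds = load_or_generate(name)
    naive, _ = inverse_variance_mean(ds)
    res = pet_peese(ds, alpha_gate=0.05)
    rows.append(
        {
            "condition": name,
            "true_delta": CONDITIONS[name].delta,
            "naive_mean": round(naive, 3),
            "pet_b0": round(res.pet.b0, 3),
            "pet_b0_p": round(res.pet.p_b0, 3),
            "pet_b1": round(res.pet.b1, 3),
            "pet_b1_p": round(res.pet.p_b1, 4),
            "peese_b0": round(res.peese.b0, 3),
            "selected": res.selected_model,
            "estimate": round(res.estimate, 3),
            "bias_flag": res.publication_bias_flag,
        }
    )
    print(
        f"{name}: naive mean {naive:+.3f} | PET b0 {res.pet.b0:+.3f} "
        f"(p={res.pet.p_b0:.3f}), b1 {res.pet.b1:+.3f} (p={res.pet.p_b1:.4f}) "
        f"| selected {res.selected_model} -> estimate {res.estimate:+.3f} "
        f"| bias flag {res.publication_bias_flag}"
    )

pd.DataFrame(rows).to_csv(RESULTS / "03_pet_peese.csv", index=False)
print(
    "\nUnder censoring with no effect the conditional estimate collapses to "
    "~0 while the naive mean does not; with a genuine large signal the rule "
    "switches to PEESE."
)
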