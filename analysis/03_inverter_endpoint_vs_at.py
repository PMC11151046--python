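#!/usr/bin/env python
"""Inverter circuit: the NOT-gate reverses the endpoint-At correlation.

The constitutive beta_to_omega stage ramps from t=0 until the amplified
alpha, through the killer template, floods the system with the pT_beta
pseudotemplate and deactivates beta.  The sooner the amplification, the
lower the plateau: the endpoint is now positively correlated with At.
Writes results/inverter_endpoint_at.csv and results/inverter_regression.json.
"""

import json
from pathlib import Path

import pandas as pd

from celia.studies import endpoint_at_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = endpoint_at_study("inverter", n_conditions=12)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame({"at_min": res.at, "endpoint": res.endpoint}).to_csv(
        OUT / "inverter_endpoint_at.csv", index=False
    )
    summary = {"slope_signal_per_min": res.slope, "intercept_signal": res.intercept, "r2": res.r2}
    (OUT / "inverter_regression.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"At range {res.at.min():.0f}-{res.at.max():.0f} min over 12 conditions")
    print(f"endpoint vs At: slope {res.slope:.4f} signal/min (positive), R^2 = {res.r2:.4f}")


if __name__ == "__main__":
    main()
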