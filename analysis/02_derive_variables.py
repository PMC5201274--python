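#!/usr/bin/env python
"""Score the questionnaire instruments into analysis variables.

Builds the demand/support composites (1-4), the six-item depressive-symptom
sum (0-24) and the 0-4 unhealthy-behavior count from the cohort produced by
01_simulate_cohort.py, and writes the scoring rules used (YAML) for audit.

Writes results/derived.csv and results/derivation_rules.yaml.
"""

from pathlib import Path

import pandas as pd

from panelmediate.derive import DerivationRules
from panelmediate.pipeline import BEHAVIORS

OUT = Path("results")


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    out = cohort[["sid", "age", "sex", "single", "edu"]].copy()
    for w in range(1, 5):
        out[f"demands_w{w}"] = cohort[[f"dem{j}_w{w}" for j in range(1, 5)]].mean(axis=1)
        out[f"support_w{w}"] = cohort[[f"sup{j}_w{w}" for j in range(1, 6)]].mean(axis=1)
        out[f"depscore_w{w}"] = cohort[[f"dep{j}_w{w}" for j in range(1, 7)]].sum(axis=1)
        for b in BEHAVIORS:
            out[f"{b}_w{w}"] = cohort[f"{b}_w{w}"]
        out[f"nbehav_w{w}"] = out[[f"{b}_w{w}" for b in BEHAVIORS]].sum(axis=1)
    out.to_csv(OUT / "derived.csv", index=False)
    (OUT / "derivation_rules.yaml").write_text(DerivationRules().to_yaml())

    print(f"derived variables for {len(out)} subjects")
    for w in (1, 4):
        print(f"  wave {w}: demands {out[f'demands_w{w}'].mean():.2f}, "
              f"support {out[f'support_w{w}'].mean():.2f}, "
              f"depressive {out[f'depscore_w{w}'].mean():.1f}, "
              f"behavior count {out[f'nbehav_w{w}'].mean():.2f}")
    print("score ranges: demands/support 1-4, depressive 0-24, count 0-4")


if __name__ == "__main__":
    main()
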