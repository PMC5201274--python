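#!/usr/bin/env python
"""Sensitivity analyses: variant operationalizations and adjustment.

Re-runs screening and mediation with baseline covariate adjustment (age,
sex, civil status, education) switched on.  Covariates enter as exogenous
predictors of the wave-1 constructs only, so in the recursive
observed-score route the lag-1 path coefficients — which condition on the
previous wave — are exactly invariant to adjustment; the run verifies that
the pipeline reproduces this, the strong form of "results not markedly
different after adjustment".  Variant behavior operationalizations
(any-smoking, irregular activity) coincide with the main definitions on
this cohort because the generator emits the binary indicators directly.

Writes results/sensitivity.csv.
"""

from pathlib import Path

from panelmediate.pipeline import BEHAVIORS, RunConfig, sensitivity_suite

OUT = Path("results")
SEED = 11


def main() -> None:
    rc = RunConfig(csv_path=str(OUT / "derived.csv"), exposure="sup",
                   mediators=BEHAVIORS, outcome="dep", route="composite",
                   n_draws=5000, seed=SEED)
    table = sensitivity_suite(rc, variants={
        "main": {},
        "covariate-adjusted": {"covariate_adjustment": True},
    })
    table.to_csv(OUT / "sensitivity.csv", index=False)
    print(table.round(5).to_string(index=False))
    wide = table.pivot(index="mediator", columns="variant", values="indirect")
    shift = (wide["covariate-adjusted"] - wide["main"]).abs().max()
    print(f"\nmax |indirect effect shift| under adjustment: {shift:.5f} "
          "(exact invariance expected in the recursive observed-score route)")


if __name__ == "__main__":
    main()
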