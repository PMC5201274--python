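# panelmediate

Longitudinal mediation analysis for multi-wave occupational-health panels:
autoregressive cross-lagged structural equation models linking psychosocial
work characteristics (demands, social support), dichotomous unhealthy
behaviors (smoking, excessive drinking, unhealthy diet, physical
inactivity) and depressive symptoms, with overall total/direct/indirect
effects computed by the product-of-coefficients method and tested with
Monte Carlo simulation confidence intervals.

The package is written for epidemiologists and biostatisticians who want a
tested, reproducible implementation of this analysis chain — including a
synthetic cohort generator with known true effects, so every stage carries
a parameter-recovery and calibration test without access to restricted
cohort data.

## The model

Let X_t, M_t, Y_t denote the latent exposure (work characteristic),
mediator (behavior propensity) and outcome (depressive symptoms) at
analysis waves t = 1..4 (biennial measurements).  The structural model is
a lag-1 autoregressive cross-lagged system with time-specific free paths

    Z_{t+1} = B_t Z_t + ζ_{t+1},        Z_t = (X_t, M_t, Y_t)',

measured through ordinal questionnaire items under a probit latent-response
model (binary behaviors are thresholded propensities).  Two estimation
routes are provided:

* **wls** — thresholds and a polychoric/tetrachoric/polyserial correlation
  matrix are estimated first, then the moment structure is fitted by
  diagonally weighted least squares with sandwich standard errors and
  mean-scaled test statistics (categorical-faithful);
* **ml** — normal-theory maximum likelihood, with full-information
  (casewise) likelihood over missingness patterns (missingness-faithful).
  Recursive path models with observed constructs are solved exactly in
  closed form.

With standardized coefficients β̂ on the edges of the (construct, wave)
graph, the overall effects of X at wave 1 on Y at wave 4 are sums over
forward paths of products of edge coefficients:

    indirect = Σ_{paths through ≥1 M node} Π β̂_edge
    direct   = Σ_{paths avoiding M}        Π β̂_edge
    total    = direct + indirect,   proportion mediated = indirect / total.

Percentile confidence intervals come from 20,000 draws of the coefficient
vector from N(β̂, V̂).  Mediation models are only fitted for behaviors that
pass a screening gate: at least one significant exposure→behavior path AND
one significant behavior→depression path in bivariate cross-lagged models
(two-sided α = 0.05 per path).

## Worked example

```python
from panelmediate import (RunConfig, run_pipeline, three_construct_config,
                          true_effects)

cfg = three_construct_config(
    n_subjects=1500, seed=5,
    crosslag={("X", "M"): 0.25, ("M", "Y"): 0.25, ("X", "Y"): 0.15})
res = run_pipeline(RunConfig(sim_config=cfg, exposure="X", mediators=("M",),
                             outcome="Y", route="composite",
                             n_draws=20000, seed=3))
print(res.gates["M"].reason)
print(res.report[["model", "total", "indirect",
                  "indirect_lo", "indirect_hi"]].round(4))
print(true_effects(cfg, "X", "Y", ["M"]))
```

prints

```
3/3 exposure->mediator and 3/3 mediator->outcome paths significant
   model   total  indirect  indirect_lo  indirect_hi
0  X-M-Y  0.2034    0.0948        0.079       0.1119
EffectDecomposition(total=0.20625..., direct=0.1125, indirect=0.09375..., ...)
```

i.e. the gate opens, the estimated overall effect of X@wave1 on Y@wave4 is
0.203 of which 0.095 flows through M (the generating truth is 0.206 and
0.094), and the 95% Monte Carlo interval for the indirect effect excludes
zero.

The numbered scripts under `analysis/` run the full study-shaped analysis
on a synthetic cohort calibrated to realistic baseline marginals (demands
2.6, support 3.1 on the 1–4 scale; smoking 8.3%, excessive drinking 5.2%,
unhealthy diet 6.8%, inactivity 16.1%): simulate, derive, screen/gate,
mediate, sensitivity, and simulation calibration.  Run them in order from
the repository root:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_derive_variables.py
...
```

A thin CLI wraps the same pipeline: `panelmediate run --simulate --seed 1`.

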