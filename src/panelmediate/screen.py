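"""Bivariate cross-lagged screening and the mediation gating rule.

For each exposure-behavior and behavior-outcome pair, a two-construct
autoregressive cross-lagged model is fitted with both directions freed at
every transition.  A mediation model is fitted only when the screens show
at least one significant exposure-to-mediator path AND at least one
significant mediator-to-outcome path (two-sided alpha = 0.05 per path, no
multiplicity correction — deliberately liberal screening).  Reverse-
direction paths are always estimated and reported but never enter the
gating decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .fit import FitResult, fit
from .model import ModelSpec, crosslagged_spec

__all__ = ["ScreeningOptions", "ScreeningResult", "GateDecision",
           "fit_bivariate", "gate_mediation"]

ALPHA = 0.05


@dataclass(frozen=True)
class ScreeningOptions:
    """Estimation options shared by both screens of a mediator.

    ``route`` selects how constructs are measured: "latent-wls" fits the
    full ordinal measurement model by DWLS, "latent-ml" treats items as
    continuous, and "composite" fits the observed-variable path model on
    one score column per construct (fast, used for simulation studies).
    """

    route: str = "latent-wls"
    covariates: Tuple[str, ...] = ()
    continuous_covariates: Tuple[str, ...] = ("age",)
    alpha: float = ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.route not in ("latent-wls", "latent-ml", "composite"):
            raise ValueError(f"unknown screening route {self.route!r}")


@dataclass
class ScreeningResult:
    """Per-transition cross-lagged estimates of one construct pair."""

    pair: Tuple[str, str]  # (A, B): A->B is the hypothesized direction
    table: pd.DataFrame    # transition, direction, est, se, p, std, significant
    fit: FitResult
    alpha: float = ALPHA

    @property
    def n_transitions(self) -> int:
        return self.fit.n_waves - 1

    def significant_forward(self) -> int:
        t = self.table
        return int(t.loc[t.direction == "forward", "significant"].sum())

    def significant_reverse(self) -> int:
        t = self.table
        return int(t.loc[t.direction == "reverse", "significant"].sum())

    @property
    def any_forward_significant(self) -> bool:
        return self.significant_forward() > 0


@dataclass
class GateDecision:
    open: bool
    mediator: str
    reason: str
    exposure_leg_significant: int = 0
    outcome_leg_significant: int = 0


def _spec_for_pair(pair_items: Dict[str, Sequence[Sequence[str]]],
                   options: ScreeningOptions) -> ModelSpec:
    estimator = "wls" if options.route == "latent-wls" else "ml"
    return crosslagged_spec(
        pair_items,
        cross_pairs="all",
        error_covariances=options.route != "composite",
        covariates=options.covariates,
        estimator=estimator,
        continuous_columns=options.continuous_covariates,
    )


def fit_bivariate(pair: Tuple[str, str],
                  construct_items: Dict[str, Sequence[Sequence[str]]],
                  data: pd.DataFrame,
                  options: ScreeningOptions = ScreeningOptions()) -> ScreeningResult:
    """Fit the two-construct cross-lagged model for (A, B) and flag the
    significant paths per transition in both directions."""
    a, b = pair
    for name in pair:
        if name not in construct_items:
            raise ValueError(f"no items declared for construct {name!r}")
    pair_items = {a: construct_items[a], b: construct_items[b]}
    spec = _spec_for_pair(pair_items, options)
    res = fit(spec, data, seed=options.seed)
    rows: List[dict] = []
    for row in res.structural.itertuples():
        if row.src_construct == row.dst_construct:
            continue
        direction = "forward" if (row.src_construct, row.dst_construct) == (a, b) \
            else "reverse"
        rows.append({
            "transition": f"{row.src_wave}->{row.dst_wave}",
            "direction": direction,
            "src": row.src_construct, "dst": row.dst_construct,
            "est": row.est, "se": row.se, "p": row.p, "std": row.std,
            "significant": bool(row.p < options.alpha),
            "star": "*" if row.p < options.alpha else "",
        })
    table = pd.DataFrame(rows)
    return ScreeningResult(pair=pair, table=table, fit=res, alpha=options.alpha)


def gate_mediation(exposure_screen: ScreeningResult,
                   outcome_screen: ScreeningResult) -> GateDecision:
    """Mediation models are fitted only when both legs carry at least one
    significant forward path; the decision is a pure function of the two
    significance-flag sets."""
    mediator = exposure_screen.pair[1]
    if outcome_screen.pair[0] != mediator:
        raise ValueError("screens do not share a mediator construct")
    k_exp = exposure_screen.significant_forward()
    k_out = outcome_screen.significant_forward()
    if k_exp > 0 and k_out > 0:
        return GateDecision(True, mediator,
                            f"{k_exp}/{exposure_screen.n_transitions} exposure->mediator and "
                            f"{k_out}/{outcome_screen.n_transitions} mediator->outcome "
                            "paths significant", k_exp, k_out)
    missing = []
    if k_exp == 0:
        missing.append("exposure->mediator")
    if k_out == 0:
        missing.append("mediator->outcome")
    return GateDecision(False, mediator,
                        "no significant " + " or ".join(missing) + " path; "
                        "no mediation model fitted", k_exp, k_out)
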