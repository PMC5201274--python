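"""End-to-end orchestration: simulate/load -> derive -> screen -> gate ->
mediate -> report, with reproducibility metadata.

Each stage writes its table under the configured output directory and a
manifest JSON records the configuration, seeds, per-stage timing,
convergence diagnostics and warnings, sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import derive as derive_mod
from .fit import fit
from .mediation import (EffectDecomposition, StructuralGraph, mediation_report,
                        monte_carlo_ci)
from .model import crosslagged_spec
from .screen import GateDecision, ScreeningOptions, ScreeningResult, \
    fit_bivariate, gate_mediation
from .simulate import SimConfig, generate_panel

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sensitivity_suite",
           "construct_items_for"]

BEHAVIORS = ("smoke", "alco", "diet", "inact")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``csv_path`` / ``sim_config`` supplies the panel.
    ``route`` is the screening/mediation estimation route ("composite",
    "latent-ml" or "latent-wls"); ``exposure`` is the work characteristic
    ("sup" or "dem"); mediators default to the four behaviors plus the
    0-4 count analogue when present.
    """

    csv_path: str | None = None
    sim_config: SimConfig | None = None
    exposure: str = "sup"
    mediators: Tuple[str, ...] = BEHAVIORS
    outcome: str = "dep"
    route: str = "composite"
    covariate_adjustment: bool = False
    covariates: Tuple[str, ...] = ("sex", "age", "single", "edu")
    smoking_variant: str = "daily"
    inactivity_variant: str = "main"
    n_draws: int = 20_000
    level: float = 0.95
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.csv_path is None) == (self.sim_config is None):
            raise ValueError("exactly one input source (csv_path or sim_config)")
        if not self.mediators:
            raise ValueError("mediator set must be non-empty")


@dataclass
class PipelineResult:
    data: pd.DataFrame
    screens: Dict[str, Tuple[ScreeningResult, ScreeningResult]]
    gates: Dict[str, GateDecision]
    decompositions: Dict[str, EffectDecomposition]
    report: pd.DataFrame
    manifest: dict

    @property
    def gated_out(self) -> List[str]:
        return [m for m, g in self.gates.items() if not g.open]


def construct_items_for(name: str, n_waves: int, route: str) -> List[List[str]]:
    """Item columns per wave for a construct under the given route.

    The composite route uses one score column per construct; the latent
    routes use the raw items for multi-item constructs (binary behaviors
    stay single-indicator).
    """
    if route == "composite":
        col = {"sup": "support", "dem": "demands", "dep": "depscore",
               "nbehav": "nbehav"}.get(name, name)
        return [[f"{col}_w{w}"] for w in range(1, n_waves + 1)]
    n_items = {"sup": 5, "dem": 4, "dep": 6}.get(name)
    if n_items is None:
        return [[f"{name}_w{w}"] for w in range(1, n_waves + 1)]
    return [[f"{name}{j}_w{w}" for j in range(1, n_items + 1)]
            for w in range(1, n_waves + 1)]


def _ensure_derived(data: pd.DataFrame, config: RunConfig, n_waves: int) -> pd.DataFrame:
    """Add composite score / count columns where derivable and absent."""
    out = data.copy()
    # observed-variable variant: construct score columns from emitted latents
    for c in data.columns:
        if c.startswith("lat_"):
            alias = c[4:]
            if alias not in out.columns:
                out[alias] = data[c]
    raw_derived = derive_mod.derive_panel(
        data, n_waves=n_waves,
        smoking_variant=config.smoking_variant,
        inactivity_variant=config.inactivity_variant)
    for c in raw_derived.columns:
        if c not in out.columns:
            out[c] = raw_derived[c]
    for w in range(1, n_waves + 1):
        if f"demands_w{w}" not in out.columns:
            dem = [f"dem{j}_w{w}" for j in range(1, 5)]
            if all(c in out.columns for c in dem):
                out[f"demands_w{w}"] = out[dem].mean(axis=1)
        if f"support_w{w}" not in out.columns:
            sup = [f"sup{j}_w{w}" for j in range(1, 6)]
            if all(c in out.columns for c in sup):
                out[f"support_w{w}"] = out[sup].mean(axis=1)
        if f"depscore_w{w}" not in out.columns:
            dep = [f"dep{j}_w{w}" for j in range(1, 7)]
            if all(c in out.columns for c in dep):
                out[f"depscore_w{w}"] = out[dep].sum(axis=1)
        if f"nbehav_w{w}" not in out.columns:
            four = [f"{b}_w{w}" for b in BEHAVIORS]
            if all(c in out.columns for c in four):
                out[f"nbehav_w{w}"] = out[four].sum(axis=1)
    return out


def _mediation_model(config: RunConfig, items: Dict[str, list],
                     mediator: str, data: pd.DataFrame, seed: int):
    spec = crosslagged_spec(
        {config.exposure: items[config.exposure],
         mediator: items[mediator],
         config.outcome: items[config.outcome]},
        cross_pairs="all",
        error_covariances=config.route != "composite",
        covariates=config.covariates if config.covariate_adjustment else (),
        estimator="wls" if config.route == "latent-wls" else "ml",
        continuous_columns=("age",) if config.covariate_adjustment else (),
    )
    return fit(spec, data, seed=seed)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; mediation is short-circuited for mediators whose
    gate is closed, recorded explicitly as "no mediation model fitted"."""
    t_start = time.time()
    timings: Dict[str, float] = {}
    if config.sim_config is not None:
        data = generate_panel(config.sim_config)
        n_waves = config.sim_config.n_waves
    else:
        data = pd.read_csv(config.csv_path)
        n_waves = 4
    timings["input"] = time.time() - t_start

    t0 = time.time()
    data = _ensure_derived(data, config, n_waves)
    timings["derive"] = time.time() - t0

    items = {name: construct_items_for(name, n_waves, config.route)
             for name in (config.exposure, config.outcome, *config.mediators)}
    options = ScreeningOptions(
        route=config.route,
        covariates=config.covariates if config.covariate_adjustment else (),
        continuous_covariates=("age",) if config.covariate_adjustment else (),
        seed=config.seed,
    )
    t0 = time.time()
    screens: Dict[str, Tuple[ScreeningResult, ScreeningResult]] = {}
    gates: Dict[str, GateDecision] = {}
    for m in config.mediators:
        s_xm = fit_bivariate((config.exposure, m), items, data, options)
        s_my = fit_bivariate((m, config.outcome), items, data, options)
        screens[m] = (s_xm, s_my)
        gates[m] = gate_mediation(s_xm, s_my)
    timings["screen"] = time.time() - t0

    t0 = time.time()
    decomps: Dict[str, EffectDecomposition] = {}
    fit_warnings: List[str] = []
    for m in config.mediators:
        if not gates[m].open:
            continue
        mfit = _mediation_model(config, items, m, data, config.seed)
        fit_warnings.extend(mfit.warnings_)
        graph = StructuralGraph.from_fit(mfit, config.exposure, [m], config.outcome)
        decomps[m] = monte_carlo_ci(mfit, graph, n_draws=config.n_draws,
                                    level=config.level, seed=config.seed)
    timings["mediate"] = time.time() - t0

    report = mediation_report({
        f"{config.exposure}-{m}-{config.outcome}": d for m, d in decomps.items()
    })

    screen_rows = []
    for m, (s_xm, s_my) in screens.items():
        for label, s in (("exposure-mediator", s_xm), ("mediator-outcome", s_my)):
            t = s.table.copy()
            t.insert(0, "screen", label)
            t.insert(0, "mediator", m)
            screen_rows.append(t)
    screen_table = pd.concat(screen_rows, ignore_index=True)

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "n_subjects": int(len(data)),
        "n_waves": n_waves,
        "gates": {m: dataclasses.asdict(g) for m, g in gates.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "warnings": fit_warnings,
        "screen_hash": _hash_frame(screen_table),
        "report_hash": _hash_frame(report),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        screen_table.to_csv(out / "screening.csv", index=False)
        report.to_csv(out / "mediation.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(data=data, screens=screens, gates=gates,
                          decompositions=decomps, report=report,
                          manifest=manifest)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.sim_config is not None:
        d["sim_config"] = config.sim_config.to_dict()
    return d


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(10).to_csv(index=False).encode()).hexdigest()[:16]


def sensitivity_suite(config: RunConfig,
                      variants: Dict[str, dict] | None = None) -> pd.DataFrame:
    """Re-run screening/mediation under variant operationalizations and
    covariate adjustment on/off; emits a side-by-side effects table."""
    if variants is None:
        variants = {
            "main": {},
            "smoking-any": {"smoking_variant": "any"},
            "inactivity-irregular": {"inactivity_variant": "irregular"},
            "covariate-adjusted": {"covariate_adjustment": True},
        }
    rows = []
    for name, overrides in variants.items():
        cfg = dataclasses.replace(config, **overrides)
        res = run_pipeline(cfg)
        for m in cfg.mediators:
            gate = res.gates[m]
            d = res.decompositions.get(m)
            rows.append({
                "variant": name, "mediator": m, "gate_open": gate.open,
                "total": d.total if d else np.nan,
                "direct": d.direct if d else np.nan,
                "indirect": d.indirect if d else np.nan,
                "indirect_lo": d.ci_indirect[0] if d else np.nan,
                "indirect_hi": d.ci_indirect[1] if d else np.nan,
            })
    return pd.DataFrame(rows)
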