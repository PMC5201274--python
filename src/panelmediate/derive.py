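"""Scoring and dichotomization rules for the occupational-health instruments.

Turns raw questionnaire items into the analysis variables: DCQ demand and
support composites (1-4), the SCL-CD6 depressive-symptom sum (0-24), and the
four binary unhealthy-behavior indicators (daily smoking, excessive alcohol
by AUDIT consumption items or CAGE, unhealthy diet, physical inactivity)
plus their 0-4 count.  Sensitivity operationalizations (any smoking,
irregular activity) are selected per call via ``variant`` arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DerivationRules",
    "score_scale",
    "score_scl_cd6",
    "derive_smoking",
    "derive_alcohol_audit",
    "derive_alcohol_cage",
    "derive_diet",
    "derive_inactivity",
    "count_unhealthy",
    "derive_panel",
]

_MISSING = float("nan")


@dataclass(frozen=True)
class DerivationRules:
    """Thresholds and category lists; defaults follow the study definitions."""

    audit_weekly_units_male: float = 21.0
    audit_weekly_units_female: float = 14.0
    audit_binge_units: float = 6.0  # per occasion, at least weekly
    cage_min_positive: int = 2
    smoking_positive_daily: tuple = ("daily",)
    smoking_positive_any: tuple = ("daily", "sometimes")
    diet_unhealthy_categories: tuple = ("a lot of fat, sugar or fast food",)
    diet_healthy_categories: tuple = (
        "varying/average diet",
        "avoid fat and sugar",
        "special diet",
    )
    inactivity_main_categories: tuple = ("never", "very little")
    inactivity_irregular_categories: tuple = ("never", "very little", "now and then")
    activity_categories: tuple = ("never", "very little", "now and then", "regularly")
    scale_min: int = 1
    scale_max: int = 4
    depressive_item_min: int = 0
    depressive_item_max: int = 4
    # scale scores are missing when more than this fraction of items is missing
    max_missing_fraction: float = 0.5
    # per-wave alcohol instrument: the consumption-based rule in the first two
    # analysis waves, CAGE thereafter (the instrument changed between them)
    alcohol_instrument_by_wave: tuple = ("audit", "audit", "cage", "cage")

    def __post_init__(self) -> None:
        if min(self.audit_weekly_units_male, self.audit_weekly_units_female,
               self.audit_binge_units) <= 0:
            raise ValueError("alcohol thresholds must be positive")
        if set(self.diet_unhealthy_categories) & set(self.diet_healthy_categories):
            raise ValueError("diet category lists must be disjoint")

    def to_yaml(self) -> str:
        d = {k: list(v) if isinstance(v, tuple) else v
             for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=True)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def score_scale(items: Sequence[float], scale: str,
                rules: DerivationRules = DerivationRules()) -> float:
    """Demand (4 items) or support (5 items) composite: mean of the observed
    1-4 items, missing when more than ``max_missing_fraction`` are missing."""
    n_expected = {"demands": 4, "support": 5}.get(scale)
    if n_expected is None:
        raise ValueError(f"unknown scale {scale!r}")
    if len(items) != n_expected:
        raise ValueError(f"{scale} needs {n_expected} items, got {len(items)}")
    vals = [v for v in items if not _is_missing(v)]
    for v in vals:
        if not rules.scale_min <= v <= rules.scale_max:
            raise ValueError(f"item value {v} outside {rules.scale_min}-{rules.scale_max}")
    if len(items) - len(vals) > rules.max_missing_fraction * len(items):
        return _MISSING
    if not vals:
        return _MISSING
    return float(np.mean(vals))


def score_scl_cd6(items: Sequence[float], allow_missing: bool = False,
                  rules: DerivationRules = DerivationRules()) -> float:
    """SCL-CD6 sum of six 0-4 items, range 0-24.

    By default any missing item makes the score missing; with
    ``allow_missing`` the observed-item mean is rescaled to the 0-24 range.
    """
    if len(items) != 6:
        raise ValueError(f"SCL-CD6 needs 6 items, got {len(items)}")
    vals = [v for v in items if not _is_missing(v)]
    for v in vals:
        if not rules.depressive_item_min <= v <= rules.depressive_item_max:
            raise ValueError(f"depressive item {v} outside 0-4")
    if len(vals) < 6:
        if not allow_missing or len(vals) < 3:
            return _MISSING
        return float(np.mean(vals) * 6)
    return float(np.sum(vals))


def derive_smoking(status: str, variant: str = "daily") -> float:
    """1 iff daily smoking (main) or daily/occasional smoking (any variant)."""
    if _is_missing(status):
        return _MISSING
    if status not in ("daily", "sometimes", "never"):
        raise ValueError(f"unknown smoking category {status!r}")
    if variant == "daily":
        return float(status == "daily")
    if variant == "any":
        return float(status in ("daily", "sometimes"))
    raise ValueError(f"unknown smoking variant {variant!r}")


def derive_alcohol_audit(sex: str, weekly_units: float,
                         binge_six_at_least_weekly: bool,
                         rules: DerivationRules = DerivationRules()) -> float:
    """Excessive drinking by consumption: >= 21 units/week (men) or >= 14
    (women), or >= 6 units per occasion at least weekly."""
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex code {sex!r}")
    if _is_missing(weekly_units) and _is_missing(binge_six_at_least_weekly):
        return _MISSING
    threshold = (rules.audit_weekly_units_male if sex == "male"
                 else rules.audit_weekly_units_female)
    heavy = (not _is_missing(weekly_units)) and weekly_units >= threshold
    if not _is_missing(weekly_units) and weekly_units < 0:
        raise ValueError("weekly_units must be >= 0")
    binge = bool(binge_six_at_least_weekly) if not _is_missing(binge_six_at_least_weekly) else False
    return float(heavy or binge)


def derive_alcohol_cage(cage_items: Sequence[float],
                        rules: DerivationRules = DerivationRules()) -> float:
    """1 iff at least ``cage_min_positive`` (default 2) of the 4 CAGE items."""
    if len(cage_items) != 4:
        raise ValueError(f"CAGE needs 4 items, got {len(cage_items)}")
    if any(_is_missing(v) for v in cage_items):
        return _MISSING
    if any(v not in (0, 1) for v in cage_items):
        raise ValueError("CAGE items must be binary")
    return float(sum(cage_items) >= rules.cage_min_positive)


def derive_diet(category: str, rules: DerivationRules = DerivationRules()) -> float:
    """1 iff the single diet item falls in the unhealthy category list."""
    if _is_missing(category):
        return _MISSING
    if category in rules.diet_unhealthy_categories:
        return 1.0
    if category in rules.diet_healthy_categories:
        return 0.0
    raise ValueError(f"unknown diet category {category!r}")


def derive_inactivity(exercise_category: str, variant: str = "main",
                      rules: DerivationRules = DerivationRules()) -> float:
    """1 iff exercising very little/never (main) or also only now and then
    (irregular sensitivity variant)."""
    if _is_missing(exercise_category):
        return _MISSING
    if exercise_category not in rules.activity_categories:
        raise ValueError(f"unknown exercise category {exercise_category!r}")
    if variant == "main":
        return float(exercise_category in rules.inactivity_main_categories)
    if variant == "irregular":
        return float(exercise_category in rules.inactivity_irregular_categories)
    raise ValueError(f"unknown inactivity variant {variant!r}")


def count_unhealthy(behaviors: Sequence[float], allow_missing: bool = False) -> float:
    """0-4 count of unhealthy behaviors; missing when any component is
    missing unless ``allow_missing`` (then the observed sum is returned)."""
    if len(behaviors) != 4:
        raise ValueError(f"need 4 behavior indicators, got {len(behaviors)}")
    vals = [v for v in behaviors if not _is_missing(v)]
    if any(v not in (0, 1) for v in vals):
        raise ValueError("behavior indicators must be binary")
    if len(vals) < 4 and not allow_missing:
        return _MISSING
    if not vals:
        return _MISSING
    return float(sum(vals))


def derive_panel(raw: pd.DataFrame, n_waves: int = 4,
                 rules: DerivationRules = DerivationRules(),
                 smoking_variant: str = "daily",
                 inactivity_variant: str = "main") -> pd.DataFrame:
    """Column-convention frame derivation.

    Recognized per-wave raw columns (``_w<t>`` suffix): ``dem1..dem4``,
    ``sup1..sup5``, ``dep1..dep6``, ``smoking_status``, ``weekly_units`` +
    ``binge_weekly``, ``cage1..cage4``, ``diet_category``, ``exercise``.
    Emits ``demands_w<t>``, ``support_w<t>``, ``depscore_w<t>``,
    ``smoke_w<t>``, ``alco_w<t>``, ``diet_w<t>``, ``inact_w<t>`` and
    ``nbehav_w<t>`` for whichever inputs are present.
    """
    out = pd.DataFrame(index=raw.index)
    for keep in ("sid", "age", "sex", "single", "edu"):
        if keep in raw.columns:
            out[keep] = raw[keep]
    for w in range(1, n_waves + 1):
        dem = [f"dem{j}_w{w}" for j in range(1, 5)]
        sup = [f"sup{j}_w{w}" for j in range(1, 6)]
        dep = [f"dep{j}_w{w}" for j in range(1, 7)]
        if all(c in raw.columns for c in dem):
            out[f"demands_w{w}"] = raw[dem].apply(
                lambda r: score_scale(list(r), "demands", rules), axis=1)
        if all(c in raw.columns for c in sup):
            out[f"support_w{w}"] = raw[sup].apply(
                lambda r: score_scale(list(r), "support", rules), axis=1)
        if all(c in raw.columns for c in dep):
            out[f"depscore_w{w}"] = raw[dep].apply(
                lambda r: score_scl_cd6(list(r), rules=rules), axis=1)
        if f"smoking_status_w{w}" in raw.columns:
            out[f"smoke_w{w}"] = raw[f"smoking_status_w{w}"].map(
                lambda s: derive_smoking(s, smoking_variant))
        instrument = rules.alcohol_instrument_by_wave[w - 1]
        if instrument == "audit" and f"weekly_units_w{w}" in raw.columns:
            out[f"alco_w{w}"] = raw.apply(
                lambda r: derive_alcohol_audit(
                    "female" if r.get("sex", 0) == 1 else "male",
                    r[f"weekly_units_w{w}"],
                    bool(r.get(f"binge_weekly_w{w}", 0)),
                    rules), axis=1)
        elif instrument == "cage" and f"cage1_w{w}" in raw.columns:
            cage = [f"cage{j}_w{w}" for j in range(1, 5)]
            out[f"alco_w{w}"] = raw[cage].apply(
                lambda r: derive_alcohol_cage(list(r), rules), axis=1)
        if f"diet_category_w{w}" in raw.columns:
            out[f"diet_w{w}"] = raw[f"diet_category_w{w}"].map(
                lambda s: derive_diet(s, rules))
        if f"exercise_w{w}" in raw.columns:
            out[f"inact_w{w}"] = raw[f"exercise_w{w}"].map(
                lambda s: derive_inactivity(s, inactivity_variant, rules))
        four = [f"smoke_w{w}", f"alco_w{w}", f"diet_w{w}", f"inact_w{w}"]
        if all(c in out.columns for c in four):
            out[f"nbehav_w{w}"] = out[four].apply(
                lambda r: count_unhealthy(list(r)), axis=1)
    return out
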