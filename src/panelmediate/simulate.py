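"""Synthetic multi-wave occupational-health cohort generator.

Generates wide-format panel datasets with the statistical structure the
downstream cross-lagged mediation analysis assumes: latent constructs
(work characteristics, behavior propensities, depressive symptoms) evolving
by a lag-1 linear system with known autoregressive and cross-lagged
coefficients, ordinal questionnaire items produced from the latents through
a probit (thresholded latent response) measurement model, binary behavior
indicators produced by thresholding a propensity, baseline covariates, and
optional MCAR/MAR item missingness.

Every latent construct is normalized to unit marginal variance at every
wave (innovation variances are solved for), so the generating coefficients
are standardized coefficients and exact total/direct/indirect effects are
plain path products of the configuration values — see :func:`true_effects`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import EffectDecomposition

__all__ = [
    "ItemBlock",
    "Missingness",
    "SimConfig",
    "study_default_config",
    "three_construct_config",
    "generate_panel",
    "apply_missingness",
    "true_effects",
    "transition_matrices",
    "write_panel",
]


@dataclass(frozen=True)
class ItemBlock:
    """Measurement design for one construct.

    ``thresholds`` are ordered cutpoints on the unit-variance latent
    response scale; an item with K categories has K-1 cutpoints.
    ``first_code`` is the code of the lowest category (1 for the 1-4
    demand/support items, 0 for the 0-4 depressive items and for binaries).
    """

    prefix: str
    n_items: int
    n_categories: int
    loadings: Tuple[float, ...]
    thresholds: Tuple[Tuple[float, ...], ...]
    first_code: int = 1

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if len(self.loadings) != self.n_items:
            raise ValueError(f"{self.prefix}: need {self.n_items} loadings")
        if len(self.thresholds) != self.n_items:
            raise ValueError(f"{self.prefix}: need thresholds per item")
        for lam in self.loadings:
            if not 0 < abs(lam) <= 1:
                raise ValueError("loadings must lie in (0, 1] in absolute value")
        for tau in self.thresholds:
            if len(tau) != self.n_categories - 1:
                raise ValueError(
                    f"{self.prefix}: {self.n_categories} categories need "
                    f"{self.n_categories - 1} thresholds"
                )
            if not all(a < b for a, b in zip(tau, tau[1:])):
                raise ValueError(f"{self.prefix}: thresholds must strictly increase")

    @property
    def binary(self) -> bool:
        return self.n_categories == 2

    def columns(self, wave: int) -> list[str]:
        if self.n_items == 1:
            return [f"{self.prefix}_w{wave}"]
        return [f"{self.prefix}{j + 1}_w{wave}" for j in range(self.n_items)]


@dataclass(frozen=True)
class Missingness:
    """Cell-level missingness mechanism.

    MCAR masks item cells independently at ``rate``.  MAR masks cells in
    waves >= 2 with a probability that increases with the subject's observed
    wave-1 score on ``driver`` (a construct name), keeping the marginal rate
    near ``rate``.
    """

    mechanism: str = "none"
    rate: float = 0.0
    driver: str = "dep"

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "MCAR", "MAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("missingness rate must be in [0, 1]")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    ``ar_coefficients`` gives the lag-1 stability path of each construct;
    ``crosslag`` maps (source, target) construct pairs to a standardized
    lag-1 coefficient, either a scalar (constant over transitions) or a
    sequence of length ``n_waves - 1``.  ``covariate_effects`` maps baseline
    covariate names to per-construct effects on the wave-1 latent means.
    """

    n_subjects: int
    items: Dict[str, ItemBlock]
    ar_coefficients: Dict[str, float]
    crosslag: Dict[Tuple[str, str], object] = field(default_factory=dict)
    n_waves: int = 4
    residual_correlations: Dict[str, float] = field(default_factory=dict)
    missingness: Missingness = field(default_factory=Missingness)
    covariate_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    emit_latents: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        for name in self.ar_coefficients:
            if name not in self.items:
                raise ValueError(f"construct {name!r} has no item block")
        for (src, dst) in self.crosslag:
            if src not in self.constructs or dst not in self.constructs:
                raise ValueError(f"crosslag edge ({src}, {dst}) names unknown construct")
        for c, r in self.residual_correlations.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"residual correlation for {c!r} must be in [0, 1)")

    @property
    def constructs(self) -> list[str]:
        return list(self.ar_coefficients)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["crosslag"] = {f"{s}->{t}": v for (s, t), v in self.crosslag.items()}
        return d


COVARIATES = ("age", "sex", "single", "edu")

# Baseline marginals of the analytic sample: age 47.6 (SD 8.9, range 20-67),
# 57.5% women, 20.6% single, six ordered education categories.
_EDU_PROBS = np.array([0.009, 0.059, 0.444, 0.070, 0.402, 0.016])


def transition_matrices(config: SimConfig) -> list[np.ndarray]:
    """Per-transition lag-1 coefficient matrices B_t with B[target, source]."""
    cons = config.constructs
    idx = {c: i for i, c in enumerate(cons)}
    k = len(cons)
    mats = []
    for t in range(config.n_waves - 1):
        B = np.zeros((k, k))
        for c, a in config.ar_coefficients.items():
            B[idx[c], idx[c]] = float(a)
        for (src, dst), coef in config.crosslag.items():
            if np.ndim(coef) == 0:
                val = float(coef)
            else:
                seq = np.asarray(coef, dtype=float)
                if seq.size != config.n_waves - 1:
                    raise ValueError(
                        f"crosslag ({src}, {dst}): need {config.n_waves - 1} values"
                    )
                val = seq[t]
            B[idx[dst], idx[src]] = val
        mats.append(B)
    return mats


def _latent_covariances(config: SimConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Wave-1 covariance (stationary fixed point) and innovation covariances.

    Innovation variances are solved so that diag(V_t) = 1 at every wave; a
    configuration whose paths explain >= 100% of a construct's variance is
    rejected as non-stationary.
    """
    mats = transition_matrices(config)
    k = mats[0].shape[0]
    V = np.eye(k)
    B0 = mats[0]
    for _ in range(500):
        expl = B0 @ V @ B0.T
        if np.any(np.diag(expl) >= 1.0):
            raise ValueError("lag-1 system explains >= 100% of a construct's variance")
        V_new = expl + np.diag(1.0 - np.diag(expl))
        if np.max(np.abs(V_new - V)) < 1e-12:
            V = V_new
            break
        V = V_new
    psis = []
    Vt = V
    for B in mats:
        expl = B @ Vt @ B.T
        if np.any(np.diag(expl) >= 1.0):
            raise ValueError("lag-1 system explains >= 100% of a construct's variance")
        psi = np.diag(1.0 - np.diag(expl))
        psis.append(psi)
        Vt = expl + psi
    return V, psis


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(47.6, 8.9, n), 20, 67)
    sex = (rng.random(n) < 0.575).astype(int)  # 1 = female
    single = (rng.random(n) < 0.206).astype(int)
    edu = rng.choice(np.arange(1, 7), size=n, p=_EDU_PROBS)
    return pd.DataFrame({"age": age, "sex": sex, "single": single, "edu": edu})


def generate_panel(config: SimConfig) -> pd.DataFrame:
    """Generate a wide person-by-wave panel; deterministic given config.seed.

    Columns: subject ``sid``, baseline covariates, one column per item and
    wave (``dem1_w1`` ... ``smoke_w4``), and — when ``config.emit_latents``
    — the true latent construct scores ``lat_<construct>_w<t>``.
    """
    master = np.random.SeedSequence(config.seed)
    ss_cov, ss_lat, ss_item, _ss_miss = master.spawn(4)
    n = config.n_subjects
    cons = config.constructs
    k = len(cons)

    cov_df = _simulate_covariates(n, np.random.default_rng(ss_cov))

    V1, psis = _latent_covariances(config)
    mats = transition_matrices(config)
    rng = np.random.default_rng(ss_lat)

    # baseline covariate shifts enter the wave-1 latent means (standardized covariates)
    mean1 = np.zeros((n, k))
    if config.covariate_effects:
        z = {
            c: (cov_df[c] - cov_df[c].mean()) / max(cov_df[c].std(ddof=0), 1e-12)
            for c in COVARIATES
        }
        for cov, effects in config.covariate_effects.items():
            if cov not in z:
                raise ValueError(f"unknown covariate {cov!r}")
            for c, beta in effects.items():
                mean1[:, cons.index(c)] += beta * z[cov].to_numpy()

    lat = np.empty((config.n_waves, n, k))
    chol1 = np.linalg.cholesky(V1 + 1e-12 * np.eye(k))
    lat[0] = mean1 + rng.standard_normal((n, k)) @ chol1.T
    for t in range(config.n_waves - 1):
        innov = rng.standard_normal((n, k)) * np.sqrt(np.diag(psis[t]))
        lat[t + 1] = lat[t] @ mats[t].T + innov

    irng = np.random.default_rng(ss_item)
    data = {"sid": np.arange(1, n + 1)}
    for c in COVARIATES:
        data[c] = cov_df[c].to_numpy()

    for ci, c in enumerate(cons):
        block = config.items[c]
        r = config.residual_correlations.get(c, 0.0)
        shared = irng.standard_normal((n, block.n_items))  # item-specific stable part
        for w in range(config.n_waves):
            cols = block.columns(w + 1)
            for j, col in enumerate(cols):
                lam = block.loadings[j]
                sig2 = 1.0 - lam * lam
                if sig2 <= 0:
                    # loading 1: the item is a deterministic threshold of the
                    # construct itself (binary behaviors)
                    if r > 0:
                        raise ValueError(
                            f"{c}: residual correlation requires loading < 1")
                    ystar = lat[w, :, ci]
                else:
                    a = r / sig2 if r > 0 else 0.0
                    if a > 1.0:
                        raise ValueError(
                            f"{c}: residual correlation {r} exceeds residual variance"
                        )
                    eps = (np.sqrt(a) * shared[:, j]
                           + np.sqrt(1.0 - a) * irng.standard_normal(n))
                    ystar = lam * lat[w, :, ci] + np.sqrt(sig2) * eps
                codes = np.searchsorted(np.asarray(block.thresholds[j]), ystar)
                data[col] = (codes + block.first_code).astype(float)
        if config.emit_latents:
            for w in range(config.n_waves):
                data[f"lat_{c}_w{w + 1}"] = lat[w, :, ci]

    df = pd.DataFrame(data)
    if config.missingness.mechanism != "none":
        df = apply_missingness(df, config)
    return df


def item_columns(config: SimConfig) -> list[str]:
    cols = []
    for c in config.constructs:
        block = config.items[c]
        for w in range(config.n_waves):
            cols.extend(block.columns(w + 1))
    return cols


def apply_missingness(data: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Mask item cells per the configured mechanism; deterministic given seed.

    MCAR: every item cell independently with probability ``rate``.
    MAR: cells in waves >= 2 masked with probability depending on the
    subject's observed wave-1 mean score on the driver construct (higher
    scores are more likely to be masked), calibrated so the average rate
    over masked-eligible cells is close to ``rate``.
    """
    mechanism = config.missingness.mechanism
    rate = config.missingness.rate
    if mechanism == "none" or rate == 0.0:
        return data.copy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    out = data.copy()
    cols = [c for c in item_columns(config) if c in out.columns]
    n = len(out)
    if mechanism == "MCAR":
        mask = rng.random((n, len(cols))) < rate
    elif mechanism == "MAR":
        driver = config.missingness.driver
        block = config.items[driver]
        w1 = out[block.columns(1)].mean(axis=1).to_numpy()
        z = (w1 - np.nanmean(w1)) / max(np.nanstd(w1), 1e-12)
        # logistic in the observed wave-1 driver score, centered on `rate`
        logit0 = np.log(rate / (1.0 - rate))
        p = 1.0 / (1.0 + np.exp(-(logit0 + 1.0 * z)))
        later = [c for c in cols if not c.endswith("_w1")]
        mask = np.zeros((n, len(cols)), dtype=bool)
        sel = [i for i, c in enumerate(cols) if c in later]
        mask[:, sel] = rng.random((n, len(sel))) < p[:, None]
    else:  # pragma: no cover - guarded by Missingness validation
        raise ValueError(mechanism)
    arr = out[cols].to_numpy(dtype=float)
    arr[mask] = np.nan
    out[cols] = arr
    return out


def true_effects(
    config: SimConfig,
    source: str,
    sink: str,
    mediators: Sequence[str],
) -> EffectDecomposition:
    """Exact standardized total/direct/indirect effects of source@wave1 on
    sink@wave(n_waves) implied by the generating coefficients.

    total is the (sink, source) entry of the ordered product of the
    transition matrices; direct repeats the product with every edge into a
    mediator construct removed, so indirect = total - direct sums exactly
    the products over paths visiting at least one mediator node.
    """
    cons = config.constructs
    for name in (source, sink, *mediators):
        if name not in cons:
            raise ValueError(f"unknown construct {name!r}")
    idx = {c: i for i, c in enumerate(cons)}
    mats = transition_matrices(config)
    k = len(cons)
    total_mat = np.eye(k)
    direct_mat = np.eye(k)
    med_rows = [idx[m] for m in mediators]
    for B in mats:
        Bd = B.copy()
        Bd[med_rows, :] = 0.0
        total_mat = B @ total_mat
        direct_mat = Bd @ direct_mat
    total = float(total_mat[idx[sink], idx[source]])
    direct = float(direct_mat[idx[sink], idx[source]])
    indirect = total - direct
    prop = indirect / total if abs(total) > 1e-12 else np.nan
    return EffectDecomposition(
        total=total, direct=direct, indirect=indirect, proportion_mediated=prop
    )


def study_default_config(n_subjects: int = 3706, seed: int = 0) -> SimConfig:
    """Default cohort calibrated to the baseline marginals of the study
    sample: demand mean ~2.6, support mean ~3.1 on the 1-4 scale, smoking
    8.3%, excessive alcohol 5.2%, unhealthy diet 6.8%, inactivity 16.1%,
    right-skewed 0-24 depressive scores.

    Cross-lagged structure mirrors the reported pattern: small negative
    support->alcohol and support->diet paths, small positive behavior->
    depression paths, and a direct support->depression path; demands carry
    no paths into behaviors.
    """
    q = stats.norm.ppf
    dem_tau = (-1.4, -0.1, 1.1)
    sup_tau = (-2.0, -0.85, 0.45)
    dep_tau = (0.0, 0.8, 1.5, 2.1)
    items = {
        "dem": ItemBlock("dem", 4, 4, (0.75, 0.7, 0.65, 0.7), (dem_tau,) * 4, 1),
        "sup": ItemBlock("sup", 5, 4, (0.8, 0.75, 0.7, 0.7, 0.65), (sup_tau,) * 5, 1),
        "smoke": ItemBlock("smoke", 1, 2, (1.0,), ((float(q(0.917)),),), 0),
        "alco": ItemBlock("alco", 1, 2, (1.0,), ((float(q(0.948)),),), 0),
        "diet": ItemBlock("diet", 1, 2, (1.0,), ((float(q(0.932)),),), 0),
        "inact": ItemBlock("inact", 1, 2, (1.0,), ((float(q(0.839)),),), 0),
        "dep": ItemBlock("dep", 6, 5, (0.8, 0.75, 0.75, 0.7, 0.7, 0.65), (dep_tau,) * 6, 0),
    }
    ar = {
        "dem": 0.6,
        "sup": 0.6,
        "smoke": 0.85,
        "alco": 0.7,
        "diet": 0.7,
        "inact": 0.65,
        "dep": 0.6,
    }
    crosslag = {
        ("sup", "alco"): -0.05,
        ("sup", "diet"): -0.04,
        ("alco", "dep"): 0.05,
        ("diet", "dep"): 0.04,
        ("inact", "dep"): 0.04,
        ("sup", "dep"): -0.08,
        ("dem", "dep"): 0.07,
        ("dep", "alco"): 0.02,
        ("dep", "diet"): 0.02,
    }
    resid = {"dem": 0.1, "sup": 0.1, "dep": 0.1}
    cov_eff = {
        "age": {"dep": -0.05},
        "sex": {"dep": 0.08, "sup": 0.05},
        "edu": {"dem": 0.05},
    }
    return SimConfig(
        n_subjects=n_subjects,
        items=items,
        ar_coefficients=ar,
        crosslag=crosslag,
        residual_correlations=resid,
        covariate_effects=cov_eff,
        seed=seed,
    )


def three_construct_config(
    n_subjects: int = 500,
    n_waves: int = 4,
    ar: Mapping[str, float] | None = None,
    crosslag: Mapping[Tuple[str, str], object] | None = None,
    seed: int = 0,
    binary_mediator: bool = False,
) -> SimConfig:
    """Compact X/M/Y cohort for simulation studies of the effect calculus.

    X is a work-characteristic analogue, M a behavior propensity and Y a
    depressive-symptom analogue; by default M is observed directly (the
    observed-variable path-model variant), with ``binary_mediator`` the M
    item is dichotomized at the 16% tail.
    """
    ar = dict(ar or {"X": 0.5, "M": 0.5, "Y": 0.5})
    crosslag = dict(
        crosslag if crosslag is not None else {("X", "M"): 0.2, ("M", "Y"): 0.2, ("X", "Y"): 0.15}
    )
    m_block = (
        ItemBlock("m", 1, 2, (1.0,), ((float(stats.norm.ppf(0.839)),),), 0)
        if binary_mediator
        else ItemBlock("m", 1, 4, (0.8,), ((-1.0, 0.0, 1.0),), 1)
    )
    items = {
        "X": ItemBlock("x", 4, 4, (0.8, 0.75, 0.7, 0.7), ((-1.0, 0.0, 1.0),) * 4, 1),
        "M": m_block,
        "Y": ItemBlock("y", 6, 5, (0.8, 0.75, 0.75, 0.7, 0.7, 0.65), ((-1.0, 0.0, 0.8, 1.6),) * 6, 0),
    }
    return SimConfig(
        n_subjects=n_subjects,
        items=items,
        ar_coefficients=ar,
        crosslag=crosslag,
        n_waves=n_waves,
        seed=seed,
    )


def write_panel(data: pd.DataFrame, config: SimConfig, path: str, manifest_path: str | None = None) -> None:
    """Write the panel as CSV (missing cells empty) plus a manifest JSON
    recording the configuration, seed and true effect parameters."""
    data.to_csv(path, index=False)
    if manifest_path is not None:
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "transition_matrices": [m.tolist() for m in transition_matrices(config)],
            "constructs": config.constructs,
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
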