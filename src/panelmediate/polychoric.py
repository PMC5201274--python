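"""Polychoric / tetrachoric / polyserial correlations with thresholds.

Ordinal and binary observations are modeled as thresholded standard-normal
latent responses.  Estimation is two-step: thresholds from the univariate
margins (normal quantiles of cumulative proportions), then each pairwise
correlation by maximum likelihood with thresholds held fixed.  The
asymptotic covariance of the correlation vector — needed for robust
(sandwich) standard errors and mean-scaled test statistics downstream — is
assembled from per-observation influence functions (pair score divided by
unit expected information).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "bvn_cdf",
    "bvn_pdf",
    "estimate_thresholds",
    "polychoric_pair",
    "polyserial_pair",
    "polychoric_matrix",
    "CorrelationResult",
]

_CLIP = 0.999  # correlation boundary for degenerate tables
_INF = 10.0    # effective infinity on the latent-response scale

# positive half of the 20-point Gauss-Legendre rule; the quadrature loops
# evaluate both (1-x)/2 and (1+x)/2, reconstructing the full rule
_gx, _gw = np.polynomial.legendre.leggauss(20)
_GL_X, _GL_W = _gx[_gx > 0], _gw[_gx > 0]


def _phi(x):
    return stats.norm.cdf(x)


def bvn_cdf(a, b, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= a, Y <= b) with correlation rho,
    vectorized over a and b (scalar rho).  Drezner-Wesolowsky/Genz scheme:
    Gauss-Legendre quadrature of the correlation integral for moderate rho
    and the tail expansion for |rho| > 0.925."""
    a = np.clip(np.asarray(a, dtype=float), -_INF, _INF)
    b = np.clip(np.asarray(b, dtype=float), -_INF, _INF)
    a, b = np.broadcast_arrays(a, b)
    dh, dk = -a, -b  # work with the upper-quadrant probability bvnu(dh, dk)
    rho = float(np.clip(rho, -1.0, 1.0))
    if rho == 0.0:
        return _phi(a) * _phi(b)
    hk = dh * dk
    if abs(rho) < 0.925:
        hs = (dh * dh + dk * dk) / 2.0
        asr = np.arcsin(rho)
        sn1 = np.sin(asr * (1.0 - _GL_X) / 2.0)
        sn2 = np.sin(asr * (1.0 + _GL_X) / 2.0)
        acc = np.zeros_like(dh)
        for sn in (sn1, sn2):
            ex = np.exp(
                (sn[:, None] * hk.ravel()[None, :] - hs.ravel()[None, :])
                / (1.0 - sn[:, None] ** 2)
            )
            acc += (ex * _GL_W[:, None]).sum(axis=0).reshape(dh.shape)
        p = acc * asr / (4.0 * np.pi) + _phi(-dh) * _phi(-dk)
        return np.clip(p, 0.0, 1.0)
    # high-correlation branch
    sgn = 1.0 if rho > 0 else -1.0
    dk = dk * sgn
    hk = hk * sgn
    bvn = np.zeros_like(dh)
    if abs(rho) < 1.0:
        as_ = (1.0 - rho) * (1.0 + rho)
        a_ = np.sqrt(as_)
        bs = (dh - dk) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / as_ + hk) / 2.0
        m = asr > -100.0
        bvn = np.where(
            m,
            a_ * np.exp(asr) * (1.0 - c * (bs - as_) * (1.0 - d * bs / 5.0) / 3.0
                                + c * d * as_ * as_ / 5.0),
            0.0,
        )
        m2 = -hk < 100.0
        bb = np.sqrt(bs)
        sp = np.sqrt(2.0 * np.pi) * _phi(-bb / a_)
        bvn = bvn - np.where(
            m2,
            np.exp(-hk / 2.0) * sp * bb * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0),
            0.0,
        )
        a2 = a_ / 2.0
        for sign in (-1.0, 1.0):
            xs = (a2 * (1.0 + sign * _GL_X)) ** 2  # quadrature nodes, shape (20,)
            rs = np.sqrt(1.0 - xs)
            asr2 = -(bs.ravel()[None, :] / xs[:, None] + hk.ravel()[None, :]) / 2.0
            ok = asr2 > -100.0
            sp2 = 1.0 + c.ravel()[None, :] * xs[:, None] * (1.0 + d.ravel()[None, :] * xs[:, None])
            ep = np.exp(
                -hk.ravel()[None, :] * (1.0 - rs[:, None]) / (2.0 * (1.0 + rs[:, None]))
            ) / rs[:, None]
            term = np.where(ok, np.exp(asr2) * (ep - sp2), 0.0)
            bvn = bvn + (a2 * (_GL_W[:, None] * term).sum(axis=0)).reshape(dh.shape)
        bvn = -bvn / (2.0 * np.pi)
    if rho > 0:
        p = bvn + _phi(-np.maximum(dh, dk))
    else:
        p = -bvn + np.maximum(0.0, _phi(-dh) - _phi(-dk))
    return np.clip(p, 0.0, 1.0)


def bvn_pdf(a, b, rho: float) -> np.ndarray:
    """Standard bivariate normal density, vectorized over a and b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    det = 1.0 - rho * rho
    z = (a * a - 2.0 * rho * a * b + b * b) / det
    out = np.exp(-z / 2.0) / (2.0 * np.pi * np.sqrt(det))
    return np.where((np.abs(a) >= _INF) | (np.abs(b) >= _INF), 0.0, out)


def estimate_thresholds(x: np.ndarray, categories: Sequence[float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Thresholds from univariate margins: Phi^-1 of cumulative proportions.

    Returns (category values, thresholds); a column with a single observed
    category is rejected.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    cats = np.unique(x) if categories is None else np.asarray(categories, dtype=float)
    if len(cats) < 2:
        raise ValueError("need >= 2 observed categories")
    counts = np.array([(x == c).sum() for c in cats], dtype=float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    tau = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    return cats, tau


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-_INF], tau_x, [_INF]))
    ay = np.concatenate(([-_INF], tau_y, [_INF]))
    C = bvn_cdf(ax[:, None], ay[None, :], rho)
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, 1e-300, 1.0)


def _cell_dprobs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    # d Phi2(a, b; rho) / d rho = phi2(a, b; rho)
    ax = np.concatenate(([-_INF], tau_x, [_INF]))
    ay = np.concatenate(([-_INF], tau_y, [_INF]))
    D = bvn_pdf(ax[:, None], ay[None, :], rho)
    return D[1:, 1:] - D[:-1, 1:] - D[1:, :-1] + D[:-1, :-1]


@dataclass
class PairEstimate:
    rho: float
    clipped: bool
    influence: np.ndarray  # per (jointly observed) observation
    n: int


def polychoric_pair(x: np.ndarray, y: np.ndarray,
                    tau_x: np.ndarray | None = None,
                    tau_y: np.ndarray | None = None) -> PairEstimate:
    """Two-step ML polychoric (tetrachoric for 2x2) correlation of two
    ordinal columns; pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("empty pairwise overlap")
    cats_x, tx = estimate_thresholds(x)
    cats_y, ty = estimate_thresholds(y)
    if tau_x is not None:
        tx = np.asarray(tau_x, dtype=float)
    if tau_y is not None:
        ty = np.asarray(tau_y, dtype=float)
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    table = np.zeros((len(cats_x), len(cats_y)))
    np.add.at(table, (ix, iy), 1.0)

    def nll(r: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tx, ty, r))))

    res = optimize.minimize_scalar(nll, bounds=(-_CLIP, _CLIP), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    clipped = abs(rho) >= _CLIP - 1e-6
    if clipped:
        rho = np.sign(rho) * _CLIP
        warnings.warn("polychoric estimate at boundary; clipped to +/-0.999")
    P = _cell_probs(tx, ty, rho)
    dP = _cell_dprobs(tx, ty, rho)
    score_cell = dP / P
    info = float(np.sum(dP * score_cell))  # expected unit information
    info = max(info, 1e-12)
    influence = score_cell[ix, iy] / info
    return PairEstimate(rho=rho, clipped=clipped, influence=influence, n=x.size)


def polyserial_pair(z: np.ndarray, y: np.ndarray,
                    tau_y: np.ndarray | None = None) -> PairEstimate:
    """Two-step ML polyserial correlation of a continuous column (internally
    standardized) with an ordinal column."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(z) | np.isnan(y))
    z, y = z[ok], y[ok]
    if z.size == 0:
        raise ValueError("empty pairwise overlap")
    z = (z - z.mean()) / max(z.std(), 1e-12)
    cats_y, ty = estimate_thresholds(y)
    if tau_y is not None:
        ty = np.asarray(tau_y, dtype=float)
    iy = np.searchsorted(cats_y, y)
    hi = np.concatenate((ty, [_INF]))[iy]
    lo = np.concatenate(([-_INF], ty))[iy]

    def nll(r: float) -> float:
        s = np.sqrt(1.0 - r * r)
        p = _phi((hi - r * z) / s) - _phi((lo - r * z) / s)
        return -float(np.sum(np.log(np.clip(p, 1e-300, None))))

    res = optimize.minimize_scalar(nll, bounds=(-_CLIP, _CLIP), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    clipped = abs(rho) >= _CLIP - 1e-6
    if clipped:
        rho = np.sign(rho) * _CLIP
        warnings.warn("polyserial estimate at boundary; clipped to +/-0.999")
    # per-observation score by central difference of the cell log-likelihood
    eps = 1e-5

    def loglik_i(r: float) -> np.ndarray:
        s = np.sqrt(1.0 - r * r)
        p = _phi((hi - r * z) / s) - _phi((lo - r * z) / s)
        return np.log(np.clip(p, 1e-300, None))

    score = (loglik_i(rho + eps) - loglik_i(rho - eps)) / (2.0 * eps)
    info = max(float(np.mean(score ** 2)), 1e-12)
    return PairEstimate(rho=rho, clipped=clipped, influence=score / info, n=z.size)


def _pearson_pair(x: np.ndarray, y: np.ndarray) -> PairEstimate:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("empty pairwise overlap")
    x = (x - x.mean()) / max(x.std(), 1e-12)
    y = (y - y.mean()) / max(y.std(), 1e-12)
    r = float(np.mean(x * y))
    influence = x * y - r * (x * x + y * y) / 2.0
    return PairEstimate(rho=r, clipped=False, influence=influence, n=x.size)


@dataclass
class CorrelationResult:
    """Mixed polychoric/polyserial/Pearson correlation matrix.

    ``acov`` is the estimated asymptotic covariance (including the 1/n
    factor) of the vectorized lower-triangle correlations, ordered as
    ``pairs``.
    """

    columns: List[str]
    R: np.ndarray
    thresholds: Dict[str, np.ndarray]
    categories: Dict[str, np.ndarray]
    pairs: List[Tuple[str, str]]
    acov: np.ndarray | None
    pair_n: np.ndarray
    warnings: List[str] = field(default_factory=list)

    def corr_vector(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.columns)}
        return np.array([self.R[idx[a], idx[b]] for a, b in self.pairs])


def polychoric_matrix(data: pd.DataFrame,
                      ordinal: Sequence[str] | None = None,
                      continuous: Sequence[str] = (),
                      compute_acov: bool = True) -> CorrelationResult:
    """Pairwise correlation matrix of ordinal (polychoric/tetrachoric),
    mixed (polyserial) and continuous (Pearson) columns, with per-item
    thresholds and the influence-function asymptotic covariance of the
    correlation vector under pairwise-present observations."""
    continuous = list(continuous)
    if ordinal is None:
        ordinal = [c for c in data.columns if c not in continuous]
    cols = list(ordinal) + continuous
    is_ord = {c: c in set(ordinal) for c in cols}
    d = len(cols)
    n = len(data)
    thresholds: Dict[str, np.ndarray] = {}
    categories: Dict[str, np.ndarray] = {}
    for c in ordinal:
        cats, tau = estimate_thresholds(data[c].to_numpy(dtype=float))
        thresholds[c] = tau
        categories[c] = cats
    R = np.eye(d)
    pairs: List[Tuple[str, str]] = []
    warn_list: List[str] = []
    infl = np.zeros((n, d * (d - 1) // 2)) if compute_acov else None
    pair_n = np.zeros(d * (d - 1) // 2, dtype=int)
    k = 0
    for i in range(d):
        for j in range(i + 1, d):
            a, b = cols[i], cols[j]
            xa = data[a].to_numpy(dtype=float)
            xb = data[b].to_numpy(dtype=float)
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                if is_ord[a] and is_ord[b]:
                    est = polychoric_pair(xa, xb, thresholds[a], thresholds[b])
                elif is_ord[b]:
                    est = polyserial_pair(xa, xb, thresholds[b])
                elif is_ord[a]:
                    est = polyserial_pair(xb, xa, thresholds[a])
                else:
                    est = _pearson_pair(xa, xb)
            for w in wlist:
                warn_list.append(f"{a}~{b}: {w.message}")
            R[i, j] = R[j, i] = est.rho
            pairs.append((a, b))
            pair_n[k] = est.n
            if compute_acov:
                ok = ~(np.isnan(xa) | np.isnan(xb))
                infl[np.flatnonzero(ok), k] = est.influence
            k += 1
    acov = None
    if compute_acov:
        counts = (infl != 0).astype(float)
        # E[psi_p psi_q] over jointly observed rows, scaled by pair sizes
        overlap = counts.T @ counts
        overlap = np.maximum(overlap, 1.0)
        raw = (infl.T @ infl) / overlap
        scale = np.sqrt(np.outer(pair_n, pair_n))
        acov = raw / scale
        acov = 0.5 * (acov + acov.T)
    return CorrelationResult(columns=cols, R=R, thresholds=thresholds,
                             categories=categories, pairs=pairs, acov=acov,
                             pair_n=pair_n, warnings=warn_list)
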