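"""Estimation of autoregressive cross-lagged structural models.

Two routes, mirroring common practice for panel SEM with mixed ordinal and
binary indicators:

* ``wls`` — categorical-faithful: thresholds and a polychoric/polyserial
  correlation matrix are estimated first (pairwise-present observations),
  then the moment structure is fitted by diagonally weighted least squares
  with weights from the asymptotic variances of the correlations; standard
  errors are sandwich estimates and test statistics are mean-scaled.
  Ordinal/binary indicators follow the delta parameterization: latent
  response variances are fixed at one, so item residual variances (and the
  disturbance variance of a single-indicator construct) are derived, not
  free.

* ``ml`` — missingness-faithful: items treated as continuous under a
  normal-theory likelihood, either on the listwise covariance matrix or by
  full-information (casewise) likelihood over missingness patterns.

Recursive path models with every construct observed directly are solved in
closed form (per-equation OLS, the exact ML solution); the general
optimizer is used otherwise and is cross-checked against the closed form in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import Edge, Latent, ModelSpec, Node
from .polychoric import CorrelationResult, polychoric_matrix

__all__ = [
    "FitResult",
    "fit",
    "fit_indices",
    "standardize",
    "nested_test",
    "NotConvergedError",
]

_PENALTY = 1e4


class NotConvergedError(RuntimeError):
    pass


@dataclass
class _Param:
    name: str
    kind: str
    start: float
    slots: List[Tuple] = field(default_factory=list)  # ("L"|"B"|"P"|"T"|"M", i, j)


class _Assembler:
    """Maps the free-parameter vector to RAM matrices and the implied
    covariance; owns the bookkeeping of fixed, free, equality-constrained
    and derived (delta-parameterization) entries."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.wls = model.estimator == "wls"
        # latent order: covariates (wave 0) then constructs wave-major
        self.lat_nodes: List[Node] = [(c, 0) for c in model.covariates]
        for w in range(1, model.n_waves + 1):
            for lat in model.latents:
                if lat.wave == w:
                    self.lat_nodes.append(lat.node)
        self.lidx = {n: i for i, n in enumerate(self.lat_nodes)}
        self.obs = model.observed
        self.oidx = {c: i for i, c in enumerate(self.obs)}
        self.nL = len(self.lat_nodes)
        self.nO = len(self.obs)
        self.L_fixed = np.zeros((self.nO, self.nL))
        self.B_fixed = np.zeros((self.nL, self.nL))
        self.P_fixed = np.zeros((self.nL, self.nL))
        self.T_fixed = np.zeros((self.nO, self.nO))
        self.derived_psi: List[int] = []   # unit-total-variance latents (wls)
        self.derived_theta: List[int] = [] # items with derived residual (wls)
        self.params: List[_Param] = []
        self._by_name: Dict[str, _Param] = {}
        self._build()

    def _param(self, name: str, kind: str, start: float) -> _Param:
        p = self._by_name.get(name)
        if p is None:
            p = _Param(name, kind, start)
            self._by_name[name] = p
            self.params.append(p)
        return p

    def _build(self) -> None:
        m = self.model
        for cov in m.covariates:
            li = self.lidx[(cov, 0)]
            self.L_fixed[self.oidx[cov], li] = 1.0
            if self.wls:
                self.P_fixed[li, li] = 1.0  # correlation scale
            else:
                self._param(f"var({cov})", "psi_var", 1.0).slots.append(("P", li, li))
        for a_i, a in enumerate(m.covariates):
            for b in m.covariates[a_i + 1:]:
                p = self._param(f"cov({a},{b})", "psi_cov", 0.0)
                p.slots.append(("P", self.lidx[(a, 0)], self.lidx[(b, 0)]))
        endo = {e.dst for e in m.edges}
        for lat in m.latents:
            li = self.lidx[lat.node]
            for j, item in enumerate(lat.items):
                oi = self.oidx[item]
                if j == 0 or lat.single:
                    self.L_fixed[oi, li] = 1.0
                else:
                    tag = (f"lam({lat.construct},{j})"
                           if m.loadings_equal_over_waves
                           else f"lam({item})")
                    self._param(tag, "loading", 1.0).slots.append(("L", oi, li))
                if not self.wls and not lat.single:
                    self._param(f"theta({item})", "resid_var", 0.5).slots.append(
                        ("T", oi, oi))
                elif self.wls and not lat.single:
                    self.derived_theta.append(oi)
                # single-indicator: residual fixed 0 in both routes
            if self.wls and lat.single:
                self.derived_psi.append(li)
            else:
                start = 0.5 if not lat.single else 1.0
                if lat.node in endo:
                    start = 0.4
                self._param(f"psi({lat.construct}@{lat.wave})", "psi_var",
                            start).slots.append(("P", li, li))
        for e in m.edges:
            name = e.group or f"b({e.src[0]}@{e.src[1]}->{e.dst[0]}@{e.dst[1]})"
            start = 0.3 if e.src[0] == e.dst[0] else 0.0
            self._param(name, "beta", start).slots.append(
                ("B", self.lidx[e.dst], self.lidx[e.src]))
        for cov, c in m.covariate_targets:
            self._param(f"b({cov}->{c}@1)", "beta", 0.0).slots.append(
                ("B", self.lidx[(c, 1)], self.lidx[(cov, 0)]))
        if m.within_wave_covariances:
            for w in range(1, m.n_waves + 1):
                nodes = [l.node for l in m.latents if l.wave == w]
                for i, a in enumerate(nodes):
                    for b in nodes[i + 1:]:
                        self._param(f"psi({a[0]},{b[0]}@{w})", "psi_cov",
                                    0.0).slots.append(
                            ("P", self.lidx[a], self.lidx[b]))
        for (it1, it2) in m.error_covariances:
            self._param(f"thcov({it1},{it2})", "resid_cov", 0.02).slots.append(
                ("T", self.oidx[it1], self.oidx[it2]))

    # -- parameter vector ---------------------------------------------------
    @property
    def names(self) -> List[str]:
        return [p.name for p in self.params]

    @property
    def start(self) -> np.ndarray:
        return np.array([p.start for p in self.params])

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def matrices(self, theta: np.ndarray):
        L = self.L_fixed.copy()
        B = self.B_fixed.copy()
        P = self.P_fixed.copy()
        T = self.T_fixed.copy()
        for val, p in zip(theta, self.params):
            for (mat, i, j) in p.slots:
                if mat == "L":
                    L[i, j] = val
                elif mat == "B":
                    B[i, j] = val
                elif mat == "P":
                    P[i, j] = val
                    P[j, i] = val
                elif mat == "T":
                    T[i, j] = val
                    T[j, i] = val
        return L, B, P, T

    def implied(self, theta: np.ndarray):
        """Model-implied covariance (correlation in the wls route) and the
        latent covariance matrix; returns (Sigma, V, penalty)."""
        L, B, P, T = self.matrices(theta)
        penalty = 0.0
        G = np.linalg.inv(np.eye(self.nL) - B)
        if self.derived_psi:
            # disturbance variance of unit-variance latents = 1 - explained;
            # exact after n_waves sweeps because B only links adjacent waves
            for _ in range(self.model.n_waves + 2):
                V = G @ P @ G.T
                for j in self.derived_psi:
                    new = P[j, j] + (1.0 - V[j, j])
                    if new < 1e-6:
                        penalty += _PENALTY * (1e-6 - new) ** 2
                        new = 1e-6
                    P[j, j] = new
        V = G @ P @ G.T
        Sigma = L @ V @ L.T + T
        for oi in self.derived_theta:
            # delta parameterization: item residual = 1 - common variance,
            # so the implied latent-response variance is exactly 1
            resid = 1.0 - Sigma[oi, oi]
            if resid < 1e-6:
                penalty += _PENALTY * (1e-6 - resid) ** 2
            Sigma[oi, oi] = 1.0
        for val in np.diag(P):
            if val < 0:
                penalty += _PENALTY * val ** 2
        return Sigma, V, penalty


# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, uncertainty and fit of a structural model."""

    model: ModelSpec
    param_names: List[str]
    theta: np.ndarray
    vcov: np.ndarray
    n_used: int
    converged: bool
    n_iter: int
    gradient_norm: float
    chi_square: float
    df: int
    chi_square_unscaled: float
    scale_factor: float
    chi_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    structural: pd.DataFrame
    covariate_effects: pd.DataFrame
    latent_sd: Dict[Node, float]
    method: str
    warnings_: List[str] = field(default_factory=list)

    @property
    def n_waves(self) -> int:
        return self.model.n_waves

    def se(self, index: int) -> float:
        v = self.vcov[index, index]
        return float(np.sqrt(v)) if v > 0 else np.nan

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.param_names,
            "estimate": self.theta,
            "se": [self.se(i) for i in range(len(self.theta))],
        })


def fit_indices(chi_sq_model: float, df_model: int, chi_sq_null: float,
                df_null: int, n: int) -> Tuple[float, float]:
    """CFI and RMSEA from model and baseline chi-square statistics."""
    if df_model <= 0:
        raise ValueError("df_model must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    dm = max(chi_sq_model - df_model, 0.0)
    d0 = max(chi_sq_null - df_null, 0.0)
    cfi = 1.0 - dm / max(dm, d0, np.finfo(float).tiny) if max(dm, d0) > 0 else 1.0
    rmsea = float(np.sqrt(dm / (df_model * (n - 1))))
    return float(cfi), rmsea


def _num_jacobian(fun, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = np.asarray(fun(x))
    J = np.zeros((f0.size, x.size))
    for k in range(x.size):
        xp = x.copy(); xp[k] += eps
        xm = x.copy(); xm[k] -= eps
        J[:, k] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2 * eps)
    return J


def _num_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    p = x.size
    H = np.zeros((p, p))
    f0 = fun(x)
    fp = np.zeros(p); fm = np.zeros(p)
    for k in range(p):
        xp = x.copy(); xp[k] += eps
        xm = x.copy(); xm[k] -= eps
        fp[k] = fun(xp); fm[k] = fun(xm)
        H[k, k] = (fp[k] - 2 * f0 + fm[k]) / eps ** 2
    for k in range(p):
        for l in range(k + 1, p):
            xx = x.copy(); xx[k] += eps; xx[l] += eps
            H[k, l] = H[l, k] = (fun(xx) - fp[k] - fp[l] + f0) / eps ** 2
    return 0.5 * (H + H.T)


def _pinv_psd(A: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(0.5 * (A + A.T))
    w_inv = np.where(w > 1e-12 * max(w.max(), 1.0), 1.0 / w, 0.0)
    return (Q * w_inv) @ Q.T


def _structural_tables(asm: _Assembler, theta: np.ndarray, vcov: np.ndarray,
                       V: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame, Dict]:
    latent_sd = {n: float(np.sqrt(max(V[i, i], 0.0)))
                 for n, i in asm.lidx.items()}
    rows = []
    for e in asm.model.edges:
        name = e.group or f"b({e.src[0]}@{e.src[1]}->{e.dst[0]}@{e.dst[1]})"
        idx = asm.index_of(name)
        est = theta[idx]
        se = np.sqrt(vcov[idx, idx]) if vcov[idx, idx] > 0 else np.nan
        ratio = latent_sd[e.src] / max(latent_sd[e.dst], 1e-12)
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        rows.append({
            "src_construct": e.src[0], "src_wave": e.src[1],
            "dst_construct": e.dst[0], "dst_wave": e.dst[1],
            "est": est, "se": se,
            "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            "std": est * ratio, "sd_ratio": ratio, "index_": idx,
        })
    structural = pd.DataFrame(rows)
    cov_rows = []
    for cov, c in asm.model.covariate_targets:
        idx = asm.index_of(f"b({cov}->{c}@1)")
        est = theta[idx]
        se = np.sqrt(vcov[idx, idx]) if vcov[idx, idx] > 0 else np.nan
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        cov_rows.append({"covariate": cov, "construct": c, "est": est, "se": se,
                         "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan})
    return structural, pd.DataFrame(cov_rows), latent_sd


# ---------------------------------------------------------------------------
# closed-form route: recursive path model, everything observed


def _fit_path_ols(model: ModelSpec, data: pd.DataFrame,
                  asm: _Assembler) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact ML for a recursive all-observed path model: per-equation OLS.

    Residual variances enter the parameter vector on the ML scale (SSR/n);
    coefficient covariance blocks use the unbiased residual variance.
    Cross-equation coefficient covariances are zero under the model's
    independent-disturbance assumption.
    """
    cols = model.observed
    d = data[cols].dropna()
    n = len(d)
    node_col = {l.node: l.items[0] for l in model.latents}
    for c in model.covariates:
        node_col[(c, 0)] = c
    parents: Dict[Node, List[Tuple[Node, str]]] = {}
    for e in model.edges:
        name = f"b({e.src[0]}@{e.src[1]}->{e.dst[0]}@{e.dst[1]})"
        parents.setdefault(e.dst, []).append((e.src, name))
    for cov, c in model.covariate_targets:
        parents.setdefault((c, 1), []).append(((cov, 0), f"b({cov}->{c}@1)"))
    theta = asm.start.copy()
    vcov = np.zeros((len(theta), len(theta)))
    resid: Dict[Node, np.ndarray] = {}
    eq_info: Dict[Node, tuple] = {}
    for dst, plist in parents.items():
        y = d[node_col[dst]].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n)] +
                            [d[node_col[s]].to_numpy(dtype=float) for s, _ in plist])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        resid[dst] = r
        k = X.shape[1]
        s2_ml = float(r @ r) / n
        s2_ub = float(r @ r) / max(n - k, 1)
        xtx_inv = np.linalg.inv(X.T @ X)
        idxs = [asm.index_of(nm) for _, nm in plist]
        eq_info[dst] = (frozenset(s for s, _ in plist), idxs, xtx_inv, k)
        for a, ia in enumerate(idxs, start=1):
            theta[ia] = coef[a]
            for b, ib in enumerate(idxs, start=1):
                vcov[ia, ib] = s2_ub * xtx_inv[a, b]
        pv = asm.index_of(f"psi({dst[0]}@{dst[1]})")
        theta[pv] = s2_ml
        vcov[pv, pv] = 2 * s2_ml ** 2 / n
    # cross-equation coefficient covariances for equations sharing a
    # regressor set: cov(b_u, b_v) = sigma_uv (X'X)^-1
    if model.within_wave_covariances:
        dsts = list(eq_info)
        for i, u in enumerate(dsts):
            for v in dsts[i + 1:]:
                pu, iu, xtx_inv, k = eq_info[u]
                pv_, iv, _, _ = eq_info[v]
                if pu != pv_ or u[1] != v[1]:
                    continue
                s_uv = float(resid[u] @ resid[v]) / max(n - k, 1)
                for a, ia in enumerate(iu, start=1):
                    for b, ib in enumerate(iv, start=1):
                        vcov[ia, ib] = s_uv * xtx_inv[a, b]
                        vcov[ib, ia] = s_uv * xtx_inv[b, a]
    exo = [l.node for l in model.latents if l.node not in parents]
    exo += [(c, 0) for c in model.covariates]
    exo_pos = {nd: i for i, nd in enumerate(exo)}
    S_exo = np.zeros((len(exo), len(exo)))
    if exo:
        E = np.column_stack([d[node_col[nd]].to_numpy(dtype=float) for nd in exo])
        S_exo = np.cov(E, rowvar=False, ddof=0).reshape(len(exo), len(exo))
        for i, nd in enumerate(exo):
            key = (f"psi({nd[0]}@{nd[1]})" if nd[1] > 0 else f"var({nd[0]})")
            pi = asm.index_of(key)
            theta[pi] = S_exo[i, i]
            vcov[pi, pi] = 2 * S_exo[i, i] ** 2 / n
    # disturbance / exogenous covariances from residual or sample moments
    for p in asm.params:
        if p.kind != "psi_cov":
            continue
        for (_mat, i, j) in p.slots:
            a, b = asm.lat_nodes[i], asm.lat_nodes[j]
            pi = asm.index_of(p.name)
            if a in resid and b in resid:
                theta[pi] = float(np.mean(resid[a] * resid[b]))
            elif a in exo_pos and b in exo_pos:
                theta[pi] = float(S_exo[exo_pos[a], exo_pos[b]])
    return theta, vcov, n


# ---------------------------------------------------------------------------


def _ml_discrepancy(S: np.ndarray, logdet_S: float, asm: _Assembler):
    p = S.shape[0]

    def F(theta: np.ndarray) -> float:
        Sigma, _, pen = asm.implied(theta)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e8 + pen
        try:
            tr = float(np.trace(np.linalg.solve(Sigma, S)))
        except np.linalg.LinAlgError:
            return 1e8 + pen
        return logdet + tr - logdet_S - p + pen

    return F


def _fiml_neg2ll(data: np.ndarray, asm: _Assembler, mean_idx: np.ndarray):
    """Casewise -2 loglik grouped by missingness pattern; means are the
    trailing block of the parameter vector."""
    isnan = np.isnan(data)
    patterns: Dict[bytes, np.ndarray] = {}
    for i, row in enumerate(isnan):
        patterns.setdefault(row.tobytes(), []).append(i)
    groups = []
    for key, idxs in patterns.items():
        obs = ~np.frombuffer(key, dtype=bool)
        if obs.sum() == 0:
            continue
        groups.append((obs, data[np.asarray(idxs)][:, obs]))

    def neg2ll(theta_full: np.ndarray) -> float:
        theta = theta_full[: len(asm.params)]
        mu = theta_full[len(asm.params):]
        Sigma, _, pen = asm.implied(theta)
        total = 2.0 * pen
        for obs, X in groups:
            So = Sigma[np.ix_(obs, obs)]
            sign, logdet = np.linalg.slogdet(So)
            if sign <= 0:
                return 1e10
            diff = X - mu[obs]
            try:
                sol = np.linalg.solve(So, diff.T)
            except np.linalg.LinAlgError:
                return 1e10
            quad = float(np.sum(diff.T * sol))
            ni = X.shape[0]
            total += ni * (obs.sum() * np.log(2 * np.pi) + logdet) + quad
        return total

    return neg2ll


def _em_saturated(data: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """EM estimate of a saturated mean/covariance under MAR missingness."""
    n, p = data.shape
    mu = np.nanmean(data, axis=0)
    X0 = np.where(np.isnan(data), mu, data)
    Sigma = np.cov(X0, rowvar=False, ddof=0) + 1e-6 * np.eye(p)
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for i in range(n):
            obs = ~np.isnan(data[i])
            x = data[i]
            if obs.all():
                xc = x
                C = np.zeros((p, p))
            else:
                mis = ~obs
                So = Sigma[np.ix_(obs, obs)]
                Smo = Sigma[np.ix_(mis, obs)]
                sol = np.linalg.solve(So, (x[obs] - mu[obs]))
                xc = x.copy()
                xc[mis] = mu[mis] + Smo @ sol
                C = np.zeros((p, p))
                C[np.ix_(mis, mis)] = (Sigma[np.ix_(mis, mis)]
                                       - Smo @ np.linalg.solve(So, Smo.T))
            sum_x += xc
            sum_xx += np.outer(xc, xc) + C
        mu_new = sum_x / n
        Sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        if (np.max(np.abs(mu_new - mu)) < tol
                and np.max(np.abs(Sigma_new - Sigma)) < tol):
            mu, Sigma = mu_new, Sigma_new
            break
        mu, Sigma = mu_new, Sigma_new
    return mu, Sigma


def _loglik_gaussian(data: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    asm_dummy = None
    isnan = np.isnan(data)
    total = 0.0
    patterns: Dict[bytes, List[int]] = {}
    for i, row in enumerate(isnan):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, idxs in patterns.items():
        obs = ~np.frombuffer(key, dtype=bool)
        if obs.sum() == 0:
            continue
        X = data[np.asarray(idxs)][:, obs]
        So = Sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(So)
        diff = X - mu[obs]
        sol = np.linalg.solve(So, diff.T)
        quad = float(np.sum(diff.T * sol))
        total += -0.5 * (X.shape[0] * (obs.sum() * np.log(2 * np.pi) + logdet) + quad)
    return total


def _minimize(objective, x0: np.ndarray, seed: int = 0,
              max_iter: int = 1000) -> optimize.OptimizeResult:
    rng = np.random.default_rng(seed)
    best = None
    x = x0
    for attempt in range(4):
        res = optimize.minimize(objective, x, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success or np.linalg.norm(res.jac, np.inf) < 1e-6:
            best = res
            break
        x = x0 + 0.05 * rng.standard_normal(x0.size)  # jittered restart
    # polish with a higher-precision gradient; the default forward-difference
    # step limits coefficient accuracy to ~1e-4
    polish = optimize.minimize(objective, best.x, method="L-BFGS-B",
                               jac="3-point",
                               options={"maxiter": 200, "ftol": 1e-14,
                                        "gtol": 1e-10})
    if polish.fun <= best.fun:
        polish.nit += best.nit
        return polish
    return best


def fit(model: ModelSpec, data: pd.DataFrame, seed: int = 0,
        method: str | None = None) -> FitResult:
    """Estimate a ModelSpec on a wide panel table.

    ``method`` overrides route selection: "ols" forces the closed-form
    recursive path solution, "numeric" the general optimizer.
    """
    asm = _Assembler(model)
    warns: List[str] = []

    if model.estimator == "ml":
        return _fit_ml(model, data, asm, seed=seed, method=method, warns=warns)
    return _fit_wls(model, data, asm, seed=seed, warns=warns)


def _finish(model, asm, theta, vcov, n, converged, n_iter, gnorm,
            chi, df, chi_unscaled, scale, chi0, df0, method, warns) -> FitResult:
    _, V, _ = asm.implied(theta)
    structural, covefts, latent_sd = _structural_tables(asm, theta, vcov, V)
    if df > 0:
        cfi, rmsea = fit_indices(chi, df, chi0, df0, n)
    else:
        cfi, rmsea = 1.0, 0.0
    return FitResult(
        model=model, param_names=asm.names, theta=theta, vcov=vcov,
        n_used=n, converged=converged, n_iter=n_iter, gradient_norm=gnorm,
        chi_square=chi, df=df, chi_square_unscaled=chi_unscaled,
        scale_factor=scale, chi_baseline=chi0, df_baseline=df0,
        cfi=cfi, rmsea=rmsea, structural=structural,
        covariate_effects=covefts, latent_sd=latent_sd, method=method,
        warnings_=warns,
    )


def _parent_sets(model: ModelSpec) -> Dict[Node, frozenset]:
    parents: Dict[Node, set] = {}
    for e in model.edges:
        parents.setdefault(e.dst, set()).add(e.src)
    for cov, c in model.covariate_targets:
        parents.setdefault((c, 1), set()).add((cov, 0))
    return {k: frozenset(v) for k, v in parents.items()}


def _can_use_ols(model: ModelSpec) -> bool:
    """Per-equation OLS is the exact ML solution for an all-observed
    recursive system when disturbances are independent, or (seemingly-
    unrelated-regressions equivalence) when the equations of each wave
    share one regressor set."""
    if not (all(l.single for l in model.latents)
            and not model.error_covariances
            and all(e.group is None for e in model.edges)):
        return False
    if not model.within_wave_covariances:
        return True
    parents = _parent_sets(model)
    by_wave: Dict[int, set] = {}
    for (c, w), ps in parents.items():
        by_wave.setdefault(w, set()).add(ps)
    return all(len(sets) == 1 for sets in by_wave.values())


def _fit_ml(model, data, asm, seed, method, warns) -> FitResult:
    cols = model.observed
    n_free = len(asm.params)
    if method is None:
        method = "ols" if (_can_use_ols(model)
                           and model.missing_policy == "pairwise") else "numeric"
    if method == "ols":
        if not _can_use_ols(model):
            raise ValueError("closed-form route requires an all-observed "
                             "recursive model without constraints")
        theta, vcov, n = _fit_path_ols(model, data, asm)
        d = data[cols].dropna()
        S = np.cov(d.to_numpy(dtype=float), rowvar=False, ddof=0)
        sign, logdet_S = np.linalg.slogdet(S)
        F = _ml_discrepancy(S, logdet_S, asm)
        fmin = max(F(theta), 0.0)
        chi = n * fmin
        p = len(cols)
        df = p * (p + 1) // 2 - n_free
        chi0, df0 = _ml_baseline(S, n)
        return _finish(model, asm, theta, vcov, n, True, 0, 0.0,
                       chi, df, chi, 1.0, chi0, df0, "ols", warns)

    if model.missing_policy == "fiml":
        X = data[cols].to_numpy(dtype=float)
        X = X[~np.isnan(X).all(axis=1)]
        n = X.shape[0]
        p = len(cols)
        mu0 = np.nanmean(X, axis=0)
        neg2ll = _fiml_neg2ll(X, asm, np.arange(p))
        x0 = np.concatenate([asm.start, mu0])
        res = _minimize(lambda t: neg2ll(t) / n, x0, seed=seed)
        theta_full = res.x
        H = _num_hessian(neg2ll, theta_full)
        vcov_full = 2.0 * _pinv_psd(H)
        theta = theta_full[:n_free]
        vcov = vcov_full[:n_free, :n_free]
        mu_s, Sig_s = _em_saturated(X)
        ll_sat = _loglik_gaussian(X, mu_s, Sig_s)
        ll_hat = -0.5 * neg2ll(theta_full)
        chi = max(2.0 * (ll_sat - ll_hat), 0.0)
        df = p * (p + 1) // 2 - n_free
        # independence baseline: per-variable normal ML, closed form
        ll_base = 0.0
        for j in range(p):
            xj = X[:, j]
            xj = xj[~np.isnan(xj)]
            v = xj.var()
            ll_base += -0.5 * xj.size * (np.log(2 * np.pi * v) + 1.0)
        chi0 = max(2.0 * (ll_sat - ll_base), 0.0)
        df0 = p * (p - 1) // 2
        converged = res.success or np.linalg.norm(res.jac, np.inf) < 1e-5
        if not converged:
            warns.append(f"FIML optimizer: |grad|={np.linalg.norm(res.jac, np.inf):.2e}"
                         f" after {res.nit} iterations")
        return _finish(model, asm, theta, vcov, n, converged, res.nit,
                       float(np.linalg.norm(res.jac, np.inf)),
                       chi, df, chi, 1.0, chi0, df0, "fiml", warns)

    # complete-case normal-theory ML
    d = data[cols].dropna()
    n = len(d)
    S = np.cov(d.to_numpy(dtype=float), rowvar=False, ddof=0)
    p = len(cols)
    n_moments = p * (p + 1) // 2
    if n_free > n_moments:
        raise ValueError(f"model not identified: {n_free} parameters for "
                         f"{n_moments} moments")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        S = S + 1e-8 * np.eye(p)
        sign, logdet_S = np.linalg.slogdet(S)
        warns.append("sample covariance not PD; ridge added")
    F = _ml_discrepancy(S, logdet_S, asm)
    res = _minimize(F, asm.start, seed=seed)
    theta = res.x
    H = _num_hessian(F, theta)
    vcov = (2.0 / n) * _pinv_psd(H)
    chi = n * max(res.fun, 0.0)
    df = n_moments - n_free
    chi0, df0 = _ml_baseline(S, n)
    converged = res.success or np.linalg.norm(res.jac, np.inf) < 1e-6
    if not converged:
        warns.append(f"ML optimizer: |grad|={np.linalg.norm(res.jac, np.inf):.2e}"
                     f" after {res.nit} iterations")
    return _finish(model, asm, theta, vcov, n, converged, res.nit,
                   float(np.linalg.norm(res.jac, np.inf)),
                   chi, df, chi, 1.0, chi0, df0, "numeric", warns)


def _ml_baseline(S: np.ndarray, n: int) -> tuple[float, int]:
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    F0 = float(np.sum(np.log(np.diag(S))) - logdet_S)
    return n * max(F0, 0.0), p * (p - 1) // 2


def _fit_wls(model, data, asm, seed, warns) -> FitResult:
    cols = model.observed
    ordinal = [c for c in cols if c not in model.continuous_columns]
    corr = polychoric_matrix(data[cols], ordinal=ordinal,
                             continuous=[c for c in cols
                                         if c in model.continuous_columns])
    warns.extend(corr.warnings)
    s = corr.corr_vector()
    q = s.size
    n_free = len(asm.params)
    if n_free > q:
        raise ValueError(f"model not identified: {n_free} parameters for "
                         f"{q} correlation moments")
    Gam = corr.acov
    wdiag = np.clip(np.diag(Gam), 1e-12, None)
    W = 1.0 / wdiag
    tri = np.triu_indices(len(cols), k=1)

    def sigma_vec(theta: np.ndarray) -> np.ndarray:
        Sigma, _, _ = asm.implied(theta)
        return Sigma[tri]

    def F(theta: np.ndarray) -> float:
        Sigma, _, pen = asm.implied(theta)
        r = s - Sigma[tri]
        return float(np.sum(W * r * r)) + pen

    res = _minimize(F, asm.start, seed=seed)
    theta = res.x
    Delta = _num_jacobian(sigma_vec, theta)
    WD = Delta * W[:, None]
    H = Delta.T @ WD
    bread = _pinv_psd(H)
    meat = WD.T @ Gam @ WD
    vcov = bread @ meat @ bread
    # mean-scaled test statistic: E[F_min] = tr(U Gamma) under the model
    U = np.diag(W) - WD @ bread @ WD.T
    df = q - n_free
    trUG = float(np.trace(U @ Gam))
    T_raw = max(float(np.sum(W * (s - sigma_vec(theta)) ** 2)), 0.0)
    scale = trUG / df if df > 0 else 1.0
    chi = T_raw / scale if scale > 0 else T_raw
    # independence baseline: all correlations zero, no free parameters
    T0_raw = float(np.sum(W * s * s))
    df0 = q
    tr0 = float(np.trace(np.diag(W) @ Gam))
    chi0 = T0_raw / (tr0 / df0) if tr0 > 0 else T0_raw
    n = int(np.median(corr.pair_n))
    converged = res.success or np.linalg.norm(res.jac, np.inf) < 1e-6
    if not converged:
        warns.append(f"DWLS optimizer: |grad|={np.linalg.norm(res.jac, np.inf):.2e}"
                     f" after {res.nit} iterations")
    return _finish(model, asm, theta, vcov, n, converged, res.nit,
                   float(np.linalg.norm(res.jac, np.inf)),
                   chi, df, T_raw, scale, chi0, df0, "dwls", warns)


def standardize(fit: FitResult) -> Dict[tuple, float]:
    """Standardized structural coefficients: raw x sd(source)/sd(target)
    under the model-implied latent covariance."""
    out = {}
    for row in fit.structural.itertuples():
        src = (row.src_construct, row.src_wave)
        dst = (row.dst_construct, row.dst_wave)
        if fit.latent_sd[dst] <= 0:
            raise ZeroDivisionError(f"zero model-implied variance for {dst}")
        out[(src, dst)] = row.std
    return out


def nested_test(fit_free: FitResult, fit_constrained: FitResult
                ) -> Tuple[float, int, float]:
    """Chi-square difference test of nested structural constraints.

    Uses the scaled difference statistic when either fit carries a
    robust scale factor.
    """
    ddf = fit_constrained.df - fit_free.df
    if ddf < 0:
        raise ValueError("constrained model must have more df than free model")
    if ddf == 0:
        return 0.0, 0, 1.0
    c_f, c_c = fit_free.scale_factor, fit_constrained.scale_factor
    if abs(c_f - 1.0) > 1e-12 or abs(c_c - 1.0) > 1e-12:
        cd = (fit_constrained.df * c_c - fit_free.df * c_f) / ddf
        cd = max(cd, 1e-12)
        stat = max((fit_constrained.chi_square_unscaled
                    - fit_free.chi_square_unscaled) / cd, 0.0)
    else:
        stat = max(fit_constrained.chi_square - fit_free.chi_square, 0.0)
    p = float(stats.chi2.sf(stat, ddf))
    return float(stat), int(ddf), p
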