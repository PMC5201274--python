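"""Product-of-coefficients mediation effects over cross-lagged path systems.

The fitted autoregressive mediation model is viewed as a DAG whose nodes are
(construct, wave) pairs and whose edges are the forward lag-1 standardized
structural coefficients.  The overall indirect effect of the exposure at the
first analysis wave on the outcome at the last is the sum, over all forward
paths that visit a mediator node at least once, of the product of the edge
coefficients along the path; paths that avoid mediators sum to the overall
direct effect, and total = direct + indirect by construction.  Sampling
uncertainty is propagated by Monte Carlo simulation: coefficient vectors are
drawn from a multivariate normal centered at the estimates with the fit's
covariance, the decomposition is recomputed per draw, and percentile
intervals are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

Node = Tuple[str, int]

__all__ = [
    "EffectDecomposition",
    "StructuralGraph",
    "enumerate_paths",
    "effect_decomposition",
    "monte_carlo_ci",
    "mediation_report",
    "parse_report",
]

#: |total| below this is treated as zero when forming the proportion mediated
_TOTAL_TOL = 10 * np.finfo(float).eps


@dataclass
class EffectDecomposition:
    """Total/direct/indirect effect decomposition with optional MC intervals."""

    total: float
    direct: float
    indirect: float
    proportion_mediated: float = np.nan
    ci_total: Tuple[float, float] | None = None
    ci_direct: Tuple[float, float] | None = None
    ci_indirect: Tuple[float, float] | None = None
    level: float = 0.95
    n_draws: int = 0
    seed: int | None = None
    significant: Dict[str, bool] = field(default_factory=dict)
    proportion_interpretable: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.total, self.direct + self.indirect, atol=1e-10):
            raise ValueError("total must equal direct + indirect")


class StructuralGraph:
    """(construct, wave) DAG of forward lag-1 structural edges.

    Each edge carries the standardized coefficient (``coef``), the index of
    the underlying raw parameter in the fit's estimate vector (``index``),
    and the standardization ratio sd(source)/sd(target) (``sd_ratio``)
    applied to raw draws.
    """

    def __init__(self, x: str, mediators: Sequence[str], y: str, n_waves: int):
        self.x = x
        self.mediators = tuple(mediators)
        self.y = y
        self.n_waves = n_waves
        self.graph = nx.DiGraph()

    def add_edge(
        self,
        src: Node,
        dst: Node,
        coef: float,
        index: int | None = None,
        sd_ratio: float = 1.0,
    ) -> None:
        if dst[1] != src[1] + 1:
            raise ValueError(f"edge {src}->{dst} does not advance exactly one wave")
        self.graph.add_edge(src, dst, coef=float(coef), index=index, sd_ratio=sd_ratio)

    @property
    def source(self) -> Node:
        return (self.x, 1)

    @property
    def sink(self) -> Node:
        return (self.y, self.n_waves)

    def edges(self) -> Iterable[tuple[Node, Node, dict]]:
        return self.graph.edges(data=True)

    @classmethod
    def from_fit(
        cls,
        fit,
        x: str,
        mediators: Sequence[str],
        y: str,
        constructs: Sequence[str] | None = None,
    ) -> "StructuralGraph":
        """Build the graph from a FitResult's structural table, keeping only
        forward lag-1 edges among the selected constructs."""
        keep = set([x, y, *mediators]) if constructs is None else set(constructs)
        g = cls(x, mediators, y, fit.n_waves)
        for row in fit.structural.itertuples():
            if row.src_construct not in keep or row.dst_construct not in keep:
                continue
            if row.dst_wave != row.src_wave + 1:
                continue
            g.add_edge(
                (row.src_construct, row.src_wave),
                (row.dst_construct, row.dst_wave),
                coef=row.std,
                index=row.index_,
                sd_ratio=row.sd_ratio,
            )
        return g


def enumerate_paths(graph: StructuralGraph) -> tuple[list[list[Node]], list[list[Node]]]:
    """All forward paths from exposure@wave1 to outcome@waveT, split into
    (indirect, direct): a path is indirect iff it visits >= 1 mediator node."""
    g = graph.graph
    if graph.source not in g or graph.sink not in g:
        raise ValueError("source or sink node absent from graph")
    meds = set(graph.mediators)
    indirect, direct = [], []
    for path in nx.all_simple_paths(g, graph.source, graph.sink):
        if any(node[0] in meds for node in path[1:-1]):
            indirect.append(path)
        else:
            direct.append(path)
    return indirect, direct


def _path_product(graph: nx.DiGraph, path: Sequence[Node], key: str = "coef") -> float:
    out = 1.0
    for a, b in zip(path, path[1:]):
        out *= graph[a][b][key]
    return out


def effect_decomposition(graph: StructuralGraph) -> EffectDecomposition:
    """Point-estimate decomposition by products of standardized coefficients."""
    ind_paths, dir_paths = enumerate_paths(graph)
    indirect = sum(_path_product(graph.graph, p) for p in ind_paths)
    direct = sum(_path_product(graph.graph, p) for p in dir_paths)
    total = direct + indirect
    prop = indirect / total if abs(total) > _TOTAL_TOL else np.nan
    return EffectDecomposition(
        total=total,
        direct=direct,
        indirect=indirect,
        proportion_mediated=prop,
        proportion_interpretable=abs(total) > _TOTAL_TOL,
    )


def _nearest_psd(V: np.ndarray) -> np.ndarray:
    V = 0.5 * (V + V.T)
    w, Q = np.linalg.eigh(V)
    if w.min() >= 0:
        return V
    w = np.clip(w, 0.0, None)
    return (Q * w) @ Q.T


def monte_carlo_ci(
    fit,
    graph: StructuralGraph,
    n_draws: int = 20_000,
    level: float = 0.95,
    seed: int = 0,
) -> EffectDecomposition:
    """Monte Carlo percentile intervals for the effect decomposition.

    Draws raw structural-coefficient vectors from N(estimates, vcov)
    restricted to the edges of the graph, standardizes each draw with the
    point-estimate sd ratios, recomputes indirect/direct/total per draw and
    returns percentile intervals; deterministic given ``seed``.
    """
    point = effect_decomposition(graph)
    edges = list(graph.edges())
    idx = sorted({d["index"] for _, _, d in edges if d["index"] is not None})
    if not idx:
        raise ValueError("graph carries no estimable edge coefficients")
    pos = {i: k for k, i in enumerate(idx)}
    mu = np.asarray(fit.theta)[idx]
    V = np.asarray(fit.vcov)[np.ix_(idx, idx)]
    if np.any(np.linalg.eigvalsh(0.5 * (V + V.T)) < -1e-10):
        V = _nearest_psd(V)
    rng = np.random.default_rng(seed)
    w, Q = np.linalg.eigh(_nearest_psd(V))
    A = Q * np.sqrt(np.clip(w, 0.0, None))  # exact for singular vcov
    draws = mu[None, :] + rng.standard_normal((n_draws, len(idx))) @ A.T

    # standardized edge draws, ndraws x n_edges
    edge_draws = {}
    for a, b, d in edges:
        if d["index"] is None:
            edge_draws[(a, b)] = np.full(n_draws, d["coef"])
        else:
            edge_draws[(a, b)] = draws[:, pos[d["index"]]] * d["sd_ratio"]

    ind_paths, dir_paths = enumerate_paths(graph)

    def _sum_products(paths):
        out = np.zeros(n_draws)
        for p in paths:
            prod = np.ones(n_draws)
            for a, b in zip(p, p[1:]):
                prod *= edge_draws[(a, b)]
            out += prod
        return out

    ind = _sum_products(ind_paths)
    dire = _sum_products(dir_paths)
    tot = ind + dire
    lo, hi = 50 * (1 - level), 50 * (1 + level)
    ci = {k: tuple(np.percentile(v, [lo, hi])) for k, v in
          (("indirect", ind), ("direct", dire), ("total", tot))}
    sig = {k: not (ci[k][0] <= 0.0 <= ci[k][1]) for k in ci}
    interpretable = abs(point.total) > _TOTAL_TOL and sig["total"]
    return EffectDecomposition(
        total=point.total,
        direct=point.direct,
        indirect=point.indirect,
        proportion_mediated=point.indirect / point.total
        if abs(point.total) > _TOTAL_TOL
        else np.nan,
        ci_total=ci["total"],
        ci_direct=ci["direct"],
        ci_indirect=ci["indirect"],
        level=level,
        n_draws=n_draws,
        seed=seed,
        significant=sig,
        proportion_interpretable=interpretable,
    )


def path_breakdown(graph: StructuralGraph) -> pd.DataFrame:
    """Per-path table: path string, coefficient product, and each indirect
    path's share of the overall indirect effect."""
    ind_paths, dir_paths = enumerate_paths(graph)
    indirect_sum = sum(_path_product(graph.graph, p) for p in ind_paths)
    rows = []
    for kind, paths in (("indirect", ind_paths), ("direct", dir_paths)):
        for p in paths:
            prod = _path_product(graph.graph, p)
            rows.append({
                "path": " -> ".join(f"{c}@{w}" for c, w in p),
                "kind": kind,
                "product": prod,
                "share_of_indirect": (prod / indirect_sum
                                      if kind == "indirect" and abs(indirect_sum) > _TOTAL_TOL
                                      else np.nan),
            })
    return pd.DataFrame(rows, columns=["path", "kind", "product", "share_of_indirect"])


_REPORT_COLS = [
    "model",
    "total", "total_lo", "total_hi", "total_sig",
    "direct", "direct_lo", "direct_hi", "direct_sig",
    "indirect", "indirect_lo", "indirect_hi", "indirect_sig",
    "proportion_mediated", "proportion_interpretable",
    "n_draws", "level",
]


def mediation_report(decompositions: Mapping[str, EffectDecomposition]) -> pd.DataFrame:
    """One row per exposure-mediator-outcome model: the three effects with
    percentile CIs, significance markers and the proportion mediated.
    Returns an empty (but fully typed) table when no mediator passed gating.
    """
    rows = []
    for model, d in decompositions.items():
        rows.append({
            "model": model,
            "total": d.total,
            "total_lo": d.ci_total[0] if d.ci_total else np.nan,
            "total_hi": d.ci_total[1] if d.ci_total else np.nan,
            "total_sig": d.significant.get("total", False),
            "direct": d.direct,
            "direct_lo": d.ci_direct[0] if d.ci_direct else np.nan,
            "direct_hi": d.ci_direct[1] if d.ci_direct else np.nan,
            "direct_sig": d.significant.get("direct", False),
            "indirect": d.indirect,
            "indirect_lo": d.ci_indirect[0] if d.ci_indirect else np.nan,
            "indirect_hi": d.ci_indirect[1] if d.ci_indirect else np.nan,
            "indirect_sig": d.significant.get("indirect", False),
            "proportion_mediated": d.proportion_mediated,
            "proportion_interpretable": d.proportion_interpretable,
            "n_draws": d.n_draws,
            "level": d.level,
        })
    return pd.DataFrame(rows, columns=_REPORT_COLS)


def parse_report(table: pd.DataFrame) -> Dict[str, EffectDecomposition]:
    """Inverse of :func:`mediation_report` (round-trip safe)."""
    out: Dict[str, EffectDecomposition] = {}
    for row in table.itertuples(index=False):
        out[row.model] = EffectDecomposition(
            total=row.total,
            direct=row.direct,
            indirect=row.indirect,
            proportion_mediated=row.proportion_mediated,
            ci_total=(row.total_lo, row.total_hi),
            ci_direct=(row.direct_lo, row.direct_hi),
            ci_indirect=(row.indirect_lo, row.indirect_hi),
            level=row.level,
            n_draws=int(row.n_draws),
            significant={
                "total": bool(row.total_sig),
                "direct": bool(row.direct_sig),
                "indirect": bool(row.indirect_sig),
            },
            proportion_interpretable=bool(row.proportion_interpretable),
        )
    return out
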