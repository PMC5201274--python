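"""Declarative specification of autoregressive cross-lagged latent models.

A model is a set of construct-wave latents, each measured by one or more
items (first loading fixed to 1 for identification; a single-indicator
construct is the observed variable itself), directed lag-1 structural
edges among them (free per transition or constrained equal over time),
cross-wave covariances between the errors of the same item, and optional
baseline covariates entering the wave-1 constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

Node = Tuple[str, int]

__all__ = ["Latent", "Edge", "ModelSpec", "crosslagged_spec"]


@dataclass(frozen=True)
class Latent:
    construct: str
    wave: int
    items: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError(f"latent {self.construct}@{self.wave} needs >= 1 item")

    @property
    def node(self) -> Node:
        return (self.construct, self.wave)

    @property
    def single(self) -> bool:
        return len(self.items) == 1


@dataclass(frozen=True)
class Edge:
    src: Node
    dst: Node
    group: str | None = None  # equality-constraint label; None = free

    def __post_init__(self) -> None:
        if self.dst[1] != self.src[1] + 1:
            raise ValueError(f"structural edge {self.src}->{self.dst} must span one wave")


@dataclass
class ModelSpec:
    """Measurement + structural model, serializable to/from plain dicts."""

    latents: List[Latent]
    edges: List[Edge]
    error_covariances: List[Tuple[str, str]] = field(default_factory=list)
    covariates: Tuple[str, ...] = ()
    covariate_targets: List[Tuple[str, str]] = field(default_factory=list)  # (cov, construct@wave1)
    continuous_columns: Tuple[str, ...] = ()  # treated as continuous in the wls route
    estimator: str = "wls"
    missing_policy: str = "pairwise"
    within_wave_covariances: bool = True
    loadings_equal_over_waves: bool = True

    def __post_init__(self) -> None:
        if self.estimator not in ("wls", "ml"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.missing_policy not in ("pairwise", "fiml"):
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")
        nodes = {lat.node for lat in self.latents}
        if len(nodes) != len(self.latents):
            raise ValueError("duplicate construct-wave latents")
        for e in self.edges:
            if e.src not in nodes or e.dst not in nodes:
                raise ValueError(f"edge {e.src}->{e.dst} references unknown latent")
        for cov, c in self.covariate_targets:
            if cov not in self.covariates:
                raise ValueError(f"covariate target references unknown covariate {cov!r}")
            if (c, 1) not in nodes:
                raise ValueError(f"covariate target {c!r} is not a wave-1 construct")
        items = [it for lat in self.latents for it in lat.items]
        if len(items) != len(set(items)):
            raise ValueError("an item may load on only one latent")

    @property
    def constructs(self) -> List[str]:
        seen: Dict[str, None] = {}
        for lat in self.latents:
            seen.setdefault(lat.construct, None)
        return list(seen)

    @property
    def n_waves(self) -> int:
        return max(lat.wave for lat in self.latents)

    @property
    def observed(self) -> List[str]:
        cols = [it for lat in sorted(self.latents, key=lambda l: l.wave) for it in lat.items]
        return cols + list(self.covariates)

    def latent(self, node: Node) -> Latent:
        for lat in self.latents:
            if lat.node == node:
                return lat
        raise KeyError(node)

    def to_dict(self) -> dict:
        return {
            "latents": [
                {"construct": l.construct, "wave": l.wave, "items": list(l.items)}
                for l in self.latents
            ],
            "edges": [
                {"src": list(e.src), "dst": list(e.dst), "group": e.group}
                for e in self.edges
            ],
            "error_covariances": [list(p) for p in self.error_covariances],
            "covariates": list(self.covariates),
            "covariate_targets": [list(p) for p in self.covariate_targets],
            "continuous_columns": list(self.continuous_columns),
            "estimator": self.estimator,
            "missing_policy": self.missing_policy,
            "within_wave_covariances": self.within_wave_covariances,
            "loadings_equal_over_waves": self.loadings_equal_over_waves,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            latents=[Latent(x["construct"], x["wave"], tuple(x["items"]))
                     for x in d["latents"]],
            edges=[Edge(tuple(x["src"]), tuple(x["dst"]), x.get("group"))
                   for x in d["edges"]],
            error_covariances=[tuple(p) for p in d.get("error_covariances", [])],
            covariates=tuple(d.get("covariates", ())),
            covariate_targets=[tuple(p) for p in d.get("covariate_targets", [])],
            continuous_columns=tuple(d.get("continuous_columns", ())),
            estimator=d.get("estimator", "wls"),
            missing_policy=d.get("missing_policy", "pairwise"),
            within_wave_covariances=d.get("within_wave_covariances", True),
            loadings_equal_over_waves=d.get("loadings_equal_over_waves", True),
        )


def crosslagged_spec(
    construct_items: Mapping[str, Sequence[Sequence[str]]],
    cross_pairs: Sequence[Tuple[str, str]] | str = "all",
    equal_over_time: bool = False,
    error_covariances: bool = True,
    covariates: Sequence[str] = (),
    estimator: str = "wls",
    missing_policy: str = "pairwise",
    continuous_columns: Sequence[str] = (),
    within_wave_covariances: bool = True,
) -> ModelSpec:
    """Build the standard autoregressive cross-lagged specification.

    ``construct_items[name][t]`` lists the item columns of construct
    ``name`` at wave t+1.  All constructs get autoregressive lag-1 paths;
    ``cross_pairs`` selects directed cross-lagged pairs ("all" = every
    ordered pair, covering both the hypothesized and the reverse
    direction).  With ``equal_over_time`` the selected paths share one
    coefficient per pair across transitions (the constrained model of the
    nested-constraint test); otherwise each transition is free.
    """
    names = list(construct_items)
    n_waves = len(next(iter(construct_items.values())))
    latents = []
    for name in names:
        waves = construct_items[name]
        if len(waves) != n_waves:
            raise ValueError("all constructs must be measured at all waves")
        for w, items in enumerate(waves, start=1):
            latents.append(Latent(name, w, tuple(items)))
    if cross_pairs == "all":
        pairs = [(a, b) for a in names for b in names if a != b]
    else:
        pairs = list(cross_pairs)
    edges = []
    for t in range(1, n_waves):
        for name in names:
            grp = f"ar:{name}" if equal_over_time else None
            edges.append(Edge((name, t), (name, t + 1), grp))
        for a, b in pairs:
            grp = f"cl:{a}->{b}" if equal_over_time else None
            edges.append(Edge((a, t), (b, t + 1), grp))
    ecovs: List[Tuple[str, str]] = []
    if error_covariances:
        for name in names:
            waves = construct_items[name]
            if len(waves[0]) < 2:
                continue  # single indicators have no separable item error
            for j in range(len(waves[0])):
                for t1 in range(n_waves):
                    for t2 in range(t1 + 1, n_waves):
                        ecovs.append((waves[t1][j], waves[t2][j]))
    cov_targets = [(cov, name) for cov in covariates for name in names]
    return ModelSpec(
        latents=latents,
        edges=edges,
        error_covariances=ecovs,
        covariates=tuple(covariates),
        covariate_targets=cov_targets,
        continuous_columns=tuple(continuous_columns),
        estimator=estimator,
        missing_policy=missing_policy,
        within_wave_covariances=within_wave_covariances,
    )
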