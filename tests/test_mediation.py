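"""Path enumeration, product-of-coefficients decomposition against the
matrix-product oracle, Monte Carlo intervals, and report round-trips."""

import numpy as np
import pandas as pd
import pytest

from panelmediate.mediation import (EffectDecomposition, StructuralGraph,
                                    effect_decomposition, enumerate_paths,
                                    mediation_report, monte_carlo_ci,
                                    parse_report, path_breakdown)


def _full_forward_graph(T, coefs=None, rng=None):
    """X/M/Y graph with the full forward edge set per transition:
    X->X, X->M, X->Y, M->M, M->Y, Y->Y."""
    g = StructuralGraph("X", ["M"], "Y", T)
    idx = 0
    for t in range(1, T):
        for (a, b) in [("X", "X"), ("X", "M"), ("X", "Y"),
                       ("M", "M"), ("M", "Y"), ("Y", "Y")]:
            c = (coefs[(a, b, t)] if coefs is not None
                 else rng.uniform(-0.5, 0.5))
            g.add_edge((a, t), (b, t + 1), coef=c, index=idx)
            idx += 1
    return g


def _matrix_oracle(graph):
    """Independent oracle: total from the ordered product of per-transition
    coefficient matrices; direct from the product with edges into M zeroed."""
    names = ["X", "M", "Y"]
    pos = {c: i for i, c in enumerate(names)}
    T = graph.n_waves
    total_m = np.eye(3)
    direct_m = np.eye(3)
    for t in range(1, T):
        B = np.zeros((3, 3))
        for (a, w), (b, w2), d in graph.edges():
            if w == t:
                B[pos[b], pos[a]] = d["coef"]
        Bd = B.copy()
        Bd[pos["M"], :] = 0.0
        total_m = B @ total_m
        direct_m = Bd @ direct_m
    total = total_m[pos["Y"], pos["X"]]
    direct = direct_m[pos["Y"], pos["X"]]
    return total, direct, total - direct


class TestEnumeratePaths:
    def test_four_wave_full_forward_set(self):
        g = _full_forward_graph(4, coefs={k: 0.1 for k in
                                          [(a, b, t) for t in (1, 2, 3)
                                           for (a, b) in [("X", "X"), ("X", "M"), ("X", "Y"),
                                                          ("M", "M"), ("M", "Y"), ("Y", "Y")]]})
        ind, dire = enumerate_paths(g)
        assert len(ind) == 3 and len(dire) == 3
        as_strings = {" ".join(f"{c}{w}" for c, w in p) for p in ind}
        assert as_strings == {"X1 M2 M3 Y4", "X1 M2 Y3 Y4", "X1 X2 M3 Y4"}
        dir_strings = {" ".join(f"{c}{w}" for c, w in p) for p in dire}
        assert dir_strings == {"X1 X2 X3 Y4", "X1 X2 Y3 Y4", "X1 Y2 Y3 Y4"}

    def test_two_wave_single_direct_path(self):
        g = StructuralGraph("X", ["M"], "Y", 2)
        g.add_edge(("X", 1), ("Y", 2), 0.3, index=0)
        ind, dire = enumerate_paths(g)
        assert ind == [] and len(dire) == 1

    def test_three_wave_counts(self):
        rng = np.random.default_rng(0)
        g = _full_forward_graph(3, rng=rng)
        ind, dire = enumerate_paths(g)
        assert len(ind) == 1 and len(dire) == 2
        assert [c for c, _ in ind[0]] == ["X", "M", "Y"]

    def test_missing_source_rejected(self):
        g = StructuralGraph("X", ["M"], "Y", 3)
        g.add_edge(("M", 1), ("Y", 2), 0.1)
        with pytest.raises(ValueError):
            enumerate_paths(g)


class TestEffectDecomposition:
    def test_zero_exposure_to_mediator(self):
        coefs = {k: 0.2 for k in [(a, b, t) for t in (1, 2, 3)
                 for (a, b) in [("X", "X"), ("X", "M"), ("X", "Y"),
                                ("M", "M"), ("M", "Y"), ("Y", "Y")]]}
        for t in (1, 2, 3):
            coefs[("X", "M", t)] = 0.0
        d = effect_decomposition(_full_forward_graph(4, coefs=coefs))
        assert d.indirect == 0.0
        assert d.total == d.direct

    def test_single_product(self):
        g = StructuralGraph("X", ["M"], "Y", 3)
        g.add_edge(("X", 1), ("M", 2), 0.5, index=0)
        g.add_edge(("M", 2), ("Y", 3), 0.4, index=1)
        d = effect_decomposition(g)
        assert d.indirect == pytest.approx(0.20, abs=1e-15)
        assert d.direct == 0.0
        assert d.proportion_mediated == pytest.approx(1.0)

    @pytest.mark.parametrize("T", [2, 3, 4, 5])
    def test_matrix_product_oracle_equivalence(self, T):
        """Sum-over-paths decomposition == matrix-product oracle to 1e-12
        for random coefficient assignments."""
        rng = np.random.default_rng(T)
        for _ in range(30):
            g = _full_forward_graph(T, rng=rng)
            d = effect_decomposition(g)
            total, direct, indirect = _matrix_oracle(g)
            assert d.total == pytest.approx(total, abs=1e-12)
            assert d.direct == pytest.approx(direct, abs=1e-12)
            assert d.indirect == pytest.approx(indirect, abs=1e-12)
            assert d.total == pytest.approx(d.direct + d.indirect, abs=1e-14)

    def test_path_breakdown_shares_sum_to_one(self):
        rng = np.random.default_rng(9)
        g = _full_forward_graph(4, rng=rng)
        table = path_breakdown(g)
        ind = table[table.kind == "indirect"]
        assert ind["share_of_indirect"].sum() == pytest.approx(1.0, abs=1e-12)
        assert len(table) == 6


class _FakeFit:
    def __init__(self, theta, vcov):
        self.theta = np.asarray(theta, dtype=float)
        self.vcov = np.asarray(vcov, dtype=float)


class TestMonteCarloCI:
    def test_zero_vcov_degenerate(self):
        g = StructuralGraph("X", ["M"], "Y", 3)
        g.add_edge(("X", 1), ("M", 2), 0.5, index=0)
        g.add_edge(("M", 2), ("Y", 3), 0.4, index=1)
        fit = _FakeFit([0.5, 0.4], np.zeros((2, 2)))
        d = monte_carlo_ci(fit, g, n_draws=2000, seed=0)
        assert d.ci_indirect == pytest.approx((0.2, 0.2), abs=1e-12)
        assert d.ci_total == pytest.approx((0.2, 0.2), abs=1e-12)

    def test_single_edge_matches_normal_quantiles(self):
        """A one-edge 'effect' is a linear function of one coefficient, so
        the percentile interval must match est +/- 1.96 SE."""
        g = StructuralGraph("X", [], "Y", 2)
        g.add_edge(("X", 1), ("Y", 2), 0.3, index=0)
        se = 0.07
        fit = _FakeFit([0.3], [[se ** 2]])
        d = monte_carlo_ci(fit, g, n_draws=200_000, seed=1)
        assert d.ci_total[0] == pytest.approx(0.3 - 1.96 * se, abs=0.002)
        assert d.ci_total[1] == pytest.approx(0.3 + 1.96 * se, abs=0.002)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        g = _full_forward_graph(4, rng=rng)
        p = 18
        A = rng.standard_normal((p, p))
        fit = _FakeFit(rng.standard_normal(p) * 0.1, 0.001 * (A @ A.T))
        d1 = monte_carlo_ci(fit, g, n_draws=5000, seed=7)
        d2 = monte_carlo_ci(fit, g, n_draws=5000, seed=7)
        assert d1.ci_indirect == d2.ci_indirect
        assert d1.ci_total == d2.ci_total

    def test_nonpsd_vcov_repaired(self):
        g = StructuralGraph("X", ["M"], "Y", 3)
        g.add_edge(("X", 1), ("M", 2), 0.5, index=0)
        g.add_edge(("M", 2), ("Y", 3), 0.4, index=1)
        V = np.array([[0.01, 0.02], [0.02, 0.01]])  # indefinite
        d = monte_carlo_ci(_FakeFit([0.5, 0.4], V), g, n_draws=2000, seed=0)
        assert d.ci_indirect[0] <= 0.2 <= d.ci_indirect[1]

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        g = _full_forward_graph(4, rng=rng)
        theta = np.zeros(18)
        for _, _, d_ in g.edges():
            theta[d_["index"]] = d_["coef"]
        fit = _FakeFit(theta, 0.002 * np.eye(18))
        d = monte_carlo_ci(fit, g, n_draws=20_000, seed=4)
        for point, ci in ((d.total, d.ci_total), (d.direct, d.ci_direct),
                          (d.indirect, d.ci_indirect)):
            assert ci[0] <= point <= ci[1]


class TestReport:
    def _decomp(self):
        return EffectDecomposition(
            total=-0.10957, direct=-0.10097, indirect=-0.0086,
            proportion_mediated=0.0785,
            ci_total=(-0.1504, -0.06852), ci_direct=(-0.1498, -0.06801),
            ci_indirect=(-0.031, 0.0091), level=0.95, n_draws=20000,
            significant={"total": True, "direct": True, "indirect": False})

    def test_roundtrip(self):
        table = mediation_report({"sup-alco-dep": self._decomp()})
        back = parse_report(table)["sup-alco-dep"]
        assert back.total == pytest.approx(-0.10957)
        assert back.ci_indirect == pytest.approx((-0.031, 0.0091))
        assert back.significant == {"total": True, "direct": True,
                                    "indirect": False}

    def test_four_row_support_shape(self):
        decomps = {f"sup-{m}-dep": self._decomp()
                   for m in ("alco", "diet", "inact", "nbehav")}
        table = mediation_report(decomps)
        assert len(table) == 4
        assert list(table.model) == ["sup-alco-dep", "sup-diet-dep",
                                     "sup-inact-dep", "sup-nbehav-dep"]

    def test_empty_table_has_header(self):
        table = mediation_report({})
        assert table.empty and "indirect_lo" in table.columns

    def test_identity_enforced(self):
        with pytest.raises(ValueError):
            EffectDecomposition(total=0.5, direct=0.1, indirect=0.1)
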