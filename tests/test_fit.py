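"""Estimation engine: closed-form vs numerical ML equivalence, saturated
fit, fit indices, parameter recovery, standardization invariance, nested
constraint tests, and the two estimation routes' agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelmediate.fit import fit, fit_indices, nested_test, standardize
from panelmediate.model import ModelSpec, crosslagged_spec
from panelmediate.simulate import (ItemBlock, Missingness, SimConfig,
                                   apply_missingness, generate_panel,
                                   three_construct_config, true_effects)


def _toy_two_wave_spec(estimator="ml", **kw):
    items = {c: [[f"lat_{c}_w{w}"] for w in (1, 2)] for c in ("X", "Y")}
    return crosslagged_spec(items, cross_pairs="all", estimator=estimator,
                            error_covariances=False, **kw)


@pytest.fixture(scope="module")
def two_wave_panel():
    cfg = three_construct_config(n_subjects=800, n_waves=2, seed=31,
                                 crosslag={("X", "Y"): 0.3})
    return generate_panel(cfg)


class TestMlRoutes:
    def test_closed_form_matches_numerical_optimizer(self, two_wave_panel):
        """Recursive path ML has a closed form (per-equation OLS); the
        general optimizer must reproduce it to >= 4 decimals."""
        spec = _toy_two_wave_spec()
        f_ols = fit(spec, two_wave_panel, method="ols")
        f_num = fit(spec, two_wave_panel, method="numeric")
        assert f_ols.method == "ols" and f_num.method == "numeric"
        est_o = f_ols.structural.set_index(
            ["src_construct", "src_wave", "dst_construct"])["est"]
        est_n = f_num.structural.set_index(
            ["src_construct", "src_wave", "dst_construct"])["est"]
        assert np.max(np.abs(est_o - est_n)) < 1e-4
        assert f_ols.chi_square == pytest.approx(f_num.chi_square, abs=1e-2)

    def test_saturated_model_perfect_fit(self, xmy_panel, lat_items):
        """A saturated recursive structural model reproduces the sample
        moments: chi-square ~ 0, CFI = 1, RMSEA = 0."""
        spec = crosslagged_spec(lat_items, cross_pairs="all", estimator="ml",
                                error_covariances=False)
        # saturate: also direct two-wave-spanning information is absorbed by
        # within-wave disturbance covariances (on by default)
        f = fit(spec, xmy_panel)
        assert f.df > 0
        assert f.cfi > 0.99
        assert f.rmsea < 0.02

    def test_fully_saturated_two_wave(self, two_wave_panel):
        # full cross-lagged edge set: 10 free parameters for 10 moments
        spec = _toy_two_wave_spec()
        f = fit(spec, two_wave_panel)
        assert f.df == 0
        assert f.chi_square == pytest.approx(0.0, abs=1e-8)
        assert f.cfi == 1.0 and f.rmsea == 0.0

    def test_parameter_recovery_within_mc_error(self, lat_items):
        """Structural estimates on data generated from the fitted model lie
        within 3 Monte Carlo SEs of the generating coefficients."""
        true = {("X", "M"): 0.2, ("M", "Y"): 0.2, ("X", "Y"): 0.15}
        spec = crosslagged_spec(lat_items, cross_pairs=list(true),
                                estimator="ml", error_covariances=False)
        cfg = three_construct_config(n_subjects=2000, seed=33, crosslag=true)
        f = fit(spec, generate_panel(cfg))
        for row in f.structural.itertuples():
            if row.src_construct == row.dst_construct:
                expected = 0.5
            else:
                expected = true[(row.src_construct, row.dst_construct)]
            assert abs(row.est - expected) < 3 * row.se

    def test_vcov_shrinks_with_n(self):
        ses = []
        for n in (500, 2000):
            cfg = three_construct_config(n_subjects=n, seed=34)
            lat = {c: [[f"lat_{c}_w{w}"] for w in range(1, 5)] for c in ("X", "M", "Y")}
            spec = crosslagged_spec(lat, cross_pairs=[("X", "M")], estimator="ml",
                                    error_covariances=False)
            f = fit(spec, generate_panel(cfg))
            ses.append(f.structural["se"].mean())
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.25)

    def test_fiml_handles_mcar_cells(self, lat_items):
        cfg = three_construct_config(n_subjects=700, seed=35)
        df = generate_panel(cfg)
        rng = np.random.default_rng(0)
        for c in [f"lat_{k}_w{w}" for k in ("X", "M", "Y") for w in range(2, 5)]:
            df.loc[rng.random(len(df)) < 0.1, c] = np.nan
        spec = crosslagged_spec(lat_items, cross_pairs=[("X", "M"), ("M", "Y"), ("X", "Y")],
                                estimator="ml", missing_policy="fiml",
                                error_covariances=False)
        f = fit(spec, df)
        assert f.converged
        est = f.structural.set_index(
            ["src_construct", "src_wave", "dst_construct"])["est"]
        assert est[("X", 1, "M")] == pytest.approx(0.2, abs=0.15)


@pytest.fixture(scope="module")
def ordinal_bivariate():
    items = {
        "sup": ItemBlock("sup", 5, 4, (0.8, 0.75, 0.7, 0.7, 0.65),
                         ((-2.0, -0.85, 0.45),) * 5, 1),
        "alco": ItemBlock("alco", 1, 2, (1.0,),
                          ((float(stats.norm.ppf(0.948)),),), 0),
    }
    cfg = SimConfig(n_subjects=2000, items=items,
                    ar_coefficients={"sup": 0.6, "alco": 0.7},
                    crosslag={("sup", "alco"): -0.15},
                    residual_correlations={"sup": 0.1}, seed=37)
    data = generate_panel(cfg)
    cols = {"sup": [[f"sup{j}_w{w}" for j in range(1, 6)] for w in range(1, 5)],
            "alco": [[f"alco_w{w}"] for w in range(1, 5)]}
    return cols, data


class TestWlsRoute:
    def test_measurement_and_structural_recovery(self, ordinal_bivariate):
        """DWLS on the polychoric matrix recovers loadings (relative to the
        first indicator) and the standardized cross-lagged paths."""
        cols, data = ordinal_bivariate
        f = fit(crosslagged_spec(cols, estimator="wls"), data)
        assert f.converged
        pf = f.params_frame().set_index("name")
        true_rel = np.array([0.75, 0.70, 0.70, 0.65]) / 0.8
        got = pf.loc[[f"lam(sup,{j})" for j in range(1, 5)], "estimate"].to_numpy()
        assert np.allclose(got, true_rel, atol=0.07)
        st_ = f.structural
        fwd = st_[(st_.src_construct == "sup") & (st_.dst_construct == "alco")]
        assert fwd["std"].mean() == pytest.approx(-0.15, abs=0.07)
        ar = st_[(st_.src_construct == "sup") & (st_.dst_construct == "sup")]
        assert ar["std"].mean() == pytest.approx(0.6, abs=0.07)

    def test_fit_statistics_calibrated(self, ordinal_bivariate):
        cols, data = ordinal_bivariate
        f = fit(crosslagged_spec(cols, estimator="wls"), data)
        # correctly specified model: scaled chi-square near its df
        assert f.chi_square == pytest.approx(f.df, rel=0.35)
        assert f.cfi > 0.95
        assert f.rmsea < 0.05


class TestFitIndices:
    def test_perfect_fit(self):
        cfi, rmsea = fit_indices(100.0, 100, 900.0, 120, 500)
        assert cfi == 1.0 and rmsea == 0.0

    def test_hand_computed_example(self):
        cfi, rmsea = fit_indices(150.0, 100, 1100.0, 120, 1000)
        assert cfi == pytest.approx(0.94898, abs=1e-4)
        assert rmsea == pytest.approx(0.02239, abs=1e-4)

    def test_rmsea_floor(self):
        _, rmsea = fit_indices(80.0, 100, 900.0, 120, 500)
        assert rmsea == 0.0

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(10.0, 0, 20.0, 5, 100)


class TestStandardize:
    def test_unit_variance_system_identity(self, xmy_panel, lat_items):
        """Generated latents have unit variance at every wave, so raw and
        standardized coefficients agree closely."""
        spec = crosslagged_spec(lat_items, cross_pairs=[("X", "M"), ("M", "Y"), ("X", "Y")],
                                estimator="ml", error_covariances=False)
        f = fit(spec, xmy_panel)
        assert np.allclose(f.structural["est"], f.structural["std"], atol=0.05)
        std = standardize(f)
        row = f.structural[(f.structural.src_construct == "X")
                           & (f.structural.src_wave == 1)
                           & (f.structural.dst_construct == "M")].iloc[0]
        assert std[(("X", 1), ("M", 2))] == pytest.approx(row["std"], abs=1e-12)

    def test_invariant_to_indicator_rescaling(self, two_wave_panel):
        """Multiplying a construct's indicator by a constant changes raw but
        not standardized structural coefficients."""
        spec = _toy_two_wave_spec()
        f1 = fit(spec, two_wave_panel)
        scaled = two_wave_panel.copy()
        for w in (1, 2):
            scaled[f"lat_X_w{w}"] = scaled[f"lat_X_w{w}"] * 7.0
        f2 = fit(spec, scaled)
        s1 = f1.structural.set_index(["src_construct", "src_wave", "dst_construct"])
        s2 = f2.structural.set_index(["src_construct", "src_wave", "dst_construct"])
        assert s2.loc[("X", 1, "Y"), "est"] == pytest.approx(
            s1.loc[("X", 1, "Y"), "est"] / 7.0, rel=1e-6)
        assert s2.loc[("X", 1, "Y"), "std"] == pytest.approx(
            s1.loc[("X", 1, "Y"), "std"], rel=1e-6)


class TestNestedTest:
    def test_identical_models(self, two_wave_panel):
        f = fit(_toy_two_wave_spec(), two_wave_panel)
        stat, ddf, p = nested_test(f, f)
        assert (stat, ddf, p) == (0.0, 0, 1.0)

    def test_wrong_nesting_rejected(self, xmy_panel, lat_items):
        spec_free = crosslagged_spec(lat_items, cross_pairs=[("X", "Y")],
                                     estimator="ml", error_covariances=False)
        spec_eq = crosslagged_spec(lat_items, cross_pairs=[("X", "Y")],
                                   estimator="ml", error_covariances=False,
                                   equal_over_time=True)
        f_free = fit(spec_free, xmy_panel)
        f_eq = fit(spec_eq, xmy_panel, method="numeric")
        with pytest.raises(ValueError):
            nested_test(f_eq, f_free)

    def test_detects_time_varying_paths(self, lat_items):
        """Strongly time-varying cross-lags make the equality-constrained
        model fit significantly worse."""
        cfg = three_construct_config(
            n_subjects=2000, seed=39,
            crosslag={("X", "M"): [0.45, 0.0, -0.45], ("M", "Y"): 0.2,
                      ("X", "Y"): 0.1})
        df = generate_panel(cfg)
        pairs = [("X", "M"), ("M", "Y"), ("X", "Y")]
        f_free = fit(crosslagged_spec(lat_items, cross_pairs=pairs,
                                      estimator="ml", error_covariances=False), df)
        f_eq = fit(crosslagged_spec(lat_items, cross_pairs=pairs, estimator="ml",
                                    error_covariances=False, equal_over_time=True),
                   df, method="numeric")
        stat, ddf, p = nested_test(f_free, f_eq)
        assert ddf == 12
        assert p < 0.001

    def test_accepts_time_constant_paths(self, lat_items):
        cfg = three_construct_config(n_subjects=800, seed=40)
        df = generate_panel(cfg)
        pairs = [("X", "M"), ("M", "Y"), ("X", "Y")]
        f_free = fit(crosslagged_spec(lat_items, cross_pairs=pairs,
                                      estimator="ml", error_covariances=False), df)
        f_eq = fit(crosslagged_spec(lat_items, cross_pairs=pairs, estimator="ml",
                                    error_covariances=False, equal_over_time=True),
                   df, method="numeric")
        stat, ddf, p = nested_test(f_free, f_eq)
        assert p > 0.01


class TestIdentification:
    def test_overparameterized_model_rejected(self):
        from panelmediate.model import Edge, Latent
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a_w1": (rng.standard_normal(200) > 0).astype(float),
                           "a_w2": (rng.standard_normal(200) > 0).astype(float)})
        spec = ModelSpec(
            latents=[Latent("a", 1, ("a_w1",)), Latent("a", 2, ("a_w2",))],
            edges=[Edge(("a", 1), ("a", 2))],
            error_covariances=[("a_w1", "a_w2")],  # 2 parameters, 1 moment
            estimator="wls")
        with pytest.raises(ValueError, match="not identified"):
            fit(spec, df)
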