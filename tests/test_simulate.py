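"""Generator contracts: determinism, calibration of marginals, the latent
lag-1 dynamics, missingness mechanisms, and the exact effect calculus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelmediate.simulate import (ItemBlock, Missingness, SimConfig,
                                   apply_missingness, generate_panel,
                                   study_default_config,
                                   three_construct_config,
                                   transition_matrices, true_effects)


class TestGeneratePanel:
    def test_deterministic_given_seed(self, xmy_config, xmy_panel):
        again = generate_panel(xmy_config)
        pd.testing.assert_frame_equal(xmy_panel, again)

    def test_distinct_seeds_differ(self, xmy_config):
        import dataclasses
        other = generate_panel(dataclasses.replace(xmy_config, seed=999))
        assert not other.equals(generate_panel(xmy_config))

    def test_zero_crosslag_independence(self):
        cfg = three_construct_config(
            n_subjects=8000, seed=3,
            crosslag={("X", "M"): 0.0, ("M", "Y"): 0.0, ("X", "Y"): 0.0})
        df = generate_panel(cfg)
        # X items at wave 1 vs the M indicator at wave 2: independent by construction
        for j in range(1, 5):
            r = np.corrcoef(df[f"x{j}_w1"], df["m_w2"])[0, 1]
            assert abs(r) < 0.05

    def test_smoking_prevalence_matches_threshold(self):
        """Behavior threshold at the 91.7% normal quantile gives ~8.3%
        wave-1 prevalence, the baseline current-smoking figure."""
        cfg = study_default_config(n_subjects=40000, seed=11)
        df = generate_panel(cfg)
        assert df["smoke_w1"].mean() == pytest.approx(0.083, abs=0.008)

    @pytest.mark.parametrize("col, prevalence", [
        ("alco_w1", 0.052), ("diet_w1", 0.068), ("inact_w1", 0.161)])
    def test_behavior_prevalences(self, col, prevalence):
        cfg = study_default_config(n_subjects=40000, seed=12)
        df = generate_panel(cfg)
        assert df[col].mean() == pytest.approx(prevalence, abs=0.01)

    def test_scale_means_near_baseline_table(self):
        cfg = study_default_config(n_subjects=20000, seed=13)
        df = generate_panel(cfg)
        dem = df[[f"dem{j}_w1" for j in range(1, 5)]].mean(axis=1)
        sup = df[[f"sup{j}_w1" for j in range(1, 6)]].mean(axis=1)
        assert dem.mean() == pytest.approx(2.6, abs=0.1)
        assert sup.mean() == pytest.approx(3.1, abs=0.1)

    def test_latent_lag1_autocorrelation_matches_ar(self):
        cfg = three_construct_config(
            n_subjects=20000, seed=4,
            ar={"X": 0.6, "M": 0.4, "Y": 0.5},
            crosslag={})
        df = generate_panel(cfg)
        for c, a in (("X", 0.6), ("M", 0.4), ("Y", 0.5)):
            r = np.corrcoef(df[f"lat_{c}_w1"], df[f"lat_{c}_w2"])[0, 1]
            assert r == pytest.approx(a, abs=0.03)

    def test_unit_latent_variance_every_wave(self, xmy_panel):
        for c in ("X", "M", "Y"):
            for w in range(1, 5):
                assert xmy_panel[f"lat_{c}_w{w}"].var() == pytest.approx(1.0, abs=0.15)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            three_construct_config(n_subjects=-5)
        with pytest.raises(ValueError):
            ItemBlock("bad", 1, 3, (0.7,), ((1.0, 0.5),), 0)  # non-increasing
        with pytest.raises(ValueError):
            Missingness("MCAR", 1.5)
        with pytest.raises(ValueError):
            # AR of 1.2 explains >= 100% of the construct's variance
            generate_panel(three_construct_config(
                n_subjects=50, ar={"X": 1.2, "M": 0.5, "Y": 0.5}, crosslag={}))


class TestMissingness:
    def test_rate_zero_is_identity(self, xmy_config, xmy_panel):
        import dataclasses
        cfg = dataclasses.replace(xmy_config,
                                  missingness=Missingness("MCAR", 0.0))
        pd.testing.assert_frame_equal(apply_missingness(xmy_panel, cfg), xmy_panel)

    def test_mcar_rate_recovered(self):
        import dataclasses
        cfg = dataclasses.replace(three_construct_config(n_subjects=4000, seed=8),
                                  missingness=Missingness("MCAR", 0.1))
        df = apply_missingness(generate_panel(cfg), cfg)
        item_cols = [c for c in df.columns
                     if not c.startswith(("lat_", "sid", "age", "sex", "single", "edu"))]
        frac = df[item_cols].isna().to_numpy().mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_mar_depends_on_wave1_driver(self):
        import dataclasses
        cfg = dataclasses.replace(
            three_construct_config(n_subjects=6000, seed=9),
            missingness=Missingness("MAR", 0.15, driver="Y"))
        raw = generate_panel(cfg)
        df = apply_missingness(raw, cfg)
        w1 = raw[[f"y{j}_w1" for j in range(1, 7)]].mean(axis=1)
        tert = pd.qcut(w1, 3, labels=False, duplicates="drop")
        later = [c for c in df.columns if c.startswith("y") and not c.endswith("_w1")]
        rates = df[later].isna().mean(axis=1).groupby(tert).mean()
        assert rates.iloc[-1] > rates.iloc[0] + 0.05

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            Missingness("NMAR", 0.1)


class TestTrueEffects:
    def test_zero_xm_gives_zero_indirect(self):
        cfg = three_construct_config(
            crosslag={("X", "M"): 0.0, ("M", "Y"): 0.3, ("X", "Y"): 0.2})
        d = true_effects(cfg, "X", "Y", ["M"])
        assert d.indirect == 0.0
        assert d.total == d.direct

    def test_three_wave_single_product(self):
        cfg = three_construct_config(
            n_waves=3, ar={"X": 0.0, "M": 0.0, "Y": 0.0},
            crosslag={("X", "M"): [0.5, 0.0], ("M", "Y"): [0.0, 0.4]})
        d = true_effects(cfg, "X", "Y", ["M"])
        assert d.indirect == pytest.approx(0.20, abs=1e-12)
        assert d.direct == 0.0
        assert d.proportion_mediated == pytest.approx(1.0)

    def test_total_is_matrix_product_entry(self):
        """Path-calculus total equals the (Y, X) entry of the ordered
        product of transition matrices, for random coefficients."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            ar = {c: rng.uniform(0.1, 0.5) for c in ("X", "M", "Y")}
            cl = {p: rng.uniform(-0.25, 0.25)
                  for p in [("X", "M"), ("M", "Y"), ("X", "Y"),
                            ("Y", "M"), ("M", "X")]}
            cfg = three_construct_config(ar=ar, crosslag=cl)
            mats = transition_matrices(cfg)
            prod = mats[2] @ mats[1] @ mats[0]
            d = true_effects(cfg, "X", "Y", ["M"])
            assert d.total == pytest.approx(prod[2, 0], abs=1e-14)
            assert d.total == pytest.approx(d.direct + d.indirect, abs=1e-14)
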