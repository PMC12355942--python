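import numpy as np
import pandas as pd
import pytest

from domoptics import (ARINTRegressor, PanArcticRegressor, SampleTable,
                       YanDOCModel, compare_doc_models, diagnostics,
                       fit_doc_model, info_criteria, invert_a254, predict_doc)
from domoptics.docmodels import CARBON_MOLAR_MASS
from domoptics.sensitivity import NoiseModel, NoiseSpec
from domoptics.synthetic import synth_dataset


def _pan_arctic_table(n=50, C=0.5, M=0.05, seed=0):
    rng = np.random.default_rng(seed)
    a350 = rng.uniform(0.5, 10.0, n)
    s_um = rng.uniform(14.0, 25.0, n)  # S275-295 in 1/um
    doc = a350 * 10.0 ** (C + M * s_um)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"p{i}" for i in range(n)],
        "doc": doc, "a350": a350, "s275_295": s_um / 1000.0,  # stored in 1/nm
    }))


def _yan_table(n=50, phi=1507.0, doc_cor=32.2, seed=0):
    rng = np.random.default_rng(seed)
    a275 = rng.uniform(2.0, 40.0, n)
    s275 = rng.uniform(0.013, 0.025, n)
    s380 = rng.uniform(0.010, 0.020, n)
    doc_um = phi * a275 * (s275 + 0.078 * s380 - 0.0084) + doc_cor
    return SampleTable(pd.DataFrame({
        "sample_id": [f"y{i}" for i in range(n)],
        "doc": doc_um * CARBON_MOLAR_MASS / 1000.0,
        "a275": a275, "s275_295": s275, "s380_443": s380,
    }))


class TestNoiselessRecovery:
    def test_arint(self):
        table, truth = synth_dataset(n=50, b0=1.0, b1=0.5, b2=-0.2, seed=1)
        fit = fit_doc_model("arint", table, proxy="arix")
        b0, b1, b2 = truth.arint_coefficients
        assert fit.b0_ == pytest.approx(b0, rel=1e-9)
        assert fit.b1_ == pytest.approx(b1, rel=1e-9)
        assert fit.b2_ == pytest.approx(b2, rel=1e-9)

    def test_pan_arctic(self):
        fit = fit_doc_model("pan_arctic", _pan_arctic_table(C=0.5, M=0.05))
        assert fit.C_ == pytest.approx(0.5, rel=1e-9)
        assert fit.M_ == pytest.approx(0.05, rel=1e-9)

    def test_doc_ls(self):
        fit = fit_doc_model("doc_ls", _yan_table())
        assert fit.phi_ == pytest.approx(1507.0, rel=1e-6)
        assert fit.doc_cor_ == pytest.approx(32.2, rel=1e-6)

    def test_constant_proxy_is_rank_deficient(self):
        table, _ = synth_dataset(n=20, proxy_range=(0.5, 0.5 + 1e-15), seed=2)
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_doc_model("arint", table, proxy="arix")

    def test_inv_s275_proxy(self):
        table, truth = synth_dataset(n=50, b0=2.0, b1=0.7, b2=-0.25,
                                     proxy_kind="inv_s275_295",
                                     proxy_range=(0.04, 0.07), seed=3)
        fit = fit_doc_model("arint", table, proxy="inv_s275_295")
        assert fit.b2_ == pytest.approx(truth.arint_coefficients[2], rel=1e-6)


class TestPredict:
    def test_arint_arithmetic(self):
        """b0=1, b1=0.5, b2=-0.2, A254=10, P=1: DOC = 1 + 10*(0.5-0.2) = 4."""
        est = ARINTRegressor("arix")
        est.b0_, est.b1_, est.b2_ = 1.0, 0.5, -0.2
        assert est.predict(np.array([[10.0, 1.0]]))[0] == pytest.approx(4.0)

    def test_doc_uv_hand_value(self):
        """a275=10, S275=0.0200, S380=0.0180: 1507*10*0.013004 + 32.2 = 228.17 uM."""
        model = YanDOCModel.global_uv()
        pred = model.predict(np.array([[10.0, 0.020, 0.018]]))[0]
        doc_um = pred * 1000.0 / CARBON_MOLAR_MASS
        assert doc_um == pytest.approx(228.1703, abs=1e-3)
        assert pred == pytest.approx(2.7406, abs=1e-3)  # mg/L

    def test_pan_arctic_hand_value(self):
        """C=0.5, M=0.05, S=20 1/um, a350=2: DOC = 2 * 10^1.5 = 63.246."""
        est = PanArcticRegressor()
        est.C_, est.M_ = 0.5, 0.05
        assert est.predict(np.array([[2.0, 20.0]]))[0] == pytest.approx(
            2.0 * 10**1.5, rel=1e-9)

    def test_predict_doc_on_table(self):
        table, truth = synth_dataset(n=30, seed=5)
        fit = fit_doc_model("arint", table, proxy="arix")
        pred = predict_doc(fit, table)
        assert np.allclose(pred, table.df["doc"], rtol=1e-9)


class TestInvertA254:
    def test_round_trip_identity(self):
        table, _ = synth_dataset(n=25, seed=6)
        fit = fit_doc_model("arint", table, proxy="arix")
        proxy = table.df["arix"].values
        a254 = table.df["a254"].values
        doc = fit.predict(np.column_stack([a254, proxy]))
        assert np.allclose(invert_a254(fit, doc, proxy), a254, rtol=1e-10)

    def test_pure_uncolored_doc_absorbs_nothing(self):
        est = ARINTRegressor("arix")
        est.b0_, est.b1_, est.b2_ = 1.0, 0.5, -0.2
        assert invert_a254(est, np.array([1.0]), np.array([0.4]))[0] == 0.0

    def test_beer_lambert_form(self):
        """A254 = cDOC / (b1 + b2*P): doubling colored DOC doubles absorbance."""
        est = ARINTRegressor("arix")
        est.b0_, est.b1_, est.b2_ = 1.0, 0.5, -0.2
        a1 = invert_a254(est, np.array([3.0]), np.array([0.5]))[0]
        a2 = invert_a254(est, np.array([5.0]), np.array([0.5]))[0]
        assert a2 == pytest.approx(2.0 * a1)


class TestDiagnostics:
    def test_ratio_and_epsilon(self):
        table, _ = synth_dataset(n=10, b0=1.0, b1=0.5, b2=-0.2, seed=7)
        fit = fit_doc_model("arint", table, proxy="arix")
        d = diagnostics(fit, table)
        p = table.df["arix"].values
        assert np.allclose(d.interaction_ratio, fit.b2_ * p / fit.b1_, rtol=1e-9)
        assert np.allclose(d.epsilon_proxy, 1.0 / (fit.b1_ + fit.b2_ * p), rtol=1e-9)
        assert np.allclose(d.cdoc, table.df["doc"] - fit.b0_, rtol=1e-9)

    def test_no_interaction_limit(self):
        est = ARINTRegressor("arix")
        est.b0_, est.b1_, est.b2_ = 1.0, 0.5, 0.0
        table, _ = synth_dataset(n=10, seed=8)
        d = diagnostics(est, table)
        assert np.allclose(d.interaction_ratio, 0.0)
        assert d.epsilon_proxy.nunique() == 1

    def test_generator_ratio_range_round_trip(self):
        """Default regime puts b2*P/b1 in [-0.5, -0.1]; the fit reproduces it."""
        table, _ = synth_dataset(n=300, seed=9)
        fit = fit_doc_model("arint", table, proxy="arix")
        lo, hi = diagnostics(fit, table).ratio_range
        assert lo == pytest.approx(-0.5, abs=0.02)
        assert hi == pytest.approx(-0.1, abs=0.02)

    def test_natural_regime_signs(self):
        """On generator defaults, b1 > 0 and b2 < 0, the signs seen in natural waters."""
        noise = NoiseModel(NoiseSpec("relative", 0.05), NoiseSpec("absolute", 0.0),
                           NoiseSpec("absolute", 0.0))
        for seed in range(5):
            table, _ = synth_dataset(n=200, noise=noise, seed=seed)
            fit = fit_doc_model("arint", table, proxy="arix")
            assert fit.b1_ > 0 and fit.b2_ < 0


class TestInfoCriteria:
    def test_closed_form_n10_rss10_k2(self):
        resid = np.ones(10)  # RSS = 10
        ic = info_criteria(resid, k=2)
        assert ic.logL == pytest.approx(-14.18939, abs=1e-5)
        assert ic.aic == pytest.approx(32.3788, abs=1e-4)
        assert ic.aicc == pytest.approx(34.0931, abs=1e-4)
        assert ic.bic == pytest.approx(32.9840, abs=1e-4)
        assert ic.caic == pytest.approx(34.9840, abs=1e-4)

    def test_penalty_ordering_at_equal_rss(self):
        resid = np.ones(20)
        ic0, ic2 = info_criteria(resid, 0), info_criteria(resid, 2)
        for attr in ("aic", "aicc", "bic", "caic"):
            assert getattr(ic0, attr) < getattr(ic2, attr)

    def test_aicc_tends_to_aic(self):
        resid = np.ones(10**6)
        ic = info_criteria(resid, 3)
        assert ic.aicc == pytest.approx(ic.aic, abs=1e-4)
        assert ic.aicc >= ic.aic

    def test_perfect_fit_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|zero residual"):
            info_criteria(np.zeros(10), 2)


class TestCompare:
    def test_interaction_present_prefers_arint(self):
        noise = NoiseModel(NoiseSpec("relative", 0.03), NoiseSpec("absolute", 0.0),
                           NoiseSpec("absolute", 0.0))
        table, _ = synth_dataset(n=150, b0=1.0, b1=0.6, b2=-0.3, noise=noise, seed=10)
        report = compare_doc_models(table, proxies=("arix",))
        assert report.loc["arint_arix", "preferred"]
        assert report.loc["arint_arix", "criteria_won"] == 4
        assert report.loc["arint_arix", "rmse_pct_change_vs_base"] < 0

    def test_no_interaction_prefers_base_on_bic(self):
        """DOC = beta*A254 + noise: the parsimony penalty beats a spurious b2."""
        rng = np.random.default_rng(12)
        a254 = rng.uniform(5, 60, 100)
        doc = 0.5 * a254 + rng.normal(0, 0.5, 100)
        doc = np.clip(doc, 0.1, None)
        table = SampleTable(pd.DataFrame({
            "sample_id": [f"b{i}" for i in range(100)],
            "doc": doc, "a254": a254, "arix": rng.uniform(0.2, 1.0, 100),
        }))
        report = compare_doc_models(table, proxies=("arix",))
        assert report.loc["base", "bic"] < report.loc["arint_arix", "bic"]
        assert report.loc["base", "caic"] < report.loc["arint_arix", "caic"]

    def test_pinned_doc_ls_reproduces_doc_uv(self):
        table = _yan_table()
        uv = fit_doc_model("doc_uv", table)
        pinned = YanDOCModel(phi=YanDOCModel.GLOBAL_PHI,
                             doc_cor=YanDOCModel.GLOBAL_DOC_COR)
        X = table.df[["a275", "s275_295", "s380_443"]].values
        assert np.array_equal(pinned.predict(X), uv.predict(X))
        assert uv.n_estimated_params == 0

    def test_arint_with_b2_zero_matches_base(self):
        """Forcing no interaction reduces ARINT to the base model exactly."""
        table, _ = synth_dataset(n=40, b2=-0.3, seed=13)
        base = fit_doc_model("base", table)
        est = ARINTRegressor("arix")
        est.b0_, est.b1_, est.b2_ = base.intercept_, base.slope_, 0.0
        a254 = table.df["a254"].values
        pred = est.predict(np.column_stack([a254, table.df["arix"].values]))
        assert np.allclose(pred, base.predict(a254), rtol=1e-12)


class TestStochasticRecovery:
    def test_arint_3se_coverage(self):
        """n=200, 5% relative DOC noise: truth inside 3 SE in >= 95 of 100 seeds."""
        noise = NoiseModel(NoiseSpec("relative", 0.05), NoiseSpec("absolute", 0.0),
                           NoiseSpec("absolute", 0.0))
        hits = 0
        for seed in range(100):
            table, truth = synth_dataset(n=200, noise=noise, seed=seed)
            fit = fit_doc_model("arint", table, proxy="arix")
            b0, b1, b2 = truth.arint_coefficients
            if (abs(fit.b0_ - b0) < 3 * fit.b0_se_
                    and abs(fit.b1_ - b1) < 3 * fit.b1_se_
                    and abs(fit.b2_ - b2) < 3 * fit.b2_se_):
                hits += 1
        assert hits >= 95
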