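import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from domoptics import EEM, ParafacScores, arix, classic_indices, emission_intensity, parix
from domoptics.indices import UndefinedIndexError, mask_scatter


def _random_eem(seed: int) -> EEM:
    rng = np.random.default_rng(seed)
    ex = np.arange(250.0, 501.0, 5.0)
    em = np.arange(300.0, 601.0, 2.0)
    return EEM(f"r{seed}", ex, em, rng.uniform(0.1, 5.0, size=(em.size, ex.size)))


class TestEmissionIntensity:
    def test_grid_point_identity(self, two_component_eem):
        eem, truth = two_component_eem
        assert emission_intensity(eem, 320.0, 400.0) == pytest.approx(
            float(truth.true_intensity(320.0, 400.0)), abs=1e-12)

    def test_linearity_between_grid_points(self):
        eem = EEM("lin", [300, 320], [380, 390], [[1.0, 1.0], [3.0, 3.0]])
        assert emission_intensity(eem, 310.0, 385.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("ex,em", [(240.0, 400.0), (320.0, 250.0),
                                       (600.0, 400.0), (320.0, 700.0)])
    def test_no_extrapolation(self, ex, em, two_component_eem):
        eem, _ = two_component_eem
        with pytest.raises(UndefinedIndexError):
            emission_intensity(eem, ex, em)


class TestArix:
    def test_uniform_eem_gives_one(self, uniform_eem):
        assert arix(uniform_eem) == pytest.approx(1.0)

    def test_two_gaussian_closed_form(self, two_component_eem):
        eem, truth = two_component_eem
        # (2 e^{-100/7200} + e^{-14400/3200}) / (2 e^{-14400/7200} + e^{-100/3200})
        expected = (2 * np.exp(-100 / 7200) + np.exp(-14400 / 3200)) / \
                   (2 * np.exp(-14400 / 7200) + np.exp(-100 / 3200))
        assert expected == pytest.approx(1.59974, abs=5e-5)
        assert arix(eem) == pytest.approx(expected, rel=1e-9)
        assert truth.true_arix() == pytest.approx(expected, rel=1e-12)

    def test_detection_floor_flags_undefined(self, uniform_eem):
        with pytest.raises(UndefinedIndexError, match="floor"):
            arix(uniform_eem, detection_floor=10.0)

    def test_monotone_in_long_emission_component(self, two_component_eem):
        """Adding fluorescence that is stronger at 520 than 390 nm raises ARIX."""
        eem, _ = two_component_eem
        base = arix(eem)
        extra = np.exp(-((eem.emission - 540.0) ** 2) / (2 * 50.0**2))
        boosted = EEM(eem.sample_id, eem.excitation, eem.emission,
                      eem.intensities + extra[:, None])
        assert arix(boosted) > base


class TestClassicIndices:
    def test_uniform_eem_values(self, uniform_eem):
        rec = classic_indices(uniform_eem)
        assert rec.fi == pytest.approx(1.0)
        assert rec.bix == pytest.approx(1.0)
        assert rec.freshness == pytest.approx(1.0)
        assert rec.hix == pytest.approx(0.5)
        assert rec.hix1999 == pytest.approx(1.0)
        assert rec.arix == pytest.approx(1.0)

    def test_linear_emission_spectrum(self, linear_emission_eem):
        """I(em) = em/1000: band sums are arithmetic series, point ratios exact."""
        rec = classic_indices(linear_emission_eem)
        assert rec.hix1999 == pytest.approx(457.5 / 322.5, rel=1e-9)       # 1.41860
        assert rec.hix == pytest.approx(457.5 / 780.0, rel=1e-9)           # 0.58654
        assert rec.fi == pytest.approx(470.0 / 520.0, rel=1e-9)            # 0.90385
        assert rec.bix == pytest.approx(430.0 / 380.0, rel=1e-9)           # 1.13158
        assert rec.freshness == pytest.approx(380.0 / 435.0, rel=1e-9)     # 0.87356

    @given(st.integers(0, 20), st.floats(0.01, 1e4))
    def test_scale_invariance(self, seed, c):
        eem = _random_eem(seed)
        scaled = EEM(eem.sample_id, eem.excitation, eem.emission, c * eem.intensities)
        a, b = classic_indices(eem), classic_indices(scaled)
        for name, val in a.as_dict().items():
            assert getattr(b, name) == pytest.approx(val, rel=1e-9)

    @given(st.integers(0, 50))
    def test_hix_identity(self, seed):
        """HIX and HIX_1999 share a numerator: HIX = HIX_1999 / (1 + HIX_1999)."""
        rec = classic_indices(_random_eem(seed))
        assert rec.hix == pytest.approx(rec.hix1999 / (1 + rec.hix1999), rel=1e-9)

    def test_out_of_range_flags_only_that_index(self):
        # emission grid stops at 500 nm: FI (needs 520) and ARIX undefined, BIX fine
        ex = np.arange(250.0, 401.0, 5.0)
        em = np.arange(300.0, 501.0, 2.0)
        eem = EEM("short", ex, em, np.ones((em.size, ex.size)))
        rec = classic_indices(eem)
        assert rec.fi is None and rec.arix is None
        assert rec.bix == pytest.approx(1.0)
        assert rec.hix == pytest.approx(0.5)

    def test_band_sum_matches_trapezoid_oracle(self, two_component_eem):
        """1-nm inclusive band sums track trapezoid integration on fine grids."""
        eem, truth = two_component_eem
        rec = classic_indices(eem)
        em_fine = np.linspace(435.0, 480.0, 4501)
        high = np.trapezoid(truth.true_intensity(254.0, em_fine), em_fine) / 1.0
        em_fine = np.linspace(300.0, 345.0, 4501)
        low = np.trapezoid(truth.true_intensity(254.0, em_fine), em_fine) / 1.0
        assert rec.hix1999 == pytest.approx(high / low, rel=0.01)


class TestParix:
    def test_equal_scores(self):
        s = ParafacScores({"C3": 0.5, "C4": 0.5}, long_component="C4", short_component="C3")
        assert parix(s) == pytest.approx(1.0)

    def test_zero_long_component_is_zero(self):
        """No long-emission fluorescence: no PA/PP structures, PARIX = 0."""
        s = ParafacScores({"C3": 1.0, "C4": 0.0}, "C4", "C3")
        assert parix(s) == 0.0

    def test_zero_short_component_is_error(self):
        s = ParafacScores({"C3": 0.0, "C4": 1.0}, "C4", "C3")
        with pytest.raises(UndefinedIndexError):
            parix(s)

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        a = ParafacScores({"C3": 2.0, "C4": 3.0}, "C4", "C3")
        b = ParafacScores({"C3": 2.0 * c, "C4": 3.0 * c}, "C4", "C3")
        assert parix(b) == pytest.approx(parix(a), rel=1e-12)

    def test_missing_designated_component(self):
        with pytest.raises(ValueError, match="missing"):
            ParafacScores({"C3": 1.0}, "C4", "C3")


class TestScatterMask:
    def test_mask_restores_smooth_background(self):
        """A Raman-like spike near em 359 at ex 320 is excised and re-interpolated."""
        ex = np.arange(250.0, 501.0, 5.0)
        em = np.arange(300.0, 601.0, 2.0)
        intens = np.full((em.size, ex.size), 2.0)
        j = int(np.argmin(np.abs(ex - 320.0)))
        i = int(np.argmin(np.abs(em - 360.0)))
        intens[i, j] += 50.0
        cleaned = mask_scatter(EEM("spiked", ex, em, intens))
        assert cleaned.intensities[i, j] == pytest.approx(2.0)
        # untouched region unchanged
        assert cleaned.intensities[-1, j] == 2.0
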