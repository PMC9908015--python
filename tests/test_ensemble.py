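"""Ensemble-mode analysis: correction, calibration, LOD, statistics."""

import numpy as np
import pytest

from aptaruler import (
    CalibrationFit,
    Spectrum,
    compare_groups,
    correct_spectrum,
    estimate_concentration,
    estimate_lod,
    eu_to_ng,
    fit_calibration,
    predict_rg,
    rg_ratio,
    synth_titration,
)

LAM = np.linspace(430.0, 800.0, 200)


def _fit_printed():
    """Calibration object carrying the experimentally printed line."""
    return CalibrationFit(
        slope=0.106,
        intercept=0.902,
        r_squared=0.995,
        concentrations=np.array([15.0, 31.0, 62.0, 125.0, 250.0, 500.0]),
        rg_means=np.zeros(6),
        rg_sds=np.zeros(6),
    )


class TestCorrectSpectrum:
    def test_background_equal_raw_gives_zero(self):
        raw = Spectrum(LAM, np.ones_like(LAM))
        exc = Spectrum(LAM, np.full_like(LAM, 2.0))
        out = correct_spectrum(raw, raw, exc)
        np.testing.assert_allclose(out.intensity, 0.0)

    def test_unit_excitation_zero_background_is_identity(self):
        raw = Spectrum(LAM, np.abs(np.sin(LAM / 40)) + 0.1)
        zero = Spectrum(LAM, np.zeros_like(LAM))
        one = Spectrum(LAM, np.ones_like(LAM))
        out = correct_spectrum(raw, zero, one)
        np.testing.assert_allclose(out.intensity, raw.intensity)

    def test_algebraic_inversion(self):
        true = np.abs(np.cos(LAM / 55)) + 0.5
        exc = 0.5 + (LAM - 430) / 370
        bg = 0.2 + 0.001 * LAM
        raw = Spectrum(LAM, true * exc + bg)
        out = correct_spectrum(raw, Spectrum(LAM, bg), Spectrum(LAM, exc))
        np.testing.assert_allclose(out.intensity, true, rtol=1e-12)

    def test_rg_invariant_to_excitation_rescaling(self):
        true = np.abs(np.cos(LAM / 55)) + 0.5
        exc = 0.5 + (LAM - 430) / 370
        raw = Spectrum(LAM, true * exc)
        zero = Spectrum(LAM, np.zeros_like(LAM))
        rg1 = rg_ratio(correct_spectrum(raw, zero, Spectrum(LAM, exc)))
        raw2 = Spectrum(LAM, true * exc * 7.5)
        rg2 = rg_ratio(correct_spectrum(raw2, zero, Spectrum(LAM, exc * 7.5)))
        assert rg2 == pytest.approx(rg1, rel=1e-12)

    def test_disjoint_grids_rejected(self):
        raw = Spectrum(LAM, np.ones_like(LAM))
        short = Spectrum(np.linspace(500, 600, 20), np.ones(20))
        with pytest.raises(ValueError):
            correct_spectrum(raw, short, short)


class TestFitCalibration:
    CONC = [15.0, 31.0, 62.0, 125.0, 250.0, 500.0]

    def test_noiseless_points_recovered_exactly(self):
        rg = [[0.106 * np.log(c) + 0.902] * 3 for c in self.CONC]
        fit = fit_calibration(self.CONC, rg)
        assert fit.slope == pytest.approx(0.106, abs=1e-12)
        assert fit.intercept == pytest.approx(0.902, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_blanks_excluded_but_stored(self):
        conc = [0.0] + self.CONC
        rg = [[1.24, 1.25]] + [[0.106 * np.log(c) + 0.902] * 2 for c in self.CONC]
        fit = fit_calibration(conc, rg)
        assert fit.concentrations.min() > 0
        np.testing.assert_allclose(fit.blank_rg, [1.24, 1.25])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([15.0, 31.0], [[1.2], [1.3]])

    def test_slope_recovery_is_unbiased(self):
        slopes = []
        for seed in range(200):
            df, _ = synth_titration(seed=seed)
            levels = sorted(df["concentration_eu_ml"].unique())
            reps = [
                df.loc[df["concentration_eu_ml"] == c, "rg"].to_list()
                for c in levels
            ]
            slopes.append(fit_calibration(levels, reps).slope)
        assert np.mean(slopes) == pytest.approx(0.106, abs=0.002)


class TestPredictEstimate:
    def test_printed_line_at_500(self):
        # 0.106 ln(500) + 0.902 = 1.5607, vs measured 1.563 (within 0.2%)
        rg = predict_rg(_fit_printed(), 500.0)
        assert rg == pytest.approx(1.563, rel=0.002)

    def test_mutual_inverses(self):
        fit = _fit_printed()
        for c in (1.0, 15.0, 500.0, 4000.0):
            assert estimate_concentration(fit, predict_rg(fit, c)) == pytest.approx(
                c, rel=1e-9
            )

    def test_intercept_at_unit_concentration(self):
        assert predict_rg(_fit_printed(), 1.0) == pytest.approx(0.902)

    def test_blank_rg_maps_into_lod_bracket(self):
        # the pre-incubation RG inverts to a concentration between the
        # highest blank-like and lowest detectable tested levels
        c = estimate_concentration(_fit_printed(), 1.242)
        assert 15.0 < c < 31.0

    def test_zero_slope_inversion_rejected(self):
        fit = _fit_printed()
        fit.slope = 0.0
        with pytest.raises(ValueError):
            estimate_concentration(fit, 1.3)


class TestLod:
    def test_bracket(self):
        flags = [(15.0, False), (31.0, True), (62.0, True)]
        assert estimate_lod(None, flags) == (15.0, 31.0)

    def test_bracket_shifts(self):
        flags = [(15.0, False), (31.0, False), (62.0, True)]
        assert estimate_lod(None, flags) == (31.0, 62.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod(None, [(15.0, True), (31.0, False), (62.0, True)])

    @pytest.mark.parametrize("flags", [[(15.0, True)], [(15.0, False)]])
    def test_open_bracket_rejected(self, flags):
        with pytest.raises(ValueError):
            estimate_lod(None, flags)

    def test_detection_threshold_never_rises_with_less_noise(self):
        """Lower replicate scatter can only move the detectable bracket down."""
        first_sig = {}
        for sd in (0.05, 0.005):
            hits = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                blanks = rng.normal(1.10, sd, 3)
                sig = [
                    c
                    for c in (15.0, 31.0, 62.0, 125.0)
                    if compare_groups(
                        [blanks, rng.normal(0.106 * np.log(c) + 0.902, sd, 3)]
                    ).significant
                ]
                if sig:
                    hits.append(min(sig))
            first_sig[sd] = np.mean(hits)
        assert first_sig[0.005] <= first_sig[0.05]


class TestUnits:
    @pytest.mark.parametrize("eu,ng", [(500.0, 50.0), (4000.0, 400.0), (0.0, 0.0)])
    def test_eu_to_ng(self, eu, ng):
        assert eu_to_ng(eu) == ng

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            eu_to_ng(-1.0)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = [1.0, 1.1, 0.9]
        res = compare_groups([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        n_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 0.01, 3)
            b = rng.normal(5.0, 0.01, 3)
            if compare_groups([a, b]).significant:
                n_sig += 1
        assert n_sig >= 99

    def test_anova_identical_groups(self):
        g = [1.0, 1.2, 0.8]
        res = compare_groups([g, g, g], mode="multi")
        assert res.test_name == "anova"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_variance_diagnostic(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups([[1.0, 1.0], [2.0, 2.0]])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0], [2.0, 3.0]])

    def test_mode_group_count_contract(self):
        with pytest.raises(ValueError):
            compare_groups([[1, 2], [3, 4], [5, 6]], mode="two-sample")
        with pytest.raises(ValueError):
            compare_groups([[1, 2], [3, 4]], mode="multi")
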