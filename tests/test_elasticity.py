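"""Conversion models, Moens-Korteweg PWV, transit-time reference, error stats."""

import numpy as np
import pytest

from pwvlab.elasticity import (PwvConstants, PwvEstimate, elasticity_table,
                               error_analysis, estimate_pwv_from_hardness,
                               moens_korteweg, reference_ptt, reference_pwv,
                               shore_to_elasticity, theoretical_pwv_table)

MODELS = ("DMA", "Gent", "RDA", "Ruess", "Secant")

# published elasticity values (MPa, 2 dp) per hardness level and model
GOLDEN_E = {
    10: (0.45, 0.41, 0.29, 0.67, 0.28),
    20: (0.88, 0.73, 0.51, 0.84, 0.48),
    30: (1.69, 1.14, 0.92, 1.07, 0.82),
    40: (3.26, 1.69, 1.64, 1.35, 1.41),
    50: (6.29, 2.46, 2.93, 1.71, 2.41),
}

# published theoretical PWV (m/s, 2 dp) per (wall mm, hardness) and model
GOLDEN_PWV = {
    (1.0, 10): (6.74, 6.42, 5.36, 8.17, 5.27),
    (1.0, 20): (9.36, 8.56, 7.17, 9.18, 6.90),
    (1.0, 30): (13.00, 10.69, 9.58, 10.33, 9.04),
    (1.0, 40): (18.05, 13.00, 12.80, 11.62, 11.85),
    (1.0, 50): (25.07, 15.67, 17.11, 13.06, 15.54),
    (1.5, 10): (8.25, 7.87, 6.57, 10.00, 6.45),
    (1.5, 20): (11.46, 10.48, 8.78, 11.25, 8.45),
    (1.5, 30): (15.92, 13.09, 11.73, 12.65, 11.08),
    (1.5, 40): (22.11, 15.92, 15.68, 14.23, 14.52),
    (1.5, 50): (30.71, 19.19, 20.96, 16.00, 19.03),
    (2.0, 10): (9.53, 9.08, 7.59, 11.55, 7.45),
    (2.0, 20): (13.24, 12.10, 10.14, 12.99, 9.76),
    (2.0, 30): (18.38, 15.12, 13.55, 14.61, 12.79),
    (2.0, 40): (25.53, 18.38, 18.11, 16.43, 16.76),
    (2.0, 50): (35.46, 22.16, 24.20, 18.48, 21.97),
}


class TestShoreToElasticity:
    def test_all_golden_cells(self):
        for sha, row in GOLDEN_E.items():
            for model, expected in zip(MODELS, row):
                assert round(shore_to_elasticity(sha, model), 2) == expected, \
                    (sha, model)

    def test_dma_at_zero_hardness(self):
        assert shore_to_elasticity(0, "DMA") == pytest.approx(0.2354)

    def test_strictly_increasing_on_validated_range(self):
        for model in MODELS:
            e = [shore_to_elasticity(s, model) for s in np.linspace(10, 50, 41)]
            assert np.all(np.diff(e) > 0), model

    def test_gent_singular_at_100(self):
        with pytest.raises(ValueError, match="singular"):
            shore_to_elasticity(100, "Gent")

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            shore_to_elasticity(30, "Hooke")

    def test_case_insensitive_model_name(self):
        assert shore_to_elasticity(30, "ruess") == shore_to_elasticity(30, "Ruess")


class TestMoensKorteweg:
    def test_round_number_closed_form(self):
        # E = 1 MPa, W = 1 mm, rho = 1000, d = 10 mm -> exactly 10 m/s
        assert moens_korteweg(1.0, 1.0) == pytest.approx(10.0)

    def test_scale_property(self):
        assert moens_korteweg(4.0, 1.5) == pytest.approx(2 * moens_korteweg(1.0, 1.5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            moens_korteweg(-1.0, 1.0)

    def test_all_golden_pwv_cells(self):
        for (w, sha), row in GOLDEN_PWV.items():
            for model, expected in zip(MODELS, row):
                pwv = moens_korteweg(shore_to_elasticity(sha, model), w)
                assert round(pwv, 2) == expected, (w, sha, model)


class TestTheoreticalTable:
    def test_75_cells_match_golden_table(self):
        table = theoretical_pwv_table()
        assert len(table) == 75
        for (w, sha), row in GOLDEN_PWV.items():
            for model, expected in zip(MODELS, row):
                got = table[(table.wall_mm == w) & (table.sha == sha)
                            & (table.model == model)].pwv_2dp.item()
                assert got == expected, (w, sha, model)

    def test_monotone_in_hardness_and_thickness(self):
        table = theoretical_pwv_table()
        for (_, m), g in table.groupby(["wall_mm", "model"]):
            assert np.all(np.diff(g.sort_values("sha").pwv) > 0)
        for (_, m), g in table.groupby(["sha", "model"]):
            assert np.all(np.diff(g.sort_values("wall_mm").pwv) > 0)

    def test_elasticity_table_shape(self):
        assert len(elasticity_table()) == 25


class TestReferencePtt:
    def test_uniform_shift(self):
        up = np.arange(60) * 1.0
        assert reference_ptt(up, up + 0.03) == pytest.approx(0.030)

    def test_median_robust_to_outlier(self):
        up = np.arange(60) * 1.0
        down = up + 0.03
        down[13] = up[13] + 0.3
        assert reference_ptt(up, down) == pytest.approx(0.030)

    def test_swapped_channels_detected(self):
        up = np.arange(20) * 1.0
        with pytest.raises(ValueError, match="swapped"):
            reference_ptt(up + 0.03, up)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            reference_ptt([], [1.0])


class TestReferencePwv:
    def test_thirty_centimetres_in_thirty_ms(self):
        assert reference_pwv(0.03).value == pytest.approx(10.0)
        assert reference_pwv(0.015).value == pytest.approx(20.0)

    def test_method_tag(self):
        assert reference_pwv(0.03).method == "M"

    def test_nonpositive_ptt_rejected(self):
        with pytest.raises(ValueError):
            reference_pwv(0.0)


class TestEstimateFromHardness:
    def test_exact_hardness_equals_theory(self):
        est = estimate_pwv_from_hardness(50, 2.0, "DMA", method_tag="R")
        assert round(est.value, 2) == 35.46
        assert est.method == "R" and est.conversion == "DMA"

    def test_tolerance_band_brackets_theory(self):
        # manufacturer Shore A tolerance of +/-2 around 30 brackets 14.61
        lo = estimate_pwv_from_hardness(28, 2.0, "Ruess").value
        hi = estimate_pwv_from_hardness(32, 2.0, "Ruess").value
        assert lo < 14.61 < hi

    def test_zero_hardness_still_finite(self):
        est = estimate_pwv_from_hardness(1e-9, 1.0, "DMA")
        assert np.isfinite(est.value) and est.value > 0

    def test_negative_pwv_impossible(self):
        with pytest.raises(ValueError):
            PwvEstimate(-1.0, "T")


class TestErrorAnalysis:
    def test_identical_pairs_degenerate(self):
        x = np.arange(10.0)
        s = error_analysis(x, x)
        assert s.degenerate and s.median == 0.0 and s.iqr == 0.0

    def test_shift_detected_by_t_test(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(10, 2, 45)
        s = error_analysis(ref + 5 + rng.normal(0, 1, 45), ref)
        assert s.test_used == "t_test" and s.p_value < 0.05

    def test_gate_consistency(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(0, 1, 30) if rng.random() < 0.5 \
                else rng.standard_t(1, 30)
            s = error_analysis(d, np.zeros(30))
            assert (s.test_used == "t_test") == (s.shapiro_p >= 0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            error_analysis([1.0, 2.0], [1.0, 2.0])

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            error_analysis([1.0, 2.0, 3.0], [1.0, 2.0])
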