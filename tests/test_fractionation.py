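"""Baseline, integration, quantification, COD rates and the pipeline."""

import numpy as np
import pytest

from respirocod import (RespirogramModel, SimulationConfig, characterize,
                        cod_degradation_rates, estimate_endogenous_baseline,
                        filter_fractions, integrate_our, paper_fixture,
                        quantify_fractions, simulate_respirogram)
from respirocod.core import CODSeries
from respirocod.fractionation import SegmentationResult, StageError
from tests.conftest import make_series


class TestBaseline:
    def test_reference_plateau_mean(self, table2):
        assert estimate_endogenous_baseline(table2, 70.0) == pytest.approx(
            (11.0 + 11.2 + 11.3) / 3, abs=5e-3)

    def test_constant_tail(self):
        s = make_series(np.arange(6) * 10.0, [20, 15, 13, 11.5, 11.5, 11.5])
        assert estimate_endogenous_baseline(s, 30.0) == pytest.approx(11.5)

    def test_t2_beyond_last_point(self, table2):
        with pytest.raises(ValueError):
            estimate_endogenous_baseline(table2, 85.0)


class TestIntegration:
    def test_rectangle(self):
        s = make_series([0.0, 30.0, 60.0], [12.0, 12.0, 12.0])
        assert integrate_our(s, 0.0, 60.0) == pytest.approx(12.0)

    def test_reference_first_segment(self, table2):
        # hand trapezoid of (46.8, 39.6, 28.8, 22.2) at 5-min spacing
        assert integrate_our(table2, 0.0, 15.0) == pytest.approx(8.575)

    def test_baseline_at_maximum_zeroes_integral(self, table2):
        top = float(table2.our.max())
        assert integrate_our(table2, 0.0, 80.0, baseline=top,
                             subtract_baseline=True) == 0.0

    def test_interpolated_bounds(self):
        s = make_series([0.0, 10.0, 20.0], [10.0, 10.0, 10.0])
        assert integrate_our(s, 2.5, 17.5) == pytest.approx(10 * 15 / 60)

    def test_reversed_bounds_rejected(self, table2):
        with pytest.raises(ValueError):
            integrate_our(table2, 20.0, 10.0)


class TestQuantify:
    def test_algebraic_identity_in_yield(self, table2):
        seg = SegmentationResult(t1=15.0, t2=70.0, our_en=11.1667)
        a = quantify_fractions(table2, seg, y_h=0.68)
        b = quantify_fractions(table2, seg, y_h=0.84)  # halves (1 - y_h)
        assert b.rbcod == pytest.approx(2 * a.rbcod)
        assert b.sbcod == pytest.approx(2 * a.sbcod)

    def test_zero_after_baseline_subtraction(self):
        s = make_series(np.arange(10) * 5.0, np.full(10, 7.0))
        seg = SegmentationResult(t1=15.0, t2=40.0, our_en=7.0)
        res = quantify_fractions(s, seg)
        assert res.rbcod == 0.0 and res.sbcod == 0.0

    def test_invalid_yield_rejected(self, table2):
        seg = SegmentationResult(t1=15.0, t2=70.0, our_en=11.1667)
        with pytest.raises(ValueError):
            quantify_fractions(table2, seg, y_h=1.0)

    def test_smoothing_flag_close_to_raw_on_smooth_data(self, table2):
        seg = SegmentationResult(t1=15.0, t2=70.0, our_en=11.1667)
        raw = quantify_fractions(table2, seg)
        smooth = quantify_fractions(table2, seg, smooth=True)
        assert smooth.rbcod == pytest.approx(raw.rbcod, rel=0.15)
        assert smooth.sbcod == pytest.approx(raw.sbcod, rel=0.15)

    def test_additivity_of_segment_integrals(self, table2):
        seg = SegmentationResult(t1=15.0, t2=70.0, our_en=11.1667)
        res = quantify_fractions(table2, seg)
        whole = integrate_our(table2, 0.0, 70.0, baseline=seg.our_en,
                              subtract_baseline=True) / (1 - 0.68)
        assert res.rbcod + res.sbcod == pytest.approx(whole, abs=1e-9)


class TestCodRates:
    def test_reference_mixture_rates(self, cod_mixture):
        rates = cod_degradation_rates(cod_mixture, [0, 15, 70, 80])
        vals = [r for _, _, r in rates]
        assert vals[0] == pytest.approx(5.86, abs=5e-3)
        assert vals[1] == pytest.approx(3.227, abs=5e-3)
        assert vals[2] == pytest.approx(1.39, abs=5e-3)

    def test_flat_cod_zero_rate(self):
        cod = CODSeries([0.0, 10.0, 20.0], [100.0, 100.0, 100.0])
        rates = cod_degradation_rates(cod, [0, 20])
        assert rates[0][2] == 0.0

    def test_two_point_hand_arithmetic(self):
        cod = CODSeries([0.0, 10.0], [100.0, 90.0])
        assert cod_degradation_rates(cod, [0, 10])[0][2] == pytest.approx(1.0)

    def test_unsampled_breakpoint_rejected(self, cod_mixture):
        with pytest.raises(ValueError, match="not a sampled time"):
            cod_degradation_rates(cod_mixture, [0, 42, 80])

    def test_collinear_interior_point_does_not_change_rates(self):
        cod = CODSeries([0.0, 20.0], [100.0, 60.0])
        dense = CODSeries([0.0, 10.0, 20.0], [100.0, 80.0, 60.0])
        r1 = cod_degradation_rates(cod, [0, 20])
        r2 = cod_degradation_rates(dense, [0, 20])
        assert r1[0][2] == pytest.approx(r2[0][2])


class TestFilterFractions:
    def test_difference_and_percentages(self):
        fx = filter_fractions(tcod=418.0, pcod=192.9, scod=69.8)
        assert fx.ccod == pytest.approx(155.3)
        p, c, s = fx.percentages
        assert p == pytest.approx(46.1, abs=0.1)
        assert c == pytest.approx(37.2, abs=0.1)
        assert s == pytest.approx(16.7, abs=0.1)
        assert p + c + s == pytest.approx(100.0, abs=0.1)

    def test_all_colloidal(self):
        fx = filter_fractions(tcod=100.0, pcod=0.0, scod=0.0)
        assert fx.ccod == 100.0
        assert fx.percentages[1] == pytest.approx(100.0)

    def test_negative_colloidal_rejected(self):
        with pytest.raises(ValueError, match="negative colloidal"):
            filter_fractions(tcod=100.0, pcod=80.0, scod=30.0)


class TestCharacterize:
    def test_reference_curve_stage_boundaries(self, table2):
        res = characterize(table2)
        assert res.segmentation.t1 == 15.0
        assert res.segmentation.t2 == 70.0
        assert res.segmentation.our_en == pytest.approx(11.1667, abs=5e-3)

    def test_synthetic_fraction_recovery_noiseless(self, fast_sim_config):
        resp = simulate_respirogram(fast_sim_config)
        res = characterize(resp.our_series)
        assert res.rbcod == pytest.approx(fast_sim_config.ss0, rel=0.05)
        assert res.sbcod == pytest.approx(fast_sim_config.xs0, rel=0.05)

    def test_grid_refinement_stability(self, fast_sim_config):
        import dataclasses
        coarse = simulate_respirogram(
            dataclasses.replace(fast_sim_config, sample_interval_min=4.0))
        fine = simulate_respirogram(
            dataclasses.replace(fast_sim_config, sample_interval_min=1.0))
        res_c = characterize(coarse.our_series)
        res_f = characterize(fine.our_series)
        total_c = res_c.rbcod + res_c.sbcod
        total_f = res_f.rbcod + res_f.sbcod
        assert abs(total_c - total_f) / total_f < 0.03

    def test_too_short_series_rejected(self):
        s = make_series(np.arange(7) * 5.0, np.linspace(40, 11, 7))
        with pytest.raises(ValueError, match="at least 8"):
            characterize(s)

    def test_stage_errors_are_labelled(self):
        s = make_series(np.arange(8) * 5.0,
                        50.0 * 0.7 ** np.arange(8))
        with pytest.raises(StageError, match="endogenous-onset"):
            characterize(s)

    def test_cod_rates_attached_when_sampled(self, table2, cod_mixture):
        res = characterize(table2, cod=cod_mixture)
        assert res.rates is not None
        assert res.rates[0][2] == pytest.approx(5.86, abs=5e-3)


class TestModelFacade:
    def test_fit_returns_results_with_summary(self, table2):
        res = RespirogramModel(table2).fit()
        assert res.t1 == 15.0 and res.t2 == 70.0
        text = res.summary()
        assert "RBCOD" in text and "SBCOD" in text
        assert "15.00" in text and "70.00" in text

    def test_from_dataframe(self, table2):
        import pandas as pd
        df = pd.DataFrame({"time_min": table2.times,
                           "our_mgO2_L_h": table2.our})
        res = RespirogramModel.from_dataframe(df).fit()
        assert res.t2 == 70.0

    def test_hydrolysis_params_exposed(self, table2):
        res = RespirogramModel(table2).fit()
        p = res.hydrolysis_params
        assert p is not None and p.k_h > 0

    def test_plot_segments_draws_axes(self, table2):
        ax = RespirogramModel(table2).fit().plot_segments()
        assert ax.get_xlabel() == "time (min)"
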