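"""Breakpoints, spectral maxima, melting temperatures and Hill fits."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingbind import synthdata, titrate
from wingbind.titrate import (BreakpointModel, HillModel, NoBreakpointError,
                              NoTransitionError)


class TestBreakpoint:
    def test_exact_two_segment_data(self):
        r = np.linspace(0, 4, 12)
        s = 1.0 * r + (0.1 - 1.0) * np.maximum(r - 2.0, 0.0)
        res = BreakpointModel(r, s).fit()
        assert res.breakpoint == pytest.approx(2.0, abs=1e-6)
        assert res.slope_before == pytest.approx(1.0, abs=1e-9)
        assert res.slope_after == pytest.approx(0.1, abs=1e-6)

    def test_synthetic_noiseless_curve(self, spec0):
        df = synthdata.gen_titration_curve(spec0)
        res = titrate.breakpoint_stoichiometry(df["ratio"], df["signal"])
        assert res.breakpoint == pytest.approx(spec0.stoichiometry_break,
                                               abs=1e-6)

    def test_noisy_curves_localize_break(self):
        """2% noise, 50 seeds: median |x0 - 2| <= 0.15 molar-ratio units."""
        errs = []
        for seed in range(50):
            spec = synthdata.SynthSpec(seed=seed)
            df = synthdata.gen_titration_curve(spec)
            res = titrate.breakpoint_stoichiometry(df["ratio"], df["signal"])
            errs.append(abs(res.breakpoint - spec.stoichiometry_break))
        assert np.median(errs) <= 0.15

    def test_straight_line_raises_no_breakpoint(self):
        r = np.linspace(0, 4, 12)
        with pytest.raises(NoBreakpointError):
            BreakpointModel(r, 0.7 * r + 0.3).fit()

    def test_affine_transform_leaves_breakpoint_fixed(self, spec0):
        df = synthdata.gen_titration_curve(spec0)
        base = titrate.breakpoint_stoichiometry(df["ratio"], df["signal"])
        scaled = titrate.breakpoint_stoichiometry(
            df["ratio"], 3.5 * df["signal"] - 11.0)
        assert scaled.breakpoint == pytest.approx(base.breakpoint, abs=1e-6)
        assert scaled.slope_before == pytest.approx(3.5 * base.slope_before,
                                                    rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            BreakpointModel([0, 1, 2, 3, 4], [0, 1, 2, 2.1, 2.2])

    def test_unsorted_ratios_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            BreakpointModel([0, 2, 1, 3, 4, 5], np.zeros(6))


class TestLambdaMax:
    def test_gaussian_peak_on_grid(self):
        wl = np.arange(310.0, 421.0, 1.0)
        y = np.exp(-0.5 * ((wl - 355.0) / 28.0) ** 2)
        assert titrate.lambda_max(wl, y) == pytest.approx(355.0, abs=1e-6)

    def test_off_grid_peak_interpolated(self):
        wl = np.arange(310.0, 421.0, 1.0)
        y = np.exp(-0.5 * ((wl - 355.4) / 28.0) ** 2)
        assert titrate.lambda_max(wl, y) == pytest.approx(355.4, abs=0.01)

    def test_edge_maximum_warns(self):
        wl = np.arange(310.0, 316.0, 1.0)
        y = np.linspace(1.0, 0.2, len(wl))
        with pytest.warns(UserWarning, match="edge"):
            assert titrate.lambda_max(wl, y) == 310.0

    def test_synthetic_blue_shift(self, spec0):
        free, bound = synthdata.gen_emission_pair(spec0)
        shift = titrate.blue_shift(free["wavelength_nm"], free["intensity"],
                                   bound["wavelength_nm"], bound["intensity"])
        assert shift == pytest.approx(
            spec0.lambda_max_free_nm - spec0.lambda_max_bound_nm, abs=0.05)


class TestMelting:
    def test_synthetic_tm_recovered(self, spec0):
        free, bound = synthdata.gen_melting_pair(spec0)
        tm = titrate.tm_from_melt(free["temperature_c"], free["a260"])
        assert tm == pytest.approx(spec0.tm_free_c, abs=0.1)

    def test_delta_tm_study_value(self, spec0):
        free, bound = synthdata.gen_melting_pair(spec0)
        dt = titrate.delta_tm(free["temperature_c"], free["a260"],
                              bound["temperature_c"], bound["a260"])
        assert dt == pytest.approx(spec0.tm_bound_c - spec0.tm_free_c, abs=0.2)

    def test_tm_antisymmetry(self, spec0):
        """Swapping the pair negates the stabilization."""
        free, bound = synthdata.gen_melting_pair(spec0)
        fwd = titrate.delta_tm(free["temperature_c"], free["a260"],
                               bound["temperature_c"], bound["a260"])
        rev = titrate.delta_tm(bound["temperature_c"], bound["a260"],
                               free["temperature_c"], free["a260"])
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_noisy_delta_tm(self):
        """1% noise, 30 seeds: derivative-peak Tm stays within two grid
        steps (1.0 degC) in the median and is unbiased."""
        errs = []
        for seed in range(30):
            spec = synthdata.SynthSpec(seed=seed)
            free, bound = synthdata.gen_melting_pair(spec)
            dt = titrate.delta_tm(free["temperature_c"], free["a260"],
                                  bound["temperature_c"], bound["a260"])
            errs.append(dt - (spec.tm_bound_c - spec.tm_free_c))
        assert np.median(np.abs(errs)) <= 1.0
        assert abs(np.mean(errs)) <= 0.5

    def test_flat_curve_raises(self):
        t = np.arange(20.0, 81.0, 1.0)
        with pytest.raises(NoTransitionError):
            titrate.tm_from_melt(t, np.full_like(t, 0.7))

    def test_narrow_span_rejected(self):
        t = np.arange(40.0, 50.0, 1.0)
        with pytest.raises(ValueError, match="20 deg"):
            titrate.tm_from_melt(t, np.linspace(0.5, 1.0, len(t)))


class TestHill:
    def test_half_saturation_definition(self):
        assert titrate.hill_curve(12.0, 4.5, 12.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("n_true", [1.0, 2.0, 4.5, 6.0])
    def test_exact_recovery_across_steepness(self, n_true):
        conc = np.array(synthdata.EMSA_CONCENTRATIONS_UM)
        frac = titrate.hill_curve(conc, n_true, 12.0)
        res = HillModel(conc, frac).fit()
        assert res.n == pytest.approx(n_true, rel=1e-4)
        assert res.k_half == pytest.approx(12.0, rel=1e-4)

    def test_synthetic_noiseless_curve(self, spec0):
        df = synthdata.gen_emsa_curve(spec0)
        res = titrate.hill_fit(df["conc_um"], df["fraction_bound"])
        assert res.n == pytest.approx(spec0.hill_n, rel=1e-4)

    def test_noisy_cooperativity_estimate(self):
        """2% fraction noise, 50 seeds: median fitted n within 4.5 +/- 0.5."""
        ns = []
        for seed in range(50):
            spec = synthdata.SynthSpec(seed=seed)
            df = synthdata.gen_emsa_curve(spec)
            ns.append(titrate.hill_fit(df["conc_um"], df["fraction_bound"]).n)
        assert abs(np.median(ns) - 4.5) <= 0.5

    def test_hill_curve_monotone(self):
        conc = np.linspace(0.5, 40, 100)
        f = titrate.hill_curve(conc, 4.5, 12.0)
        assert np.all(np.diff(f) > 0)
        assert f[0] > 0 and f[-1] < 1

    def test_flat_data_raises(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(RuntimeError, match="flat"):
            HillModel(conc, np.full(5, 0.4)).fit()

    def test_out_of_range_fraction_rejected(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        with pytest.raises(ValueError, match="fractions"):
            HillModel(conc, [0.0, 0.2, 0.5, 0.9, 1.2])

    def test_summary_reports_ci(self, spec0):
        df = synthdata.gen_emsa_curve(spec0)
        res = titrate.hill_fit(df["conc_um"], df["fraction_bound"])
        assert "95% CI" in res.summary()
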