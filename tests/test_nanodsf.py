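"""Two-state unfolding model: closed forms, fitting, per-gram assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidkit import (FitError, GeneratorTransition, PerGramThermo,
                       Thermogram, TransitionParams, fit_first_transition,
                       fit_second_transition, fraction_unfolded,
                       melting_temperature, onset_temperature, per_gram,
                       predict_signal, simulate_thermogram)
from capsidkit.constants import R_CAL, celsius_to_kelvin


class TestFractionUnfolded:
    def test_half_unfolded_at_tm(self):
        assert fraction_unfolded(1.46e5, 434, 1.46e5 / 434) == pytest.approx(0.5, abs=1e-9)

    def test_direct_evaluation(self):
        # independent evaluation of the logistic form at 62 °C
        dH, dS, T = 1.46e5, 434.0, 335.15
        x = np.exp(-dH / (R_CAL * T) + dS / R_CAL)
        assert fraction_unfolded(dH, dS, T) == pytest.approx(x / (1 + x), abs=1e-12)
        assert fraction_unfolded(dH, dS, T) == pytest.approx(0.3061, abs=1e-3)

    def test_sharp_limit_is_step(self):
        tm_k = 335.0
        dH = 1e9
        assert fraction_unfolded(dH, dH / tm_k, tm_k - 1) < 1e-6
        assert fraction_unfolded(dH, dH / tm_k, tm_k + 1) > 1 - 1e-6

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            fraction_unfolded(1e5, 300, 0.0)

    @given(t=st.floats(250, 450), dh=st.floats(1e4, 1e6))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_monotone(self, t, dh):
        ds = dh / 340.0
        f = fraction_unfolded(dh, ds, t)
        f2 = fraction_unfolded(dh, ds, t + 1.0)
        assert 0.0 <= f <= 1.0
        assert f2 >= f
        if 1e-12 < f < 1 - 1e-12:  # strict away from floating-point saturation
            assert f2 > f


class TestPredictSignal:
    PARAMS = TransitionParams(dH=1.46e5, dS=434.0, a=0.002, b=0.75, c=0.002, d=0.78)

    def test_baselines_far_from_tm(self):
        p = self.PARAMS
        lo, hi = np.array([10.0]), np.array([120.0])
        assert predict_signal(p, lo)[0] == pytest.approx(p.a * 10 + p.b, abs=1e-6)
        assert predict_signal(p, hi)[0] == pytest.approx(p.c * 120 + p.d, abs=1e-6)

    def test_midpoint_of_baselines_at_tm(self):
        p = self.PARAMS
        tm = melting_temperature(p.dH, p.dS)
        mid = 0.5 * ((p.a * tm + p.b) + (p.c * tm + p.d))
        assert predict_signal(p, np.array([tm]))[0] == pytest.approx(mid, abs=1e-9)


class TestDerivedTemperatures:
    def test_melting_temperature_values(self):
        assert melting_temperature(3.21e5, 925.0) == pytest.approx(321000 / 925 - 273.15, abs=1e-9)
        assert melting_temperature(3.21e5, 925.0) == pytest.approx(73.9, abs=0.05)
        assert melting_temperature(2.7315e5, 1000.0) == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        assert melting_temperature(2 * 1.46e5, 2 * 434) == melting_temperature(1.46e5, 434)

    def test_onset_closed_form(self):
        expected = 146000 / (434 + R_CAL * np.log(19)) - 273.15
        assert onset_temperature(1.46e5, 434.0) == pytest.approx(expected, abs=1e-9)
        assert onset_temperature(1.46e5, 434.0) == pytest.approx(58.8, abs=0.05)

    def test_onset_at_half_equals_tm_boundary(self):
        with pytest.raises(ValueError):
            onset_temperature(1.46e5, 434.0, f_onset=0.5)
        # approaching 0.5 from below converges to Tm
        near = onset_temperature(1.46e5, 434.0, f_onset=0.4999999)
        assert near == pytest.approx(melting_temperature(1.46e5, 434.0), abs=1e-3)

    @given(f=st.floats(0.001, 0.49), dh=st.floats(5e4, 5e5))
    @settings(derandomize=True, max_examples=50)
    def test_onset_consistency_and_order(self, f, dh):
        ds = dh / 340.0
        t_on = onset_temperature(dh, ds, f)
        assert t_on < melting_temperature(dh, ds)
        assert fraction_unfolded(dh, ds, celsius_to_kelvin(t_on)) == pytest.approx(f, abs=1e-9)

    def test_rejects_nonpositive(self):
        for args in [(-1.0, 434), (1.46e5, 0.0)]:
            with pytest.raises(ValueError):
                melting_temperature(*args)


class TestFitting:
    def test_noiseless_roundtrip_recovers_parameters(self):
        tg = simulate_thermogram(GeneratorTransition(1.46e5, 62.0, 0.03),
                                 None, noise_sd=0.0, seed=0)
        fit = fit_first_transition(tg)
        assert fit.params.dH == pytest.approx(1.46e5, rel=1e-3)
        assert fit.tm_c == pytest.approx(62.0, abs=0.01)
        assert fit.params.a == pytest.approx(fit.params.c)

    def test_fu_consistency_on_fit(self, fp_thermogram):
        fit = fit_first_transition(fp_thermogram(seed=3))
        p = fit.params
        assert fraction_unfolded(p.dH, p.dS, celsius_to_kelvin(fit.tm_c)) == pytest.approx(0.5, abs=1e-9)
        assert fraction_unfolded(p.dH, p.dS, celsius_to_kelvin(fit.tonset_c)) == pytest.approx(0.05, abs=1e-9)
        assert fit.tonset_c < fit.tm_c

    def test_noisy_recovery_over_seeds(self, fp_thermogram):
        tms = [fit_first_transition(fp_thermogram(seed=s)).tm_c for s in range(20)]
        assert np.mean(tms) == pytest.approx(62.0, abs=0.5)

    def test_second_transition_with_inherited_baseline(self, fp_thermogram):
        tg = fp_thermogram(seed=5)
        first = fit_first_transition(tg)
        second = fit_second_transition(tg, inherited=first)
        assert second.tm_c == pytest.approx(73.7, abs=0.3)
        assert second.params.a == first.params.c
        assert second.params.b == first.params.d
        assert second.constraint_mode == "second"

    def test_single_transition_sample_free_baselines(self, ep_thermogram):
        tg = ep_thermogram(seed=2)
        fit = fit_second_transition(tg)
        assert fit.params.dH == pytest.approx(2.78e5, rel=0.05)
        assert fit.constraint_mode == "free"

    def test_pure_baseline_is_flagged_failure(self):
        tg = simulate_thermogram(None, None, noise_sd=0.0005, seed=0)
        with pytest.raises(FitError):
            fit_first_transition(tg)

    def test_inherited_window_order_enforced(self, fp_thermogram):
        tg = fp_thermogram()
        first = fit_first_transition(tg)
        with pytest.raises(ValueError):
            fit_second_transition(tg, window=(40.0, 60.0), inherited=first)

    def test_tiny_window_rejected(self, fp_thermogram):
        with pytest.raises(ValueError):
            fit_first_transition(fp_thermogram(), window=(61.0, 62.0))


class TestPerGram:
    def test_vp1_n_termini_assignment(self):
        pg = per_gram(1.46e5, 434.0, 2.2e4)
        assert pg.h == pytest.approx(6.64, abs=0.01)
        assert pg.s_g == pytest.approx(1.97e-2, abs=1e-4)
        assert pg.within_globular_range

    def test_outside_range(self):
        pg = per_gram(1.46e5, 434.0, 1.46e5)  # 1 cal/g
        assert pg.h == pytest.approx(1.0)
        assert not pg.within_globular_range

    @given(k=st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=30)
    def test_scaling_invariance(self, k):
        base = per_gram(1.46e5, 434.0, 2.2e4)
        scaled = per_gram(k * 1.46e5, k * 434.0, k * 2.2e4)
        assert scaled.h == pytest.approx(base.h, rel=1e-12)
        assert scaled.s_g == pytest.approx(base.s_g, rel=1e-12)
        assert scaled.within_globular_range == base.within_globular_range

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            per_gram(1.46e5, 434.0, 0.0)


class TestThermogramContainer:
    def test_rejects_decreasing_grid(self):
        with pytest.raises(ValueError):
            Thermogram(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            Thermogram(np.array([1.0, 2.0, 3.0]), np.array([0.0, np.nan, 0.0]))
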