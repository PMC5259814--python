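"""Waveform processing, Poiseuille WSS, TAWSS/OSI, Reynolds number."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from castseg.datasets import inlet_flow_table
from castseg.hemodynamics import (BloodModel, FlowWaveform, WSSField,
                                  average_cycles, flow_rate, flow_report,
                                  lowpass_filter, osi, poiseuille_wss,
                                  reynolds, synthetic_doppler_trace, tawss)


def waveform_from(values, period=0.15, kind="flow"):
    values = np.asarray(values, dtype=float)
    t = period * np.arange(len(values)) / len(values)
    return FlowWaveform(t=t, values=values, kind=kind)


def field_from(values, period=0.15, r_um=250.0):
    q = waveform_from(values, period)
    return poiseuille_wss(q, s=np.array([0.0]), radius=np.array([r_um]))


class TestAverageCycles:
    def test_identical_cycles_reproduce_template(self):
        period, n = 0.15, 50
        phase = np.arange(n) / n
        template = 0.2 + 0.3 * np.exp(-((phase - 0.3) / 0.1) ** 2)
        t = np.arange(6 * n) * period / n
        v = np.tile(template, 6)
        wave = average_cycles(t, v, n_cycles=5, n_phase=n)
        peak = np.argmax(template)
        rolled = np.roll(template, -peak)  # cycles are delimited peak-to-peak
        assert np.allclose(wave.values, rolled, atol=1e-9)
        assert wave.period == pytest.approx(period)

    def test_noise_suppression_scales_with_cycle_count(self):
        rng = np.random.default_rng(8)
        period, n, n_cycles = 0.15, 200, 5
        phase = np.arange(n) / n
        template = 0.2 + 0.3 * np.exp(-((phase - 0.3) / 0.05) ** 2)
        # sharply defined systolic maximum so that noise cannot move the
        # detected peak: isolates the ensemble-averaging statistics
        template[int(0.3 * n)] += 0.2
        t = np.arange(8 * n) * period / n
        clean = np.tile(template, 8)
        noise_sd = 0.03  # 10 % of the pulse amplitude
        v = clean + rng.normal(0, noise_sd, clean.shape)
        wave = average_cycles(t, v, n_cycles=n_cycles, n_phase=n)

        def best_aligned_rms(signal):
            # residual against the template at the best circular alignment,
            # removing the peak-detection phase ambiguity
            return min(np.sqrt(np.mean((signal - np.roll(template, k)) ** 2))
                       for k in range(n))

        singles = [v[i * n:(i + 1) * n] for i in range(n_cycles)]
        rms_single = np.mean([best_aligned_rms(s) for s in singles])
        rms_mean = best_aligned_rms(wave.values)
        # ensemble averaging reduces the residual RMS by ~ sqrt(n_cycles)
        ratio = rms_single / rms_mean
        assert np.sqrt(n_cycles) / 1.6 < ratio < np.sqrt(n_cycles) * 1.6

    def test_too_few_cycles_reports_count(self):
        t, v = synthetic_doppler_trace(n_cycles=3, seed=0)
        with pytest.raises(ValueError, match="need 5"):
            average_cycles(t, v, n_cycles=5)


class TestLowpass:
    def test_bandlimited_signal_unchanged(self):
        t = 0.15 * np.arange(100) / 100
        w = waveform_from(0.2 + 0.1 * np.sin(2 * np.pi * t / 0.15))
        out = lowpass_filter(w, 8)
        assert np.allclose(out.values, w.values, atol=1e-9)

    def test_single_harmonic_truncation(self):
        v = np.where(np.arange(100) < 30, 1.0, 0.0)
        out = lowpass_filter(waveform_from(v), 1)
        spec = np.fft.rfft(out.values)
        assert np.allclose(np.abs(spec[2:]), 0.0, atol=1e-9)

    def test_mean_preserved(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=128)
        out = lowpass_filter(waveform_from(v), 8)
        assert out.mean == pytest.approx(v.mean(), abs=1e-9)

    def test_rejects_zero_harmonics(self):
        with pytest.raises(ValueError):
            lowpass_filter(waveform_from(np.ones(10)), 0)


class TestFlowRate:
    def test_parabolic_conversion_scale(self):
        w = waveform_from([0.2], kind="velocity")
        q = flow_rate(w, inlet_radius=250.0, profile="parabolic")
        assert q.values[0] == pytest.approx(19.63, abs=0.01)
        assert q.kind == "flow"

    def test_plug_is_twice_parabolic(self):
        w = waveform_from([0.1, 0.3, 0.2], kind="velocity")
        qp = flow_rate(w, 200.0, "parabolic")
        qg = flow_rate(w, 200.0, "plug")
        assert np.allclose(qg.values, 2 * qp.values)

    def test_zero_velocity_zero_flow(self):
        q = flow_rate(waveform_from([0.0, 0.0], kind="velocity"), 250.0)
        assert np.allclose(q.values, 0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            flow_rate(waveform_from([1.0], kind="flow"), 250.0)
        with pytest.raises(ValueError):
            flow_rate(waveform_from([1.0], kind="velocity"), -1.0)


class TestPoiseuilleWss:
    def test_hand_computed_magnitude(self):
        field = field_from([25.8], r_um=250.0)
        assert field.tau[0, 0] == pytest.approx(7.36, abs=0.01)

    def test_inverse_cubic_radius_law(self):
        q = waveform_from([10.0])
        s = np.array([0.0, 1.0])
        f = poiseuille_wss(q, s, np.array([250.0, 125.0]))
        assert f.tau[1, 0] / f.tau[0, 0] == pytest.approx(8.0)

    def test_zero_flow_zero_stress(self):
        assert np.allclose(field_from([0.0, 0.0]).tau, 0.0)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            poiseuille_wss(waveform_from([1.0]), np.array([0.0]),
                           np.array([0.0]))


class TestTawssOsi:
    def test_constant_signal(self):
        f = WSSField(s=np.array([0.0]), t=np.linspace(0, 0.99, 100),
                     tau=np.full((1, 100), 6.0), period=1.0)
        assert tawss(f)[0] == pytest.approx(6.0)
        assert osi(f)[0] == pytest.approx(0.0)

    def test_sinusoid_closed_forms(self):
        t = np.arange(100) / 100
        A = 3.0
        f = WSSField(s=np.array([0.0]), t=t,
                     tau=A * np.sin(2 * np.pi * t)[None, :], period=1.0)
        assert tawss(f)[0] == pytest.approx(2 * A / np.pi, rel=5e-3)
        assert osi(f)[0] == pytest.approx(0.5, abs=1e-3)

    def test_tawss_scales_linearly_with_flow(self):
        v = np.array([1.0, 4.0, 2.0, -0.5])
        f1, f3 = field_from(v), field_from(3 * v)
        assert tawss(f3)[0] == pytest.approx(3 * tawss(f1)[0])

    def test_osi_matches_quadrature_oracle(self):
        rng = np.random.default_rng(12)
        v = rng.normal(0.5, 2.0, 200)
        f = field_from(v)
        # independent oracle: OSI = 0.5 (1 - |m| T / I) by direct quadrature
        t = np.append(f.t, f.period)
        tau = np.append(f.tau[0], f.tau[0, 0])
        m = np.trapezoid(tau, t) / f.period
        I = np.trapezoid(np.abs(tau), t)
        expected = 0.5 * (1 - abs(m) * f.period / I)
        assert osi(f)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_signal_defined_as_zero(self):
        assert osi(field_from([0.0, 0.0, 0.0]))[0] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 64))
    def test_osi_bounds_and_tawss_triangle_inequality(self, seed, n):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 5.0, n)
        f = field_from(v)
        o = osi(f)[0]
        assert 0.0 <= o <= 0.5
        t = np.append(f.t, f.period)
        tau = np.append(f.tau[0], f.tau[0, 0])
        mean_tau = np.trapezoid(tau, t) / f.period
        assert tawss(f)[0] >= abs(mean_tau) - 1e-12


class TestReynolds:
    def test_cohort_scale_value(self):
        assert reynolds(19.8, 500.0) == pytest.approx(15.3, abs=0.05)

    def test_scaling_laws(self):
        assert reynolds(0.0, 500.0) == 0.0
        assert reynolds(10.0, 1000.0) == pytest.approx(reynolds(10.0, 500.0) / 2)

    def test_blood_model_defaults(self):
        b = BloodModel()
        assert b.viscosity == 3.5e-3
        assert b.density == 1060.0
        with pytest.raises(ValueError):
            BloodModel(viscosity=0.0)


class TestFlowReport:
    def test_cohort_averages_excluding_missing(self):
        tab = inlet_flow_table()
        rep = flow_report(tab["flow_mm3_s"], tab["wss_pa"])
        assert rep.loc["flow_mm3_s", "mean"] == pytest.approx(19.77, abs=0.01)
        assert rep.loc["flow_mm3_s", "sd"] == pytest.approx(9.95, abs=0.05)
        assert rep.loc["wss_pa", "mean"] == pytest.approx(3.26, abs=0.01)
        assert rep.loc["flow_mm3_s", "n"] == 7

    def test_single_animal_sd_zero(self):
        rep = flow_report([20.0], [3.0])
        assert rep.loc["flow_mm3_s", "sd"] == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            flow_report([None, np.nan], [1.0, 2.0])
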