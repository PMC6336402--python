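import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popdens.core import (NeuronParams, PopulationConfig, SynapseParams,
                          ampa_synapse, default_neuron, drift_h0,
                          gabaa_synapse, gabab_synapse, gamma_from_delta_v,
                          min_suprathreshold_rate)


class TestGamma:
    def test_ampa_value(self, neuron):
        # C |ln(1 - 1/65)| with C = 1 uF
        assert gamma_from_delta_v(1e-3, 1e-6, 0.0, -65e-3) \
            == pytest.approx(1.5504e-8, rel=1e-4)

    def test_small_jump_linearizes(self, neuron):
        # Gamma -> C * dv / |E_s - E_l| as dv -> 0
        g = gamma_from_delta_v(1e-6, 1e-6, 0.0, -65e-3)
        assert g == pytest.approx(1e-6 * 1e-6 / 65e-3, rel=1e-4)

    @given(dv=st.floats(1e-5, 0.06))
    def test_monotone_in_dv(self, dv):
        g1 = gamma_from_delta_v(dv, 1e-6, 0.0, -65e-3)
        g2 = gamma_from_delta_v(dv + 1e-3, 1e-6, 0.0, -65e-3)
        assert g2 > g1 > 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gamma_from_delta_v(0.1, 1e-6, 0.0, -65e-3)   # 100 mV > 65 mV
        with pytest.raises(ValueError):
            gamma_from_delta_v(0.0, 1e-6, 0.0, -65e-3)

    def test_explicit_gamma_override(self, neuron):
        s = SynapseParams("x", tau_s=5e-3, E_s=0.0, delta_v=1e-3,
                          Gamma_s=2e-8)
        assert s.gamma(neuron) == 2e-8
        assert s.jump(neuron) == pytest.approx(2e-8 / 5e-3)


class TestNeuronParams:
    def test_defaults(self, neuron):
        assert neuron.tau_m == pytest.approx(20e-3)

    def test_reset_above_cut_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(V_r=-30e-3)

    def test_threshold_above_cut_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(V_T=-35e-3)

    def test_negative_refractory_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(tau_ref=-1e-3)


class TestPopulationConfig:
    def test_v_lb_from_most_negative_reversal(self, neuron):
        cfg = PopulationConfig(neuron, (ampa_synapse(), gabab_synapse()))
        assert cfg.V_lb == pytest.approx(-100e-3)

    def test_v_lb_default_is_rest(self, cfg_ampa):
        assert cfg_ampa.V_lb == pytest.approx(-65e-3)

    def test_duplicate_labels_rejected(self, neuron):
        with pytest.raises(ValueError):
            PopulationConfig(neuron, (ampa_synapse(), ampa_synapse()))

    def test_receptor_count(self, neuron):
        cfg = PopulationConfig(neuron, (ampa_synapse(), gabaa_synapse(),
                                        gabab_synapse()))
        assert cfg.m == 3


class TestNormalization:
    def test_min_suprathreshold_rate_value(self, neuron, ampa):
        # g_l (V_T - E_l - kappa) / [(E_s - V_T) Gamma c_s]
        assert min_suprathreshold_rate(neuron, ampa) \
            == pytest.approx(4.1924, rel=1e-3)

    def test_inhibitory_receptor_rejected(self, neuron):
        with pytest.raises(ValueError):
            min_suprathreshold_rate(neuron, gabaa_synapse())


class TestDrift:
    def test_value_at_minus_60(self, cfg_ampa):
        # (1/C)[-g_l(V - E_l) + g_l kappa e^{(V-V_T)/kappa}] at V=-60 mV
        assert float(drift_h0(-60e-3, [0.0], cfg_ampa)) \
            == pytest.approx(-0.2493, rel=1e-3)

    def test_nearly_zero_at_rest_without_input(self, cfg_ampa):
        # leak vanishes at E_l; only the tiny spike-initiation current
        # remains: g_l * kappa * e^{-7.5} / C = 5.531e-5 V/s
        assert float(drift_h0(-65e-3, [0.0], cfg_ampa)) \
            == pytest.approx(0.05e-3 * 2e-3 * math.exp(-7.5) / 1e-6,
                             rel=1e-9)

    def test_threshold_condition(self, cfg_ampa):
        # at the normalization rate, drift at V_T is exactly zero
        syn = cfg_ampa.synapses[0]
        nu = min_suprathreshold_rate(cfg_ampa.neuron, syn)
        mu = syn.c_s * nu * syn.gamma(cfg_ampa.neuron)
        # F(V_T) = (1/C)[g_l kappa - g_l kappa] ... with mu (E_s - V_T):
        v = float(drift_h0(-50e-3, [mu], cfg_ampa))
        assert abs(v) < 1e-9 * abs(float(drift_h0(-50e-3, [0.0], cfg_ampa))) \
            or v == pytest.approx(0.0, abs=1e-6)

    def test_vectorized(self, cfg_ampa):
        v = np.linspace(-80e-3, -45e-3, 7)
        out = drift_h0(v, [1e-6], cfg_ampa)
        assert out.shape == v.shape

    def test_exponential_upstroke_positive_above_threshold(self, cfg_ampa):
        assert float(drift_h0(-42e-3, [0.0], cfg_ampa)) > 0
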