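import numpy as np
import pytest
from hypothesis import given, strategies as st

from popdens import protocols as pr
from popdens.core import (PopulationConfig, SynapseParams, ampa_synapse,
                          default_neuron, gabaa_synapse)
from popdens.cspdm import (VoltageGrid, apply_slope_limiter, cell_masses,
                           diffusion_coeff, evaluate_density, mean_voltage,
                           minmod, run_cspdm, tau_eff)

from oracles import deterministic_eif_period


class TestGrid:
    def test_reset_edge(self, cfg_ampa):
        g = VoltageGrid.build(cfg_ampa, 200)
        assert g.M == 200
        assert g.edges[g.ir] == pytest.approx(cfg_ampa.neuron.V_r)

    def test_domain(self, cfg_ampa):
        g = VoltageGrid.build(cfg_ampa, 100)
        assert g.edges[0] == pytest.approx(cfg_ampa.V_lb)
        assert g.edges[-1] == pytest.approx(cfg_ampa.neuron.V_c)

    def test_snapping_with_inhibitory_domain(self, neuron):
        cfg = PopulationConfig(neuron, (ampa_synapse(), gabaa_synapse()))
        g = VoltageGrid.build(cfg, 200)
        # V_r snapped to the nearest edge of the [-80, -40] mV mesh
        assert abs(g.edges[g.ir] - neuron.V_r) <= 0.5 * g.L + 1e-15

    def test_too_few_cells(self, cfg_ampa):
        with pytest.raises(ValueError):
            VoltageGrid.build(cfg_ampa, 2)


class TestCoefficients:
    def test_tau_eff_at_rest_no_input(self, neuron):
        # C / (g_l (1 - e^{-7.5})) = 20.011 ms
        assert tau_eff(-65e-3, [0.0], neuron) == pytest.approx(20.01e-3,
                                                               rel=1e-3)

    def test_tau_eff_clamped_above_threshold(self, neuron):
        assert tau_eff(-30e-3, [0.0], neuron) == 1.0

    def test_tau_eff_shrinks_with_conductance(self, neuron):
        assert tau_eff(-65e-3, [1e-4], neuron) \
            < tau_eff(-65e-3, [0.0], neuron)

    def test_diffusion_value(self):
        # sigma_g = 1 uS, E_s = 0, V = -50 mV, C = 1 uF, rescale 4 ms
        syn = SynapseParams("x", tau_s=5e-3, E_s=0.0, delta_v=1e-3)
        cfg = PopulationConfig(default_neuron(), (syn,))
        D = diffusion_coeff(-50e-3, [1e-6], 20e-3, cfg)
        assert float(D) == pytest.approx(1.0e-5, rel=1e-6)

    def test_diffusion_vanishes_at_reversal(self, cfg_ampa):
        D = diffusion_coeff(0.0, [1e-6], 20e-3, cfg_ampa)
        assert float(D) == 0.0


class TestMinmod:
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), c=st.floats(-5, 5))
    def test_bounded_by_each_argument(self, a, b, c):
        m = float(minmod(a, b, c))
        assert abs(m) <= min(abs(a), abs(b), abs(c)) + 1e-12
        if m != 0:
            assert np.sign(m) == np.sign(a) == np.sign(b) == np.sign(c)

    def test_disagreeing_signs_zero(self):
        assert float(minmod(1.0, -1.0, 1.0)) == 0.0


class TestLimiter:
    def _traces(self, a, b):
        x = np.empty(2 * len(a))
        x[0::2] = a
        x[1::2] = b
        return x

    def test_preserves_cell_averages(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(1.0, 0.5, 40))
        g = VoltageGrid.build(PopulationConfig(default_neuron(),
                                               (ampa_synapse(),)), 20)
        before = cell_masses(x, g)
        after = cell_masses(apply_slope_limiter(x, floor=False), g)
        assert np.allclose(before, after)

    def test_linear_profile_untouched(self):
        # traces continuous and linear across cells: limiter is a no-op
        v = np.linspace(0.0, 1.0, 11)
        x = self._traces(v[:-1], v[1:])
        out = apply_slope_limiter(x)
        assert np.allclose(out, x)

    def test_floor_removes_negatives(self):
        a = np.array([0.5, -0.1, 0.5])
        b = np.array([0.5, 0.2, 0.5])
        out = apply_slope_limiter(self._traces(a, b))
        assert np.min(out) >= 0.0

    def test_oscillation_flattened(self):
        a = np.array([1.0, 5.0, 1.0, 5.0])
        b = np.array([1.0, -3.0, 1.0, -3.0])
        out = apply_slope_limiter(self._traces(a, b))
        # interior extrema are pulled to their cell averages
        assert out[2] == pytest.approx(1.0)
        assert out[3] == pytest.approx(1.0)


class TestConservationAndPositivity:
    def test_mass_conserved_without_refractory(self, neuron, ampa):
        """Criterion: probability conservation (tau_ref=0) to 1e-6."""
        from dataclasses import replace
        cfg = PopulationConfig(replace(neuron, tau_ref=0.0), (ampa,))
        res = run_cspdm(cfg, [pr.constant("ampa", 1.2)], T=0.6)
        assert np.max(np.abs(res.mass - 1.0)) < 1e-6

    def test_mass_plus_refractory_conserved(self, cfg_ampa):
        res = run_cspdm(cfg_ampa, [pr.constant("ampa", 1.2)], T=0.6)
        # in stationarity the queued mass is rate * tau_ref
        r = res.rates[-1]
        assert res.mass[-1] + r * cfg_ampa.neuron.tau_ref \
            == pytest.approx(1.0, abs=1e-4)

    def test_density_positive_after_limiting(self, cfg_ampa):
        """Criterion: density positivity after limiting."""
        res = run_cspdm(cfg_ampa, [pr.constant("ampa", 1.5)], T=0.5,
                        snapshot_times=[0.1, 0.3, 0.5])
        for x in res.snapshots.values():
            assert np.min(x) >= 0.0

    def test_rates_nonnegative(self, cfg_ampa):
        res = run_cspdm(cfg_ampa, [pr.constant("ampa", 0.8)], T=0.5)
        assert np.min(res.rates) >= 0.0


class TestAgainstOracle:
    def test_zero_noise_rate_matches_period_oracle(self, neuron):
        """Criterion: zero-noise rate vs deterministic-period oracle, 2%."""
        # same mean drive carried by 500x more, 500x weaker connections:
        # conductance CV ~ 0.014, the fluctuation-free limit
        scale = 500
        base = ampa_synapse()
        dv = base.gamma(neuron) * 65e-3 / neuron.C / scale
        syn = SynapseParams("ampa", tau_s=5e-3, E_s=0.0, delta_v=dv,
                            c_s=200 * scale)
        cfg = PopulationConfig(neuron, (syn,))
        p = pr.constant("ampa", 1.2)
        nu = float(pr.evaluate_rate(p, 0.0, cfg))
        res = run_cspdm(cfg, [p], T=2.0)
        r_cs = float(np.mean(res.rates[res.times > 1.5]))
        mu = syn.c_s * nu * syn.gamma(neuron)
        period = deterministic_eif_period([mu], neuron, cfg.synapses,
                                          cfg.V_lb)
        assert r_cs == pytest.approx(1.0 / period, rel=0.02)


class TestDiagnostics:
    def test_validity_warning_below_criterion(self, cfg_ampa):
        with pytest.warns(RuntimeWarning, match="CV"):
            run_cspdm(cfg_ampa, [pr.constant("ampa", 0.1)], T=0.01)

    def test_no_warning_inside_validity(self, cfg_ampa, recwarn):
        run_cspdm(cfg_ampa, [pr.constant("ampa", 1.2)], T=0.01)
        assert not [w for w in recwarn if "CV" in str(w.message)]

    def test_density_snapshot_integrates_to_mass(self, cfg_ampa):
        res = run_cspdm(cfg_ampa, [pr.constant("ampa", 1.0)], T=0.4,
                        snapshot_times=[0.4])
        v = np.linspace(cfg_ampa.V_lb, cfg_ampa.neuron.V_c, 4001)
        m = np.trapezoid(res.density(0.4, v), v)
        assert m == pytest.approx(res.mass[-1], rel=1e-3)

    def test_mean_voltage_of_uniform_density(self, cfg_ampa):
        g = VoltageGrid.build(cfg_ampa, 50)
        x = np.full(100, 1.0 / (g.edges[-1] - g.edges[0]))
        assert mean_voltage(x, g) \
            == pytest.approx(0.5 * (g.edges[0] + g.edges[-1]))
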