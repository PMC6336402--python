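import numpy as np
import pytest
from scipy.stats import kstest

from popdens import protocols as pr
from popdens.core import PopulationConfig, facilitating_synapse
from popdens.mcs import (empirical_densities, population_rate, run_mcs,
                         stp_synapse_update)
from popdens.moments import stp_fixed_point

from oracles import ShotNoiseLaw


class TestPopulationRate:
    def test_counts(self):
        t, r = population_rate(np.array([0.0005, 0.0006, 0.0015]), N=100,
                               T=0.002)
        assert np.allclose(r, [2 / (100 * 1e-3), 1 / (100 * 1e-3)])

    def test_bad_bin(self):
        with pytest.raises(ValueError):
            population_rate(np.array([0.1]), 10, 1.0, bin=0.0)


class TestReproducibility:
    def test_same_seed_same_spikes(self, cfg_small):
        p = pr.constant("ampa", 1.2)
        a = run_mcs(cfg_small, [p], T=0.5, seed=11)
        b = run_mcs(cfg_small, [p], T=0.5, seed=11)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)

    def test_different_seed_differs(self, cfg_small):
        p = pr.constant("ampa", 1.2)
        a = run_mcs(cfg_small, [p], T=0.5, seed=11)
        b = run_mcs(cfg_small, [p], T=0.5, seed=12)
        assert not np.array_equal(a.spike_times, b.spike_times)


class TestDynamics:
    def test_refractory_period_enforced(self, cfg_small):
        p = pr.constant("ampa", 1.5)
        res = run_mcs(cfg_small, [p], T=1.0, seed=2)
        for n in np.unique(res.spike_neurons):
            t = np.sort(res.spike_times[res.spike_neurons == n])
            if len(t) > 1:
                assert np.min(np.diff(t)) >= cfg_small.neuron.tau_ref - 1e-9

    def test_nearly_silent_below_threshold_drive(self, cfg_small):
        # nu = 0.3 normalized: deep subthreshold, only rare fluctuation spikes
        p = pr.constant("ampa", 0.3)
        res = run_mcs(cfg_small, [p], T=0.5, seed=3)
        assert len(res.spike_times) / (cfg_small.N * 0.5) < 0.1

    def test_snapshot_contents(self, cfg_small):
        p = pr.constant("ampa", 1.0)
        res = run_mcs(cfg_small, [p], T=0.2, seed=4, snapshot_times=[0.2])
        snap = res.snapshots[0.2]
        assert snap["V"].shape == (cfg_small.N,)
        assert snap["g"]["ampa"].min() >= 0.0
        assert np.all(snap["V"] <= cfg_small.neuron.V_c + 1e-12)

    def test_missing_protocol_rejected(self, cfg_small):
        with pytest.raises(ValueError):
            run_mcs(cfg_small, [pr.constant("nmda", 1.0)], T=0.1)


class TestConductanceLaw:
    def test_stationary_g_matches_shotnoise_oracle(self, cfg_ampa):
        """Criterion: stationary MCS g-distribution vs oracle, KS < 0.02."""
        p = pr.constant("ampa", 1.0)
        res = run_mcs(cfg_ampa, [p], T=1.5, seed=20, snapshot_times=[1.5])
        g = res.snapshots[1.5]["g"]["ampa"]
        syn = cfg_ampa.synapses[0]
        lam = syn.c_s * float(pr.evaluate_rate(p, 0.0, cfg_ampa))
        law = ShotNoiseLaw.build(lam, syn.jump(cfg_ampa.neuron), syn.tau_s)
        stat = kstest(g, law.cdf).statistic
        assert stat < 0.02

    def test_empirical_density_normalization(self, cfg_small):
        p = pr.constant("ampa", 1.0)
        res = run_mcs(cfg_small, [p], T=0.5, seed=5, snapshot_times=[0.5])
        vb = np.linspace(cfg_small.V_lb, cfg_small.neuron.V_c, 101)
        g = res.snapshots[0.5]["g"]["ampa"]
        gb = np.linspace(0.0, g.max() * 1.01, 51)
        vd, gd = empirical_densities(res, 0.5, vb, {"ampa": gb})
        assert np.sum(gd["ampa"] * np.diff(gb)) == pytest.approx(1.0)
        frac = 1.0 - np.mean(res.snapshots[0.5]["refractory"])
        assert np.sum(vd * np.diff(vb)) == pytest.approx(frac, abs=0.02)


class TestSTP:
    def test_event_update_example(self):
        u, x, w = stp_synapse_update(0.05, 1.0, 0.05)
        assert float(u) == pytest.approx(0.0975)
        assert float(w) == pytest.approx(0.0975)
        assert float(x) == pytest.approx(0.9025)

    def test_event_update_x_first(self):
        u, x, w = stp_synapse_update(0.5, 0.8, 0.1, order="x_first")
        assert float(w) == pytest.approx(0.5 * 0.8)

    def test_unknown_order(self):
        with pytest.raises(ValueError):
            stp_synapse_update(0.5, 1.0, 0.1, order="nope")

    def test_ensemble_means_approach_fixed_point(self, neuron):
        cfg = PopulationConfig(neuron, (facilitating_synapse(c_s=50),), N=200)
        p = pr.constant("facil", 10.0, normalized=False)
        res = run_mcs(cfg, [p], T=3.0, seed=6, record_stp_every=50e-3)
        mu_u, mu_x = stp_fixed_point(10.0, 0.05, 0.7, 0.1)
        assert res.stp_means["facil"]["u"][-1] == pytest.approx(mu_u,
                                                                abs=0.02)
        # mean-field overestimates mu_x by ignoring u-x correlations; the
        # ensemble mean sits below the fixed point but in its vicinity
        assert res.stp_means["facil"]["x"][-1] == pytest.approx(mu_x,
                                                                abs=0.08)
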