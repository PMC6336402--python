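"""Ground-truth Monte Carlo simulation of the uncoupled EIF population.

Each of the N neurons integrates the EIF voltage equation by explicit
Euler; synaptic conductances decay exactly between events
(g -> g e^{-dt/tau_s}) and jump by Gamma_s/tau_s per presynaptic event.
Events are Poisson: for receptors without short-term plasticity the c_s
connections are pooled into one train of intensity c_s*nu_s(t) per neuron
(statistically identical, much faster); with STP enabled, per-synapse
(u, x) state is kept and events are drawn per connection.

The engine draws event counts per time step (a Poisson process observed at
resolution dt), which is distributionally equivalent to explicit event
times for dt well below tau_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import PopulationConfig, SynapseParams
from .protocols import RateProtocol, evaluate_rate

__all__ = ["MCSResult", "run_mcs", "population_rate", "empirical_densities",
           "stp_synapse_update"]

_EXP_CLIP = 30.0


def stp_synapse_update(u, x, U_s: float, order: str = "u_first"):
    """Apply one synaptic event to the Tsodyks-Markram pair (u, x).

    Returns ``(u_new, x_new, weight)`` where ``weight`` scales the
    conductance jump Gamma_s/tau_s of this event.  With the default
    facilitation-first convention the utilization increment precedes
    release: u_new = u + U_s (1 - u), weight = u_new * x,
    x_new = x (1 - u_new).  ``order='x_first'`` releases with the
    pre-increment u instead.
    """
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    u_new = u + U_s * (1.0 - u)
    if order == "u_first":
        w = u_new * x
    elif order == "x_first":
        w = u * x
    else:
        raise ValueError("order must be 'u_first' or 'x_first'")
    x_new = x - w
    return u_new, x_new, w


@dataclass
class MCSResult:
    """Output of one Monte Carlo run."""

    T: float
    dt: float
    N: int
    spike_neurons: np.ndarray          # neuron index per spike
    spike_times: np.ndarray            # spike time (s), strictly in (0, T]
    rate_times: np.ndarray             # 1-ms bin centers
    rates: np.ndarray                  # population rate r(t) (Hz)
    snapshots: dict = field(default_factory=dict)
    # snapshots[t] = {"V": (N,), "refractory": bool (N,), "g": {label: (N,)}}
    stp_times: Optional[np.ndarray] = None
    stp_means: dict = field(default_factory=dict)   # label -> {"u": arr, "x": arr}

    def raster(self) -> np.ndarray:
        """(n_spikes, 2) array of (neuron id, time)."""
        return np.column_stack([self.spike_neurons, self.spike_times])

    def save_raster(self, path) -> None:
        """Two-column CSV export: neuron_id, time_ms."""
        np.savetxt(path, np.column_stack([self.spike_neurons,
                                          self.spike_times * 1e3]),
                   fmt=["%d", "%.6f"], delimiter=",",
                   header="neuron_id,time_ms", comments="")


def population_rate(spike_times: np.ndarray, N: int, T: float,
                    bin: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Population rate r(t) = n_spikes(t, t+bin) / (N * bin) per bin (Hz)."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    nb = int(round(T / bin))
    counts, edges = np.histogram(spike_times, bins=nb, range=(0.0, nb * bin))
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts / (N * bin)


def run_mcs(cfg: PopulationConfig,
            protocols: Mapping[str, RateProtocol] | Sequence[RateProtocol],
            T: float, dt: float = 5e-5, seed: int = 0,
            snapshot_times: Sequence[float] = (),
            record_stp_every: Optional[float] = None,
            stp_order: str = "u_first") -> MCSResult:
    """Simulate the population for T seconds.

    ``protocols`` supplies one rate waveform per receptor label.  Snapshot
    times (s) record per-neuron voltage, refractory flags and conductances.
    ``record_stp_every`` records ensemble means of the per-synapse (u, x)
    at that interval for plastic receptors.
    """
    if isinstance(protocols, Mapping):
        proto = dict(protocols)
    else:
        proto = {p.receptor: p for p in protocols}
    for s in cfg.synapses:
        if s.label not in proto:
            raise ValueError(f"no protocol for receptor {s.label!r}")

    n = cfg.neuron
    N = cfg.N
    steps = int(round(T / dt))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # precompute absolute per-connection rate per step for each receptor
    tgrid = np.arange(steps) * dt
    rates = {s.label: np.asarray(evaluate_rate(proto[s.label], tgrid, cfg),
                                 dtype=float) * np.ones(steps)
             for s in cfg.synapses}

    V = np.full(N, n.E_l)
    clock = np.zeros(N)
    g = {s.label: np.zeros(N) for s in cfg.synapses}
    dec = {s.label: np.exp(-dt / s.tau_s) for s in cfg.synapses}
    jump = {s.label: s.jump(n) for s in cfg.synapses}

    stp_state = {}
    for s in cfg.synapses:
        if s.stp is not None:
            stp_state[s.label] = (np.full((N, s.c_s), s.stp.U_s),
                                  np.ones((N, s.c_s)))

    snap_steps = {int(round(t / dt)): t for t in snapshot_times}
    snapshots: dict = {}
    stp_rec_every = (int(round(record_stp_every / dt))
                     if record_stp_every else None)
    stp_t, stp_means = [], {lab: {"u": [], "x": []} for lab in stp_state}

    sp_id: list[np.ndarray] = []
    sp_t: list[np.ndarray] = []

    for i in range(steps):
        t_next = (i + 1) * dt
        # synaptic conductances: exact decay + Poisson arrivals
        for s in cfg.synapses:
            lab = s.label
            gl_ = g[lab]
            gl_ *= dec[lab]
            nu = rates[lab][i]
            if s.stp is None:
                if nu > 0:
                    k = rng.poisson(s.c_s * nu * dt, N)
                    gl_ += jump[lab] * k
            else:
                u, x = stp_state[lab]
                # relaxation of u toward U_s and x toward 1 (exact)
                ef = np.exp(-dt / s.stp.tau_f)
                er = np.exp(-dt / s.stp.tau_r)
                u += (s.stp.U_s - u) * (1.0 - ef)
                x += (1.0 - x) * (1.0 - er)
                if nu > 0:
                    k = rng.poisson(nu * dt, (N, s.c_s))
                    w_tot = np.zeros(N)
                    while True:
                        m = k > 0
                        if not m.any():
                            break
                        un, xn, w = stp_synapse_update(u[m], x[m], s.stp.U_s,
                                                       stp_order)
                        u[m] = un
                        x[m] = xn
                        rows = np.nonzero(m)[0]
                        np.add.at(w_tot, rows, w)
                        k = np.where(m, k - 1, k)
                    gl_ += jump[lab] * w_tot

        # voltage update (explicit Euler), refractory clamp
        ref = clock > 0.0
        arg = np.minimum((V - n.V_T) / n.kappa, _EXP_CLIP)
        rhs = -n.g_l * (V - n.E_l) + n.g_l * n.kappa * np.exp(arg)
        for s in cfg.synapses:
            rhs -= g[s.label] * (V - s.E_s)
        if not np.all(np.isfinite(rhs)):
            raise FloatingPointError(
                "voltage update overflowed; reduce dt (the EIF upstroke is "
                "steep near V_c)")
        V = np.where(ref, n.V_r, V + dt / n.C * rhs)
        clock = np.maximum(clock - dt, 0.0)

        spk = V >= n.V_c
        if spk.any():
            ids = np.nonzero(spk)[0]
            sp_id.append(ids)
            sp_t.append(np.full(ids.size, t_next))
            V[spk] = n.V_r
            clock[spk] = n.tau_ref

        if i + 1 in snap_steps:
            snapshots[snap_steps[i + 1]] = {
                "V": V.copy(),
                "refractory": clock > 0.0,
                "g": {lab: arr.copy() for lab, arr in g.items()},
            }
        if stp_rec_every and (i + 1) % stp_rec_every == 0:
            stp_t.append(t_next)
            for lab, (u, x) in stp_state.items():
                stp_means[lab]["u"].append(float(u.mean()))
                stp_means[lab]["x"].append(float(x.mean()))

    spike_neurons = (np.concatenate(sp_id) if sp_id else np.empty(0, dtype=int))
    spike_times = (np.concatenate(sp_t) if sp_t else np.empty(0))
    rt, r = population_rate(spike_times, N, T)
    return MCSResult(
        T=T, dt=dt, N=N, spike_neurons=spike_neurons, spike_times=spike_times,
        rate_times=rt, rates=r, snapshots=snapshots,
        stp_times=np.asarray(stp_t) if stp_t else None,
        stp_means={lab: {"u": np.asarray(d["u"]), "x": np.asarray(d["x"])}
                   for lab, d in stp_means.items()},
    )


def empirical_densities(result: MCSResult, t: float, v_bins: np.ndarray,
                        g_bins: Mapping[str, np.ndarray],
                        exclude_refractory: bool = True):
    """Histogram densities from a stored snapshot.

    Returns ``(v_density, g_densities)``: the voltage histogram integrates
    to the fraction of non-refractory neurons (refractory neurons are
    clamped at V_r and excluded by default); each conductance histogram
    integrates to 1.
    """
    if t not in result.snapshots:
        raise KeyError(f"no snapshot stored at t={t}")
    snap = result.snapshots[t]
    V = snap["V"]
    if exclude_refractory:
        V = V[~snap["refractory"]]
    cnt, _ = np.histogram(V, bins=v_bins)
    wv = np.diff(v_bins)
    v_density = cnt / (result.N * wv)
    g_densities = {}
    for lab, bins in g_bins.items():
        cg, _ = np.histogram(snap["g"][lab], bins=bins)
        g_densities[lab] = cg / (len(snap["g"][lab]) * np.diff(bins))
    return v_density, g_densities


def pooled_snapshot_histogram(result: MCSResult, times: Sequence[float],
                              bins: np.ndarray, what: str = "V",
                              label: Optional[str] = None,
                              exclude_refractory: bool = True
                              ) -> np.ndarray:
    """Histogram density pooled over several stationary snapshots.

    For ``what='V'`` the density is normalized by the total neuron count so
    it integrates to the average non-refractory fraction; for ``what='g'``
    it integrates to 1.
    """
    vals, ntot = [], 0
    for t in times:
        snap = result.snapshots[t]
        if what == "V":
            v = snap["V"]
            if exclude_refractory:
                v = v[~snap["refractory"]]
            vals.append(v)
            ntot += result.N
        else:
            vals.append(snap["g"][label])
            ntot += len(snap["g"][label])
    allv = np.concatenate(vals)
    cnt, _ = np.histogram(allv, bins=bins)
    return cnt / (ntot * np.diff(bins))
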