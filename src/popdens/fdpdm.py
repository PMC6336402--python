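"""Full-dimensional population density reference for one receptor type.

Tracks the joint density rho(V, g, t) of voltage and the single synaptic
conductance on a 2-D tensor mesh: conservative finite-volume transport,
upwind in V by the sign of F_V(V, g), decay advection in g plus the
nonlocal shot-noise jump term, zero flux at V_lb, g=0 and the top of the
g-domain, and re-injection of the V_c outflow at V_r (per g-slice) after
the refractory period.  The joint equation scales badly with the number of
receptor types; it is implemented for m=1 only, as the accuracy reference
for the colored-synapse solver.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import PopulationConfig, drift_fv
from .mmfm import _cell_slopes, _g_edge_flux
from .moments import steady_conductance_moments
from .protocols import RateProtocol, evaluate_rate

__all__ = ["JointDensityState", "run_fdpdm", "firing_rate_fd",
           "step_joint_density"]


@dataclass
class JointDensityState:
    """Cell-averaged joint density on the (V, g) tensor mesh."""

    v_edges: np.ndarray         # (Mv+1,)
    g_edges: np.ndarray         # (Mg+1,)
    rho: np.ndarray             # (Mv, Mg)
    queue: collections.deque = None   # FIFO of per-slice outgoing fluxes
    ir: int = 0                 # voltage cell index receiving re-injection

    @property
    def dv(self) -> float:
        return float(self.v_edges[1] - self.v_edges[0])

    @property
    def dg(self) -> float:
        return float(self.g_edges[1] - self.g_edges[0])

    def mass(self) -> float:
        return float(self.rho.sum() * self.dv * self.dg)

    def queued_mass(self, dt: float) -> float:
        if not self.queue:
            return 0.0
        return float(sum(f.sum() * self.dg for f in self.queue) * dt)

    def v_marginal(self) -> np.ndarray:
        """Density over V (integrates to the non-refractory mass)."""
        return self.rho.sum(axis=1) * self.dg

    def g_marginal(self) -> np.ndarray:
        """Density over g (normalized to the non-refractory mass)."""
        return self.rho.sum(axis=0) * self.dv


def _initial_state(cfg: PopulationConfig, nu_peak: float, Mv: int, Mg: int,
                   dt: float, headroom: float = 10.0) -> JointDensityState:
    syn = cfg.synapses[0]
    mu, sig = steady_conductance_moments(max(nu_peak, 1e-3), syn, cfg.neuron)
    g_max = max(mu + headroom * sig, 5.0 * syn.jump(cfg.neuron))
    v_edges = np.linspace(cfg.V_lb, cfg.neuron.V_c, Mv + 1)
    g_edges = np.linspace(0.0, g_max, Mg + 1)
    rho = np.zeros((Mv, Mg))
    # start concentrated at (E_l, 0)
    iv = np.searchsorted(v_edges, cfg.neuron.E_l, side="right") - 1
    iv = min(max(iv, 0), Mv - 1)
    rho[iv, 0] = 1.0 / ((v_edges[1] - v_edges[0]) * (g_edges[1] - g_edges[0]))
    nref = int(round(cfg.neuron.tau_ref / dt))
    queue = collections.deque([np.zeros(Mg) for _ in range(nref)],
                              maxlen=max(nref, 1))
    ir = np.searchsorted(v_edges, cfg.neuron.V_r, side="right") - 1
    ir = min(max(ir, 0), Mv - 1)
    return JointDensityState(v_edges=v_edges, g_edges=g_edges, rho=rho,
                             queue=queue, ir=ir)


def step_joint_density(state: JointDensityState, nu: float,
                       cfg: PopulationConfig, dt: float,
                       fv_edges: Optional[np.ndarray] = None
                       ) -> tuple[JointDensityState, float]:
    """One explicit conservative step; returns (new state, firing rate).

    ``fv_edges`` may carry the precomputed F_V(v_edge, g_center) table
    (it does not change between steps at fixed parameters).
    """
    if cfg.m != 1:
        raise NotImplementedError("the joint-density reference supports m=1")
    syn = cfg.synapses[0]
    rho = state.rho
    Mv, Mg = rho.shape
    dv, dg = state.dv, state.dg

    if fv_edges is None:
        gc = 0.5 * (state.g_edges[:-1] + state.g_edges[1:])
        fv_edges = np.empty((Mv + 1, Mg))
        for j, g in enumerate(gc):
            fv_edges[:, j] = drift_fv(state.v_edges, [g], cfg)
    cfl = float(np.max(np.abs(fv_edges))) * dt / dv
    if cfl > 1.0:
        raise ValueError(f"CFL violation ({cfl:.2f}); reduce dt below "
                         f"{dv / np.max(np.abs(fv_edges)):.2e}")
    g_bound = dg * cfg.synapses[0].tau_s / state.g_edges[-1]
    if dt > g_bound:
        raise ValueError(f"dt={dt} violates the conductance-decay stability "
                         f"bound {g_bound:.3e}")

    # voltage fluxes at interior edges: upwind by the sign of F_V with
    # minmod-limited linear reconstruction along V (second order)
    sv = np.zeros_like(rho)
    dmv = np.diff(rho, axis=0) / dv
    sv[1:-1] = np.where(np.sign(dmv[:-1]) == np.sign(dmv[1:]),
                        np.sign(dmv[:-1]) * np.minimum(np.abs(dmv[:-1]),
                                                       np.abs(dmv[1:])), 0.0)
    Jv = np.zeros((Mv + 1, Mg))
    f = fv_edges[1:Mv]
    left = rho[:-1] + 0.5 * dv * sv[:-1]
    right = rho[1:] - 0.5 * dv * sv[1:]
    Jv[1:Mv] = np.where(f > 0, f * left, f * right)
    # top edge: outflow only (spiking); bottom edge: zero flux
    f_top = fv_edges[Mv]
    out_flux = np.where(f_top > 0, f_top * rho[-1], 0.0)   # per g-slice
    Jv[Mv] = out_flux

    # conductance fluxes, vectorized over voltage rows (decay + nonlocal jump)
    h = syn.jump(cfg.neuron)
    lam = syn.c_s * nu
    Jg = _g_edge_flux(rho, state.g_edges, syn.tau_s, lam, h)
    new = rho + dt / dg * (Jg[:, :-1] - Jg[:, 1:])
    new += dt / dv * (Jv[:-1] - Jv[1:])

    # refractory return at V_r, per g-slice
    nref = int(round(cfg.neuron.tau_ref / dt))
    if nref > 0:
        back = state.queue.popleft()
        state.queue.append(out_flux.copy())
    else:
        back = out_flux
    new[state.ir] += dt / dv * back

    rate = firing_rate_fd(out_flux, dg)
    return JointDensityState(v_edges=state.v_edges, g_edges=state.g_edges,
                             rho=new, queue=state.queue, ir=state.ir), rate


def firing_rate_fd(out_flux: np.ndarray, dg: float) -> float:
    """Firing rate: integral over g of the positive V_c boundary flux."""
    return float(np.sum(np.maximum(out_flux, 0.0)) * dg)


def run_fdpdm(cfg: PopulationConfig,
              protocols: Mapping[str, RateProtocol] | Sequence[RateProtocol],
              T: float, dt: Optional[float] = None, Mv: int = 100,
              Mg: int = 100, report_dt: float = 1e-3
              ) -> tuple[np.ndarray, np.ndarray, JointDensityState]:
    """Run the joint-density reference; returns (times, rates, final state).

    When ``dt`` is omitted, the largest stable explicit step is chosen from
    the voltage CFL bound and the conductance-decay bound (with a 10%
    margin), rounded down so that ``report_dt`` is an integer multiple.
    """
    if isinstance(protocols, Mapping):
        proto = dict(protocols)
    else:
        proto = {p.receptor: p for p in protocols}
    syn = cfg.synapses[0]
    p = proto[syn.label]
    tprobe = np.linspace(0.0, T, 2049)
    nu_peak = float(np.max(evaluate_rate(p, tprobe, cfg)))
    state = _initial_state(cfg, nu_peak, Mv, Mg, dt if dt else 1e-5)

    gc = 0.5 * (state.g_edges[:-1] + state.g_edges[1:])
    fv_edges = np.empty((Mv + 1, Mg))
    for j, g in enumerate(gc):
        fv_edges[:, j] = drift_fv(state.v_edges, [g], cfg)

    if dt is None:
        bound = min(state.dv / float(np.max(np.abs(fv_edges))),
                    state.dg * syn.tau_s / state.g_edges[-1])
        dt = report_dt / int(np.ceil(report_dt / (0.9 * bound)))
        state = _initial_state(cfg, nu_peak, Mv, Mg, dt)

    steps = int(round(T / dt))
    rep = max(1, int(round(report_dt / dt)))
    times, rates = [], []
    acc = 0.0
    for i in range(steps):
        nu = float(evaluate_rate(p, (i + 1) * dt, cfg))
        state, r = step_joint_density(state, nu, cfg, dt, fv_edges)
        acc += r
        if (i + 1) % rep == 0:
            times.append((i + 1) * dt)
            rates.append(acc / rep)
            acc = 0.0
    return np.asarray(times), np.asarray(rates), state
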