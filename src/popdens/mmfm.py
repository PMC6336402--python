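"""Modified mean-field baseline.

This dimension-reduction baseline treats the conductance vector as a
deterministic parameter of the voltage equation: a steady-state rate
surface

    rbar(g) = 0                                   if F_V(V_T, g) <= 0
            = 1 / (tau_ref + int_{V_lb}^{V_c} dV / F_V(V, g))   otherwise

is precomputed, the marginal conductance densities rho_s(g_s, t) are
evolved by their 1-D master equations (decay advection toward 0 plus the
nonlocal jump term of the shot-noise input), and the population rate is
the expectation of rbar over the product of marginals.  The method is
kept faithful to its published form, including its documented
overestimation of fluctuation-driven rates at short synaptic time
constants; it is a baseline, not a method to be improved here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .core import PopulationConfig, SynapseParams, drift_fv
from .moments import steady_conductance_moments
from .protocols import RateProtocol, evaluate_rate

__all__ = ["ConductanceDensityState", "RateSurface", "mean_field_rate",
           "step_conductance_density", "expected_rate", "run_mmfm"]


def mean_field_rate(g, cfg: PopulationConfig, quad_tol: float = 1e-8) -> float:
    """Deterministic steady-state firing rate (Hz) at fixed conductances.

    Returns 0 when the drift at threshold is non-positive.  The corner
    case where F_V(V_T) > 0 but F_V vanishes elsewhere on (V_lb, V_c)
    makes the transit integral divergent: no sustained firing, 0 is
    returned.
    """
    n = cfg.neuron
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if float(drift_fv(n.V_T, g, cfg)) <= 0.0:
        return 0.0
    vgrid = np.linspace(cfg.V_lb, n.V_c, 801)
    fv = drift_fv(vgrid, g, cfg)
    if np.any(fv <= 0.0):
        return 0.0
    integral, _ = quad(lambda v: 1.0 / float(drift_fv(v, g, cfg)),
                       cfg.V_lb, n.V_c, epsabs=quad_tol, epsrel=1e-8,
                       limit=200)
    return 1.0 / (n.tau_ref + integral)


@dataclass
class RateSurface:
    """Precomputed rbar on a tensor grid of conductances (linear interp)."""

    grids: tuple[np.ndarray, ...]     # one grid per receptor
    values: np.ndarray                # rbar, shape = tuple(len(grid) ...)

    @classmethod
    def build(cls, cfg: PopulationConfig, g_max: Sequence[float],
              n_points: int = 200) -> "RateSurface":
        grids = tuple(np.linspace(0.0, gm, n_points) for gm in g_max)
        shape = tuple(len(gr) for gr in grids)
        vals = np.empty(shape)
        for idx in itertools.product(*(range(s) for s in shape)):
            g = np.array([gr[i] for gr, i in zip(grids, idx)])
            vals[idx] = mean_field_rate(g, cfg)
        return cls(grids=grids, values=vals)


def _interp_on_grid(grid: np.ndarray, x: np.ndarray):
    """Linear interpolation weights: (lower index, fraction)."""
    i = np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2)
    f = np.clip((x - grid[i]) / (grid[i + 1] - grid[i]), 0.0, 1.0)
    return i, f


@dataclass
class ConductanceDensityState:
    """Finite-volume marginal conductance density for one receptor."""

    edges: np.ndarray     # (Mg+1,) cell edges on [0, g_max]
    rho: np.ndarray       # (Mg,) cell-average density, integrates to 1

    @classmethod
    def initial(cls, syn: SynapseParams, neuron, nu_peak: float,
                Mg: int = 300, headroom: float = 10.0
                ) -> "ConductanceDensityState":
        """All-mass-at-zero start on a domain sized mu + headroom*sigma of
        the peak anticipated drive."""
        mu, sig = steady_conductance_moments(nu_peak, syn, neuron)
        g_max = max(mu + headroom * sig, 5.0 * syn.jump(neuron))
        edges = np.linspace(0.0, g_max, Mg + 1)
        rho = np.zeros(Mg)
        rho[0] = 1.0 / (edges[1] - edges[0])
        return cls(edges=edges, rho=rho)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mass(self) -> float:
        return float(np.sum(self.rho) * (self.edges[1] - self.edges[0]))

    def mean(self) -> float:
        return float(np.sum(self.rho * self.centers)
                     * (self.edges[1] - self.edges[0]))


def _minmod2(a, b):
    return np.where(np.sign(a) == np.sign(b),
                    np.sign(a) * np.minimum(np.abs(a), np.abs(b)), 0.0)


def _cell_slopes(rho: np.ndarray, d: float) -> np.ndarray:
    """Minmod-limited linear-reconstruction slopes along the last axis."""
    s = np.zeros_like(rho)
    dm = np.diff(rho, axis=-1) / d
    s[..., 1:-1] = _minmod2(dm[..., :-1], dm[..., 1:])
    return s


def _g_edge_flux(rho: np.ndarray, edges: np.ndarray, tau: float,
                 lam: float, h: float) -> np.ndarray:
    """Edge fluxes of the 1-D conductance master equation.

    J(g) = -(g/tau) rho_upwind + lam * int_{g-h}^{g} rho dg'.  The decay
    advection points toward g=0 so the upwind trace is the right-hand
    cell's; both terms use a minmod-limited linear reconstruction of the
    cell averages (second order).  When the jump spans at least one cell
    the nonlocal term integrates the reconstruction exactly; for jumps
    much smaller than a cell (slow synapses) the integral is evaluated by
    its midpoint, h * rho(g - h/2), exact for the linear reconstruction
    within one cell.  Fluxes at both domain ends are zero.  ``rho`` may
    carry leading batch axes (the joint solver's voltage rows).
    """
    dg = edges[1] - edges[0]
    n = rho.shape[-1]
    s = _cell_slopes(rho, dg)
    ge = edges[1:-1]
    upw = rho[..., 1:] - 0.5 * dg * s[..., 1:]   # right-cell trace at edge
    J = np.zeros(rho.shape[:-1] + (n + 1,))

    if h >= dg:
        # cumulative mass at edges (reconstruction preserves cell masses)
        cum = np.concatenate(
            [np.zeros(rho.shape[:-1] + (1,)), np.cumsum(rho, axis=-1) * dg],
            axis=-1)

        def cum_at(x):
            x = np.clip(x, 0.0, edges[-1])
            i = np.clip((x / dg).astype(int), 0, n - 1)
            u = x - edges[i]
            return (cum[..., i] + rho[..., i] * u
                    + s[..., i] * (0.5 * u * u - 0.5 * dg * u))

        jump = cum_at(ge) - cum_at(ge - h)
    else:
        x = np.maximum(ge - 0.5 * h, 0.0)
        i = np.clip((x / dg).astype(int), 0, n - 1)
        u = x - edges[i]
        jump = h * np.maximum(rho[..., i] + s[..., i] * (u - 0.5 * dg), 0.0)
    J[..., 1:-1] = -ge / tau * upw + lam * jump
    return J


def step_conductance_density(state: ConductanceDensityState, nu: float,
                             syn: SynapseParams, neuron, dt: float
                             ) -> ConductanceDensityState:
    """One conservative explicit step of the conductance master equation.

    Raises if dt violates the advective stability bound or if more than
    1e-6 of mass has reached the top of the domain (the truncation
    boundary is then too low).
    """
    edges = state.edges
    dg = edges[1] - edges[0]
    h = syn.jump(neuron)
    if dt > 0.9 * dg * syn.tau_s / edges[-1]:
        raise ValueError(f"dt={dt} violates the advective stability bound "
                         f"{dg * syn.tau_s / edges[-1]:.3e}")
    if state.rho[-1] * dg > 1e-6:
        raise ValueError("probability mass reached the upper conductance "
                         "boundary; enlarge the domain")
    J = _g_edge_flux(state.rho, edges, syn.tau_s, syn.c_s * nu, h)
    rho = state.rho + dt / dg * (J[:-1] - J[1:])
    return ConductanceDensityState(edges=edges, rho=rho)


def expected_rate(densities: Sequence[ConductanceDensityState],
                  surface: RateSurface) -> float:
    """Expectation of rbar over the product of conductance marginals."""
    m = len(densities)
    if m != len(surface.grids):
        raise ValueError("surface dimensionality mismatch")
    # interpolate rbar onto each marginal's cell centers, one axis at a time
    vals = surface.values
    for ax in range(m):
        grid = surface.grids[ax]
        x = densities[ax].centers
        if x[-1] > grid[-1] + 1e-12:
            raise ValueError("density support escapes the rate surface")
        i, f = _interp_on_grid(grid, x)
        vals = np.moveaxis(vals, ax, 0)
        vals = vals[i] * (1 - f)[(...,) + (None,) * (vals.ndim - 1)] \
            + vals[i + 1] * f[(...,) + (None,) * (vals.ndim - 1)]
        vals = np.moveaxis(vals, 0, ax)
    out = vals
    for ax in reversed(range(m)):
        d = densities[ax]
        dg = d.edges[1] - d.edges[0]
        out = np.tensordot(out, d.rho * dg, axes=([ax], [0]))
    return float(out)


def run_mmfm(cfg: PopulationConfig,
             protocols: Mapping[str, RateProtocol] | Sequence[RateProtocol],
             T: float, report_dt: float = 1e-3,
             Mg: int = 300, surface_points: int = 200,
             surface: Optional[RateSurface] = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Evolve the conductance marginals and report the expected rate.

    Returns ``(times, rates)`` sampled every ``report_dt``.  The rate
    surface is precomputed once (or supplied) over a domain covering the
    peak protocol drive.
    """
    if isinstance(protocols, Mapping):
        proto = dict(protocols)
    else:
        proto = {p.receptor: p for p in protocols}
    tprobe = np.linspace(0.0, T, 2049)
    nu_peak = {s.label: float(np.max(evaluate_rate(proto[s.label], tprobe, cfg)))
               for s in cfg.synapses}
    states = [ConductanceDensityState.initial(s, cfg.neuron,
                                              max(nu_peak[s.label], 1e-3), Mg)
              for s in cfg.synapses]
    if surface is None:
        surface = RateSurface.build(cfg, [st.edges[-1] for st in states],
                                    surface_points)

    # sub-stepping under the tightest advective bound among receptors
    dt = min(0.5 * (st.edges[1] - st.edges[0]) * s.tau_s / st.edges[-1]
             for s, st in zip(cfg.synapses, states))
    nrep = int(round(T / report_dt))
    sub = max(1, int(np.ceil(report_dt / dt)))
    dt = report_dt / sub
    times = np.empty(nrep)
    rates = np.empty(nrep)
    t = 0.0
    for i in range(nrep):
        for _ in range(sub):
            t += dt
            for j, s in enumerate(cfg.synapses):
                nu = float(evaluate_rate(proto[s.label], min(t, T), cfg))
                states[j] = step_conductance_density(states[j], nu, s,
                                                     cfg.neuron, dt)
        times[i] = t
        rates[i] = expected_rate(states, surface)
    return times, rates
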