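"""Colored-synapse population density solver.

In the diffusion limit each synaptic conductance acts on the voltage as an
exponentially correlated (colored) Gaussian process with mean mu_gs and
standard deviation sigma_gs.  The voltage density rho_V(V, t) then obeys a
1-D quasi-Fokker-Planck equation

    d rho_V/dt = -d/dV [ H0(V, mu_g) rho_V - D(V, sigma_g) d rho_V/dV ]

whose diffusion coefficient carries the colored-noise rescale factor

    D(V) = sum_s [sigma_gs (E_s - V)/C]^2 * tau_s tau_eff / (tau_s + tau_eff),
    tau_eff = C / (g_l - g_l e^{(<V> - V_T)/kappa} + sum_s mu_gs),

so only the m pairs of conductance moment ODEs (plus 2m STP mean ODEs)
ride along, independent of how many synaptic state variables the
underlying network model has.

The PDE is solved by a local (discontinuous) Galerkin scheme with linear
shape functions: each cell carries two trace unknowns, an auxiliary
gradient variable carries the diffusion term, numerical fluxes are upwind
in the drift and alternating (right-trace density / left-trace gradient)
in the diffusion, time stepping is backward Euler with coefficients lagged
one step, and a minmod slope limiter plus a zero floor keeps the density
non-negative.  Boundary flux leaving at V_c is queued for tau_ref and
re-injected at the V_r edge.
"""

from __future__ import annotations

import collections
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .core import PopulationConfig, drift_h0
from .moments import (MomentState, init_moment_state, step_conductance_moments,
                      step_stp_means, conductance_cv)
from .protocols import RateProtocol, evaluate_rate

__all__ = ["VoltageGrid", "CsPdmResult", "tau_eff", "diffusion_coeff",
           "apply_slope_limiter", "minmod", "run_cspdm", "CsPdmSolver"]

TAU_EFF_MIN = 1e-4   # s; lower clamp of the effective membrane time constant
TAU_EFF_MAX = 1.0    # s; upper clamp when the denominator crosses zero


@dataclass(frozen=True)
class VoltageGrid:
    """Uniform mesh on [V_lb, V_c] whose edges hit V_r and every interior E_s."""

    edges: np.ndarray      # (M+1,) cell edges
    ir: int                # edge index of the reset voltage V_r

    @property
    def M(self) -> int:
        return len(self.edges) - 1

    @property
    def L(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @classmethod
    def build(cls, cfg: PopulationConfig, M: int = 200) -> "VoltageGrid":
        v_lb, v_c = cfg.V_lb, cfg.neuron.V_c
        if M < 4:
            raise ValueError("need at least 4 voltage cells")
        edges = np.linspace(v_lb, v_c, M + 1)
        L = edges[1] - edges[0]
        # the re-injection point is snapped to the nearest edge; at the
        # default mesh width (~0.3 mV) this displaces V_r by < L/2
        ir = int(round((cfg.neuron.V_r - v_lb) / L))
        ir = min(max(ir, 0), M)
        return cls(edges=edges, ir=ir)


def tau_eff(mean_V: float, mu_g, neuron) -> float:
    """Effective membrane time constant (s), clamped to [0.1 ms, 1 s].

    tau_eff = C / (g_l - g_l e^{(<V> - V_T)/kappa} + sum_s mu_gs).  Near
    threshold the denominator crosses zero; the clamp keeps the colored-
    noise rescale factor tau_s tau_eff/(tau_s + tau_eff) bounded by tau_s,
    its correct large-tau_eff limit.
    """
    denom = (neuron.g_l - neuron.g_l
             * np.exp(min((mean_V - neuron.V_T) / neuron.kappa, 30.0))
             + float(np.sum(mu_g)))
    if denom <= neuron.C / TAU_EFF_MAX:
        return TAU_EFF_MAX
    return float(np.clip(neuron.C / denom, TAU_EFF_MIN, TAU_EFF_MAX))


def diffusion_coeff(V, sigma_g, te: float, cfg: PopulationConfig):
    """Colored-noise diffusion coefficient D(V) (V^2/s)."""
    V = np.asarray(V, dtype=float)
    out = np.zeros_like(V)
    for s, sg in zip(cfg.synapses, np.atleast_1d(sigma_g)):
        resc = s.tau_s * te / (s.tau_s + te)
        out = out + (sg * (s.E_s - V) / cfg.neuron.C) ** 2 * resc
    return out


def minmod(a1, a2, a3):
    """Minmod of three slopes: s*min|a_i| when all signs agree, else 0."""
    a1, a2, a3 = np.broadcast_arrays(np.asarray(a1, float), a2, a3)
    s = np.sign(a1)
    agree = (s == np.sign(a2)) & (s == np.sign(a3)) & (s != 0)
    return np.where(agree, s * np.minimum(np.abs(a1),
                                          np.minimum(np.abs(a2), np.abs(a3))),
                    0.0)


def apply_slope_limiter(x: np.ndarray, floor: bool = True) -> np.ndarray:
    """Minmod-limit the per-cell traces, preserving cell averages.

    ``x`` holds (left trace, right trace) per cell, interleaved.  Each
    cell's traces are pulled toward its average rho_bar by the minmod of
    (own deviation, backward average difference, forward average
    difference); boundary cells are left unlimited (their one-sided
    differences are unavailable) and a zero floor removes any residual
    negative undershoot.
    """
    a = x[0::2].copy()
    b = x[1::2].copy()
    rbar = 0.5 * (a + b)
    dm = np.diff(rbar)          # rbar_k - rbar_{k-1} at k>=1
    inner = slice(1, len(rbar) - 1)
    a[inner] = rbar[inner] - minmod(rbar[inner] - a[inner], dm[:-1], dm[1:])
    b[inner] = rbar[inner] + minmod(b[inner] - rbar[inner], dm[:-1], dm[1:])
    out = np.empty_like(x)
    out[0::2] = a
    out[1::2] = b
    if floor:
        np.maximum(out, 0.0, out=out)
    return out


@dataclass
class CsPdmResult:
    """Time series and density snapshots from a colored-synapse run."""

    times: np.ndarray                  # step end times (s)
    rates: np.ndarray                  # firing rate r(t) (Hz)
    mean_v: np.ndarray                 # <V(t)> (V)
    mass: np.ndarray                   # integral of rho_V (excl. queued)
    moments: dict                      # label -> {"mu_g","sigma_g","mu_u","mu_x"}
    grid: VoltageGrid = None
    snapshots: dict = field(default_factory=dict)   # t -> trace vector (2M,)
    clamp_events: int = 0              # tau_eff clamps
    negative_rate_clips: int = 0

    def density(self, t: float, V) -> np.ndarray:
        """Evaluate the stored piecewise-linear density snapshot at V."""
        return evaluate_density(self.snapshots[t], self.grid, V)

    def save_series(self, path) -> None:
        cols = [self.times, self.rates, self.mean_v]
        hdr = "t_s,rate_hz,mean_v_V"
        for lab, d in self.moments.items():
            cols += [d["mu_g"], d["sigma_g"]]
            hdr += f",mu_g_{lab},sigma_g_{lab}"
            if "mu_u" in d:
                cols += [d["mu_u"], d["mu_x"]]
                hdr += f",mu_u_{lab},mu_x_{lab}"
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=hdr,
                   comments="")


def evaluate_density(x: np.ndarray, grid: VoltageGrid, V) -> np.ndarray:
    """Piecewise-linear evaluation of a trace vector at voltages V."""
    V = np.atleast_1d(np.asarray(V, dtype=float))
    out = np.zeros_like(V)
    k = np.clip(np.searchsorted(grid.edges, V, side="right") - 1, 0, grid.M - 1)
    vl = grid.edges[k]
    s = (V - vl) / grid.L
    inside = (V >= grid.edges[0]) & (V <= grid.edges[-1])
    out = np.where(inside, x[2 * k] * (1 - s) + x[2 * k + 1] * s, 0.0)
    return out


def cell_masses(x: np.ndarray, grid: VoltageGrid) -> np.ndarray:
    return 0.5 * grid.L * (x[0::2] + x[1::2])


def mean_voltage(x: np.ndarray, grid: VoltageGrid) -> float:
    """Exact integral of V * rho_V over the mesh (piecewise linear)."""
    vl = grid.edges[:-1]
    vr = grid.edges[1:]
    a = x[0::2]
    b = x[1::2]
    return float(np.sum(grid.L * (a * (2 * vl + vr) + b * (vl + 2 * vr)) / 6.0))


_G1 = 0.5 * (1.0 - 1.0 / np.sqrt(3.0))   # Gauss point offsets (fraction of L)
_G2 = 0.5 * (1.0 + 1.0 / np.sqrt(3.0))


class CsPdmSolver:
    """Stepper for the local-Galerkin discretization.

    One instance holds the grid and scratch arrays; :meth:`step` assembles
    the banded backward-Euler system for the current (lagged) coefficients
    and advances the trace vector.
    """

    def __init__(self, cfg: PopulationConfig, grid: Optional[VoltageGrid] = None,
                 M: int = 200):
        self.cfg = cfg
        self.grid = grid if grid is not None else VoltageGrid.build(cfg, M)
        g = self.grid
        self.gauss = np.stack([g.edges[:-1] + _G1 * g.L,
                               g.edges[:-1] + _G2 * g.L], axis=1)  # (M, 2)
        # shape-function values at the two Gauss points
        self.phi1 = np.array([1.0 - _G1, 1.0 - _G2])
        self.phi2 = np.array([_G1, _G2])
        self.wq = 0.5 * g.L   # Gauss weight

    def initial_state(self, center: Optional[float] = None,
                      width: float = 2e-3) -> np.ndarray:
        """Gaussian density projected onto the traces, unit mass."""
        g = self.grid
        c = self.cfg.neuron.E_l if center is None else center
        rho = np.exp(-0.5 * ((g.edges - c) / width) ** 2)
        x = np.empty(2 * g.M)
        x[0::2] = rho[:-1]
        x[1::2] = rho[1:]
        x /= cell_masses(x, g).sum()
        return x

    def step(self, x: np.ndarray, mu_g: np.ndarray, sigma_g: np.ndarray,
             mean_V: float, dt: float, reinjection: float = 0.0,
             instantaneous_reset: bool = False
             ) -> tuple[np.ndarray, float]:
        """One backward-Euler step; returns (new traces, firing rate)."""
        cfg, g = self.cfg, self.grid
        M, L = g.M, g.L
        te = tau_eff(mean_V, mu_g, cfg.neuron)

        H0_e = drift_h0(g.edges, mu_g, cfg)                 # (M+1,)
        D_e = diffusion_coeff(g.edges, sigma_g, te, cfg)    # (M+1,)
        H0_q = drift_h0(self.gauss, mu_g, cfg)              # (M, 2)
        D_q = diffusion_coeff(self.gauss, sigma_g, te, cfg)

        w = self.wq
        hA = w * (H0_q * self.phi1).sum(axis=1)   # (M,)
        hB = w * (H0_q * self.phi2).sum(axis=1)
        dA = w * (D_q * self.phi1).sum(axis=1)
        dB = w * (D_q * self.phi2).sum(axis=1)

        up = H0_e > 0.0
        L2 = L * L

        # operator A (xdot = (2/L) A x + src) as five diagonals
        n = 2 * M
        d0 = np.zeros(n)
        dm1 = np.zeros(n)   # entry (r, r-1) stored at index r
        dm2 = np.zeros(n)
        dp1 = np.zeros(n)   # entry (r, r+1) stored at index r
        dp2 = np.zeros(n)

        r1 = np.arange(0, n, 2)    # rows 2k
        r2 = r1 + 1                # rows 2k+1
        k = np.arange(M)

        # --- rows 2k (left-trace equation of cell k) ---
        # a_k column
        d0[r1] = -hA / L - dA / L2 - dB / L2
        d0[r1[1:]] += np.where(up[1:M], 0.0, H0_e[1:M]) - 2.0 * D_e[1:M] / L
        # b_k column
        dp1[r1] = -hB / L + dA / L2 - dB / L2
        # a_{k+1} column (absent for k = M-1)
        dp2[r1[:-1]] = 2.0 * dB[:-1] / L2
        # a_{k-1}, b_{k-1} columns (k >= 1)
        dm2[r1[1:]] = D_e[1:M] / L
        dm1[r1[1:]] = D_e[1:M] / L + np.where(up[1:M], H0_e[1:M], 0.0)

        # --- rows 2k+1 (right-trace equation of cell k) ---
        # a_k column
        dm1[r2] = hA / L + dA / L2 + dB / L2 - D_e[1:M + 1] / L
        # b_k column
        d0[r2] = hB / L - dA / L2 + dB / L2 - D_e[1:M + 1] / L \
            - np.where(up[1:M + 1], H0_e[1:M + 1], 0.0)
        # a_{k+1} column (k <= M-2)
        dp1[r2[:-1]] = (-2.0 * dB[:-1] / L2 + 2.0 * D_e[1:M] / L
                        - np.where(up[1:M], 0.0, H0_e[1:M]))

        # backward Euler: (I/dt - (2/L) A) x_new = x/dt + src
        c = 2.0 / L
        ab = np.zeros((5, n))
        ab[2, :] = 1.0 / dt - c * d0
        ab[1, 1:] = -c * dp1[:-1]
        ab[0, 2:] = -c * dp2[:-2]
        ab[3, :-1] = -c * dm1[1:]
        ab[4, :-2] = -c * dm2[2:]

        rhs = x / dt
        ir = g.ir
        if reinjection != 0.0:
            if ir <= M - 1:
                rhs[2 * ir] += c * reinjection
            if ir >= 1:
                rhs[2 * ir - 1] -= c * reinjection

        # coefficients of the firing rate in the boundary unknowns
        ra = D_e[M] / L                                   # on a_{M-1}
        rb = D_e[M] / L + (H0_e[M] if up[M] else 0.0)     # on b_{M-1}

        if instantaneous_reset:
            # tau_ref = 0: the outgoing flux re-enters at V_r within the
            # same implicit step, which couples the re-injection rows to
            # the boundary columns and breaks the band; solve sparse.
            from scipy.sparse import dia_matrix, lil_matrix
            from scipy.sparse.linalg import spsolve
            A = dia_matrix((ab, [2, 1, 0, -1, -2]), shape=(n, n)).tolil()
            if ir <= M - 1:
                A[2 * ir, n - 2] -= c * ra
                A[2 * ir, n - 1] -= c * rb
            if ir >= 1:
                A[2 * ir - 1, n - 2] += c * ra
                A[2 * ir - 1, n - 1] += c * rb
            x_new = spsolve(A.tocsr(), rhs)
        else:
            x_new = solve_banded((2, 2), ab, rhs)

        rate = ra * x_new[-2] + rb * x_new[-1]
        return x_new, float(rate)


def run_cspdm(cfg: PopulationConfig,
              protocols: Mapping[str, RateProtocol] | Sequence[RateProtocol],
              T: float, dt: float = 2e-4, M: int = 200,
              snapshot_times: Sequence[float] = (),
              mean_v_includes_refractory: bool = True,
              cross_stp_power: int = 1,
              validity_warning: bool = True) -> CsPdmResult:
    """Run the colored-synapse solver for T seconds.

    Per step: (1) advance the conductance moments (and STP means) by
    backward Euler at the end-of-step rate, (2) refresh tau_eff, drift and
    diffusion from the previous step's <V> and the new moments, (3) take
    one implicit density step with the re-injection rate popped from the
    refractory delay queue, (4) slope-limit and floor, (5) record.
    """
    if isinstance(protocols, Mapping):
        proto = dict(protocols)
    else:
        proto = {p.receptor: p for p in protocols}
    solver = CsPdmSolver(cfg, M=M)
    grid = solver.grid
    steps = int(round(T / dt))
    tend = (np.arange(steps) + 1) * dt

    nu = {s.label: np.asarray(evaluate_rate(proto[s.label], tend, cfg),
                              dtype=float) * np.ones(steps)
          for s in cfg.synapses}

    if validity_warning:
        for s in cfg.synapses:
            numin = nu[s.label].min()
            cv = conductance_cv(numin, s)
            if cv > 0.6:
                warnings.warn(
                    f"receptor {s.label!r}: predicted stationary conductance "
                    f"CV {cv:.2f} exceeds 0.6 at the lowest protocol rate; "
                    "the diffusion approximation may be inaccurate",
                    RuntimeWarning, stacklevel=2)

    mstate = {s.label: init_moment_state(s) for s in cfg.synapses}
    x = solver.initial_state()
    mv = mean_voltage(x, grid)

    nref = int(round(cfg.neuron.tau_ref / dt))
    queue = collections.deque([0.0] * nref, maxlen=max(nref, 1))

    rates = np.empty(steps)
    mean_v = np.empty(steps)
    mass = np.empty(steps)
    mom = {s.label: {"mu_g": np.empty(steps), "sigma_g": np.empty(steps),
                     **({"mu_u": np.empty(steps), "mu_x": np.empty(steps)}
                        if s.stp else {})}
           for s in cfg.synapses}
    snap_steps = {int(round(t / dt)): t for t in snapshot_times}
    snapshots: dict = {}
    neg_clips = 0

    for i in range(steps):
        mu_g = np.empty(cfg.m)
        sg = np.empty(cfg.m)
        for j, s in enumerate(cfg.synapses):
            st = mstate[s.label]
            if s.stp is not None:
                st = step_stp_means(st, nu[s.label][i], s, dt)
            st = step_conductance_moments(st, nu[s.label][i], s, cfg.neuron,
                                          dt, cross_stp_power)
            mstate[s.label] = st
            mu_g[j] = st.mu_g
            sg[j] = st.sigma_g

        reinj = queue.popleft() if nref > 0 else 0.0
        x, r = solver.step(x, mu_g, sg, mv, dt, reinjection=reinj,
                           instantaneous_reset=(nref == 0))
        if r < 0.0:
            r = 0.0
            neg_clips += 1
        if nref > 0:
            queue.append(r)
        x = apply_slope_limiter(x)

        m_tot = cell_masses(x, grid).sum()
        if m_tot < 0:
            raise RuntimeError("negative total probability mass")
        mv = mean_voltage(x, grid)
        if mean_v_includes_refractory:
            mv = mv + sum(queue) * dt * cfg.neuron.V_r

        rates[i] = r
        mean_v[i] = mv
        mass[i] = m_tot
        for s in cfg.synapses:
            st = mstate[s.label]
            mom[s.label]["mu_g"][i] = st.mu_g
            mom[s.label]["sigma_g"][i] = st.sigma_g
            if s.stp is not None:
                mom[s.label]["mu_u"][i] = st.mu_u
                mom[s.label]["mu_x"][i] = st.mu_x
        if i + 1 in snap_steps:
            snapshots[snap_steps[i + 1]] = x.copy()

    return CsPdmResult(times=tend, rates=rates, mean_v=mean_v, mass=mass,
                       moments=mom, grid=grid, snapshots=snapshots,
                       negative_rate_clips=neg_clips)
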