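"""Independent brute-force references used only by the test suite.

None of these reuse the library's engine code paths: the shot-noise law is
built from first-principles flux balance, the deterministic period comes
from scipy's initial-value solver on the raw membrane equation, and the
plasticity fixed points are closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class ShotNoiseLaw:
    """Exact stationary law of an exponentially filtered Poisson process.

    The conductance obeys dg/dt = -g/tau between events and jumps by ``h``
    at Poisson rate ``lam``.  At stationarity the leftward advective
    probability flux through any point g equals the rightward jump flux,

        (g / tau) f(g) = lam * (F(g) - F(g - h)),

    where F is the CDF.  On (0, h] this reduces to F' = (lam tau / g) F,
    i.e. F ~ g^(lam tau); subsequent panels ((k h, (k+1) h]) are integrated
    numerically with the previous panel's interpolant supplying F(g - h).
    The resulting cumulants are kappa_n = lam tau h^n / n (mean lam tau h,
    variance lam tau h^2 / 2).
    """

    lam: float
    h: float
    tau: float
    grid: np.ndarray
    F: np.ndarray     # normalized CDF on grid

    @classmethod
    def build(cls, lam: float, h: float, tau: float,
              points_per_panel: int = 4000) -> "ShotNoiseLaw":
        if min(lam, h, tau) <= 0:
            raise ValueError("lam, h and tau must be positive")
        a = lam * tau
        mean = a * h
        sd = h * math.sqrt(a / 2.0)
        K = max(3, int(math.ceil((mean + 12.0 * sd) / h)))
        m = points_per_panel
        grids, Fs = [], []
        # panel 0: exact power law (unnormalized), F(h) = 1
        g0 = np.linspace(0.0, h, m + 1)
        with np.errstate(divide="ignore"):
            F0 = (g0 / h) ** a
        grids.append(g0)
        Fs.append(F0)
        prev_g, prev_F = g0, F0
        for k in range(1, K):
            lo, hi = k * h, (k + 1) * h
            g = np.linspace(lo, hi, m + 1)
            dg = g[1] - g[0]
            F = np.empty(m + 1)
            F[0] = prev_F[-1]

            def rhs(x, y):
                fp = np.interp(x - h, prev_g, prev_F)
                return (a / x) * (y - fp)

            y = F[0]
            for i in range(m):             # classic RK4 across the panel
                x = g[i]
                k1 = rhs(x, y)
                k2 = rhs(x + 0.5 * dg, y + 0.5 * dg * k1)
                k3 = rhs(x + 0.5 * dg, y + 0.5 * dg * k2)
                k4 = rhs(x + dg, y + dg * k3)
                y = y + dg / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                F[i + 1] = y
            grids.append(g[1:])
            Fs.append(F[1:])
            prev_g, prev_F = g, F
        grid = np.concatenate(grids)
        F = np.concatenate(Fs)
        return cls(lam=lam, h=h, tau=tau, grid=grid, F=F / F[-1])

    def cdf(self, g):
        return np.interp(np.asarray(g, dtype=float), self.grid, self.F,
                         left=0.0, right=1.0)

    def pdf(self, g):
        """Density from the flux-balance identity (exact, no differencing)."""
        g = np.asarray(g, dtype=float)
        out = np.zeros_like(g)
        pos = g > 0
        out[pos] = (self.lam * self.tau / g[pos]
                    * (self.cdf(g[pos]) - self.cdf(g[pos] - self.h)))
        return out

    def mean(self) -> float:
        return self.lam * self.tau * self.h

    def var(self) -> float:
        return self.lam * self.tau * self.h ** 2 / 2.0


def shotnoise_stationary_density(rate: float, jump: float, tau: float
                                 ) -> ShotNoiseLaw:
    """Stationary law of the conductance under total event rate ``rate``
    (Hz), per-event jump ``jump`` (S) and decay time ``tau`` (s)."""
    return ShotNoiseLaw.build(rate, jump, tau)


def deterministic_eif_period(g_fixed, neuron, synapses, V_lb: float
                             ) -> float:
    """Interspike period of the noiseless EIF at frozen conductances.

    Integrates the raw membrane equation from ``V_lb`` to the cutting
    voltage with scipy's adaptive solver and adds the refractory period.
    Returns ``inf`` (non-firing) if the trajectory stalls.
    """
    g_fixed = np.atleast_1d(np.asarray(g_fixed, dtype=float))

    def dvdt(t, V):
        v = V[0]
        rhs = (-neuron.g_l * (v - neuron.E_l)
               + neuron.g_l * neuron.kappa
               * math.exp(min((v - neuron.V_T) / neuron.kappa, 30.0)))
        for s, g in zip(synapses, g_fixed):
            rhs -= g * (v - s.E_s)
        return [rhs / neuron.C]

    def crossed(t, V):
        return V[0] - neuron.V_c
    crossed.terminal = True
    crossed.direction = 1.0

    if dvdt(0.0, [V_lb])[0] <= 0.0:
        return math.inf
    sol = solve_ivp(dvdt, [0.0, 60.0], [V_lb], events=crossed,
                    rtol=1e-10, atol=1e-12, max_step=1e-3)
    if not sol.t_events[0].size:
        return math.inf
    return float(sol.t_events[0][0]) + neuron.tau_ref


def stp_fixed_points(nu: float, U_s: float, tau_f: float, tau_r: float
                     ) -> tuple[float, float]:
    """Stationary mean utilization and availability under constant rate."""
    if nu < 0:
        raise ValueError("nu must be non-negative")
    mu_u = U_s * (1.0 + nu * tau_f) / (1.0 + U_s * nu * tau_f)
    mu_x = 1.0 / (1.0 + mu_u * nu * tau_r)
    return mu_u, mu_x
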