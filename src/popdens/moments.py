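"""Moment closure for the synaptic conductances and STP mean fields.

For each receptor type the conductance obeys filtered-Poisson (shot-noise)
dynamics; its first two raw moments evolve as

    d mu_g /dt  = -mu_g/tau_s  + c_s nu(t) Gamma_s/tau_s
    d mu_g2/dt  = -2 mu_g2/tau_s + c_s nu(t) (2 Gamma_s mu_g/tau_s + Gamma_s^2/tau_s^2)

with sigma_g = sqrt(mu_g2 - mu_g^2).  With short-term plasticity the
effective event size is modulated: Gamma_s -> Gamma_s mu_u mu_x, and the
population means mu_u, mu_x follow the Tsodyks-Markram mean-field pair

    d mu_u/dt = (U_s - mu_u)/tau_f + nu(t) U_s (1 - mu_u)
    d mu_x/dt = (1 - mu_x)/tau_r   - nu(t) mu_x mu_u

(u and x treated as statistically independent; this closure inherits the
known overestimation of mu_x under strong depression).

All steps use backward Euler, which is unconditionally stable and exact at
the fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import NeuronParams, SynapseParams

__all__ = [
    "MomentState",
    "init_moment_state",
    "step_conductance_moments",
    "step_stp_means",
    "steady_conductance_moments",
    "stp_fixed_point",
    "conductance_cv",
]


@dataclass
class MomentState:
    """First two conductance moments and STP means for one receptor."""

    mu_g: float = 0.0     # mean conductance (S)
    mu_g2: float = 0.0    # second raw moment (S^2)
    mu_u: float = 1.0     # mean utilization (1 when STP disabled)
    mu_x: float = 1.0     # mean available fraction

    @property
    def sigma_g(self) -> float:
        var = self.mu_g2 - self.mu_g ** 2
        return np.sqrt(max(var, 0.0))


def init_moment_state(syn: SynapseParams) -> MomentState:
    if syn.stp is not None:
        return MomentState(mu_u=syn.stp.U_s, mu_x=1.0)
    return MomentState()


def _effective_gammas(syn: SynapseParams, neuron: NeuronParams,
                      state: MomentState, cross_stp_power: int = 1
                      ) -> tuple[float, float, float]:
    """(Gamma_eff for the mean eq, Gamma^2_eff, Gamma_cross for the 2nd-moment
    cross term), with STP modulation applied.

    ``cross_stp_power`` controls how many factors of (mu_u mu_x) the cross
    term 2 Gamma mu_g / tau carries (1 by consistent power counting; 2
    applies the squared substitution to every Gamma^2 occurrence wholesale).
    """
    g = syn.gamma(neuron)
    if syn.stp is None:
        return g, g * g, g
    w = state.mu_u * state.mu_x
    return g * w, (g * w) ** 2, g * w ** cross_stp_power


def step_conductance_moments(state: MomentState, nu: float, syn: SynapseParams,
                             neuron: NeuronParams, dt: float,
                             cross_stp_power: int = 1) -> MomentState:
    """One backward-Euler step of the two conductance-moment ODEs.

    ``nu`` is the absolute per-connection rate (Hz) at the *end* of the
    step (backward evaluation).  If the discrete variance ever turns
    negative it is clamped to zero (cannot occur for dt <= tau_s/10).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if nu < 0:
        raise ValueError("rate must be non-negative")
    tau = syn.tau_s
    g_eff, g2_eff, g_cross = _effective_gammas(syn, neuron, state, cross_stp_power)
    lam = syn.c_s * nu
    mu = (state.mu_g + dt * lam * g_eff / tau) / (1.0 + dt / tau)
    mu2 = (state.mu_g2 + dt * lam * (2.0 * g_cross * mu / tau + g2_eff / tau ** 2)) \
        / (1.0 + 2.0 * dt / tau)
    if mu2 < mu * mu:
        mu2 = mu * mu
    return replace(state, mu_g=mu, mu_g2=mu2)


def step_stp_means(state: MomentState, nu: float, syn: SynapseParams,
                   dt: float) -> MomentState:
    """One backward-Euler step of the STP mean-field pair (mu_u, mu_x)."""
    if syn.stp is None:
        raise ValueError(f"receptor {syn.label!r} has no STP parameters")
    p = syn.stp
    u = (state.mu_u + dt * (p.U_s / p.tau_f + nu * p.U_s)) \
        / (1.0 + dt / p.tau_f + dt * nu * p.U_s)
    x = (state.mu_x + dt / p.tau_r) / (1.0 + dt / p.tau_r + dt * nu * u)
    return replace(state, mu_u=u, mu_x=x)


def stp_fixed_point(nu: float, U_s: float, tau_f: float, tau_r: float
                    ) -> tuple[float, float]:
    """Stationary (mu_u, mu_x) of the STP mean-field pair at constant rate."""
    mu_u = U_s * (1.0 + nu * tau_f) / (1.0 + U_s * nu * tau_f)
    mu_x = 1.0 / (1.0 + mu_u * nu * tau_r)
    return mu_u, mu_x


def steady_conductance_moments(nu: float, syn: SynapseParams,
                               neuron: NeuronParams) -> tuple[float, float]:
    """Stationary (mu_g, sigma_g) at constant per-connection rate nu.

    Without STP: mu_g = c_s nu Gamma_s and sigma_g = Gamma_s sqrt(c_s nu /
    (2 tau_s)).  With STP the event size is scaled by the fixed point of
    (mu_u, mu_x).
    """
    g = syn.gamma(neuron)
    if syn.stp is not None:
        mu_u, mu_x = stp_fixed_point(nu, syn.stp.U_s, syn.stp.tau_f, syn.stp.tau_r)
        g = g * mu_u * mu_x
    lam = syn.c_s * nu
    mu = lam * g
    sigma = g * np.sqrt(lam / (2.0 * syn.tau_s))
    return mu, sigma


def conductance_cv(nu: float, syn: SynapseParams) -> float:
    """Stationary coefficient of variation sigma_g/mu_g = 1/sqrt(2 tau_s c_s nu).

    The diffusion approximation behind the colored-synapse solver is
    considered valid when this is at or below 0.6.
    """
    if nu <= 0:
        return np.inf
    return 1.0 / np.sqrt(2.0 * syn.tau_s * syn.c_s * nu)
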