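"""Parameter records and deterministic single-neuron force functions.

All quantities are stored in SI units (volts, seconds, siemens, farads).
Configuration files use the physiological units (mV, ms, mS, uF, Hz) and
are converted on load by :mod:`popdens.config`.

The neuron model is the exponential integrate-and-fire (EIF) neuron

    C dV/dt = -g_l (V - E_l) + g_l kappa exp((V - V_T)/kappa) + I_syn(V, t)

with a spike recorded when V reaches the cutting voltage ``V_c``, followed
by a reset to ``V_r`` and a clamp for a refractory period ``tau_ref``.
Synapses are conductance based: each presynaptic event makes g_s jump by
``Gamma_s / tau_s`` after which g_s decays exponentially with time
constant ``tau_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "STPParams",
    "SynapseParams",
    "PopulationConfig",
    "gamma_from_delta_v",
    "min_suprathreshold_rate",
    "drift_h0",
    "drift_fv",
    "default_neuron",
    "ampa_synapse",
    "gabaa_synapse",
    "gabab_synapse",
    "facilitating_synapse",
    "depressing_synapse",
]


def gamma_from_delta_v(delta_v: float, C: float, E_s: float, E_l: float) -> float:
    """Total conductance variation Gamma_s produced by a single event.

    ``delta_v`` is the instant voltage modulation (a positive magnitude, in
    volts): the depolarization/hyperpolarization a single event would cause
    if the membrane sat at ``E_l`` with instantaneous synaptic kinetics and
    no spike-initiation current.  The returned Gamma_s has units S*s; the
    conductance jump per event is ``Gamma_s / tau_s``.

    Raises
    ------
    ValueError
        If ``delta_v`` is not in ``(0, |E_s - E_l|)`` (the logarithm is
        undefined at or beyond the driving-force magnitude).
    """
    dff = abs(E_s - E_l)
    if not 0.0 < delta_v < dff:
        raise ValueError(
            f"delta_v must lie in (0, |E_s - E_l|) = (0, {dff}); got {delta_v}"
        )
    return C * abs(math.log(1.0 - delta_v / dff))


@dataclass(frozen=True)
class NeuronParams:
    """EIF membrane constants and spiking/reset rules (SI units)."""

    C: float = 1e-6          # membrane capacitance (F)
    g_l: float = 0.05e-3     # leak conductance (S)
    E_l: float = -65e-3      # leak reversal (V)
    V_T: float = -50e-3      # threshold voltage (V)
    kappa: float = 2e-3      # spike sharpness (V)
    V_c: float = -40e-3      # cutting (spike-detection) voltage (V)
    V_r: float = -65e-3      # reset voltage (V)
    tau_ref: float = 3e-3    # refractory period (s)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_l <= 0 or self.kappa <= 0:
            raise ValueError("C, g_l and kappa must be positive")
        if not self.V_r < self.V_c:
            raise ValueError("require V_r < V_c")
        if not self.V_T < self.V_c:
            raise ValueError("require V_T < V_c")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Resting membrane time constant C/g_l (s)."""
        return self.C / self.g_l


@dataclass(frozen=True)
class STPParams:
    """Tsodyks-Markram short-term plasticity constants for one receptor.

    ``U_s`` is the baseline utilization, ``tau_f`` the facilitation time
    constant of the running utilization u, and ``tau_r`` the recovery time
    constant of the running fraction of available transmitter x.
    """

    U_s: float
    tau_f: float
    tau_r: float

    def __post_init__(self) -> None:
        if not 0.0 < self.U_s <= 1.0:
            raise ValueError("U_s must be in (0, 1]")
        if self.tau_f <= 0 or self.tau_r <= 0:
            raise ValueError("tau_f and tau_r must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Per-receptor-type synapse record.

    ``delta_v`` is stored as a positive magnitude for both excitatory and
    inhibitory receptors; ``Gamma_s`` is derived from it unless given
    explicitly.
    """

    label: str
    tau_s: float             # synaptic decay time constant (s)
    E_s: float               # synaptic reversal potential (V)
    delta_v: float           # instant voltage modulation magnitude (V)
    c_s: int = 200           # number of synaptic connections
    Gamma_s: Optional[float] = None   # total conductance variation (S*s)
    stp: Optional[STPParams] = None

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.c_s < 1:
            raise ValueError("c_s must be >= 1")

    def gamma(self, neuron: NeuronParams) -> float:
        """Gamma_s (S*s), derived from delta_v when not set explicitly."""
        if self.Gamma_s is not None:
            if self.Gamma_s <= 0:
                raise ValueError("Gamma_s must be positive")
            return self.Gamma_s
        return gamma_from_delta_v(self.delta_v, neuron.C, self.E_s, neuron.E_l)

    def jump(self, neuron: NeuronParams) -> float:
        """Conductance jump Gamma_s/tau_s per synaptic event (S)."""
        return self.gamma(neuron) / self.tau_s


@dataclass(frozen=True)
class PopulationConfig:
    """One uncoupled population of N EIF neurons with m receptor types."""

    neuron: NeuronParams
    synapses: tuple[SynapseParams, ...]
    N: int = 10_000
    v_lb_margin: float = 0.0   # optional downward extension of V_lb (V)

    def __post_init__(self) -> None:
        if isinstance(self.synapses, list):
            object.__setattr__(self, "synapses", tuple(self.synapses))
        if len(self.synapses) < 1:
            raise ValueError("at least one receptor type is required")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.v_lb_margin < 0:
            raise ValueError("v_lb_margin must be >= 0")
        labels = [s.label for s in self.synapses]
        if len(set(labels)) != len(labels):
            raise ValueError("synapse labels must be unique")
        if self.V_lb >= self.neuron.V_r:
            # V_lb == V_r is allowed (zero-flux wall at the reset point)
            if self.V_lb > self.neuron.V_r:
                raise ValueError("V_lb must not exceed V_r")

    @property
    def m(self) -> int:
        return len(self.synapses)

    @property
    def V_lb(self) -> float:
        """Lower voltage bound: min(E_l, V_r, min_s E_s) minus the margin."""
        lo = min(self.neuron.E_l, self.neuron.V_r,
                 min(s.E_s for s in self.synapses))
        return lo - self.v_lb_margin

    def gammas(self) -> np.ndarray:
        return np.array([s.gamma(self.neuron) for s in self.synapses])

    def synapse(self, label: str) -> SynapseParams:
        for s in self.synapses:
            if s.label == label:
                return s
        raise KeyError(label)


def min_suprathreshold_rate(neuron: NeuronParams, syn: SynapseParams) -> float:
    """Per-connection input rate (Hz) at which normalized nu_s equals 1.

    This is the minimum constant rate that drives the population to fire
    under fluctuation-free (mean-field) conditions,

        nu_min = g_l (V_T - E_l - kappa) / [(E_s - V_T) Gamma_s c_s],

    and is the normalization constant for :class:`~popdens.protocols.RateProtocol`
    waveforms with ``normalized=True``.
    """
    if syn.E_s <= neuron.V_T:
        raise ValueError(
            "rate normalization requires an excitatory receptor (E_s > V_T)"
        )
    num = neuron.g_l * (neuron.V_T - neuron.E_l - neuron.kappa)
    if num < 0:
        raise ValueError("V_T - E_l - kappa must be non-negative")
    return num / ((syn.E_s - neuron.V_T) * syn.gamma(neuron) * syn.c_s)


_EXP_CLIP = 30.0  # cap on (V - V_T)/kappa inside exp() to avoid overflow


def drift_h0(V, mu_g, cfg: PopulationConfig):
    """Deterministic voltage velocity (V/s) with conductances at their means.

    Evaluates (1/C) [ -g_l (V-E_l) + g_l kappa e^{(V-V_T)/kappa}
                      - sum_s mu_gs (V - E_s) ].

    ``V`` may be a scalar or array; ``mu_g`` is one mean conductance per
    receptor type (S).
    """
    n = cfg.neuron
    V = np.asarray(V, dtype=float)
    mu_g = np.atleast_1d(np.asarray(mu_g, dtype=float))
    arg = np.minimum((V - n.V_T) / n.kappa, _EXP_CLIP)
    out = -n.g_l * (V - n.E_l) + n.g_l * n.kappa * np.exp(arg)
    for s, mg in zip(cfg.synapses, mu_g):
        out = out - mg * (V - s.E_s)
    return out / n.C


def drift_fv(V, g, cfg: PopulationConfig):
    """Voltage velocity F_V(V, g) (V/s) for explicit conductance values.

    Same algebra as :func:`drift_h0` but with the per-receptor conductance
    state vector ``g`` instead of its mean.  Used by the full-dimensional
    density solver and the mean-field rate surface.
    """
    return drift_h0(V, g, cfg)


# ---------------------------------------------------------------------------
# presets: cortical EIF defaults and common receptor kinetics

def default_neuron() -> NeuronParams:
    """Cortical EIF defaults: C=1 uF, g_l=0.05 mS, E_l=V_r=-65 mV,
    V_T=-50 mV, kappa=2 mV, V_c=-40 mV, tau_ref=3 ms."""
    return NeuronParams()


def ampa_synapse(delta_v: float = 1e-3, c_s: int = 200,
                 tau_s: float = 5e-3) -> SynapseParams:
    """Fast excitatory (AMPA-like) receptor: tau_s=5 ms, E_s=0 mV."""
    return SynapseParams("ampa", tau_s=tau_s, E_s=0.0, delta_v=delta_v, c_s=c_s)


def gabaa_synapse(delta_v: float = 0.25e-3, c_s: int = 200) -> SynapseParams:
    """Fast inhibitory (GABA_A-like) receptor: tau_s=10 ms, E_s=-80 mV."""
    return SynapseParams("gabaa", tau_s=10e-3, E_s=-80e-3, delta_v=delta_v, c_s=c_s)


def gabab_synapse(delta_v: float = 0.25e-3, c_s: int = 200) -> SynapseParams:
    """Slow inhibitory (GABA_B-like) receptor: tau_s=100 ms, E_s=-100 mV."""
    return SynapseParams("gabab", tau_s=100e-3, E_s=-100e-3, delta_v=delta_v, c_s=c_s)


def facilitating_synapse(c_s: int = 200) -> SynapseParams:
    """Excitatory receptor with short-term facilitation
    (U_s=0.05, tau_f=700 ms, tau_r=100 ms, delta_v=2 mV)."""
    return SynapseParams("facil", tau_s=5e-3, E_s=0.0, delta_v=2e-3, c_s=c_s,
                         stp=STPParams(U_s=0.05, tau_f=0.7, tau_r=0.1))


def depressing_synapse(c_s: int = 200) -> SynapseParams:
    """Excitatory receptor with short-term depression
    (U_s=0.2, tau_f=50 ms, tau_r=300 ms, delta_v=2 mV)."""
    return SynapseParams("depr", tau_s=5e-3, E_s=0.0, delta_v=2e-3, c_s=c_s,
                         stp=STPParams(U_s=0.2, tau_f=0.05, tau_r=0.3))
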