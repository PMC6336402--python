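"""Deterministic input-rate waveforms and inhomogeneous Poisson sampling.

A :class:`RateProtocol` describes the mean rate nu_s(t) of the Poisson
input arriving on one synaptic connection of a given receptor type.  Rates
may be given in absolute Hz or normalized by the minimum suprathreshold
rate of the receptor (the constant per-connection rate that just drives
the population to fire under fluctuation-free conditions); the engines
convert to absolute rates through the population configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import PopulationConfig, min_suprathreshold_rate

__all__ = [
    "RateProtocol",
    "constant",
    "piecewise",
    "sinusoid",
    "table",
    "from_table_file",
    "evaluate_rate",
    "sample_poisson_train",
    "step_sine_drive",
]


@dataclass(frozen=True)
class RateProtocol:
    """Rate waveform nu_s(t) for one receptor type.

    kind:
      * ``constant``  — ``levels[0]`` for all t
      * ``piecewise`` — right-continuous step function: ``levels[i]`` on
        ``[breakpoints[i], breakpoints[i+1])``; the last level extends to
        infinity
      * ``sinusoid``  — ``baseline`` for ``t < t_on`` then
        ``center + amplitude*sin(2*pi*(t-t_on)/period)`` for
        ``t_on <= t < t_on + duration``, then ``center``
      * ``table``     — zero-order hold through tabulated (time, rate)
        samples; evaluation outside the table's support is an error
    """

    receptor: str
    kind: str
    levels: tuple[float, ...] = ()
    breakpoints: tuple[float, ...] = ()
    baseline: float = 0.0
    center: float = 0.0
    amplitude: float = 0.0
    period: float = 1.0
    t_on: float = 0.0
    duration: float = np.inf
    times: tuple[float, ...] = ()
    values: tuple[float, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "piecewise", "sinusoid", "table"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "piecewise" and len(self.levels) != len(self.breakpoints):
            raise ValueError("piecewise: need one level per breakpoint")
        if self.kind == "sinusoid" and abs(self.amplitude) > self.center:
            raise ValueError("sinusoid would go negative: |amplitude| > center")

    def __call__(self, t):
        """Raw waveform value at time(s) t (normalized units if normalized)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.levels[0])
        elif self.kind == "piecewise":
            idx = np.searchsorted(self.breakpoints, t, side="right") - 1
            if np.any(idx < 0):
                raise ValueError("piecewise protocol evaluated before first breakpoint")
            out = np.asarray(self.levels, dtype=float)[idx]
        elif self.kind == "sinusoid":
            tt = t - self.t_on
            mod = self.center + self.amplitude * np.sin(2 * np.pi * tt / self.period)
            out = np.where(t < self.t_on, self.baseline,
                           np.where(tt < self.duration, mod, self.center))
        else:  # table
            tmin, tmax = self.times[0], self.times[-1]
            if np.any(t < tmin) or np.any(t > tmax):
                raise ValueError("table protocol evaluated outside its support")
            idx = np.minimum(np.searchsorted(self.times, t, side="right") - 1,
                             len(self.values) - 1)
            out = np.asarray(self.values, dtype=float)[idx]
        if np.any(out < 0):
            raise ValueError("protocol produced a negative rate")
        return out if out.ndim else float(out)


def constant(receptor: str, level: float, normalized: bool = True) -> RateProtocol:
    return RateProtocol(receptor, "constant", levels=(level,), normalized=normalized)


def piecewise(receptor: str, breakpoints: Sequence[float],
              levels: Sequence[float], normalized: bool = True) -> RateProtocol:
    return RateProtocol(receptor, "piecewise", levels=tuple(levels),
                        breakpoints=tuple(breakpoints), normalized=normalized)


def sinusoid(receptor: str, baseline: float, center: float, amplitude: float,
             period: float, t_on: float = 0.0, duration: float = np.inf,
             normalized: bool = True) -> RateProtocol:
    return RateProtocol(receptor, "sinusoid", baseline=baseline, center=center,
                        amplitude=amplitude, period=period, t_on=t_on,
                        duration=duration, normalized=normalized)


def table(receptor: str, times: Sequence[float], values: Sequence[float],
          normalized: bool = False) -> RateProtocol:
    return RateProtocol(receptor, "table", times=tuple(times),
                        values=tuple(values), normalized=normalized)


def from_table_file(path, receptor: str, normalized: bool = False) -> RateProtocol:
    """Load a two-column text table (time_ms, rate) with zero-order hold."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("table file must have two columns: time_ms rate")
    return table(receptor, arr[:, 0] * 1e-3, arr[:, 1], normalized=normalized)


def evaluate_rate(p: RateProtocol, t, cfg: PopulationConfig):
    """Absolute per-connection rate nu_s(t) in Hz.

    Normalized protocols are scaled by the minimum suprathreshold rate of
    the protocol's receptor, which must be excitatory (E_s > V_T).
    """
    v = p(t)
    if p.normalized:
        syn = cfg.synapse(p.receptor)
        v = v * min_suprathreshold_rate(cfg.neuron, syn)
    return v


def sample_poisson_train(rate_fn: Callable, multiplicity: int, T: float,
                         seed, stream: tuple[int, ...] = ()) -> np.ndarray:
    """Inhomogeneous Poisson event times on [0, T] by thinning.

    ``rate_fn(t)`` gives the per-connection rate in Hz; events are drawn
    with intensity ``multiplicity * rate_fn(t)`` (pooled over connections).
    ``stream`` selects a reproducible substream of the master ``seed`` (for
    example ``(neuron_index, receptor_index)``) so that changing the number
    of neurons does not reshuffle other neurons' inputs.
    """
    if multiplicity < 1 or T <= 0:
        raise ValueError("multiplicity >= 1 and T > 0 required")
    probe = np.asarray(rate_fn(np.linspace(0.0, T, 4097)), dtype=float)
    if not np.all(np.isfinite(probe)):
        raise ValueError("rate function must be bounded on [0, T]")
    lam_max = multiplicity * float(probe.max())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(stream)))
    if lam_max == 0.0:
        return np.empty(0)
    # dominating homogeneous process + acceptance with ratio lam(t)/lam_max
    n = rng.poisson(lam_max * T)
    t = np.sort(rng.uniform(0.0, T, n))
    keep = rng.uniform(0.0, 1.0, n) * lam_max < multiplicity * np.asarray(rate_fn(t))
    return t[keep]


def step_sine_drive(receptor: str = "ampa", lo: float = 0.7, hi: float = 1.3,
                    segment: float = 0.1, n_steps: int = 5,
                    center: float = 1.0, amplitude: float = 0.4,
                    period: float = 0.2, sine_duration: float = 0.5,
                    ) -> RateProtocol:
    """Dynamic validity-region drive: piecewise-constant steps alternating
    between ``lo`` and ``hi`` (normalized) for ``n_steps`` segments, followed
    by a sinusoid about ``center``.

    The default spans normalized rates 0.6-1.4 with 100-ms features over
    1 s, staying inside the diffusion-validity region.
    """
    bps = [i * segment for i in range(n_steps)]
    levels = [lo if i % 2 == 0 else hi for i in range(n_steps)]
    t_sine = n_steps * segment
    # encode as a table sampled at 1 ms (piecewise + sinusoid composition)
    ts = np.arange(0.0, t_sine + sine_duration + 1e-9, 1e-3)
    vals = np.empty_like(ts)
    for i, t in enumerate(ts):
        if t < t_sine:
            k = min(int(t // segment), n_steps - 1)
            vals[i] = levels[k]
        else:
            vals[i] = center + amplitude * np.sin(2 * np.pi * (t - t_sine) / period)
    return table(receptor, ts, vals, normalized=True)
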