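"""Error functionals comparing density-method output against Monte Carlo.

Three average error ratios quantify agreement with the Monte Carlo ground
truth: ``eta_g`` on the marginal conductance density (against the Gaussian
implied by the moment closure, integrated over mu +/- 6 sigma), ``eta_v``
on the marginal voltage density, and ``eta_r`` on the population firing
rate over a time window.  All are L1 distances normalized by the Monte
Carlo mass over the same window, so identical inputs give 0 and disjoint
unit-mass densities give 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.stats import norm

__all__ = ["ErrorReport", "eta_g", "eta_v", "eta_r", "moving_average"]


@dataclass
class ErrorReport:
    """Bundle of error ratios for one engine-vs-Monte-Carlo comparison."""

    eta_g: dict = field(default_factory=dict)   # receptor label -> ratio
    eta_v: Optional[float] = None
    eta_r: dict = field(default_factory=dict)   # engine name -> ratio
    cv: dict = field(default_factory=dict)      # receptor label -> sigma/mu
    window: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {"eta_g": self.eta_g, "eta_v": self.eta_v, "eta_r": self.eta_r,
                "cv": self.cv, "window": self.window}


def eta_g(bin_edges: np.ndarray, mcs_density: np.ndarray,
          mu: float, sigma: float) -> float:
    """Average error ratio of the conductance density vs a Gaussian.

    ``mcs_density`` is a histogram density on ``bin_edges``; the Gaussian
    N(mu, sigma) is evaluated at the bin centers.  Numerator and
    denominator integrate over [mu - 6 sigma, mu + 6 sigma]; bins outside
    the histogram's support count the full Gaussian mass there (the
    empirical density is zero where no sample can fall, e.g. g < 0).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mcs_density = np.asarray(mcs_density, dtype=float)
    if mcs_density.size == 0 or not np.any(mcs_density > 0):
        raise ValueError("empty Monte Carlo histogram")
    lo, hi = mu - 6.0 * sigma, mu + 6.0 * sigma
    # common fine grid over the window
    xs = np.linspace(lo, hi, 4001)
    idx = np.searchsorted(bin_edges, xs, side="right") - 1
    rho = np.where((idx >= 0) & (idx < len(mcs_density)),
                   mcs_density[np.clip(idx, 0, len(mcs_density) - 1)], 0.0)
    gauss = norm.pdf(xs, mu, sigma)
    num = np.trapezoid(np.abs(rho - gauss), xs)
    den = np.trapezoid(rho, xs)
    if den <= 0:
        raise ValueError("Monte Carlo histogram has no mass in the window")
    return float(num / den)


def eta_v(bin_edges: np.ndarray, mcs_density: np.ndarray,
          model_density_at) -> float:
    """Average error ratio of the voltage density.

    ``model_density_at(V)`` evaluates the model's piecewise-linear density
    at the histogram bin centers (e.g. ``lambda v: result.density(t, v)``).
    """
    centers = 0.5 * (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:]))
    widths = np.diff(bin_edges)
    rho_mcs = np.asarray(mcs_density, dtype=float)
    if rho_mcs.shape != centers.shape:
        raise ValueError("density/bin mismatch")
    rho_mod = np.asarray(model_density_at(centers), dtype=float)
    den = float(np.sum(rho_mcs * widths))
    if den <= 0:
        raise ValueError("Monte Carlo voltage histogram has no mass")
    return float(np.sum(np.abs(rho_mcs - rho_mod) * widths) / den)


def eta_r(t_ref: np.ndarray, r_ref: np.ndarray,
          t_test: np.ndarray, r_test: np.ndarray,
          t1: float, t2: float) -> float:
    """Average error ratio of the firing rate over the window [t1, t2].

    Both series are linearly interpolated onto a common grid; the result is
    the time-integrated absolute difference normalized by the integral of
    the reference rate.
    """
    if t2 <= t1:
        raise ValueError("require t2 > t1")
    for t in (t_ref, t_test):
        if t1 < t[0] - 1e-9 or t2 > t[-1] + 1e-9:
            raise ValueError("series does not cover the comparison window")
    grid = np.linspace(t1, t2, 2001)
    a = np.interp(grid, t_ref, r_ref)
    b = np.interp(grid, t_test, r_test)
    den = np.trapezoid(a, grid)
    if den <= 0:
        raise ValueError("reference rate integrates to zero on the window")
    return float(np.trapezoid(np.abs(a - b), grid) / den)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered n-point moving average with edge shrinkage."""
    if n <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")
    return out[pad:len(xp) - pad] if pad else out
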