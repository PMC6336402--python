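"""Experiment presets, run manifests and orchestration.

Each preset is a self-contained numerical experiment exercising one of
the method's result families:

* ``io_curve``       — steady-state input-output curves, Monte Carlo vs
  the colored-synapse solver (and optionally the mean-field baseline).
* ``validity_sweep`` — grid of (normalized rate, jump size) operating
  points with the conductance CV and the density error ratios, tracing
  the diffusion-validity boundary.
* ``dynamic_drive``  — time-varying drive inside the validity region;
  rate-tracking error of each density engine against Monte Carlo.
* ``multi_receptor`` — three receptor types (fast/slow excitatory and
  inhibitory kinetics) driven together; Monte Carlo vs colored-synapse.
* ``stp_demo``       — short-term facilitation: mean-field (u, x) traces
  against the per-synapse Monte Carlo ensemble means.

``run_preset`` executes all engines of a preset, writes per-engine rate
series (CSV), a summary table, and a ``manifest.json`` echoing the full
configuration, seeds and library versions so a run can be reproduced
bit-for-bit (deterministic engines) or seed-for-seed (Monte Carlo).
"""

from __future__ import annotations

import json
import logging
import platform
import time
import traceback
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np

from . import __version__
from . import protocols as pr
from .config import config_to_document
from .core import (PopulationConfig, ampa_synapse, default_neuron,
                   facilitating_synapse, gabaa_synapse, gabab_synapse)
from .cspdm import run_cspdm
from .fdpdm import run_fdpdm
from .mcs import empirical_densities, run_mcs
from .metrics import eta_g, eta_r, eta_v, moving_average
from .mmfm import run_mmfm
from .moments import conductance_cv, steady_conductance_moments
from .protocols import RateProtocol, step_sine_drive

__all__ = ["PRESETS", "run_preset", "stationary_rate"]

log = logging.getLogger("popdens")


def stationary_rate(times: np.ndarray, rates: np.ndarray,
                    discard: float = 1.0) -> float:
    """Time-averaged rate after discarding the transient (s)."""
    m = np.asarray(times) > discard
    if not m.any():
        raise ValueError("no samples after the discard window")
    return float(np.mean(np.asarray(rates)[m]))


def _write_series(path: Path, times, rates) -> None:
    np.savetxt(path, np.column_stack([times, rates]), delimiter=",",
               header="t_s,rate_hz", comments="")


def _single_ampa(N: int) -> PopulationConfig:
    return PopulationConfig(default_neuron(), (ampa_synapse(),), N=N)


# ---------------------------------------------------------------------------
# preset implementations (each returns a JSON-serializable summary dict)

def _preset_io_curve(out: Path, seed: int, fast: bool) -> dict:
    N = 2000 if fast else 10_000
    T = 2.0 if fast else 3.0
    discard = 1.0
    nus = (0.6, 0.8, 1.0, 1.2, 1.5)
    taus = ((5e-3, "tau5"),) if fast else ((5e-3, "tau5"), (100e-3, "tau100"))
    rows = []
    for tau_s, tag in taus:
        cfg = PopulationConfig(default_neuron(),
                               (ampa_synapse(tau_s=tau_s),), N=N)
        for k, nu in enumerate(nus):
            p = pr.constant("ampa", nu)
            mres = run_mcs(cfg, [p], T=T, seed=seed + k)
            r_mcs = stationary_rate(mres.rate_times, mres.rates, discard)
            cres = run_cspdm(cfg, [p], T=T)
            r_cs = stationary_rate(cres.times, cres.rates, discard)
            rows.append({"tau_s_ms": tau_s * 1e3, "nu_norm": nu,
                         "r_mcs_hz": r_mcs, "r_cspdm_hz": r_cs,
                         "abs_diff_hz": abs(r_cs - r_mcs)})
            log.info("io_curve %s nu=%.1f: MCS %.2f Hz, csPDM %.2f Hz",
                     tag, nu, r_mcs, r_cs)
    _write_table(out / "io_curve.csv", rows)
    return {"rows": rows,
            "max_abs_diff_hz": max(r["abs_diff_hz"] for r in rows)}


def _preset_validity_sweep(out: Path, seed: int, fast: bool) -> dict:
    N = 2000 if fast else 10_000
    T = 2.0 if fast else 3.0
    snap = [T - 0.5, T - 0.25, T]
    nus = (0.1, 0.3, 1.0)
    dvs = (0.5e-3, 1e-3, 2e-3)
    rows = []
    for dv in dvs:
        for k, nu in enumerate(nus):
            cfg = PopulationConfig(default_neuron(),
                                   (ampa_synapse(delta_v=dv),), N=N)
            syn = cfg.synapses[0]
            p = pr.constant("ampa", nu)
            nu_abs = float(pr.evaluate_rate(p, 0.0, cfg))
            cv = conductance_cv(nu_abs, syn)
            mres = run_mcs(cfg, [p], T=T, seed=seed + k, snapshot_times=snap)
            mu, sig = steady_conductance_moments(nu_abs, syn, cfg.neuron)
            gb = np.linspace(max(mu - 6 * sig, 0.0), mu + 6 * sig, 201)
            from .mcs import pooled_snapshot_histogram
            gd = pooled_snapshot_histogram(mres, snap, gb, "g", "ampa")
            e_g = eta_g(gb, gd, mu, sig)
            vb = np.arange(cfg.V_lb, cfg.neuron.V_c + 0.25e-3, 0.25e-3)
            vd = pooled_snapshot_histogram(mres, snap, vb, "V")
            cres = run_cspdm(cfg, [p], T=T, snapshot_times=[T],
                             validity_warning=False)
            e_v = eta_v(vb, vd, lambda v: cres.density(T, v))
            rows.append({"delta_v_mv": dv * 1e3, "nu_norm": nu, "cv": cv,
                         "eta_g": e_g, "eta_v": e_v})
            log.info("validity dv=%.2g nu=%.1f: CV=%.2f eta_g=%.3f eta_v=%.3f",
                     dv * 1e3, nu, cv, e_g, e_v)
    _write_table(out / "validity_sweep.csv", rows)
    return {"rows": rows}


def _preset_dynamic_drive(out: Path, seed: int, fast: bool) -> dict:
    N = 2000 if fast else 10_000
    cfg = _single_ampa(N)
    p = step_sine_drive()
    T = float(p.times[-1])
    mres = run_mcs(cfg, [p], T=T, seed=seed)
    r_mcs = moving_average(mres.rates, 5)
    _write_series(out / "mcs_rate.csv", mres.rate_times, r_mcs)
    cres = run_cspdm(cfg, [p], T=T)
    _write_series(out / "cspdm_rate.csv", cres.times, cres.rates)
    w_hi = min(float(mres.rate_times[-1]), float(cres.times[-1]))
    w = (w_hi - 0.4, w_hi)
    summary = {"window_s": w,
               "eta_r_cspdm": eta_r(mres.rate_times, r_mcs,
                                    cres.times, cres.rates, *w)}
    if not fast:
        mt, mr = run_mmfm(cfg, [p], T=T)
        _write_series(out / "mmfm_rate.csv", mt, mr)
        summary["eta_r_mmfm"] = eta_r(mres.rate_times, r_mcs, mt, mr, *w)
    return summary


def _preset_multi_receptor(out: Path, seed: int, fast: bool) -> dict:
    N = 2000 if fast else 10_000
    cfg = PopulationConfig(default_neuron(),
                           (ampa_synapse(), gabaa_synapse(), gabab_synapse()),
                           N=N)
    protos = [pr.constant("ampa", 1.5),
              pr.constant("gabaa", 10.0, normalized=False),
              pr.constant("gabab", 2.0, normalized=False)]
    T = 2.0 if fast else 3.0
    mres = run_mcs(cfg, protos, T=T, seed=seed)
    _write_series(out / "mcs_rate.csv", mres.rate_times, mres.rates)
    cres = run_cspdm(cfg, protos, T=T)
    _write_series(out / "cspdm_rate.csv", cres.times, cres.rates)
    r_m = stationary_rate(mres.rate_times, mres.rates)
    r_c = stationary_rate(cres.times, cres.rates)
    log.info("multi_receptor: MCS %.2f Hz, csPDM %.2f Hz", r_m, r_c)
    return {"r_mcs_hz": r_m, "r_cspdm_hz": r_c,
            "abs_diff_hz": abs(r_c - r_m)}


def _preset_stp_demo(out: Path, seed: int, fast: bool) -> dict:
    N = 2000 if fast else 10_000
    cfg = PopulationConfig(default_neuron(), (facilitating_synapse(),), N=N)
    p = pr.constant("facil", 10.0, normalized=False)
    T = 2.0 if fast else 3.0
    mres = run_mcs(cfg, [p], T=T, seed=seed, record_stp_every=10e-3)
    cres = run_cspdm(cfg, [p], T=T)
    cres.save_series(out / "cspdm_series.csv")
    mm = mres.stp_means["facil"]
    np.savetxt(out / "mcs_stp_means.csv",
               np.column_stack([mres.stp_times, mm["u"], mm["x"]]),
               delimiter=",", header="t_s,mu_u,mu_x", comments="")
    mom = cres.moments["facil"]
    summary = {
        "mu_u_final_mcs": float(mm["u"][-1]),
        "mu_x_final_mcs": float(mm["x"][-1]),
        "mu_u_final_meanfield": float(mom["mu_u"][-1]),
        "mu_x_final_meanfield": float(mom["mu_x"][-1]),
        "r_mcs_hz": stationary_rate(mres.rate_times, mres.rates),
        "r_cspdm_hz": stationary_rate(cres.times, cres.rates),
    }
    log.info("stp_demo: mu_u %.3f/%.3f  mu_x %.3f/%.3f (MCS/mean-field)",
             summary["mu_u_final_mcs"], summary["mu_u_final_meanfield"],
             summary["mu_x_final_mcs"], summary["mu_x_final_meanfield"])
    return summary


PRESETS: dict[str, Callable[[Path, int, bool], dict]] = {
    "io_curve": _preset_io_curve,
    "validity_sweep": _preset_validity_sweep,
    "dynamic_drive": _preset_dynamic_drive,
    "multi_receptor": _preset_multi_receptor,
    "stp_demo": _preset_stp_demo,
}


def _write_table(path: Path, rows: list[dict]) -> None:
    if not rows:
        return
    keys = list(rows[0])
    lines = [",".join(keys)]
    for r in rows:
        lines.append(",".join(f"{r[k]:.6g}" if isinstance(r[k], float)
                              else str(r[k]) for k in keys))
    path.write_text("\n".join(lines) + "\n")


def run_preset(name: str, out_dir, seed: int = 0, fast: bool = False
               ) -> Path:
    """Execute a preset end-to-end; returns the run directory.

    The directory receives the engine outputs, ``summary.json`` and a
    ``manifest.json`` (configuration echo, seed, versions, status).  A
    failing engine marks the manifest ``status: failed`` but completed
    outputs are preserved.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    manifest = {
        "preset": name, "seed": seed, "fast": fast,
        "popdens_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "status": "running",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    t0 = time.time()
    try:
        summary = PRESETS[name](out, seed, fast)
        manifest["status"] = "ok"
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception:
        manifest["status"] = "failed"
        manifest["traceback"] = traceback.format_exc()
        raise
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 1)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.removeHandler(fh)
        fh.close()
    return out
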