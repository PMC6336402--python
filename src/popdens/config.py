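"""Configuration documents: physiological units in, validated SI out.

Configuration files (YAML or JSON) use the units of the physiology
literature — mV, ms, mS, uF and Hz — and are converted here into the SI
:class:`~popdens.core.PopulationConfig` plus one
:class:`~popdens.protocols.RateProtocol` per receptor.  Validation errors
name the offending key.

Document schema (all keys optional unless noted)::

    neuron:
      C: 1.0            # uF
      g_l: 0.05         # mS
      E_l: -65.0        # mV
      V_T: -50.0        # mV
      kappa: 2.0        # mV
      V_c: -40.0        # mV
      V_r: -65.0        # mV
      tau_ref: 3.0      # ms
    population:
      N: 10000
      v_lb_margin: 0.0  # mV
    synapses:           # required, at least one entry
      - label: ampa     # required, unique
        tau_s: 5.0      # ms
        E_s: 0.0        # mV
        delta_v: 1.0    # mV (positive magnitude)
        c_s: 200
        stp: {U_s: 0.05, tau_f: 700.0, tau_r: 100.0}   # ms
    protocols:          # one per receptor label; default: constant 1.0 norm.
      - receptor: ampa
        kind: constant | piecewise | sinusoid | table
        normalized: true
        level: 1.0                      # constant
        breakpoints: [0, 100]  # ms     # piecewise
        levels: [0.7, 1.3]
        baseline: 0.0                   # sinusoid
        center: 1.0
        amplitude: 0.4
        period: 200.0   # ms
        t_on: 0.0       # ms
        duration: 500.0 # ms
        times: [...]    # ms            # table
        values: [...]
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import protocols as _protocols
from .core import (NeuronParams, PopulationConfig, STPParams, SynapseParams)
from .protocols import RateProtocol

__all__ = ["ConfigError", "validate_config", "load_config",
           "default_document", "config_to_document"]

_MV = 1e-3
_MS = 1e-3
_MSIEMENS = 1e-3
_UF = 1e-6


class ConfigError(ValueError):
    """Structured validation failure: ``key`` names the offending entry."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


def _num(doc: Mapping, section: str, key: str, default, scale: float = 1.0):
    v = doc.get(key, default)
    try:
        return float(v) * scale
    except (TypeError, ValueError):
        raise ConfigError(f"{section}.{key}", f"not a number: {v!r}")


def default_document() -> dict:
    """Single-AMPA Table-style defaults as a plain document."""
    return {
        "neuron": {"C": 1.0, "g_l": 0.05, "E_l": -65.0, "V_T": -50.0,
                   "kappa": 2.0, "V_c": -40.0, "V_r": -65.0, "tau_ref": 3.0},
        "population": {"N": 10_000},
        "synapses": [{"label": "ampa", "tau_s": 5.0, "E_s": 0.0,
                      "delta_v": 1.0, "c_s": 200}],
        "protocols": [{"receptor": "ampa", "kind": "constant",
                       "level": 1.0, "normalized": True}],
    }


def _build_protocol(p: Mapping, i: int, labels: set[str]) -> RateProtocol:
    sec = f"protocols[{i}]"
    receptor = p.get("receptor")
    if receptor not in labels:
        raise ConfigError(f"{sec}.receptor",
                          f"unknown receptor {receptor!r}; have {sorted(labels)}")
    kind = p.get("kind", "constant")
    normalized = bool(p.get("normalized", True))
    try:
        if kind == "constant":
            return _protocols.constant(receptor, float(p.get("level", 1.0)),
                                       normalized)
        if kind == "piecewise":
            bps = [float(b) * _MS for b in p["breakpoints"]]
            return _protocols.piecewise(receptor, bps,
                                        [float(v) for v in p["levels"]],
                                        normalized)
        if kind == "sinusoid":
            return _protocols.sinusoid(
                receptor, baseline=float(p.get("baseline", 0.0)),
                center=float(p.get("center", 1.0)),
                amplitude=float(p.get("amplitude", 0.0)),
                period=float(p.get("period", 1000.0)) * _MS,
                t_on=float(p.get("t_on", 0.0)) * _MS,
                duration=float(p.get("duration", np.inf)) * _MS,
                normalized=normalized)
        if kind == "table":
            return _protocols.table(receptor,
                                    [float(t) * _MS for t in p["times"]],
                                    [float(v) for v in p["values"]],
                                    normalized)
    except KeyError as e:
        raise ConfigError(f"{sec}.{e.args[0]}", "missing required key")
    except ValueError as e:
        raise ConfigError(sec, str(e))
    raise ConfigError(f"{sec}.kind", f"unknown protocol kind {kind!r}")


def validate_config(doc: Mapping
                    ) -> tuple[PopulationConfig, dict[str, RateProtocol]]:
    """Validate a document and return SI config + protocols per receptor.

    Receptors without an explicit protocol entry get a constant normalized
    drive of 1.0 if excitatory, or 0.0 (silent) if not.
    """
    if not isinstance(doc, Mapping):
        raise ConfigError("<document>", "top level must be a mapping")
    nd = doc.get("neuron", {})
    try:
        neuron = NeuronParams(
            C=_num(nd, "neuron", "C", 1.0, _UF),
            g_l=_num(nd, "neuron", "g_l", 0.05, _MSIEMENS),
            E_l=_num(nd, "neuron", "E_l", -65.0, _MV),
            V_T=_num(nd, "neuron", "V_T", -50.0, _MV),
            kappa=_num(nd, "neuron", "kappa", 2.0, _MV),
            V_c=_num(nd, "neuron", "V_c", -40.0, _MV),
            V_r=_num(nd, "neuron", "V_r", -65.0, _MV),
            tau_ref=_num(nd, "neuron", "tau_ref", 3.0, _MS),
        )
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError("neuron", str(e))

    sdocs = doc.get("synapses")
    if not sdocs:
        raise ConfigError("synapses", "at least one receptor is required")
    synapses = []
    for i, sd in enumerate(sdocs):
        sec = f"synapses[{i}]"
        label = sd.get("label")
        if not label:
            raise ConfigError(f"{sec}.label", "missing receptor label")
        stp = None
        if sd.get("stp"):
            st = sd["stp"]
            try:
                stp = STPParams(U_s=float(st["U_s"]),
                                tau_f=float(st["tau_f"]) * _MS,
                                tau_r=float(st["tau_r"]) * _MS)
            except KeyError as e:
                raise ConfigError(f"{sec}.stp.{e.args[0]}", "missing key")
            except ValueError as e:
                raise ConfigError(f"{sec}.stp", str(e))
        try:
            syn = SynapseParams(
                label=str(label),
                tau_s=_num(sd, sec, "tau_s", 5.0, _MS),
                E_s=_num(sd, sec, "E_s", 0.0, _MV),
                delta_v=_num(sd, sec, "delta_v", 1.0, _MV),
                c_s=int(sd.get("c_s", 200)),
                stp=stp,
            )
            syn.gamma(neuron)   # validates the delta_v domain
        except ValueError as e:
            if isinstance(e, ConfigError):
                raise
            raise ConfigError(sec, str(e))
        synapses.append(syn)

    pd = doc.get("population", {})
    try:
        cfg = PopulationConfig(
            neuron=neuron, synapses=tuple(synapses),
            N=int(pd.get("N", 10_000)),
            v_lb_margin=_num(pd, "population", "v_lb_margin", 0.0, _MV),
        )
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError("population", str(e))

    labels = {s.label for s in synapses}
    protos: dict[str, RateProtocol] = {}
    for i, p in enumerate(doc.get("protocols", [])):
        rp = _build_protocol(p, i, labels)
        if rp.receptor in protos:
            raise ConfigError(f"protocols[{i}]",
                              f"duplicate protocol for {rp.receptor!r}")
        protos[rp.receptor] = rp
    for s in synapses:
        if s.label not in protos:
            level = 1.0 if s.E_s > neuron.V_T else 0.0
            protos[s.label] = _protocols.constant(
                s.label, level, normalized=s.E_s > neuron.V_T)
    return cfg, protos


def load_config(path) -> tuple[PopulationConfig, dict[str, RateProtocol]]:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return validate_config(doc)


def config_to_document(cfg: PopulationConfig,
                       protos: Mapping[str, RateProtocol] | None = None
                       ) -> dict:
    """Physiological-unit echo of a config (for manifests)."""
    n = cfg.neuron
    doc = {
        "neuron": {"C": n.C / _UF, "g_l": n.g_l / _MSIEMENS,
                   "E_l": n.E_l / _MV, "V_T": n.V_T / _MV,
                   "kappa": n.kappa / _MV, "V_c": n.V_c / _MV,
                   "V_r": n.V_r / _MV, "tau_ref": n.tau_ref / _MS},
        "population": {"N": cfg.N, "v_lb_margin": cfg.v_lb_margin / _MV},
        "synapses": [],
        "protocols": [],
    }
    for s in cfg.synapses:
        sd = {"label": s.label, "tau_s": s.tau_s / _MS, "E_s": s.E_s / _MV,
              "delta_v": s.delta_v / _MV, "c_s": s.c_s}
        if s.stp:
            sd["stp"] = {"U_s": s.stp.U_s, "tau_f": s.stp.tau_f / _MS,
                         "tau_r": s.stp.tau_r / _MS}
        doc["synapses"].append(sd)
    for lab, p in (protos or {}).items():
        pd = {"receptor": lab, "kind": p.kind, "normalized": p.normalized}
        if p.kind == "constant":
            pd["level"] = p.levels[0]
        elif p.kind == "piecewise":
            pd["breakpoints"] = [b / _MS for b in p.breakpoints]
            pd["levels"] = list(p.levels)
        elif p.kind == "sinusoid":
            pd.update(baseline=p.baseline, center=p.center,
                      amplitude=p.amplitude, period=p.period / _MS,
                      t_on=p.t_on / _MS,
                      duration=(p.duration / _MS
                                if np.isfinite(p.duration) else None))
        else:
            pd["times"] = [t / _MS for t in p.times]
            pd["values"] = list(p.values)
        doc["protocols"].append(pd)
    return doc
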