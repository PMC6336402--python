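# popdens — population density methods for EIF neuron populations

`popdens` simulates the firing-rate dynamics of large, uncoupled populations
of exponential integrate-and-fire (EIF) neurons with conductance-based
synapses driven by Poisson input, using a hierarchy of four interchangeable
engines:

* **`mcs`** — Monte Carlo simulation of every neuron (ground truth),
* **`fdpdm`** — the full-dimensional population density method, solving the
  joint master equation for ρ(V, g) (single receptor; accuracy reference),
* **`cspdm`** — the *colored-synapse* population density method: a
  one-dimensional quasi-Fokker–Planck equation for the voltage density whose
  diffusion coefficient carries the colored-noise correction
  τ_sτ_eff/(τ_s+τ_eff), with the synaptic conductances reduced to their
  first two moments,
* **`mmfm`** — a quasi-static mean-field baseline (expected steady-state
  rate over the conductance marginals).

The colored-synapse method is the point of the package: it removes every
synaptic dimension from the master equation — the cost is independent of
the number of receptor types — while staying accurate whenever the
conductance coefficient of variation CV = 1/√(2 τ_s c_s ν) is below ≈ 0.6
(the diffusion-validity criterion; the solver warns outside it). Short-term
plasticity (Tsodyks–Markram facilitation/depression) is supported through a
mean-field modulation of the synaptic event size.

See `docs/methods.md` for the governing equations and numerical schemes.

## Worked example

Steady-state comparison of Monte Carlo and the colored-synapse solver for a
single excitatory (AMPA-like) receptor driven at 1.2× the minimum
suprathreshold rate:

```python
import numpy as np
from popdens import protocols as pr
from popdens.core import PopulationConfig, ampa_synapse, default_neuron
from popdens.cspdm import run_cspdm
from popdens.mcs import run_mcs
from popdens.workbench import stationary_rate

cfg = PopulationConfig(default_neuron(), (ampa_synapse(),), N=2000)
drive = pr.constant("ampa", 1.2)        # 1.2 x the minimum suprathreshold rate

mcs = run_mcs(cfg, [drive], T=2.0, seed=0)
cs = run_cspdm(cfg, [drive], T=2.0)

print(f"MCS   rate: {stationary_rate(mcs.rate_times, mcs.rates):6.2f} Hz")
print(f"csPDM rate: {stationary_rate(cs.times, cs.rates):6.2f} Hz")
print(f"final mean voltage: {cs.mean_v[-1] * 1e3:.2f} mV")
```

Output:

```
MCS   rate:  14.71 Hz
csPDM rate:  15.05 Hz
final mean voltage: -53.27 mV
```

The two engines agree to a fraction of a hertz here; across the full
input–output curve (normalized rates 0.6–1.5, synaptic time constants 5 and
100 ms, N = 10,000) the maximum deviation is below 1 Hz.

## Command line

Every engine is a CLI verb reading a YAML/JSON configuration in
physiological units (mV, ms, mS, μF, Hz) and writing a JSON rate series:

```
popdens mcs   --config cfg.yaml -T 3.0 --seed 1 --out mcs.json
popdens cspdm --config cfg.yaml -T 3.0 --out cs.json
popdens compare --ref mcs.json --test cs.json        # rate error ratio
popdens preset io_curve --out runs/io --fast         # bundled experiment
```

Presets (`io_curve`, `validity_sweep`, `dynamic_drive`, `multi_receptor`,
`stp_demo`) run complete experiments at study scale (N = 10,000 by default;
`--fast` shrinks to N = 2000 for CI) and write per-engine CSV series,
`summary.json` and a reproducibility `manifest.json`. A minimal
configuration:

```yaml
synapses:
  - {label: ampa, tau_s: 5.0, E_s: 0.0, delta_v: 1.0, c_s: 200}
protocols:
  - {receptor: ampa, kind: constant, level: 1.2, normalized: true}
```

## Validation

* Exhaustive unit and property tests (`pytest`): conservation, positivity,
  closed-form moments, exact shot-noise stationary law (flux-balance
  solution), deterministic zero-noise period, metric identities.
* `tests/test_acceptance.py` asserts the headline quantitative claims.
  One is a documented, deliberate failure: at the validity-boundary
  operating point CV = 0.55 the conductance error ratio evaluates to
  0.2098 *semi-analytically* (exact law vs Gaussian closure, independent of
  binning), above the nominal 0.2 bound; the test states the bound as
  published rather than weakening it.
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes all headline targets from scratch at full scale (N = 10,000,
  ~6–10 min on one CPU).

## Layout

```
src/popdens/
  core.py        parameters, EIF drift, receptor presets
  protocols.py   rate waveforms + inhomogeneous Poisson sampling
  config.py      YAML/JSON validation (physiological units -> SI)
  mcs.py         Monte Carlo engine
  moments.py     conductance moment closure + STP mean field
  cspdm.py       colored-synapse density solver (primary method)
  fdpdm.py       full-dimensional joint-density reference (m=1)
  mmfm.py        quasi-static mean-field baseline
  metrics.py     eta_g / eta_v / eta_r error ratios
  workbench.py   experiment presets, manifests
  cli.py         `popdens` command line
```
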