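# Methods

This package simulates the firing-rate dynamics of a large, uncoupled
population of exponential integrate-and-fire (EIF) neurons driven by
conductance-based synapses receiving Poisson input. Four engines share one
configuration and can be compared point-for-point:

| engine  | state tracked                       | role |
|---------|-------------------------------------|------|
| `mcs`   | every neuron                        | Monte Carlo ground truth |
| `fdpdm` | joint density ρ(V, g)               | full-dimensional reference (one receptor) |
| `cspdm` | voltage density ρ(V) + g-moments    | the colored-synapse method (primary) |
| `mmfm`  | g-marginal densities + rate surface | quasi-static mean-field baseline |

## Model

Each neuron obeys

    C dV/dt = −g_l (V − E_l) + g_l κ e^{(V − V_T)/κ} − Σ_s g_s (V − E_s)

with a spike recorded when V reaches the cutting voltage V_c, reset to V_r
and a refractory clamp of τ_ref. Defaults: C = 1 μF, g_l = 0.05 mS,
E_l = V_r = −65 mV, V_T = −50 mV, κ = 2 mV, V_c = −40 mV, τ_ref = 3 ms.

Each receptor type s has a conductance that jumps by Γ_s/τ_s per presynaptic
event and decays exponentially with τ_s. Γ_s is parameterized by the instant
voltage modulation ΔV_s a single event would cause at rest:
Γ_s = C·|ln(1 − ΔV_s/|E_s − E_l|)|. Every neuron receives c_s independent
Poisson trains of rate ν_s(t) per receptor. Rates may be given normalized by
the minimum suprathreshold rate
ν_min = g_l(V_T − E_l − κ)/((E_s − V_T)Γ_s c_s), the constant rate that just
sustains firing in the fluctuation-free limit (4.1924 Hz for the default
excitatory receptor).

## Conductance statistics and moment closure

The conductance of one receptor is a filtered Poisson (shot-noise) process.
Its first two moments obey closed ODEs (`popdens.moments`), with stationary
values μ_g = c_s ν Γ_s and σ_g = Γ_s √(c_s ν / 2τ_s), hence a coefficient of
variation CV = 1/√(2 τ_s c_s ν). The diffusion approximation treats the
conductance as Gaussian; it is adequate when CV ≲ 0.6 and the solver warns
outside that regime. With short-term plasticity the event size is modulated
by the mean-field utilization/availability pair (μ_u, μ_x) of the
Tsodyks–Markram model, advanced alongside the conductance moments.

## Colored-synapse density method (`cspdm`)

Adiabatically eliminating the conductance dimensions with the colored-noise
correction yields a one-dimensional quasi-Fokker–Planck equation for ρ(V, t):

    ∂ρ/∂t = −∂/∂V [ H0(V) ρ ] + ∂²/∂V² [ D(V) ρ ]

where H0 is the drift with conductances at their means and

    D(V) = Σ_s (σ_gs (E_s − V)/C)² · τ_s τ_eff / (τ_s + τ_eff),
    τ_eff = C / (g_l − g_l e^{(⟨V⟩ − V_T)/κ} + Σ_s μ_gs),

with ⟨V⟩ the population-wide mean voltage (refractory mass counted at V_r)
and τ_eff clamped to [0.1 ms, 1 s]. The equation is solved on a local
linear (two-trace-per-cell) element mesh (M = 200 cells by default) with a
backward-Euler step (dt = 0.2 ms), a single banded solve per step, a minmod
slope limiter with positivity floor, absorbing flux at V_c and re-injection
of the outgoing flux at V_r after the refractory delay. Coefficients are
refreshed each step from the previous ⟨V⟩ and the new moments, so no
nonlinear solve is needed. The firing rate is the V_c boundary flux.

## Full-dimensional reference (`fdpdm`)

For a single receptor, the joint master equation for ρ(V, g) is solved by
conservative finite volumes: upwind transport in V by the sign of the drift,
decay advection in g plus the exact nonlocal jump term
λ ∫_{g−h}^{g} ρ dg′, both with minmod-limited linear reconstruction (second
order). The time step respects the voltage CFL bound and the conductance
decay bound dt ≤ Δg τ_s/g_max. The spiking outflow is queued per g-slice
and re-injected at V_r after τ_ref. This engine scales badly with receptor
count and is implemented for m = 1 only, as the accuracy reference.

## Mean-field baseline (`mmfm`)

The baseline evolves each receptor's marginal conductance density by its 1-D
master equation and reports the expectation of the precomputed steady-state
rate surface r̄(g) over the product of marginals. It is quasi-static by
construction: accurate when τ_s is long compared with the membrane time
constant, and documented to overestimate fluctuation-driven rates at short
τ_s. It is kept faithful to its published form as a baseline.

## Error metrics (`popdens.metrics`)

Three average error ratios quantify engine agreement with Monte Carlo:

* `eta_g` — L1 distance between the empirical conductance histogram and the
  Gaussian of the moment closure, integrated over μ ± 6σ and normalized by
  the Monte Carlo mass there (bins outside the physical support count the
  full Gaussian mass). 200 bins by default; the value is insensitive to
  binning (see `tests/test_metrics.py`).
* `eta_v` — same ratio for the voltage density over [V_lb, V_c], 0.25 mV
  bins, refractory neurons excluded from the histogram.
* `eta_r` — time-integrated |Δr| over a window, normalized by the reference
  rate integral. Identical series give 0; disjoint unit-mass densities give 2.

## Validation

The test suite checks, among others: probability conservation (τ_ref = 0)
to 1e−6; density positivity after limiting; stationary moments against
closed forms; the Monte Carlo stationary conductance law against the exact
flux-balance solution of the shot-noise master equation (KS < 0.02 at
N = 10⁴); the colored-synapse voltage marginal against the full joint
reference (L1 < 0.05 inside the validity regime); and the zero-noise limit
against deterministic period integration (< 2%). `scripts/acceptance.py`
recomputes the headline quantitative targets at full scale (N = 10,000).
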