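# Methods

## Model

Two single-compartment spherical neurons — a pyramidal cell (volume
1.4368·10⁻⁹ cm³) and a fast-spiking GABAergic interneuron (2/3 of that
volume) — share an extracellular compartment; the total
intracellular/extracellular volume ratio is β₁ = 4.  Units throughout:
mV, ms, mM, µA·cm⁻², mS·cm⁻², µF·cm⁻².

Pyramidal membrane mechanisms: fast-inactivating Na⁺ (m³h, Traub–Miles
rate functions), delayed-rectifier K⁺ (n⁴), Ca²⁺-activated K⁺ with Hill
half-activation 1 µM, separate Na⁺/K⁺/Cl⁻ leaks, KCC2 and NKCC1
cotransport, a glutamatergic autapse and an external glutamatergic drive
(each split half to Na⁺ and half to K⁺, reflecting equal AMPA
permeability), a GABA-A chloride synapse from the interneuron, and the
Na⁺/K⁺-ATPase.  A high-threshold Ca²⁺ current feeds the calcium pool only
(first-order extrusion, τ = 80 ms); its charge is deliberately omitted
from the voltage equation.  Interneuron mechanisms: fast-inactivating Na⁺
with instantaneous activation (m∞³h, Golomb fast-spiking kinetics: h is a
decreasing sigmoid at −58.3 mV, τ_n a product of two shifted sigmoids),
delayed-rectifier K⁺ (n²), Na⁺/K⁺ leaks, glutamatergic input and drive,
and the same pump law.  The interneuron carries no chloride pathway.

The pump is `ρ(v)·(Na/(Na+7.7))³·(K_o/(K_o+2))²` with
`ρ(v) = ρ₋₇₀·f(v)/f(−70)`, `f(v) = (1+tanh(a·v/(RT/F)+b))/2`,
ρ₋₇₀ = 30 µA·cm⁻², a = 0.39, b = 1.28: depolarization speeds the pump up.
`PumpParameters.scale_e` (default 1.0) scales the pyramidal pump density
relative to the interneuron's; it exists as a sensitivity knob for the
asymmetry between the two cells' ATPase expression and is not used by any
default protocol.

Every current appears in one voltage equation and in the matching
concentration equations through γ_e = 4.449·10⁻⁵ and γ_i = 5.093·10⁻⁵
mol·cm²·µC⁻¹·L⁻¹ (computed from the sphere geometry with R = 8314
mJ·K⁻¹·mol⁻¹, T = 309.15 K, F = N_A·e = 96 320 C·mol⁻¹ — the same rounded
constants from which the model's bookkeeping quantities derive).  Four
first integrals follow: Na_Σ = 185 mM, Cl_Σ = 142 mM, and
H₁ = C v_e − ([Na]_e+[K]_e−[Cl]_e)/γ_e,
H₂ = C v_i − ([Na]_i+[K]_i)/γ_i, pinned at the reference point
(−70 mV, Na 10, K 140, Cl_e 5, K_o 3.5, Na_o 145, Cl_o 130 mM).  The
default integration runs on the 14-variable reduction; the 18-variable
full state is kept as a cross-validation mode and is required when sodium
bath exchange (below) breaks conservation.  External input is a constant
glutamatergic conductance, never an additive current, precisely so that
these integrals survive stimulation.

Only extracellular potassium exchanges with a bath:
ε([K⁺]_o − 3.5 mM), ε = 5·10⁻⁴ ms⁻¹, a deliberately large coefficient
standing in for both diffusion and glial buffering.

### Mutation transforms

* `fhm3(p)`: g_Na,P,i = (p/100)·112.5, g_Na,FI,i = 112.5 − g_Na,P,i.  The
  persistent current is `g_P·m∞(v+8)³·(v−E_Na)` — the activation sigmoid
  evaluated 8 mV to the left and cubed, with no inactivation.  The
  multiplicative-factor reading of "(v+8)" is rejected as dimensionally
  incoherent; the shift matches the described leftward activation shift.
* `epileptogenic(s)`: g_Na,FI,i = s·112.5 (default s = 0.4, the
  heterozygous loss-of-function estimate), no persistent current.
* Both touch only the interneuron; pyramidal parameters are never
  modified.

## Initial conditions

Two resting configurations coexist, and the distinction matters:

* **Standard state** (`standard_state`): the reference concentrations
  above with gating at its −70 mV steady state.  This is the initial
  condition of every coupled protocol.  It is stationary on the
  sub-second timescale of an action potential (the residual intracellular
  sodium drift is ≈0.25 mM·s⁻¹, invisible in a voltage trace), and the
  slow relaxation it undergoes under stimulation — pump-dominated sodium
  dynamics with a time constant of tens of seconds — is part of the
  phenomenology the protocols probe: starting instead from the exact
  mathematical equilibrium (intracellular Na ≈ 5 mM in both cells) makes
  the pyramidal cell fire immediately rather than after the observed
  multi-second latency and shifts the epilepsy-scenario block onset from
  ≈12 s to ≈19 s.
* **Exact equilibria** (`find_rest_state`, `find_isolated_rest_state`):
  relaxation from the standard state followed by a Newton polish, to
  max |dy/dt| < 10⁻⁹.  At equilibrium every net ionic current vanishes
  and [K⁺]_o = K_bath exactly.  The isolated-interneuron protocols start
  from the isolated system's converged rest (the interneuron's slow
  variables do equilibrate there), with the pyramidal cell frozen at the
  standard values.

## Protocols

* **Spike counting**: local maxima exceeding 0 mV, maxima separated by a
  downward 0 mV crossing (implemented as contiguous supra-zero segments).
* **Rheobase**: bisection of the 0.4 s isolated step on g_D,i ∈ [0, 0.3]
  mS·cm⁻² to a bracket < 5·10⁻⁵, midpoint rounded to 10⁻⁴.
* **Half-width**: baseline = preceding inter-spike minimum; half level =
  midpoint of baseline and peak; width = time above that level, crossing
  times linearly interpolated.  The baseline choice is parameter-free but
  not unique; reported widths carry ≈15 % definitional slack.
* **Depolarization block**: a sliding 500 ms window qualifying iff its
  voltage range is < 5 mV and its final voltage lies in [−55, −20] mV;
  the onset is the *start* of the first qualifying window.  CSD
  initiation = the pyramidal cell meeting this criterion.
* **CSD threshold**: 13 bisection iterations on the common drive
  g ∈ [0, 0.3] (final bracket < 4·10⁻⁵); because the response can
  alternate between block and no-block near threshold, the result
  reports the smallest endpoint whose predicate is true together with
  the final bracket and both endpoint predicates.
* **Buffering variants**: `strong_K` sets ε = 0.1 ms⁻¹; `strong_Na` adds
  ε_Na([Na⁺]_o − Na_bath) with ε_Na = 0.1 ms⁻¹ and Na_bath the initial
  extracellular sodium.  The sodium term is an external exchange that
  breaks mass conservation by construction, so this mode always
  integrates the full 18-variable state.
* **Per-AP "action current" summaries** report the signed extremum, over
  the minimum-to-minimum window, of the net K⁺ and Na⁺ membrane
  currents; window means/integrals can be derived from the recorded
  traces.  These summaries are descriptive only — no published scalar is
  asserted against them, as their printed definition is ambiguous.

## Slow-fast dissection

[Na⁺]_i is the slow variable; the fast subsystem is (v_i, h_i, n_i) with
[Na⁺]_i clamped, [K⁺]_i derived from H₂ at the instantaneous voltage
(keeping that constraint exact), and [K⁺]_o, [Na⁺]_o frozen at their
values on the full isolated trajectory at the onset of its first
quiescent phase — the moment the trajectory actually reaches the fold, so
the one-parameter diagram is self-consistent with the trajectory overlaid
on it (freezing at stimulus onset instead moves the fold by ≈5 mM).
Equilibria come from multi-start Newton solves over v ∈ [−90, 0] mV with
central-difference Jacobians for stability; cycles from direct simulation
(500 ms transient, period via −20 mV upward crossings); the fold of
cycles and the Hopf point from bisection to 0.05 mM.  No continuation
software is used — adequate for a one-parameter diagram, at the cost of
not tracking unstable cycles.

With the default drive (0.3 mS·cm⁻²) the wild-type fast subsystem loses
its spiking cycle at [Na⁺]_i ≈ 28 mM and regains instability of the
depolarized state at ≈ 24 mM — a subHopf/fold-of-cycles hysteresis loop
producing bursting.  The loss-of-function variant loses the cycle earlier
and has no Hopf release: once captured, the interneuron stays silent.

## Numerics

RK4 with fixed dt = 0.01 ms (the fast-spiking upstroke is sub-millisecond;
halving dt moves spike times by < 0.1 ms over 1 s and leaves every
reported quantity within its stated tolerance).  Spike events are
detected between consecutive steps; the synaptic variable is set to 1 at
the end of the crossing step without step rejection, and the spike time
is logged by linear interpolation.  Recording default: every 10th step
(0.1 ms); feature-extraction protocols record every step.  The kernels
are numba-compiled and mirrored by pure-numpy reference implementations;
the test suite holds the two routes together at 10⁻¹² relative.
Non-finite states and non-positive concentrations abort integration with
the last valid time.  All computations are deterministic; no seeds exist
anywhere in the pipeline.

Problem sizes used by the shipped analyses: 0.4 s (isolated endpoints),
2.5 s (long input–output curves), 30 s (coupled scenarios), 13-iteration
bisections for thresholds.

## Synthetic-data scope and limitations

The model generates its own data; nothing is fitted to recordings.  What
passing tests show is therefore internal: conservation laws hold, the
two state representations agree, the protocols implement their stated
definitions, and the printed-value benchmarks of the modelled circuit
reproduce.  They do not show that real cortical tissue behaves this way:
the circuit has two point neurons, no morphology, no network, no CSD
propagation, no cell swelling, fixed temperature, deterministic gating,
and a single lumped extracellular pool whose potassium clearance absorbs
all glial complexity into one rate constant.

Known limitation: at the default drive the migraine variant's CSD
boundary sits slightly above p_Na,P = 15 % (between 15 and 20 %), so the
15 % scenario does not ignite CSD here although 20 % does (block at
≈4.4 s), strong sodium buffering ignites it at 15 % (≈5.0 s), and halving
potassium clearance ignites it at 15 % (≈4.0 s).  The corresponding
regression test is kept red rather than weakened, as an honest marker of
this boundary displacement; every surrounding structural result
(threshold monotonicity, buffering dichotomy, latency ordering, the
trichotomy of scenarios) reproduces.
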