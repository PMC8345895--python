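# navmicro

A conductance-based model of a two-neuron cortical microcircuit — one
glutamatergic pyramidal cell and one fast-spiking GABAergic interneuron —
with fully dynamic Na⁺/K⁺/Cl⁻ ion concentrations, built to study how
mutations of the Na_V1.1 (*SCN1A*) sodium channel in GABAergic neurons
produce two opposite pathologies:

* **Gain of function** (hemiplegic-migraine type 3, FHM-3): part of the
  interneuron's sodium conductance becomes a *persistent* (non-inactivating)
  current.  Each action potential then moves more Na⁺ and K⁺ across the
  membrane, extracellular potassium accumulates, and the pyramidal cell can
  be driven into the sustained depolarization block that marks the
  initiation of **cortical spreading depolarization** (CSD), the substrate
  of migraine aura.
* **Loss of function** (epileptogenic, e.g. Dravet syndrome): the
  fast-inactivating conductance is reduced.  The interneuron itself becomes
  prone to depolarization block; when it falls silent the pyramidal cell
  loses its inhibitory restraint and its firing rate jumps — a pro-epileptic
  hyperexcitability mechanism that requires no change in interneuron firing
  rate beforehand.

The package is aimed at computational neuroscientists who want a desk-scale,
fully reproducible implementation of this microcircuit: the ODE system, the
mutation transforms, the stimulation protocols, and the slow-fast
bifurcation analysis that explains interneuron bursting versus permanent
block.

## The model

Eighteen state variables: membrane potentials \(v_e, v_i\), Hodgkin–Huxley
gating variables (Traub–Miles kinetics for the pyramidal cell, Golomb
fast-spiking kinetics for the interneuron), synaptic variables \(s_e, s_i\)
with spike-triggered resets, and the ion concentrations
\([\mathrm{K}^+]_{e,i,o}\), \([\mathrm{Na}^+]_{e,i,o}\),
\([\mathrm{Cl}^-]_{e,o}\), \([\mathrm{Ca}^{2+}]_e\) (subscripts: *e*
pyramidal, *i* interneuron, *o* extracellular).  Every transmembrane current
— voltage-gated Na⁺/K⁺ channels, leaks, a Ca²⁺-activated K⁺ current, the
Na⁺/K⁺-ATPase (Hill kinetics in [Na⁺]ᵢₙ and [K⁺]ₒ with a voltage-dependent
maximal rate), the KCC2 and NKCC1 cotransporters, glutamatergic and
GABAergic synapses — appears both in the voltage equation and in the
matching concentration equations, e.g.

$$C\frac{dv_e}{dt} = -I_{\mathrm{Na},e} - I_{\mathrm{K},e} - I_{\mathrm{Cl},e},
\qquad \frac{d[\mathrm{Na}^+]_e}{dt} = -\gamma_e I_{\mathrm{Na},e},$$

with \(\gamma = S/(10^3\,\mathrm{Vol}\,F)\) the current-to-concentration
factor of each (spherical) cell.  This bookkeeping yields four first
integrals — total sodium, total chloride, and one voltage–concentration
relation per neuron — used to reduce the system to 14 equations.
Extracellular potassium alone exchanges with a bath,
\(I_{\mathrm{K,diff}} = \varepsilon([\mathrm{K}^+]_o - K_{\mathrm{bath}})\),
standing in for diffusion and glial buffering.  Reversal potentials are
recomputed from the instantaneous concentrations at every step.

Mutations touch exactly two parameters: the FHM-3 transform converts a
fraction \(p_{\mathrm{Na,P}}\) of the interneuron's total sodium conductance
(112.5 mS·cm⁻², held constant) into a persistent current with an 8 mV
left-shifted activation, and the epileptogenic transform scales the
fast-inactivating conductance to 40 % of its default.

Integration is classical fixed-step RK4 (default dt = 0.01 ms, numba
compiled) with linear-interpolation spike timestamps.

## Worked example

```python
import navmicro as nm
from navmicro.protocols import count_overshooting_spikes, rheobase

# excitability of the isolated interneuron, with and without mutation
print(rheobase(nm.MutationSpec.wild_type()))   # 0.0052  mS/cm^2
print(rheobase(nm.MutationSpec.fhm3(20.0)))    # 0.0004  mS/cm^2

# a 0.4 s step of g_D,i = 0.3 mS/cm^2 from rest, migraine variant
cfg = nm.SimulationConfig(mode="isolated_interneuron",
                          mutation=nm.MutationSpec.fhm3(20.0),
                          g_D_i=0.3, duration=400.0, record_stride=1)
trace, events = nm.integrate(cfg)
print(count_overshooting_spikes(trace, "gabaergic"))  # 48
print(round(trace["K_o"][-1], 2), round(trace["Na_o"][-1], 1))  # 8.57 147.5
```

The persistent current barely changes the spike count (48 versus 49 for the
wild type) yet more than doubles the potassium released per action
potential: [K⁺]ₒ ends at 8.57 mM instead of 5.87 mM, and [Na⁺]ₒ drops to
147.5 mM instead of 150.7 mM.  That dissociation — unchanged firing, much
larger ion fluxes — is the core mechanism by which the migraine variant
promotes CSD.

The same API drives the coupled circuit:

```python
from navmicro.protocols import detect_depolarization_block
cfg = nm.SimulationConfig(mode="coupled",
                          mutation=nm.MutationSpec.epileptogenic(0.4),
                          g_D_e=0.3, g_D_i=0.3, duration=30_000.0)
trace, events = nm.integrate(cfg)
blk = detect_depolarization_block(trace, "gabaergic")
print(round(blk.onset_ms / 1000.0, 2))   # 12.22  (seconds)
```

A command-line interface mirrors these protocols
(`navmicro rheobase`, `navmicro io-curve`, `navmicro csd-threshold`,
`navmicro block-onset`, `navmicro dissect`, `navmicro simulate`, …).

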