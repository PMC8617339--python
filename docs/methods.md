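# Methods

This document describes the model implemented by `cardiomech`: a coupled
electromechanical model of a human induced-pluripotent-stem-cell-derived
cardiomyocyte (hiPSC-CM), consisting of a Paci-family ionic action-potential
model strongly coupled to a Rice-type myofilament cross-bridge contractile
element (CE) reparametrized for hiPSC-CMs.

## 1. State variables and units

The coupled system has 32 ODE states integrated as one vector
(`cardiomech.layout.STATE_FIELDS`):

* 22 ionic states: membrane potential `Vm` (V), SR and cytosolic Ca²⁺
  (`CaSR`, `Cai`, mM), cytosolic Na⁺ (`Nai`, mM), and 18 Hodgkin-Huxley
  gating/adaptation variables (L-type Ca²⁺ gates `d, f1, f2, fCa`; fast
  Na⁺ `h, j, m`; funny current `Xf`; transient outward `q, r`; late Na⁺
  `mL, hL`; SR release `RyRa, RyRo, RyRc`; delayed rectifiers
  `Xr1, Xr2, Xs`).
* 10 contractile states: regulatory-unit/cross-bridge fractions
  `N, XBprer, XBpostr` (with `N_NoXB` for the non-cycling population),
  mean cross-bridge strains `xXBprer, xXBpostr` (µm), Ca²⁺-troponin
  occupancies `TRPNCaL, TRPNCaH`, sarcomere length `SL` (µm), and the
  time integral of net normalized force `intf`.

Time is in seconds throughout the core; currents are in A/F;
concentrations in mM. The API reports `V` in mV.

## 2. Ionic model

The electrophysiology is the 2020-generation Paci-family hiPSC-CM model:
13 membrane currents (`I_Na`, `I_NaL`, `I_CaL`, `I_f`, `I_K1`, `I_Kr`,
`I_Ks`, `I_to`, `I_NaCa`, `I_NaK`, `I_pCa`, `I_bNa`, `I_bCa`), SERCA
uptake, SR leak, and a three-gate (adaptation/open/close) SR release
channel. Fixed conditions: 37 °C, [Na⁺]ₒ = 151 mM, [K⁺]ₒ = 5.4 mM,
[Ca²⁺]ₒ = 1.8 mM, fixed [K⁺]ᵢ. The model beats spontaneously; pacing is
an optional rectangular current pulse.

Cytosolic and SR Ca²⁺ use instantaneous-buffer factors
`β = 1/(1 + B·K/(Ca+K)²)`. Every maximal conductance also carries a
dimensionless per-channel multiplier (`s_Na`, `s_CaL`, ...) used by the
drug and variant protocols; multipliers must be positive so that scaling
identities compose exactly.

Because the source publication chain does not restate the full equation
set, a small set of uncertain maximal-rate constants was calibrated
against the published spontaneous AP/CaT biomarker table of the
uncoupled and coupled model columns (every constant's origin is recorded
in the provenance tags emitted in each run manifest). The equations
themselves are the standard Paci-family formulations.

## 3. Contractile element

The CE is the mean-field cross-bridge model of the Rice-2008 family:

* **Thin-filament overlap.** Single-overlap fraction of the thin filament
  `SOVFthin(SL)` built from filament geometry (thick 1.65 µm, bare zone
  0.1 µm, thin 1.2 µm), used both to gate force and to weight apparent
  troponin binding.
* **Ca²⁺-based activation.** Low/high-affinity troponin occupancies
  `TRPNCaL/H` with on-rate `Kon` and off-rates `KoffL/H` scaled by a
  species modifier `Koffmod`. The regulatory signal
  `permtot = sqrt(1/(1 + (perm50/Tropreg)^nperm))` sets the
  nonpermissive↔permissive rates (`kn_p`, `kp_n`).
* **Cross-bridge cycle.** Four-pool cycle N ↔ P ↔ XBprer ↔ XBpostr with
  rates `fapp, gapp, hf, hb, gxb`, strain-dependent factors on `hf`, `hb`
  and `gxb`, and species scaling `xbmodsp`. Mean strains `xXBprer/postr`
  follow their own ODEs with the power-stroke size `x_0 = 7 nm`.
* **Force and SL dynamics.** Normalized active force is the
  strain-weighted, overlap-weighted sum of the strongly-bound fractions,
  normalized by the maximal duty fractions; absolute tension is
  `kxb · F_active` (kPa) with `kxb = 12 kPa`. Free-running shortening
  integrates `dSL/dt = (intf + (SL₀ − SL)·visc)/mass`; an
  isosarcometric mode clamps SL.
* **Passive force.** Titin (signed power law around the rest length
  `SL₀ = 1.9 µm`) plus collagen, combined by a piecewise law in the
  tissue's cardiomyocyte percentage `ctn`: pure titin at `ctn = 100`,
  and two exponential mixing branches for `100 > ctn ≥ 70` and
  `70 > ctn > 0` that represent non-cardiomyocyte tissue components.

The hiPSC reparameterization (relative to the rabbit-data baseline)
raises `Kon`, lowers `KoffL`, `Koffmod`, `perm50`, `kp_n`, `mass` and
`kxb`, and raises `nperm` and `kn_p`; the baseline set is available as
`CEParameters.rice_baseline()`.

## 4. Electromechanical coupling

The CE senses `Cai` through troponin binding. Feedback onto the Ca²⁺
balance ("strong coupling", the default) subtracts the **apparent**
myofilament binding flux from the cytosolic balance:

```
TropApr = (1 − SOVFthin)·TRPNCaL + SOVFthin·(FrSBXB·TRPNCaH + (1 − FrSBXB)·TRPNCaL)
J_CaBMyo = [Troponin] · d(TropApr)/dt,   [Troponin] = 70 µM
dCai/dt ← dCai/dt − β(Cai)·J_CaBMyo
```

where `FrSBXB` is the strongly-bound cross-bridge fraction normalized by
the maximal duty fractions, and `d(TropApr)/dt` is the exact product-rule
expansion (including moving-overlap terms). `J_CaBMyo` is biphasic over
a beat — positive (Ca²⁺ to the myofilament) during the CaT upstroke,
negative during relaxation — and integrates to zero over a steady cycle.

"Weak coupling" drives the CE feed-forward with no feedback; with the CE
disabled entirely the ionic trajectory is bit-identical to the
standalone ionic model at equal solver settings.

An optional variant additionally removes the troponin share from the
static cytosolic buffer (`Buf_C` 0.25 → 0.18 mM;
`ModelParameters.buffer_troponin_subtraction=True`). It is **off** by
default: the dynamic troponin's effective dissociation constant
(`KoffL·Koffmod/Kon` = 1.6 µM) is weaker than the static buffer's
(1.0 µM), and at hiPSC force levels the high-affinity sites barely
engage (`FrSBXB` ≈ 0.01), so the variant makes the feedback *increase*
the CaT peak; only the default flux-subtraction form reproduces the
published negative feedback effect (CaT peak ≈ −20%, tension ≈ −52%
versus weak coupling).

## 5. Protocols

* **Spontaneous / paced runs** (`protocols.run`): settle + record phases,
  uniform output sampling, per-beat steady-state criterion (consecutive
  APD₉₀ change < 1 ms and CaT-peak change < 1%), EAD and
  aftercontraction annotation. Paced mode integrates stimulus-on/off
  sub-segments exactly.
* **Coupling-feedback study** (`coupling_feedback_study`): paired
  strong/weak runs; reports percent change of CaT peak and of peak
  active tension.
* **Drugs** (`drugs` module): Hill pore-block multiplier
  `1/(1 + (D/IC₅₀)^h)` and saturating agonist multiplier
  `1 + A_max·D^h/(D^h + EC₅₀^h)` applied to per-channel conductance
  multipliers; a shipped table provides a multichannel Ca²⁺-channel
  blocker (verapamil) and an L-type agonist (Bay-K 8644).
* **Arrhythmia protocol** (`ead_protocol`, `find_ead_variants`):
  conductance-scaled variants (factors in [0.5, 2]) under fractional
  `I_Kr` block; EADs detected as sustained depolarizing deflections
  during phase-2/3 repolarization (after the AP peak, before the first
  crossing of the 90%-repolarization level), aftercontractions as
  secondary tension peaks between the main twitch peak and the next
  upstroke, above a 0.5%-of-amplitude prominence floor (simulated
  traces are noiseless; the floor only rejects solver ripple).
* **Tissue-composition sweep** (`ctn_sweep`): mechanics versus `ctn`
  with values normalized to the 70% run.

## 6. Biomarkers

AP: APA, MDP, CL, dV/dt_max, APD₁₀/₃₀/₉₀ (measured from activation to
x% repolarization of the amplitude relative to MDP), triangulation.
CaT: duration (10%–10%), rise times (10%→peak, 10%→50%, 10%→90%), decay
time 90%→10%, per-beat normalized. Mechanics: fractional shortening
(ΔSL/diastolic SL × 100), RT₂₅/₅₀/₈₀ from peak contraction, peak tension,
peak contraction/relaxation velocities. All biomarkers average the last
3 steady-state beats by default.

## 7. Sensitivity analysis

One-at-a-time ±15% perturbations of the CE constants. For biomarker `b`
and parameter `p`: `D± = (b(p·(1±0.15)) − b₀)/b₀·100`,
`S = (D₊ − D₋)/0.3`, and `r = S/max|S|` per biomarker row. Failures of
individual perturbed runs are recorded (NaN) rather than aborting the
scan.

## 8. Numerics

The full right-hand side is a single scalar-arithmetic kernel compiled
with numba (`engine.py`; pure-NumPy fallback if numba is unavailable).
Integration uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e-6,
atol 1e-9 by default. Pre-equilibrated limit-cycle states for the
standard protocol/coupling combinations are shipped as JSON
(`cardiomech/states/`) and regenerated by
`scripts/make_steady_states.py`. Runs are deterministic: identical
configuration and initial state give identical output.

## 9. Verification strategy

Unit oracles are independent of the integration path wherever possible:
an algebraic closed-form solution of the CE fixed point (valid because
the strain ODEs force the steady strains to 0 and `x_0`) validates the
dynamic core to ~1e-13; the apparent-binding product rule is checked by
integrating the derivative against the directly evaluated composite
occupancy; synthetic Ca²⁺/AP/twitch waveforms with known analytic
biomarkers validate the extraction; drug identities (D=0 → 1,
D=IC₅₀ → 0.5) and channel-scaling composition are checked exactly.
Acceptance criteria are re-derived at run time by
`scripts/acceptance.py` and mirrored one-per-test in
`tests/test_acceptance.py`.

Known discrepancy: the paced-mechanics indices (RT₅₀ at 1 Hz, fractional
shortening and RT₂₅ at 1.5 Hz) exceed their published single-cell targets
(181 vs 161 ms, 4.1 vs 1.9 %, 96 vs 89 ms respectively) and their
acceptance tests fail honestly. The ratio of the paced twitch to the
spontaneous twitch is ~0.75 for every ionic parameterization that
reproduces the spontaneous column and peak tension, whereas the published
paced values imply ~0.4; no documented configuration (ionic calibration,
RyR gating variants, afterload) satisfies the paced targets jointly with
the in-band spontaneous criteria, so the spontaneous column was kept and
the discrepancy is reported rather than tuned around.
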