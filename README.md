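# cardiomech

Coupled electromechanical model of a human induced-pluripotent-stem-cell-derived
cardiomyocyte (hiPSC-CM): a Paci-family ionic action-potential model strongly
coupled to a Rice-type myofilament cross-bridge contractile element (CE)
reparametrized for hiPSC-CMs. The package simulates spontaneous and paced
electromechanics, drug effects, arrhythmia (EAD/aftercontraction) protocols,
engineered-heart-tissue composition sweeps, and local parameter sensitivity,
and extracts the standard AP / Ca²⁺-transient / mechanical biomarkers.

See [docs/methods.md](docs/methods.md) for the model description and
verification strategy.

## Quick start (Python API)

```python
from cardiomech.protocols import ProtocolConfig, run

# spontaneous beating, strong electromechanical coupling (the default);
# starts from a shipped pre-equilibrated limit-cycle state
res = run(ProtocolConfig(mode="spontaneous", settle=30.0, record=12.0))
b = res.biomarkers()
print(f"APA  {b.APA:6.1f} mV     MDP {b.MDP:6.1f} mV    CL {b.CL:6.0f} ms")
print(f"APD90 {b.APD90:5.0f} ms     dV/dt_max {b.dVdt_max:4.1f} V/s")
print(f"peak tension {b.peak_tension:.4f} kPa")
```

produces (deterministically)

```
APA    106.0 mV     MDP  -75.5 mV    CL   1649 ms
APD90    406 ms     dV/dt_max 23.8 V/s
peak tension 0.0548 kPa
```

The time series (`res.data`) holds V, Cai, CaSR, Nai, all 13 membrane
currents, SL, active/passive force, tension, and the myofilament Ca²⁺
flux `JCaBMyo` on a uniform grid.

### Coupling-feedback study

Strong coupling subtracts the apparent Ca²⁺-troponin binding flux from
the cytosolic Ca²⁺ balance; weak coupling drives the CE feed-forward:

```python
from cardiomech.protocols import ProtocolConfig, coupling_feedback_study
strong, weak, deltas = coupling_feedback_study(
    ProtocolConfig(mode="spontaneous", settle=30.0, record=12.0))
print(deltas)
# {'cat_peak_pct': -19.58, 'tension_peak_pct': -51.58}
```

i.e. the feedback lowers the Ca²⁺-transient peak by ≈ 20% and the
active-tension peak by ≈ 50%.

### Drugs

```python
from cardiomech.drugs import load_drug_table
from cardiomech.protocols import ProtocolConfig, run

table = load_drug_table()                      # packaged CSV
scaling = table["verapamil"].multipliers(90.0)  # dose in nM
res = run(ProtocolConfig(settle=30.0, record=12.0, channel_scaling=scaling))
```

### Sensitivity

```python
from cardiomech.sensitivity import oat_sensitivity
# ±15% one-at-a-time CE-parameter scan; see `cardiomech sensitivity --help`
```

## Command-line interface

```bash
cardiomech simulate  --set protocol.record=12 --out-dir out/spont
cardiomech feedback  --out-dir out/feedback
cardiomech drug      --name verapamil --dose-nm 90 --out-dir out/vera
cardiomech drug      --list            # list drugs in the packaged table
cardiomech ead       --variant SET_A --ikr-block 0.95 --out-dir out/ead
cardiomech ctn-sweep --values 25,50,70,90,100 --out-dir out/ctn
cardiomech sensitivity --out-dir out/sens
cardiomech make-cat  --amplitude 2e-4 --out-dir out
```

Every run writes a CSV time series with a units sidecar, a biomarker
JSON, and a manifest with the fully resolved configuration and a
provenance tag for every numeric constant. Any constant is overridable
via `--config file.yaml` or `--set section.key=value`
(sections: `protocol`, `ionic`, `ce`, `tissue`).

## Acceptance quantities

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

recomputes the twelve headline quantities (spontaneous AP/CaT biomarkers,
paced mechanics at 1 and 1.5 Hz, spontaneous peak tension, and the
strong-vs-weak coupling deltas) at run time; `tests/test_acceptance.py`
checks each against its published target and tolerance band. The model is
fully deterministic — `--seed` is recorded but has no effect.

Known limitation: the three paced-mechanics indices (RT₅₀ at 1 Hz,
fractional shortening and RT₂₅ at 1.5 Hz) come out above their published
single-cell targets (181 vs 161 ms, 4.1 vs 1.9 %, 96 vs 89 ms) and those
three acceptance tests fail by design rather than being tuned around: the
spontaneous column, peak tension, and coupling deltas are all in band,
and no documented parameterization reproduces the published paced values
jointly with them (the paced twitch is ~0.75× the spontaneous twitch for
every calibration tried, where the published values imply ~0.4×).

## Repository layout

```
src/cardiomech/
  layout.py        flat state/parameter vector layout (single source of truth)
  engine.py        compiled ODE core (numba, NumPy fallback)
  parameters.py    parameter dataclasses + provenance tags
  ionic.py         ionic-model API (currents, rhs, state validation)
  contractile.py   CE API (overlap, forces, twitches, algebraic steady state)
  coupling.py      apparent troponin binding flux (strong coupling)
  drugs.py         Hill pore-block / agonist multipliers + drug table
  protocols.py     spontaneous/paced runs, EAD, ctn sweep, feedback study
  biomarkers.py    AP / CaT / mechanics biomarker extraction
  sensitivity.py   ±15% one-at-a-time sensitivity (D, S, r)
  synth.py         synthetic Ca2+ waveform generator
  io.py, cli.py    config loading, artifact writing, CLI
  states/          shipped pre-equilibrated limit-cycle states
scripts/
  acceptance.py           computes t1–t12 as JSON
  make_steady_states.py   regenerates the shipped states
tests/                    unit, property and acceptance suites
docs/methods.md           model description
```

## Reproducibility notes

* Identical configuration + initial state ⇒ identical output (no RNG in
  any simulation path; the EAD variant search uses an explicit seed).
* Solver: LSODA, rtol 1e-6, atol 1e-9; APD₉₀ moves < 0.01 ms when the
  tolerances are halved.
* A subset of ionic maximal rates was calibrated against the published
  spontaneous biomarker tables of the source model family (the paper
  chain does not restate the full equation set); every constant carries
  a provenance tag in the run manifest.
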