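# liposim

A simulator of thermosensitive liposomal doxorubicin delivery to a solid
tumour, coupling four submodels on a radially symmetric tumour +
normal-tissue geometry:

1. **Interstitial fluid flow** — steady Darcy flow driven by Starling
   transvascular filtration and lymphatic drainage, producing the elevated
   tumour interstitial fluid pressure (IFP) that suppresses convective drug
   delivery.
2. **Drug transport** — transient convection–diffusion–reaction equations
   for liposome-encapsulated, free, and protein-bound drug in the
   interstitium, with pore-model (Péclet-corrected) transcapillary exchange,
   protein binding kinetics, and saturable (Michaelis–Menten) cellular
   uptake/efflux feeding an intracellular compartment.
3. **Plasma pharmacokinetics** — a closed-form triexponential driver for a
   2-hour intravenous infusion, or, for liposomal delivery, a biexponential
   circulating-liposome pool plus free/bound plasma ODEs driven by
   heat-triggered release.
4. **Pharmacodynamics** — log-kill (Emax) tumour-cell survival with
   logistic proliferation/degradation turnover.

Two delivery modes are built in: `infusion` (2-hour constant-rate infusion
of free drug) and `liposome` (thermosensitive liposome bolus with one hour
of localized tumour hyperthermia at 42 °C starting 24 h after
administration, which triggers first-order drug release and transiently
increases vascular permeability).

## Quick start (Python)

```python
from liposim import default_config, simulate, summary

result = simulate(default_config("liposome"))   # full 48 h run, ~30 s
s = summary(result)
print(s["mean_ifp_tumour_pa"])     # 1524.7  (Pa)
print(s["mean_ifp_normal_pa"])     # 46.3    (Pa)
print(s["peak_C_i_tumour"])        # 1.47e-12 (kg per 10^5 cells)
print(s["min_survival_tumour"])    # 0.853 at ~32 h
```

`simulate` returns a `SimResult` holding the steady flow field, spatial-mean
time series of every concentration field in both regions, the plasma
series, regional survival fractions, a cumulative drug-mass budget, and the
final per-cell state. `result.save(outdir)` writes `results.csv`,
`plasma.csv`, `survival.csv` and `flow.csv`.

All physical inputs live in typed, validated dataclasses
(`SimulationConfig`); every default is in SI units (kg, m, s, Pa).
Configurations round-trip through YAML:

```python
from liposim import load_config
cfg = load_config("my_run.yaml")   # absent keys fall back to defaults
```

```yaml
# my_run.yaml — flat dotted keys or nested mappings both work
mode: liposome
heating.t_on: 86400.0
pk.vt_over_vb: 0.02
numerics:
  n_tumour: 250
  n_normal: 100
```

## Quick start (CLI)

```bash
liposim run --mode liposome --out runs/lipo       # full simulation → CSV + JSON
liposim run --mode infusion --out runs/inf
liposim compare runs/inf runs/lipo                # side-by-side scalar metrics
liposim mesh-check --factor 2 --mode infusion     # grid-convergence report
liposim fit-release release_data.csv              # fit (k_rel, Rc) to a curve
```

## Testing

```bash
python -m pytest -q tests/
```

The suite mixes hand-derived oracles (heat-kernel diffusion, matrix-
exponential binding equilibrium, closed-form log-kill survival, mass
conservation to 1e-8 over 1000 implicit steps, release-rate parameter
recovery) with property-based tests (hypothesis) and full-resolution
48-hour acceptance runs. Expect a few minutes of wall time; the long runs
are shared via session-scoped fixtures.

## Package layout

```
src/liposim/
  config.py            parameter dataclasses, YAML I/O, validation
  grid.py              1D axisymmetric finite-volume grid, area-weighted means
  flow.py              steady Darcy/Starling IFP solve
  plasma.py            plasma pharmacokinetic drivers
  release.py           heating schedule, release kinetics, rate fitting
  transport.py         coupled transport stepper (the simulator core)
  pharmacodynamics.py  log-kill survival model
  metrics.py           AUC, summaries, mode comparison, mesh checks
  cli.py               click-based command line
docs/methods.md        model formulation, numerics, parameter provenance
scripts/acceptance.py  headline-target computation
```
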