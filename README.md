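# maokin — mechanism-based inactivation kinetics for MAO inhibitors

`maokin` models and analyzes the kinetics of mechanism-based (suicide)
inactivation of the flavoenzymes monoamine oxidase A and B by clinical
irreversible inhibitors (clorgyline, selegiline, pargyline,
tranylcypromine, phenelzine) and newer propargylamines (ASS234, F2MPA,
contilisant).  It is written for enzymologists and medicinal chemists who
need the full inference chain behind a k_inact/K_I table: simulate the
assays, fit them the way a kinetics lab would, and check every estimator
against the generating model.

## The kinetic scheme

A mechanism-based inactivator first binds reversibly, is then oxidized by
the enzyme, and the reactive product either leaves (like a substrate) or
attacks the FAD cofactor:

```
E + I  ⇌[k+1/k−1]  E·I  →[k+2]  E·I*  →[k+3]  E + P     (release)
                                 E·I*  →[k+4]  E–I      (covalent, dead)
```

The package integrates this network as an ODE system (µM, minutes) in
aerobic mode (released enzyme is instantly reoxidized and recycles) or
anaerobic mode (released enzyme stays reduced and inert), and implements
the standard derived quantities:

- reversible affinity `Ki = k−1/k+1`, measured by competitive
  initial-rate assays (IC50 with the Cheng–Prusoff relation
  `IC50 = Ki(1 + S/K_M)`, and a global Michaelis–Menten fit over a
  substrate × inhibitor grid);
- Kitz–Wilson analysis: preincubation–dilution time courses give
  pseudo-first-order rates `k_obs = −d ln(activity)/dt`, and the
  hyperbola `k_obs = k_inact·I/(K_I + I)` gives the limiting rate
  `k_inact = k+2·k+4/(k+2 + k+3 + k+4)`, the half-saturating
  concentration `K_I = Ki·(k+3 + k+4)/(k+2 + k+3 + k+4)` and the
  specificity constant `k_inact/K_I`;
- the partition ratio `r = k+3/k+4` (inactivator molecules oxidized and
  released per enzyme killed), estimated from long-incubation titrations:
  remaining activity falls linearly with the load ratio x = I₀/E₀ and the
  zero-activity intercept is `r + 1`;
- stopped-flow flavin spectral kinetics: reduction bleaches 456/495 nm
  while the propargylamine adduct absorbs near 410 nm; single/double
  exponential fits of the two channels separate the oxidation step from
  the adduct-forming step and classify the mechanism as
  concerted/oxidation-limited (equal rates) or sequential.

A preset library (`maokin.synthetic_data`) carries literature-anchored
microscopic rate sets per compound/enzyme pair and a deterministic noise
model, so every pipeline stage is testable without instrument data.

## Worked example

```python
import numpy as np
from maokin import get_preset, run_preincubation
from maokin.inactivation_assays import fit_dataset
from maokin.synthetic_data import default_inactivation_protocol

preset = get_preset("clorgyline", "MAO-A")
dataset = run_preincubation(preset.rates,
                            default_inactivation_protocol(preset))
fit = fit_dataset(dataset)
print(f"k_inact = {fit.k_inact:.2f} min^-1")
print(f"K_I     = {fit.K_I:.3f} uM")
print(f"k_inact/K_I = {fit.specificity:.1f} min^-1 uM^-1")
```

prints

```
k_inact = 17.90 min^-1
K_I     = 0.329 uM
k_inact/K_I = 54.4 min^-1 uM^-1
```

i.e. the simulated preincubation–dilution protocol, analyzed exactly as a
plate-reader experiment would be (log-linear k_obs fits, then the
rectangular hyperbola), recovers the clorgyline/MAO-A specificity
constant of 55 min⁻¹µM⁻¹ to about 1%.  The same round trip for the
partition ratio:

```python
from maokin import design_titration_grid, estimate_partition, titrate_to_completion

preset = get_preset("selegiline", "MAO-A")
tit = titrate_to_completion(preset.rates, 0.2,
                            design_titration_grid(360.0, 0.2))
print(f"partition ratio r = {estimate_partition(tit).r:.0f}")
# partition ratio r = 360
```

## Command line

The `maokin` entry point exposes the pipeline as subcommands:
`generate` (synthetic datasets + manifest), `simulate` (trajectory CSV),
`fit-ic50`, `fit-ki`, `fit-kitz-wilson`, `partition`, `spectra-sim`,
`spectra-fit`, and `report` (per-compound summary table).  For example:

```bash
maokin generate --preset clorgyline --enzyme MAO-A --seed 1 --outdir out/
maokin fit-kitz-wilson --input out/inactivation.csv --out out/kw.json
```

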