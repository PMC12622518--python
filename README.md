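# glusense

Analysis toolkit for ratiometric fluorescent glutarate biosensing. Glutarate
is a five-carbon dicarboxylate — a platform chemical, an endogenous
metabolite, and the diagnostic marker of glutaric aciduria. A
genetically encoded sensor built from the CsiR ligand-binding domain and a
circularly permuted YFP reports glutarate through its 405/488 nm excitation
ratio (R = F405/F488, emission 528 nm). `glusense` implements the
quantitative analyses such a sensor enables:

* **Thermal-shift screening** (`glusense.thermal`) — melting temperatures
  from DSF/FTS melt curves via the smoothed derivative maximum; ligands are
  binders when ΔTm > 2 °C against the no-ligand control.
* **Dose–response calibration and quantification**
  (`glusense.calibration`) — the Hill-type model

      R([G]) = Rmax + (Rmin − Rmax) / (1 + ([G]/Kd)^p)

  with ΔRmax = (Rmax − Rmin)/Rmin, curve inversion
  [G] = Kd·((R − Rmin)/(Rmax − R))^(1/p) for absolute quantification,
  blank + 3σ detection limits, cpSFYFP pH correction, and agreement
  statistics against a reference method such as HPLC.
* **Transporter kinetics** (`glusense.transport`) — sensor ratio time
  courses inverted to intracellular concentration trajectories, initial
  uptake rates, Michaelis–Menten fits (v = Vmax·S/(Km+S)), and
  inhibitor-panel classification (complete suppression by a protonophore
  such as CCCP ⇒ proton-coupled transport).
* **¹³C flux partitioning** (`glusense.flux`, `glusense.isotopes`) —
  natural-abundance correction of GC-MS isotopologue areas by non-negative
  least squares through an elemental correction matrix, and the flux split
  between the glutarate hydroxylation (CsiD→L-2-HG) and glutaryl-CoA
  dehydrogenation (GcdH) pathways by constrained mixing of boundary mass
  distribution vectors: obs ≈ f·H + (1−f)·D.
* **Synthetic data** (`glusense.simulate`) — seeded generators for every
  input format, with truth records, replacing raw instrument exports.

The model-fitting cores are scikit-learn estimators (`HillCalibrator`,
`MichaelisMentenEstimator`, `TmEstimator`, `NaturalAbundanceCorrector`,
`FluxPartitioner`) and compose with sklearn pipelines; module-level
functions wrap them for one-line use.

## Worked example

Simulate a calibration plate at the sensor's published characteristics
(Rmin = 1, Rmax = 7.46 i.e. ΔRmax = 646 %, Kd = 60.68 µM), refit it, and
quantify an unknown sample:

```python
import numpy as np
from glusense import (ScenarioConfig, gen_dose_response, fit_dose_response,
                      predict_ratio, quantify_samples)
from glusense.io import read_plate_measurements

df, truth = gen_dose_response(ScenarioConfig(seed=1))
fit = fit_dose_response(read_plate_measurements(df))
print(f"Kd = {fit.Kd_uM:.2f} uM, dRmax = {100*fit.delta_Rmax:.0f} %, "
      f"p = {fit.hill_p:.2f}")

# a sample measured in triplicate after 3:1 sample:sensor mixing
r = predict_ratio(fit, 75.0)            # ratio of a 75 uM well
est, = quantify_samples(fit, {"serum_A": [r, r, r]}, dilution_factor=4/3)
print(f"serum_A: {est.conc_uM:.1f} uM ({est.censoring})")
```

Output:

```
Kd = 64.18 uM, dRmax = 646 %, p = 0.99
serum_A: 100.0 uM (quantified)
```

The refitted Kd and ΔRmax sit within a few percent of the generating truth
(60.68 µM, 646 %); the 75 µM in-well ratio maps back to the 100 µM sample
concentration through the 4/3 mixing dilution.

The same flow runs from the shell:

```bash
glusense simulate --out sim/ --seed 1
glusense calibrate --in sim/dose.csv --out cal.json --seed 1
glusense flux --in sim/labeling.csv --out flux.json --seed 1
```

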