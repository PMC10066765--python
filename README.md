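# mrnapkpd

Translational population PK/PD modelling of an LNP-delivered dual-mRNA
enzyme-replacement therapy for propionic acidemia.

Propionic acidemia is caused by deficiency of propionyl-CoA carboxylase
(PCC).  A therapeutic consisting of lipid nanoparticles carrying the two
mRNAs that encode the PCC subunits restores hepatic enzyme activity;
treatment effect shows up as suppression of the circulating disease
biomarkers 2-methyl citrate (2-MC), 3-hydroxypropionate (3-HP) and the
propionyl/acetyl carnitine ratio (C3/C2).  This package implements the full
translational modelling chain used to take such a program from animal
pharmacology to first-in-human dose selection:

* **Structural model** — linear three-compartment mRNA disposition
  (dose → plasma₁ → tissue ⇄ plasma₂, elimination from tissue), which
  produces the characteristic *delayed* plasma Cmax; an effect compartment
  (rate *k*ₑ₀) driving linear synthesis of hepatic PCC protein with
  two-pool turnover (*k*_deg, *k*_q; biexponential decline, ≈7-day terminal
  half-life); and a direct sigmoidal Imax model per biomarker,

  level(p) = E₀ + base · (1 − Imax · pᵞ / (IC50ᵞ + pᵞ)),

  with suppressible pool `base` over a non-suppressible floor `E₀`.
* **Allometry** — clearances scale as CL·(WT/WT_ref)^θ with one exponent
  (Clα) shared by the plasma→tissue clearances CL₁₂, CL₃₂ and another
  (Clβ) by the tissue-side CL₂₃, CL₂₀; volumes scale linearly.  One model
  spans mouse (0.025 kg) to human (70 kg).
* **Population layer** — log-normal between-subject variability on CL₃₂
  and proportional residual error.
* **Estimation** — maximum marginal likelihood with the scalar random
  effect integrated out by adaptive Gauss–Hermite quadrature or the
  Laplace approximation; censored-likelihood (M3) handling of
  below-quantification records (the 3-HP assay LLOQ is 25 µM/L); %RSE from
  the inverse observed information; CWRES/PRED/IPRED diagnostics and
  visual predictive checks.
* **Translation** — allometric extrapolation to adult/pediatric weights and
  steady-state dose–response summaries with 90% population prediction
  intervals.

No animal-level data are public for this program, so the package ships a
synthetic-data generator (`mrnapkpd.synthetic`) that reproduces the
reported study designs — mice with single 1–2 mg/kg IV PK sampling to 48 h,
juvenile rats (N=19) and cynomolgus monkeys (N=16) dosed q2W×3 and sampled
to 96 h post dose, and 111 knockout mice with single-dose (0.2–2 mg/kg) and
q3W×4 PD follow-up over 12 weeks.  Every generating value is provenance-
tagged (`paper` / `calibrated` / `invented`); the generate → fit → compare
round trip is the package's central validation.

## Worked example

```python
import numpy as np
from mrnapkpd import DoseEvent, default_truth, simulate_pk

truth = default_truth()
wt = 0.025                                   # mouse, kg
times = np.array([0.083, 0.5, 1.0, 4.0, 24.0, 48.0])
conc = simulate_pk(truth.pk, wt, [DoseEvent(0.0, 2.0 * wt)], times)
print(np.round(conc, 1))
```

prints

```
[ 5165.5 21947.6 23754.3 18161.6  2748.8   285.2]
```

— plasma mRNA (ng/mL) after a 2 mg/kg bolus: the observed compartment is
empty at dosing and peaks near 1 h (≈23 750 ng/mL), the distribution-then-
redistribution signature, before clearing with elimination from tissue.

The `examples/` directory walks through each capability end to end:

| script | what it shows |
| --- | --- |
| `01_single_dose_pk.py` | delayed-Cmax disposition after an IV bolus |
| `02_protein_and_biomarkers.py` | enzyme expression, 7-day half-life, biomarker suppression and washout |
| `03_population_fit.py` | simulate-then-refit round trip with %RSE |
| `04_human_dose_response.py` | allometric human extrapolation and q3W dose–response table |

A thin CLI mirrors the pipeline for shell use
(`mrnapkpd generate / fit / vpc / translate / report`); every output gets a
manifest recording command, seed and package version.

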