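# plaqueprog

Spatial mixed-effects analysis of carotid plaque progression against
baseline mechanical stresses.

Serial carotid MRI follow-up studies measure plaque progression as wall
thickness increase (WTI, mm) at lumen nodes matched between a baseline
and a follow-up scan, and relate it to the baseline mechanical
environment: plaque wall stress (PWS, kPa) and flow shear stress (FSS,
dyn/cm²).  Because nodes on a vessel wall are spatially dependent,
ordinary regression is invalid.  This package implements the spatial
linear mixed-effects (LME) machinery for that setting, for
biostatisticians and vascular-mechanics researchers who want a tested,
reproducible reference implementation:

- **Single scan pair** — `y_ij = β₀ + β₁ x_ij + ε_ij` with an
  exponential isotropic variogram, `corr(ε_a, ε_b) = φ^s` (`s` =
  Euclidean distance, mm), fitted by REML with a Wald t-test on β₁;
- **Pooled per period** — `y_ijk = β₀ + β₁ x_ijk + b_k + ε_ijk` with
  Gaussian patient random intercepts `b_k ~ N(0, τ²)`, independent
  patients and patient-specific φ_k;
- **Dependence-adjusted correlation** — `r = β̂₁ · sqrt(var(x)/var(y))`,
  the Pearson analogue that remains valid under spatial dependence;
- **Permutation validation** — shuffling WTI breaks the association, so
  refitted p-values must be Uniform(0, 1) (KS-tested), evidencing
  type-I-error control at α = 0.05;
- **Sign bookkeeping** — each scan pair is classified P / N / NS
  (significantly positive / negative / non-significant) and patients are
  tracked for whether they keep one significant sign across periods;
- **Grounded synthetic cohorts** — a generator (16 patients, 38 scan
  pairs, 400–1000 matched nodes per pair) with known β₁, φ_k, σ², τ²,
  stress fields painted from thin-wall hoop stress and Poiseuille shear
  surrogates, and tissue mechanics from the modified Mooney–Rivlin model
  `W = c₁(I₁−3) + c₂(I₂−3) + D₁[exp(D₂(I₁−3))−1]` with packaged
  vessel / calcification / lipid / loose-matrix presets.

The package also ships the per-pair reference correlation tables of the
published 16-patient study this machinery models, and re-derives every
summary count in them from the raw (p, r) cells.

## Worked example

```python
import numpy as np
from plaqueprog import (CohortConfig, generate_cohort, extract_regression_arrays,
                        fit_single)

pairs, truth = generate_cohort(CohortConfig(seed=20240919))
pair = pairs["T1-T2"][0]
arrays = extract_regression_arrays(pair, "pws")
fit = fit_single(arrays.coords, arrays.x, arrays.y)
print(f"{pair.patient_id} {pair.period_label}: n={fit.n_obs}, "
      f"beta1={fit.beta1:.5f} (truth {truth.beta1}), phi={fit.phi:.2f}, "
      f"p={fit.p_value:.4f}, r={fit.r_adj:.4f}")
```

prints

```
P1 T1-T2: n=800, beta1=0.00546 (truth 0.002), phi=0.52, p=0.3872, r=0.1336
```

a weak positive WTI–PWS association on an 800-node pair: the slope
estimate has the right sign and order of magnitude (truth 0.002
mm/kPa), the fitted spatial correlation at 1 mm distance is 0.52, and
the dependence-adjusted r of 0.13 is not significant on this single
pair — spatial dependence leaves far fewer effective observations than
800 independent nodes would.

The numbered scripts under `analysis/` drive the full narrative:
`01` re-derives every count of the reference tables, `02` evaluates the
tissue mechanics and the shrink-stretch geometry rule, `03`–`06`
simulate a cohort, fit all 38 pairs and the pooled periods, run the
permutation uniformity check, and classify the resulting signs.  Each
writes its tables under `results/`.  The `plaqueprog` command exposes
the same stages (`generate`, `fit`, `permute`, `summarize`,
`reproduce-tables`, `material-curves`, `run`).

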