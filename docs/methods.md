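# Methods

## Problem setting

Serial carotid MRI follow-up studies quantify atherosclerotic plaque
progression as the wall thickness increase (WTI, mm) between a baseline
and a follow-up scan at lumen nodes matched across the two scans, and
ask whether progression correlates with the baseline mechanical
environment: plaque wall stress (PWS, the structural maximal principal
stress at the lumen wall at peak systole, kPa) and flow shear stress
(FSS, the tangential fluid stress on the lumen, dyn/cm²).  Nodes on a
vessel are not independent observations, so ordinary regression and
Pearson correlation are invalid; the analysis instead uses spatial
linear mixed-effects (LME) models.  This package implements that
statistical machinery end to end, together with a synthetic cohort
generator whose ground truth is known, so every stage is testable
without patient data.

## Geometry and registration

Each scan is idealised as a straight tube per branch: slices 2 mm apart
along the vessel axis (the MRI slice thickness), 100 lumen nodes per
slice evenly spaced in angle, the carotid bifurcation at slice 0 with
the common carotid artery (CCA) at negative and the internal carotid
artery (ICA) at positive slice indices.  Scans are registered by
aligning bifurcation slices; node correspondence is by (slice offset,
angular index).  Index matching is a package convention — the source
protocol registers at the bifurcation but does not state how angular
positions were anchored between scans; any deterministic anchoring
yields the same statistical structure.  Only matched CCA/ICA slices
enter a dataset (the bifurcation slice is excluded), and WTI is the
node-wise thickness difference.  Distances for the spatial correlation
are Euclidean distances between baseline-scan coordinates in mm, because
the model's errors attach to the baseline spatial configuration.

## Statistical models

Single scan pair (Wald test of no correlation, H0: β₁ = 0):

    y_ij = β₀ + β₁ x_ij + ε_ij,   corr(ε_a, ε_b) = φ^s(a,b),

with s the 3D Euclidean distance (mm) and φ ∈ (0, 1) the exponential
isotropic variogram parameter (correlation at 1 mm).  Pooled per-period
model over the K patients observed in that period:

    y_ijk = β₀ + β₁ x_ijk + b_k + ε_ijk,   b_k ~ N(0, τ²),

patients independent, each with its own φ_k, giving a block-diagonal
marginal covariance σ²R_k(φ_k) + τ²11ᵀ per patient.

Estimation is restricted maximum likelihood (REML).  β and σ² are
profiled out analytically; the remaining parameters are optimised on
transformed scales: the exponential range ρ = −1/log φ (so
R = exp(−D/ρ)) and the variance ratio γ = τ²/σ², both on log scales
with bounds ρ ∈ [10⁻³, 10⁴] mm and γ ∈ [10⁻⁸, 10³].  φ^s is very badly
scaled near 0 and 1; the log-range parameterisation is the standard
remedy.  The 1-D single-pair problem uses a deterministic 13-point
coarse grid over log ρ followed by bounded scalar refinement; the
pooled problem uses L-BFGS-B from three fixed starting points, keeping
the best optimum.  All likelihood evaluations use Cholesky whitening
per block — never explicit inversion — and are validated against dense
explicit-inverse oracles to 1e-8 in the test suite.

No nugget term is included: the correlation model is pure φ^s, an
exact-fidelity choice with the nugget left as an extension point.
Coincident nodes make R singular and raise an error (an explicit
deterministic jitter is the caller's remedy).  Degrees of freedom for
the Wald t-test: n − 2 for the single model, N − K − 1 for the pooled
model (the level-1-covariate convention of standard mixed-model
software); at the hundreds of nodes typical here p-values are
insensitive to this convention.  The significance level is α = 0.05
two-sided throughout.

The dependence-adjusted correlation coefficient is

    r = β̂₁ · sqrt(var(x) / var(y)),

with plain sample variances (ddof = 1) — the literal Pearson-analogue
reading.  When the errors are independent β̂₁ is the OLS slope and r
reduces exactly to Pearson's r; `fit_single(..., phi=0.0)` exposes that
independence limit explicitly.

## Permutation validation

Randomly permuting the WTI values over nodes (globally for a single
pair, within patient blocks for pooled data — both scopes exposed, the
source procedure does not specify) breaks any WTI–stress association,
so refitted p-values should be Uniform(0, 1).  The report carries the
p-values, a one-sample Kolmogorov–Smirnov test against uniformity, and
the empirical rejection rate at 0.05.  Default scale is reduced (200
nodes, 200 permutations) for runtime; full scale is a config choice.
Refits that fail are counted and excluded; more than 5% failures voids
the report.

## Mechanical surrogates

The tissue model is the modified Mooney–Rivlin strain-energy density
W = c₁(I₁−3) + c₂(I₂−3) + D₁[exp(D₂(I₁−3))−1] with the four packaged
presets (kPa): vessel/fibrous cap (36.8, 0, 14.4, 2), calcification
(368, 0, 144, 2), lipid core (2, 0, 2, 1.5), loose matrix
(18.4, 0, 7.2, 1.5); c₂ = 0 for all tissues but the term is kept so the
form is complete.  Uniaxial incompressible Cauchy stress follows as
σ = 2(λ² − λ⁻¹)(∂W/∂I₁ + λ⁻¹ ∂W/∂I₂) and is verified against numerical
differentiation of W along the uniaxial path.

The no-load starting geometry applies 9% axial shrink (so a 10% axial
stretch restores in vivo length) and a prescribed lumen shrink, with
the outer radius solved from exact wall-volume conservation.  The full
pressurise-and-match calibration loop of an FSI solver is out of scope;
volume conservation alone reproduces the reported behaviour — for
representative diseased-carotid rings (lumen radius 3–4.5 mm with wall
thickness growing with calibre, 0.8–1.5 mm) an 8–12% lumen shrink
implies a 2.2–5.3% outer-wall shrink.  Pairing thick walls with large
lumens is deliberate: the implied outer shrink dips below 1% only for
the atypical combination of the thickest wall on the smallest lumen at
the smallest lumen shrink, a corner the conservation rule alone cannot
reproduce without the pressurisation step.

PWS and FSS fields on node grids are closed-form surrogates, labelled
as such everywhere: thin-wall hoop stress P·r/h with local wall
thickness h (kPa) and Poiseuille wall shear 4μQ/(πr³) (converted to
dyn/cm²), modulated by seeded smooth angular/axial harmonics
(amplitude 0.15 by default) standing in for plaque irregularity.
Defaults: P = 16 kPa (~120 mmHg systole), μ = 0.0035 Pa·s, Q = 6 ml/s.
These give PWS of tens of kPa and FSS of ~3–17 dyn/cm², the magnitude
ranges relevant to the cut-offs used in this literature.

## Synthetic cohorts

The generator emulates the study conditions: 16 patients, scans per
patient mixed 7×4 + 8×3 + 1×2 (38 consecutive scan pairs in periods
T1-T2, T2-T3, T3-T4), 4–10 matched CCA/ICA slices so each pair carries
400–1000 matched nodes.  WTI is drawn from the pooled generative model
with defaults β₀ = 0.1 mm, β₁ = 0.002 mm/kPa (PWS) or −0.005 mm per
dyn/cm² (FSS), σ² = 0.04 mm², τ² = 0.01 mm², and per-patient φ_k spread
over 0.6–0.9.  These choices put the dependence-adjusted r of a typical
pair in the 0.05–0.3 magnitude band (median |r| ≈ 0.08 at the default
seed) — the realistic weak-correlation regime.  One predictor is active
per generated cohort (config `predictor`); the other painted field is
carried as an inert column.  The per-patient random intercept is drawn
per scan pair, matching what the per-period pooled fit sees.  Baseline
wall thickness is a smooth harmonic field clipped to [1.0, 2.6] mm;
follow-up thickness is baseline plus WTI, floored at 0.05 mm to keep
thickness positive (at default noise the floor binds with probability
~1e-6 per node).  A single root seed streams per-patient sub-seeds via
`numpy.random.SeedSequence.spawn`, so (config, seed) fully determines a
cohort.

What the generator does not emulate: plaque biology (lipid cores,
hemorrhage, statin effects), lumen remodelling (radii are fixed over
scans), FSI-consistent stress fields, or measurement/segmentation
error.  Passing tests therefore demonstrate that the statistical
machinery is correct under its own assumptions, not that those
assumptions hold in real carotids.  One visible consequence: the
surrogate stress fields are smooth low-order harmonics and therefore
partially collinear with the smooth spatial error field, so per-pair
significance at default settings is sparser than in the real study even
though the r magnitudes match.

## Problem sizes used in the checks

The heavier validation suites run at deliberately moderated sizes:
parameter recovery uses 100 replicates of 4-patient cohorts with 150
nodes each (600 total, within the per-pair range); the null-calibration
check uses 200 single fits at 150 nodes; permutation uniformity uses 20
seeded runs of 60 permutations at 120 nodes.  Pooled per-period fits in
the analysis scripts subsample to 200 nodes per patient, a tractability
choice for the (K+1)-parameter REML optimisation that leaves the
per-pair fits untouched.

## Known limitations

- No nugget, no anisotropy, no non-exponential variograms, one
  predictor at a time, no random slopes — matching the model family
  analysed, with extension points noted in the code.
- Pooled estimates after patient reordering agree only to optimizer
  tolerance (~1e-5 relative), not machine precision: the restricted
  likelihood is exactly block-symmetric but finite-difference L-BFGS-B
  paths are order-dependent.
- The reference-table stage reproduces published per-pair (p, r) cells
  and everything derived from them; the per-pair values themselves and
  the pooled "All"-row statistics require the original patient data and
  are out of reach by construction.
- The two published summary figures for patients changing the FSS
  correlation sign disagree (12/75% vs 14/87.5%); the tables imply 14,
  and the report surfaces all three numbers rather than resolving the
  discrepancy.
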