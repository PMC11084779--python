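# Methods

## The screening problem

Superior airway space narrowing (SASN) and reduced superior airway volume
(RSAV) are defined on three-dimensional imaging: SASN as a minimal axial
airway cross-sectional area `A_min < 80 mm²`, RSAV as a posterior airway
volume `V_PAS < 12 cm³` between the axial planes through the posterior
nasal spine (Pns) and the hyoid (Hy). Both inequalities are strict; the
thresholds are configurable (`AnalysisConfig.amin_cut`, `vpas_cut`).

The package connects these 3D outcomes to what a lateral cephalometric
X-ray can show: it measures the parameters, runs the comparative and
correlational statistics, builds stepwise regression models predicting
`A_min`/`V_PAS` from 2D parameters, and converts each predictor into a
three-zone triage rule (classify positive / refer to 3D imaging / classify
negative).

## Airway morphometry conventions

All grids use axes x left→right, y posterior→anterior, z inferior→superior,
in mm, with voxel-centre origins.

* **Transversal planes are axial voxel slices** (normal = z). The minimum
  search over `[z_Hy, z_Pns]` is a slice scan; nothing is interpolated
  below voxel resolution, and a tie between two equidistant slices resolves
  to the inferior one. The alternative — sections orthogonal to a local
  centerline — is out of scope; axial sections match conventional CT
  reformats.
* **The midsagittal plane** is the sagittal voxel slab containing the
  median x of the S, N and Me landmarks.
* **Sagittal diameters** (IPAS on the B–Go line, MPAS through the uvula tip
  parallel to B–Go, SPAS through the Ut–Pns midpoint parallel to B–Go) are
  the *longest contiguous* airway run along the line, sampled at
  quarter-voxel steps in the midsagittal slab. A "diameter" summing two
  disjoint lumina would be anatomically meaningless, hence the longest-run
  definition. A line that misses the airway yields 0; a line outside the
  grid raises an error.
* **Volumes** sum voxel volumes over slices whose centre lies in the
  closed z-range, divided by 1000 (mm³ → cm³). `A_Sag` is the maximum over
  sagittal slabs of airway area restricted to the range.
* Level areas `A_IAS/A_MAS/A_SPAS` are axial areas at each measurement
  line's anchor height; the IPAS anchor is the B–Go midpoint.

**Accuracy.** With voxels defined by centre-inclusion, areas and volumes
carry quantisation error roughly proportional to voxel size over lumen
radius. At 0.5 mm spacing the phantom suite shows errors below 1% for radii
≥ 5 mm (the clinical range of airway minima); a 3 mm lumen needs ~0.2 mm
voxels to stay within 2%. Tests therefore exercise clinically sized phantoms
at 0.5 mm and reserve finer grids for the extreme-pinch cases. Phantom grids
are laid out so voxel *boundaries* (not centres) align with the tube's end
planes, which avoids knife-edge ties at analytic surfaces.

## Cephalometric conventions

* `ANB = SNA − SNB`, signed (negative in Class III patterns).
* The articular angle `SArGo` is measured at Ar between S and Go, so the
  Björk sum identity `Sum = NSAr + SArGo + ArGoMe` holds by construction.
* `SP-SN` is the acute angle between the undirected palatal (Ans–Pns) and
  anterior-cranial-base (S–N) lines. `MP-SN` and `SP-MP` use the
  conventional anterior-opening form: both lines oriented to point
  anteriorly, unsigned angle in [0, 180).
* Overjet `OJ` is the anterior offset of the upper incisor edge over the
  lower; overbite `OB` the vertical overlap (negative = open bite). The
  incisor offsets are taken along the global y/z axes of the midsagittal
  frame; an occlusal-plane rotation is not applied because no occlusal
  landmarks beyond the incisor edges are part of the landmark set.
* Bilateral landmarks are averaged for sagittal measurements; transversal
  distances (DI4, DI6, DMA, DCH) use the 3D originals.
* Missing optional landmarks leave their parameters `None` (absent, never
  zero), and downstream statistics delete pairwise.

## Synthetic cohort generator

The generator is the package's stand-in for the unavailable patient-level
data; its defaults are the study conditions.

* **Design: Gaussian copula.** A latent multivariate normal is drawn over
  all directly measured parameters; each column maps through its marginal.
  Most marginals are normal with the reference mean/SD. The outcome columns
  `A_min` and `V_PAS` use two-component normal mixtures solved (by least
  squares on three moment/quantile equations) to match mean, SD *and* the
  outcome prevalence at the clinical threshold exactly — a plain normal
  cannot: with mean 143.0 and SD 90.2, a normal puts only 24% below
  80 mm², whereas the reference cohort has 30% (the real distribution is
  right-skewed). The mixture weight equals the prevalence and the narrow
  component's SD is fixed at one fifth of the marginal SD, mirroring the
  affected subgroup's spread; the remaining three parameters are solved.
  An infeasible request (prevalence unreachable at the given moments)
  raises an invalid-spec error.
* **Correlation targets** default to the reference study's two published
  columns (every parameter vs `A_min` and vs `V_PAS`); unspecified pairs
  are zero. The assembled matrix is generally *not* positive semi-definite
  — the published pairwise targets are jointly infeasible — so it is
  repaired by eigenvalue clipping at 1e-8 and diagonal rescaling. The
  repair shrinks the dense columns substantially (e.g. the A_min–SPAS
  target 0.706 becomes ≈ 0.44 under the full default set) while preserving
  their ordering; the effective matrix is stored in `DataFrame.attrs`.
  Feasible user-specified targets are recovered within ±0.01 at n = 10⁵.
* **Attenuation correction.** A monotone marginal transform attenuates
  Pearson correlation by λ = corr(Z, T(Z)) (computed by Gauss–Hermite
  quadrature). Latent correlations are pre-divided by λ for
  normal-vs-mixture pairs, and solved numerically (2D quadrature + root
  finding) for the mixture-vs-mixture pair, so requested correlations are
  met on the observed scale.
* **Derived columns** (`ANB`, `Sum`, the two face-height ratios, `BMI`)
  are computed from their parents, not drawn, so record-level identities
  hold in every synthetic table. Consequence: their marginal SDs and their
  correlations to the outcomes are implied rather than controlled.
* **Gender** is assigned by thresholding an independent latent normal at
  the 53% female fraction. Body height/weight SDs are not published; the
  defaults (9 cm, 13 kg) are typical adult dispersions. Two entries of the
  reference cohort column were internally inconsistent with their group
  summaries and are corrected in `reference.py` (noted inline there).
* **Truncation:** latent rows with any |z| > 5 are redrawn (unphysiological
  tails), with a deterministic redraw loop under the spec seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: all non-outcome marginals are Gaussian (real
cephalometric parameters are mildly skewed); only the two published
correlation columns are targeted, so the dense mutual correlation structure
among airway parameters is absent and discriminative performance of single
predictors on synthetic cohorts (e.g. the IPAS AUC in the README example)
is weaker than in the reference cohort; there is no measurement error, no
rater effect, no segmentation artefact and no demographic confounding.
Geometry code is instead validated on phantoms with closed-form truth.

## Rater tables and ICC

Rater tables follow the two-way crossed model
`y_ij = μ + s_i + r_j + e_ij` with the true absolute-agreement ICC
`σ_s²/(σ_s²+σ_r²+σ_e²)`. The estimator is ICC(A,1) from the two-way ANOVA
mean squares with the F-based confidence interval using a Satterthwaite
denominator-df approximation; with only k rater-effect draws the estimate
is conditional on the realised raters, which is why calibration is checked
as CI coverage over replicate panels (≥ 90% at the 20-subject, 2-rater
design) rather than point-estimate consistency.

## Stepwise regression

Selection is the classic bidirectional probability-of-F procedure:
enter the candidate with the smallest p-of-F if `p < 0.05`, then remove any
included term with `p > 0.10`; the thresholds are quoted as F-bounds in the
source material but are interpreted as probability levels, the convention of
the statistics packages of that workflow (an F-statistic of 0.05 as an
*entry* bound would admit everything). Entry p-values are computed via
partial correlations after residualising all candidates against the current
model in one QR pass — algebraically identical to the coefficient t-test in
the augmented model — with ties broken by larger partial F, then name.
Exactly collinear candidates are skipped; a step limit of twice the
candidate count guards against oscillation. Complete-case analysis applies
over the candidate union, with the n used recorded. The default candidate
pool is every parameter readable on a lateral cephalogram plus
demographics: 3D airway parameters and the transversal distances are
excluded.

## ROC and the triage rule

* Curves are empirical: one point per distinct observed value (plus the
  call-nothing extreme), with the classification "score ≤ value" for
  lower-is-positive predictors. Direction is an explicit flag; reported
  thresholds always stay on the original measurement scale. Equivalent
  midpoint thresholds are stored alongside.
* AUC equals the tie-corrected Mann–Whitney statistic (verified against
  exhaustive pair counting); its SE is DeLong's estimator, with a Wald 95%
  CI clipped to [0, 1] and a normal test against 0.5. Hanley–McNeil is a
  documented alternative, not the default.
* The single cut-off maximises Youden's J, ties broken toward higher
  specificity, then the less extreme threshold; when no threshold beats
  chance the result carries a `degenerate` flag.
* The triage rule takes the least extreme observed value reaching the
  sensitivity target (≥ 0.90 by default) and the most extreme value
  keeping specificity at its target, stores them sorted as
  (lower, upper), and refers the in-between zone to 3D imaging. On a step
  curve exact 90% rarely exists, so "the value where sensitivity is 90%"
  is the first value *at or above* it — conservative, which is what makes
  the scheme's ≥ 90%/≥ 90% guarantee on the construction sample exact. On
  very separable data the two target points can coincide or cross; sorting
  preserves the guarantee, so both are returned as valid rules (with a
  `crossed` flag) rather than as errors.

## Problem sizes

Default checks use: 100-patient cohorts for pipeline behaviour (with
binomial slack on prevalences), 10⁴–10⁵ rows for moment/correlation
recovery, 100 seeds × 10⁴ rows for the stepwise recovery study, 1000
simulated datasets for the triage guarantee, 500 panels for ICC
calibration, and phantoms at 0.2–1.0 mm spacing. These sizes put Monte
Carlo error well below the tolerances asserted while keeping the whole
suite around a minute of compute.

## Known limitations

* Axial (not centerline-orthogonal) minimal sections; oblique airways
  would measure slightly larger areas.
* Masks are taken as given; no segmentation from grayscale CT.
* The two-threshold guarantee is an in-sample property; out-of-sample
  performance depends on the predictor's transportability, which the
  reference-cohort discussion itself flags as acquisition-dependent.
* The NRRD reader/writer covers the raw/gzip single-file form the package
  itself emits, not the full format.
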