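# Methods

This note documents the models, conventions and numerical choices behind
`fovtopo`, in the order the pipeline applies them.

## The synthetic foveal phantom

Real foveal OCT scans cannot be shipped with the package, so every stage is
driven and validated by a parametric phantom (`fovtopo.phantom`). It
emulates the two study populations — normal controls with a fully excavated
foveal pit, and albinism-like retinas with graded foveal hypoplasia and
nasal-temporal asymmetry — with enough structure that every downstream
metric has an exact, independently computable answer.

### Layer thickness model

The retina is five stacked bands between six boundaries: RNFL (ILM to
RNFL/GCL), GCL, IPL, the INL–OPL complex, and the outer retina (OPL to
RPE). Each band's thickness along a meridian is a baseline minus a narrow
pit Gaussian plus a broad rim Gaussian:

    T_b(x) = max(0, m_b(x) · [B_b − a_b e^{−x²/2σ_p²} + r_b e^{−x²/2σ_r²}])

with x the signed eccentricity in mm. The pit width σ_p = 0.30 mm and rim
width σ_r = 0.90 mm are shared by all bands; amplitudes are per band. The
control preset (µm):

| band    | baseline B | pit a | rim r | at fovea |
|---------|-----------:|------:|------:|---------:|
| RNFL    | 14         | 12    | 0     | 2        |
| GCL     | 33         | 45    | 18    | 6        |
| IPL     | 36         | 42    | 14    | 8        |
| INL–OPL | 55         | 30    | 5     | 30       |
| outer   | 195        | −28   | 0     | 223      |

The negative outer-retina "pit" is the foveal doming of the photoreceptor
complex. These values give a foveal total retinal thickness of ~270 µm, a
peak GCL of ~40 µm near 0.9 mm eccentricity, and a per-quadrant GCL AUC of
0.0858 mm² (summed four-quadrant AUC 0.343 mm²) — the thickness and area
scales reported for healthy adult foveae with this measurement. The
difference-of-Gaussians form was chosen because it reproduces the
pit-plus-rim shape with the fewest parameters *and* integrates in closed
form, which is what makes the oracle below exact.

Boundaries are stacked upward from a flat RPE by the cumulative band
thicknesses, so the six traces are ordered at every column by construction.

### Hypoplasia presets

`grade1` … `grade4` scale all pit amplitudes by 0.60 / 0.35 / 0.15 / 0,
from a shallow pit down to no excavation at all (a grade-4-like GCL keeps
~43 µm across the fovea). Shrinking the pit adds central tissue, so each
band's baseline and rim are simultaneously rescaled by exactly the area the
lost excavation would have removed (a closed-form factor, no fitting): a
layer's quadrant AUC is therefore *grade-invariant*. This mirrors the
empirical finding the phantom is built to emulate — hypoplasia redistributes
the GCL and IPL without changing their total area.

### Asymmetry

A side multiplier raises the nasal (horizontal scans) or superior (vertical
scans) half of each profile:

    m_b(x) = (1 + (ρ_b − 1) Φ(x / w)) · 2 / (1 + ρ_b)

where Φ is the standard normal CDF and w = 0.2 mm the blend half-width. Two
deliberate choices:

* **Probit rather than logistic blend.** Visually the two sigmoids are
  indistinguishable, but Gaussian-CDF × Gaussian integrals have an exact
  closed form (error functions plus Owen's T), so the analytic AUC oracle
  stays exact at any ρ. A logistic blend would have forced a numerical
  oracle.
* **Area-preserving normalization 2/(1+ρ).** Without it, raising one side
  inflates the *summed* AUC by (1+ρ)/2 — asymmetric retinas would carry more
  tissue. With it, asymmetry only redistributes a layer laterally: the
  quadrant ratio still equals ρ exactly (both quadrants share the factor),
  while the summed AUC is ρ-invariant, as observed between real groups.

Each band expresses the phenotype's ρ with a fixed weight
(1 + weight·(ρ−1)): GCL 1.0, RNFL and IPL 0.3, INL–OPL 0.1, outer retina 0.
The GCL thus carries the full factor — its measured N:T AUC ratio *is* ρ —
while total retinal thickness stays only mildly asymmetric (a fully shared ρ
of 1.45 would make the whole retina 45% thicker nasally, which no retina
does, and which destabilizes the DoG foveal fit). A convenient consequence:
at the albinism-like ρ = 1.45 the IPL ratio comes out ≈ 1.13 and at the
control-like ρ = 1.20 it is ≈ 1.06, close to the values reported for those
groups.

### The closed-form AUC oracle

For an unclamped band, the quadrant integral ∫₀^L m(x)·f(x) dx decomposes
into ∫ f, ∫ Φ(x/w) dx, and ∫ Φ(x/w) e^{−x²/2σ²} dx. The last uses

    ∫₀^h Φ(bu) φ(u) du = Φ(h)/2 − 1/4 + arctan(b)/2π − T(h, b)

with Owen's T from `scipy.special.owens_t`; the oracle agrees with adaptive
quadrature to below 10⁻⁹ mm² (tested). If the max(0, ·) clamp activates
anywhere on a quadrant the closed form is invalid: the oracle warns and
falls back to adaptive quadrature of the clamped profile. Composite layers
(GCIPL, TRT) are sums of bands.

### Rendering and motion

A rendered frame is the piecewise-constant band-intensity image (distinct
reflectance per band, vitreous dark, outer retina bright), circularly
translated by its per-frame shift, optionally axially jittered per lateral
strip (nystagmus-scale intra-frame motion), and multiplied by gamma speckle
of unit mean. Defaults: lateral shift SD 3 px, axial 2 px, speckle SD 0.2
(chosen so single-frame NCC against the reference sits around 0.9 — the
regime in which an 0.85 acceptance threshold passes most frames but rejects
blinks and outliers), drop-frame probability 0. Dropped frames are rendered
as structureless noise. All true shifts are stored for registration ground
truth, and everything derives from one seed per call. The noise and motion
statistics of the real scans were never characterized, so these are
conventions, not estimates.

### Cohorts

`make_cohort` draws 25 control and 30 albinism-like participants by
default. Ages and axial lengths are truncated normals matched to the study
groups (26.2 ± 6.9 vs 24.3 ± 11.9 years; 24.08 ± 1.05 vs 23.19 ± 1.63 mm);
sex is Bernoulli at 48.0% / 46.7% female. The GCL asymmetry factor is
uniform on (1.04, 1.36) for controls and (1.37, 1.53) for albinism —
centered on 1.20 and 1.45, with the albinism range strictly above the
control range so parameter-recovery assertions are unambiguous. Albinism
grades are uniform over grade 1–4, and half the albinism participants
contribute one eye only, mirroring the study's scan inventory. Scans use a
7-mm nominal length so that even the shortest axial lengths retain ±2.5 mm
of coverage. Each scan carries two repeat segmentations: independent
per-column boundary noise (SD 0.4 px) with the first repeat biased
+0.03 px at the GCL/IPL boundary, reproducing the sub-pixel
first-thicker-than-second repeatability bias the measurement shows.
Albinism scans also carry two simulated observer foveal marks
(SD 50 µm about the true center).

What the phantom does *not* emulate: optical attenuation and depth roll-off,
vascular shadows, segmentation failures correlated across columns, axial
curvature of the retina, and volumetric structure. Passing tests therefore
demonstrate the correctness of the measurement chain, not the clinical
behavior of any segmentation algorithm on real scans.

## Registration (`fovtopo.register`)

Translation-only, integer-pixel registration: each frame's shift is the
argmax of its circular FFT cross-correlation with a reference frame
(sub-pixel spline warping is deliberately out of scope — translation
dominates B-scan motion and integer shifts keep phantom ground truth
exact). The reference defaults to the frame with the highest mean pairwise
NCC among 10 evenly sampled frames, and can be overridden. Strip
registration then splits each frame into 64-column blocks (a trailing block
narrower than 8 columns merges into its neighbor) and aligns each
independently, correcting intra-frame axial drift. NCC is computed on
mean-subtracted, unit-variance data over the mutually valid region only;
pixels wrapped in by a translation are masked out of NCC and averaging.
Selection ranks units (frames, or strips independently per position) by
NCC, keeps those ≥ 0.85, and averages the best 30 per pixel with a coverage
count; ties break toward the earlier frame, so selection is deterministic.
A scan in which no unit passes anywhere fails loudly rather than averaging
garbage.

## Thickness and eccentricity (`fovtopo.layers`, `fovtopo.fovea`)

The axial scale (default 3.24 µm/px) comes from scanner metadata and is
never inferred from image content. The lateral scale corrects the nominal
scan length by axial length / 24 mm and divides by 1000 A-scans. Thickness
is the raw boundary gap — no smoothing is applied before measurement.

The DoG foveal fit uses `scipy.optimize.curve_fit` with five starts for the
center parameter (raw minimum and ±0.2, ±0.4 mm), bounds forcing
σ₂ ∈ [0.02, 0.5] mm < σ₁ ∈ [0.5, 8] mm, and reports the argmin of the
fitted curve on a 1-µm grid. It requires ±2 mm of coverage around the raw
minimum; if no start converges it falls back to the raw minimum with a
flag. On noise-free symmetric phantoms the center is exact to the grid; on
asymmetric profiles the symmetric model acquires a small temporal bias
(≈ −3 µm at ρ = 1.04 up to ≈ −27 µm at ρ = 1.45), which propagates to at
most ≈ 0.02 of extra N:T ratio error at the extreme — a known limitation of
fitting a symmetric model to an asymmetric retina. Scans without a pit
never use the DoG path: their center is the mean of observer marks, with a
warning when marks disagree by more than 0.5 mm.

Quadrant conventions: positive eccentricity is nasal (horizontal) or
superior (vertical); OD horizontal scans map image-left to temporal, OS
horizontal scans are mirrored so nasal stays positive, and vertical scans
keep image orientation for both eyes. These are declared conventions
carried in metadata — scan direction is hardware-dependent and must be
known to the caller.

## Metrics (`fovtopo.topo`)

Profiles are linearly interpolated at exactly 51 eccentricities (−2.5 to
+2.5 mm in 0.1-mm steps); a scan that does not reach ±2.5 mm raises a
coverage error naming the missing side rather than extrapolating. The two
repeat segmentations are averaged pointwise *on the grid, before* any AUC.
Quadrant AUC is the trapezoid rule over the 26 samples of one side, with
the eccentricity-0 sample shared by both quadrants, so the two quadrants of
a scan sum exactly to the full ±2.5 mm integral. Thickness is µm,
eccentricity mm, AUC mm². Against the phantom's closed form the trapezoid
error is ≤ 3 × 10⁻⁵ mm² on default shapes (bound asserted at 2 × 10⁻⁴).
The GCL fraction (100·GCL/GCIPL) masks grid points where the GCIPL is
thinner than 1 µm instead of dividing by a vanishing denominator. A
participant-eye missing an orientation simply has no summed AUC or
superior:inferior ratio — missing quadrants are reported, never imputed.

## Statistics (`fovtopo.stats`)

Standard machinery delegates to `scipy.stats`; the module fixes the study's
conventions on top:

* Everything is two-tailed.
* Mann-Whitney U is reported as min(U₁, U₂), with midranks for ties. For
  groups of ≤ 8 the permutation null is enumerated exhaustively (valid with
  ties, which scipy's exact method does not handle); larger samples use the
  tie-corrected normal approximation with continuity correction. Whether
  the original analyses used exact or approximate nulls is unknowable from
  the outside; at the study's sample sizes the approximation applies.
* The 2×2 sex chi-square uses Yates continuity correction — the uncorrected
  statistic does not reproduce the published "P > 0.99" on the study's sex
  counts; the corrected one does.
* The group-comparison gate: both groups pass D'Agostino–Pearson normality
  (P > 0.05) *and* a two-tailed F-ratio variance check at α = 0.05 → pooled
  unpaired t; otherwise Mann-Whitney. The gate record (normality p's,
  F, decision) is attached to every result so the chosen path is auditable.
  Groups below n = 8 skip the normality test and fall back to Mann-Whitney
  with a flag. The variance check is an F-ratio because the source analysis
  names no specific test.
* Bland-Altman: bias ± 1.96·SD limits, with 95% CIs from SE(bias) = SD/√n
  and SE(limit) = √3·SD/√n on n−1 t quantiles.
* Eye selection is a uniform seeded draw per participant; single-eye
  participants keep their eye.

## Pipeline and reproducibility (`fovtopo.pipeline`)

`run(RunConfig(seed=...))` composes the stages in acquisition order and is
bit-identical under a fixed seed. Configuration is validated up front with
field-level messages; nothing is computed on an invalid config. Every scan
appears exactly once in the inclusion log, included or excluded with an
enumerated reason (LOW_CONTRAST, NOT_FOVEAL, SHORT_COVERAGE,
NO_FRAMES_PASS_NCC). The published participant tables ship as packaged CSVs
so the demographics computations run offline; the albinism table's ages
average 23.87 ± 10.97 years while the published summary prints 24.3 ± 11.9
— the table is kept verbatim and the discrepancy documented here rather
than reconciled. Similarly, the eye-averaged control axial length from the
table is 24.12 mm against a printed 24.08 mm (the summary may have used
single selected eyes).

Problem sizes: the default synthetic study (25 + 30 participants, two eyes,
two orientations, two repeats, 1000 A-scans per scan) analyses in ~3 s;
registration audits use 256 × 160-pixel stacks of 40 frames, which preserve
every property being tested at a fraction of the full-frame cost.

## Known limitations

* Line scans only: two meridians, not volumetric topography.
* Integer-pixel translation registration; no rotation, shear, or sub-pixel
  refinement.
* The DoG center model is symmetric; its bias on strongly asymmetric
  retinas is characterized above but not corrected.
* The phantom's speckle/motion statistics are conventions; quantitative
  noise-robustness results should be read as relative, not clinical.
* No multiple-testing correction is applied, matching the source analysis
  it reimplements.
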