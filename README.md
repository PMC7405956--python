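# fovtopo

Quantifying foveal **ganglion cell layer (GCL)** and **inner plexiform layer
(IPL)** topography from OCT line scans.

In foveal hypoplasia — characteristic of albinism — the inner retinal layers
fail to excavate fully at the fovea, and the *shape* of the GCL and IPL
across the foveal region changes, not just their average thickness. This
package implements a complete, testable version of the analysis used to
measure that change: multi-frame B-scan registration and averaging,
boundary-contour–based layer thickness with axial-length lateral rescaling,
foveal localization, per-quadrant area-under-the-curve (AUC) asymmetry
metrics, and the accompanying repeatability and group statistics. Because
clinical OCT scans cannot be redistributed, the package ships a synthetic
foveal phantom whose ground truth has closed-form answers for every
downstream metric, so the whole chain is verifiable end to end.

Intended users: vision scientists and OCT image-analysis developers who want
a reference implementation of quadrant AUC asymmetry metrics, or a ground-
truth phantom for validating their own layer-analysis pipelines.

## The measurement

For a line scan through the fovea, segmentation yields one axial pixel
coordinate per boundary per A-scan column (ILM, RNFL/GCL, GCL/IPL, IPL/INL,
OPL, RPE). Layer thickness at a column is the boundary gap times the axial
scale; the lateral position of column *i* is

    x_i = i · L_nominal · (AL / 24 mm) / N_ascans

where AL is the participant's axial length, 24 mm the scanner's assumed
axial length, and N_ascans = 1000. The foveal center is the minimum of a
difference-of-Gaussians (DoG) fit to total retinal thickness,

    T(x) = C + A₁ e^{−(x−µ)²/2σ₁²} − A₂ e^{−(x−µ)²/2σ₂²},  σ₂ < σ₁,

for eyes with a pit, or the mean of manual observer marks when the pit is
absent. Thickness is then linearly interpolated at 100-µm steps over
±2.5 mm (51 samples), and each quadrant's AUC is the trapezoidal integral
of thickness (mm) over eccentricity 0–2.5 mm, in mm². Asymmetry is the
quadrant AUC ratio: nasal:temporal (horizontal scans) and superior:inferior
(vertical scans). Group comparisons are gated by the D'Agostino–Pearson
normality test (unpaired *t* when both groups are normal with comparable
variance, Mann-Whitney *U* otherwise); repeatability uses Bland-Altman bias
and 1.96·SD limits of agreement.

## Worked example

```python
from fovtopo.phantom import phenotype_preset, make_boundary_profiles
from fovtopo.layers import thickness_profiles
from fovtopo.fovea import fit_dog_center, eccentricity_axis
from fovtopo.topo import interpolate_grid, quadrant_auc, asymmetry_ratio

# a control-like retina with 45% more GCL area nasally than temporally
phenotype = phenotype_preset("control", rho_nt=1.45)
contours, truth = make_boundary_profiles(phenotype)

profiles = thickness_profiles(contours)           # TRT, GCL, IPL, GCIPL
center = fit_dog_center(profiles["TRT"])          # DoG fit of the pit
gcl = interpolate_grid(eccentricity_axis(profiles["GCL"], center))

nasal = quadrant_auc(gcl, "nasal")
temporal = quadrant_auc(gcl, "temporal")
print(f"center {center.abscissa_mm:.3f} mm ({center.method})")
print(f"GCL AUC nasal {nasal:.4f} mm^2, temporal {temporal:.4f} mm^2, "
      f"N:T {asymmetry_ratio(nasal, temporal):.3f}")
```

prints

```
center 2.970 mm (dog_fit)
GCL AUC nasal 0.1003 mm^2, temporal 0.0709 mm^2, N:T 1.415
```

The center sits mid-scan (a 6-mm scan spans 0–5.994 mm), each quadrant
carries roughly a tenth of a mm² of GCL, and the pipeline recovers the
generative asymmetry factor 1.45 to within ~0.035 even though this extreme
probe runs through the DoG fit of an asymmetric profile (feeding the true
center instead recovers it within 0.012).

A full synthetic study — 25 controls vs 30 albinism-like participants, two
eyes, two scan orientations, two repeat segmentations — runs from the shell:

```sh
fovtopo run --seed 1 --out results/run1
```

writing the cohort table, per-scan metrics, GCL-fraction profiles,
Bland-Altman repeatability and gated group statistics. `fovtopo register`
exposes the frame/strip registration and NCC-thresholded averaging for a
multi-frame TIFF stack, and `fovtopo simulate` / `fovtopo metrics` cover the
remaining stages individually.

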