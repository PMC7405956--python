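"""Synthetic foveal cross-sections with known ground truth.

The study population (controls with a fully excavated pit; albinism with
graded foveal hypoplasia and nasal-temporal asymmetry) is emulated by a
parametric phantom.  Each retinal layer band's thickness along a meridian is
a baseline minus a narrow pit Gaussian plus a broad rim Gaussian:

    T(x) = max(0, m(x) · [B − a_p·exp(−x²/2σ_p²) + a_r·exp(−x²/2σ_r²)])

with x the signed anatomical eccentricity in mm.  The side multiplier
``m(x) = 1 + (ρ−1)·Φ(x/w)`` (Φ the standard normal CDF, w the blend
half-width) raises the nasal (or superior) side by the asymmetry factor ρ
while keeping the profile smooth through the fovea.  The probit blend is
chosen over other sigmoids because the quadrant integral of m·T then has an
exact closed form (error functions plus Owen's T), giving an independent
oracle for the trapezoidal AUC computed by the analysis pipeline.

Five bands are stacked to produce the six segmentation boundaries
(ILM, RNFL/GCL, GCL/IPL, IPL/INL, OPL, RPE):  RNFL, GCL, IPL, the INL-OPL
complex, and the outer retina (OPL to RPE, which domes rather than pits at
the fovea).  Hypoplasia presets scale the pit amplitudes down:  grade-4-like
retinas keep essentially the full inner-layer thickness across the fovea.

Rendered B-scan stacks add frame-to-frame translation, per-strip axial
jitter (nystagmus-scale motion), occasional signal-free dropped frames, and
multiplicative gamma speckle, with every true shift stored for registration
ground truth.  All randomness flows from one explicit seed per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import atan, erf, pi, sqrt

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import ndtr, owens_t

from .layers import (
    DEFAULT_AXIAL_UM_PER_PX,
    ScanMeta,
    SegmentationContours,
    lateral_scale_um_per_ascan,
)
from .register import BScanStack
from .topo import ThicknessProfile

__all__ = [
    "LayerShape",
    "FoveaPhenotype",
    "MotionModel",
    "ScanGrid",
    "CohortRanges",
    "CohortData",
    "ClampWarning",
    "GridTooShortError",
    "phenotype_preset",
    "layer_thickness_um",
    "make_boundary_profiles",
    "analytic_quadrant_auc",
    "render_base_image",
    "render_bscan_stack",
    "make_cohort",
    "ScanRecord",
    "BAND_NAMES",
    "GRADE_PIT_FACTOR",
    "ASYM_WEIGHTS",
    "DEFAULT_INTENSITIES",
    "DEFAULT_NOISE_LEVEL",
]

#: layer bands, vitread to sclerad; consecutive boundary pairs delimit them
BAND_NAMES = ("RNFL", "GCL", "IPL", "INL_OPL", "OUTER")

_BAND_BOUNDARY = {  # band -> (upper, lower) boundary names
    "RNFL": ("ILM", "RNFL_GCL"),
    "GCL": ("RNFL_GCL", "GCL_IPL"),
    "IPL": ("GCL_IPL", "IPL_INL"),
    "INL_OPL": ("IPL_INL", "OPL"),
    "OUTER": ("OPL", "RPE"),
}

_COMPOSITE = {"GCIPL": ("GCL", "IPL"), "TRT": BAND_NAMES}

#: how strongly each band expresses the asymmetry multiplier rho.
#: The ganglion cell layer carries the full factor (so its quadrant AUC
#: ratio equals rho); the plexiform/nerve-fiber layers express it partially
#: and the outer retina not at all, keeping total retinal thickness only
#: mildly asymmetric as in real scans.
ASYM_WEIGHTS = {"RNFL": 0.3, "GCL": 1.0, "IPL": 0.3, "INL_OPL": 0.1, "OUTER": 0.0}

#: pit-amplitude multiplier of the hypoplasia-grade presets (1 = full pit)
GRADE_PIT_FACTOR = {
    "control": 1.0,
    "grade1": 0.60,
    "grade2": 0.35,
    "grade3": 0.15,
    "grade4": 0.0,
}


class ClampWarning(UserWarning):
    """A layer's generative thickness went negative and was clamped to 0;
    the closed-form AUC oracle no longer applies there."""


class GridTooShortError(ValueError):
    """Scan grid does not cover the required eccentricity range."""


@dataclass
class LayerShape:
    """Baseline/pit/rim amplitudes (µm) of one layer band."""

    baseline_um: float
    pit_um: float
    rim_um: float


@dataclass
class FoveaPhenotype:
    """Generative parameters of one retina's foveal cross-section.

    ``rho_nt`` multiplies the nasal side of horizontal meridians, ``rho_si``
    the superior side of vertical meridians; ``rho_nt = rho_si = 1`` is a
    radially symmetric phantom.  Pit and rim widths are shared by all layer
    bands; amplitudes are per band.
    """

    layers: dict[str, LayerShape]
    sigma_pit_mm: float = 0.30
    sigma_rim_mm: float = 0.90
    rho_nt: float = 1.0
    rho_si: float = 1.0
    blend_halfwidth_mm: float = 0.2
    grade: str = "control"
    asym_weights: dict = field(default_factory=lambda: dict(ASYM_WEIGHTS))

    def rho_eff(self, layer: str, axis: str) -> float:
        """Per-band effective asymmetry factor: 1 + weight·(ρ − 1)."""
        rho = self.rho_nt if axis == "nt" else self.rho_si
        return 1.0 + self.asym_weights.get(layer, 1.0) * (rho - 1.0)

    def __post_init__(self) -> None:
        if self.sigma_pit_mm <= 0 or self.sigma_rim_mm <= 0:
            raise ValueError("pit and rim widths must be positive")
        if self.sigma_pit_mm >= self.sigma_rim_mm:
            raise ValueError("pit width must be narrower than rim width")
        if self.rho_nt < 0 or self.rho_si < 0:
            raise ValueError("asymmetry multipliers must be >= 0")
        if self.blend_halfwidth_mm < 0:
            raise ValueError("blend half-width must be >= 0")
        missing = [b for b in BAND_NAMES if b not in self.layers]
        if missing:
            raise ValueError(f"missing layer band(s): {', '.join(missing)}")

    def scaled(self, pit_factor: float = 1.0, baseline_factor: float = 1.0) -> "FoveaPhenotype":
        """Copy with all pit amplitudes (and optionally baselines) rescaled."""
        new = {
            b: LayerShape(
                baseline_um=s.baseline_um * baseline_factor,
                pit_um=s.pit_um * pit_factor,
                rim_um=s.rim_um * baseline_factor,
            )
            for b, s in self.layers.items()
        }
        return replace(self, layers=new)


_CONTROL_LAYERS = {
    "RNFL": LayerShape(14.0, 12.0, 0.0),
    "GCL": LayerShape(33.0, 45.0, 18.0),
    "IPL": LayerShape(36.0, 42.0, 14.0),
    "INL_OPL": LayerShape(55.0, 30.0, 5.0),
    # outer retina (ONL + photoreceptors + RPE) domes at the fovea: negative pit
    "OUTER": LayerShape(195.0, -28.0, 0.0),
}


def phenotype_preset(
    name: str = "control", rho_nt: float = 1.0, rho_si: float = 1.0
) -> FoveaPhenotype:
    """A named point on the control-to-hypoplasia spectrum.

    ``control`` has a fully excavated pit (GCL ≈ 6 µm at the fovea);
    ``grade1`` … ``grade4`` scale the inner-layer pit amplitudes down to
    none, so a grade-4-like retina keeps its inner layers across the fovea.
    """
    if name not in GRADE_PIT_FACTOR:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(GRADE_PIT_FACTOR)}")
    g = GRADE_PIT_FACTOR[name]
    sp, sr, L = 0.30, 0.90, 2.5
    layers = {}
    for b, s in _CONTROL_LAYERS.items():
        # area-preserving hypoplasia: shrinking the pit adds central tissue,
        # so the baseline+rim amplitudes shrink by exactly the area the lost
        # excavation would have removed — summed AUC is grade-invariant, as
        # observed between the study's groups
        pit_area = s.pit_um * _gauss_int(sp, L)
        flat_area = s.baseline_um * L + s.rim_um * _gauss_int(sr, L)
        scale = max(1.0 - (1.0 - g) * pit_area / flat_area, 0.1)
        layers[b] = LayerShape(
            baseline_um=s.baseline_um * scale,
            pit_um=s.pit_um * g,
            rim_um=s.rim_um * scale,
        )
    return FoveaPhenotype(
        layers=layers,
        sigma_pit_mm=sp,
        sigma_rim_mm=sr,
        rho_nt=rho_nt,
        rho_si=rho_si,
        grade=name,
    )


def _base_profile_um(shape: LayerShape, x_mm: np.ndarray, sp: float, sr: float) -> np.ndarray:
    x2 = np.square(x_mm)
    return (
        shape.baseline_um
        - shape.pit_um * np.exp(-x2 / (2.0 * sp**2))
        + shape.rim_um * np.exp(-x2 / (2.0 * sr**2))
    )


def _side_multiplier(x_mm: np.ndarray, rho: float, w_mm: float) -> np.ndarray:
    """Asymmetry weighting of the two sides of the fovea.

    The positive (nasal/superior) side is raised by ρ relative to the
    negative side through a smooth probit blend, and the whole profile is
    normalised by 2/(1+ρ) so that the *total* area is independent of ρ:
    asymmetry redistributes a layer laterally rather than adding tissue,
    which is how the measured eyes behave (summed AUC is group-invariant
    while the quadrant ratio is not).
    """
    if rho == 1.0:
        return np.ones_like(np.asarray(x_mm, dtype=float))
    if w_mm == 0.0:
        blend = np.where(x_mm > 0, 1.0, np.where(x_mm < 0, 0.0, 0.5))
    else:
        blend = ndtr(np.asarray(x_mm) / w_mm)
    return (1.0 + (rho - 1.0) * blend) * (2.0 / (1.0 + rho))


def layer_thickness_um(
    phenotype: FoveaPhenotype,
    layer: str,
    x_mm: np.ndarray,
    axis: str = "nt",
    clamp: bool = True,
) -> np.ndarray:
    """Generative thickness of ``layer`` at signed eccentricities ``x_mm``.

    ``axis`` selects which asymmetry multiplier applies: ``'nt'`` (positive =
    nasal) or ``'si'`` (positive = superior).  Composite layers (GCIPL, TRT)
    are sums of their bands.
    """
    x_mm = np.asarray(x_mm, dtype=float)
    if layer in _COMPOSITE:
        parts = [
            layer_thickness_um(phenotype, b, x_mm, axis=axis, clamp=clamp)
            for b in _COMPOSITE[layer]
        ]
        return np.sum(parts, axis=0)
    if layer not in phenotype.layers:
        raise ValueError(f"unknown layer {layer!r}")
    rho = phenotype.rho_eff(layer, axis)
    raw = _base_profile_um(
        phenotype.layers[layer], x_mm, phenotype.sigma_pit_mm, phenotype.sigma_rim_mm
    ) * _side_multiplier(x_mm, rho, phenotype.blend_halfwidth_mm)
    return np.maximum(raw, 0.0) if clamp else raw


@dataclass
class ScanGrid:
    """Sampling geometry of a rendered/contoured scan."""

    n_ascans: int = 1000
    n_rows: int = 496
    axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX
    nominal_length_mm: float = 6.0
    axial_length_mm: float = 24.0
    center_offset_mm: float = 0.0  # fovea position relative to scan center

    @property
    def lateral_um_per_ascan(self) -> float:
        return lateral_scale_um_per_ascan(
            self.nominal_length_mm, self.axial_length_mm, self.n_ascans
        )

    def x_scan_mm(self) -> np.ndarray:
        """Raw abscissa (mm), origin at column 0."""
        return np.arange(self.n_ascans) * self.lateral_um_per_ascan / 1000.0

    @property
    def center_mm(self) -> float:
        """Foveal center in raw scan coordinates."""
        half = (self.n_ascans - 1) / 2.0 * self.lateral_um_per_ascan / 1000.0
        return half + self.center_offset_mm

    @property
    def half_extent_mm(self) -> float:
        return (self.n_ascans - 1) / 2.0 * self.lateral_um_per_ascan / 1000.0


def make_boundary_profiles(
    phenotype: FoveaPhenotype,
    orientation: str = "horizontal",
    grid: ScanGrid | None = None,
    eye: str = "OD",
    halfwidth_mm: float = 2.5,
    seg_noise_px: float = 0.0,
    seg_bias_px: float = 0.0,
    rng: np.random.Generator | None = None,
    scan_id: str = "",
    participant: str = "",
    repeat: int = 1,
) -> tuple[SegmentationContours, dict[str, ThicknessProfile]]:
    """Render ground-truth boundary contours and thickness profiles.

    Boundaries are stacked upward from a flat RPE by the cumulative layer
    thicknesses, so the six traces are ordered at every column by
    construction.  ``seg_noise_px`` adds independent per-column jitter to
    each boundary (emulating manual segmentation error), after which
    ordering is re-imposed; ``seg_bias_px`` moves the GCL/IPL boundary down,
    making the GCL systematically thicker (a repeat-measurement bias knob).

    Returns the contours plus noise-free ground-truth profiles for TRT, GCL,
    IPL and GCIPL on the *anatomical* eccentricity axis (centered, nasal or
    superior positive).
    """
    grid = grid or ScanGrid()
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if eye not in ("OD", "OS"):
        raise ValueError(f"unknown eye {eye!r}")
    need = halfwidth_mm + abs(grid.center_offset_mm)
    if grid.half_extent_mm < need:
        raise GridTooShortError(
            f"scan half-extent {grid.half_extent_mm:.3f} mm < required "
            f"{need:.3f} mm (±{halfwidth_mm} mm about the fovea)"
        )

    # anatomical eccentricity of each column: OS horizontal scans are the
    # mirror image of OD, so image-right is temporal there
    x_rel = grid.x_scan_mm() - grid.center_mm
    axis = "nt" if orientation == "horizontal" else "si"
    u = -x_rel if (orientation == "horizontal" and eye == "OS") else x_rel

    bands = {}
    clamped = False
    for b in BAND_NAMES:
        raw = layer_thickness_um(phenotype, b, u, axis=axis, clamp=False)
        if np.any(raw < 0):
            clamped = True
        bands[b] = np.maximum(raw, 0.0)
    if clamped:
        warnings.warn(
            "negative generative thickness clamped to 0; closed-form AUC oracle "
            "does not apply to this phenotype",
            ClampWarning,
            stacklevel=2,
        )

    ax = grid.axial_um_per_px
    rpe_y = np.full(grid.n_ascans, round(grid.n_rows * 0.85), dtype=float)
    y = {"RPE": rpe_y}
    level = rpe_y.copy()
    for band in reversed(BAND_NAMES):
        upper, _lower = _BAND_BOUNDARY[band]
        level = level - bands[band] / ax
        y[upper] = level.copy()
    if np.any(y["ILM"] < 0):
        raise ValueError("retina does not fit in the image: increase n_rows")

    if seg_bias_px:
        y["GCL_IPL"] = y["GCL_IPL"] + seg_bias_px
    if seg_noise_px:
        if rng is None:
            raise ValueError("seg_noise_px > 0 requires an rng")
        for b in y:
            y[b] = y[b] + rng.normal(0.0, seg_noise_px, size=grid.n_ascans)
    # re-impose ordering (noise can cross boundaries where layers vanish)
    order = ("ILM", "RNFL_GCL", "GCL_IPL", "IPL_INL", "OPL", "RPE")
    prev = y[order[0]]
    for b in order[1:]:
        y[b] = np.maximum(y[b], prev)
        prev = y[b]

    meta = ScanMeta(
        scan_id=scan_id or f"{participant or 'phantom'}_{eye}_{orientation}",
        participant=participant,
        eye=eye,
        orientation=orientation,
        nominal_length_mm=grid.nominal_length_mm,
        n_ascans=grid.n_ascans,
        axial_um_per_px=grid.axial_um_per_px,
        axial_length_mm=grid.axial_length_mm,
        repeat=repeat,
    )
    contours = SegmentationContours(boundaries=y, meta=meta, n_rows=grid.n_rows)

    neg, pos = ("temporal", "nasal") if axis == "nt" else ("inferior", "superior")
    truth: dict[str, ThicknessProfile] = {}
    ecc = np.sort(u)
    for layer in ("TRT", "GCL", "IPL", "GCIPL"):
        truth[layer] = ThicknessProfile(
            ecc_mm=ecc,
            thickness_um=layer_thickness_um(phenotype, layer, ecc, axis=axis),
            layer=layer,
            meta=meta,
            centered=True,
            neg_label=neg,
            pos_label=pos,
        )
    return contours, truth


# ---------------------------------------------------------------------------
# closed-form quadrant AUC oracle


def _gauss_int(sigma: float, L: float) -> float:
    """∫₀ᴸ exp(−x²/2σ²) dx."""
    return sigma * sqrt(pi / 2.0) * erf(L / (sigma * sqrt(2.0)))


def _phi_gauss_int(sigma: float, w: float, L: float) -> float:
    """∫₀ᴸ Φ(x/w)·exp(−x²/2σ²) dx  via Owen's T.

    With x = σu this is σ√(2π)·∫₀^{L/σ} Φ(bu)φ(u)du, b = σ/w, and
    ∫₀ʰ Φ(bu)φ(u)du = Φ(h)/2 − 1/4 + arctan(b)/2π − T(h, b).
    """
    h = L / sigma
    b = sigma / w
    f = ndtr(h) / 2.0 - 0.25 + atan(b) / (2.0 * pi) - float(owens_t(h, b))
    return sigma * sqrt(2.0 * pi) * f


def _phi_int(w: float, L: float) -> float:
    """∫₀ᴸ Φ(x/w) dx = L·Φ(L/w) + w·[φ(L/w) − φ(0)]."""
    phi = lambda z: np.exp(-z * z / 2.0) / sqrt(2.0 * pi)
    return L * float(ndtr(L / w)) + w * (phi(L / w) - phi(0.0))


def analytic_quadrant_auc(
    phenotype: FoveaPhenotype,
    layer: str,
    quadrant: str,
    halfwidth_mm: float = 2.5,
) -> float:
    """Exact area (mm²) under the generative thickness over one quadrant.

    Uses the error-function / Owen's-T closed form of the blended
    difference-of-Gaussians profile.  If the max(0, ·) clamp is active
    anywhere on the quadrant the closed form is invalid; the function then
    warns and falls back to adaptive numerical quadrature of the clamped
    profile.
    """
    axes = {"temporal": ("nt", -1), "nasal": ("nt", +1),
            "inferior": ("si", -1), "superior": ("si", +1)}
    if quadrant not in axes:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    axis, sign = axes[quadrant]
    if layer in _COMPOSITE:
        return sum(
            analytic_quadrant_auc(phenotype, b, quadrant, halfwidth_mm)
            for b in _COMPOSITE[layer]
        )
    L = halfwidth_mm
    rho = phenotype.rho_eff(layer, axis)
    w = phenotype.blend_halfwidth_mm
    shape = phenotype.layers[layer]
    sp, sr = phenotype.sigma_pit_mm, phenotype.sigma_rim_mm

    # clamp check on a 1-µm grid
    xs = sign * np.arange(0.0, L + 5e-4, 1e-3)
    raw = layer_thickness_um(phenotype, layer, xs, axis=axis, clamp=False)
    if np.any(raw < 0):
        warnings.warn(
            f"{layer} thickness clamps to 0 on the {quadrant} quadrant; "
            "using adaptive quadrature instead of the closed form",
            ClampWarning,
            stacklevel=2,
        )
        val, _ = quad(
            lambda x: max(
                float(layer_thickness_um(phenotype, layer, np.array([x]), axis=axis,
                                         clamp=False)[0]),
                0.0,
            ),
            0.0 if sign > 0 else -L,
            L if sign > 0 else 0.0,
            limit=200,
        )
        return val / 1000.0

    A = (
        shape.baseline_um * L
        - shape.pit_um * _gauss_int(sp, L)
        + shape.rim_um * _gauss_int(sr, L)
    )
    if rho == 1.0:
        return A / 1000.0
    if w == 0.0:
        P = A  # step blend: the whole positive side is multiplied by rho
    else:
        P = (
            shape.baseline_um * _phi_int(w, L)
            - shape.pit_um * _phi_gauss_int(sp, w, L)
            + shape.rim_um * _phi_gauss_int(sr, w, L)
        )
    if sign > 0:
        area = A + (rho - 1.0) * P
    else:
        area = A + (rho - 1.0) * (A - P)
    # area-preserving normalisation of the side multiplier
    area *= 2.0 / (1.0 + rho)
    return area / 1000.0


# ---------------------------------------------------------------------------
# B-scan rendering


@dataclass
class MotionModel:
    """Inter- and intra-frame eye-motion statistics for rendering.

    Per-frame global shifts are drawn as rounded normals; explicit integer
    shift arrays may be supplied instead for exact-recovery fixtures.
    Dropped frames (blinks / saccade washout) are rendered as structureless
    noise.
    """

    lateral_sd_px: float = 3.0
    axial_sd_px: float = 2.0
    strip_jitter_sd_px: float = 0.0
    strip_width_px: int = 64
    drop_prob: float = 0.0
    lateral_shifts: np.ndarray | None = None  # (n_frames,) int override
    axial_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.lateral_sd_px, self.axial_sd_px, self.strip_jitter_sd_px) < 0:
            raise ValueError("motion SDs must be >= 0")
        if not 0 <= self.drop_prob <= 1:
            raise ValueError("drop_prob must be in [0, 1]")
        for name in ("lateral_shifts", "axial_shifts"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if not np.all(np.isfinite(v)) or np.any(v != np.round(v)):
                    raise ValueError(f"{name} must be finite integers")
                setattr(self, name, v.astype(int))


#: mean reflectance of each region, vitread to sclerad (arbitrary units)
DEFAULT_INTENSITIES = {
    "vitreous": 0.05,
    "RNFL": 0.55,
    "GCL": 0.30,
    "IPL": 0.50,
    "INL_OPL": 0.28,
    "OUTER": 0.65,
    "below": 0.10,
}

DEFAULT_NOISE_LEVEL = 0.2  # multiplicative speckle SD as a fraction of intensity


def render_base_image(
    contours: SegmentationContours, intensities: dict | None = None
) -> np.ndarray:
    """Noise-free piecewise-constant B-scan image from boundary contours."""
    inten = intensities or DEFAULT_INTENSITIES
    n_rows = contours.n_rows or int(np.ceil(contours.boundaries["RPE"].max())) + 20
    rows = np.arange(n_rows)[:, None]
    img = np.full((n_rows, contours.n_columns), inten["vitreous"])
    y = contours.boundaries
    for band in BAND_NAMES:
        upper, lower = _BAND_BOUNDARY[band]
        mask = (rows >= y[upper][None, :]) & (rows < y[lower][None, :])
        img[mask] = inten[band]
    img[rows >= y["RPE"][None, :]] = inten["below"]
    return img


def render_bscan_stack(
    contours: SegmentationContours,
    motion: MotionModel | None = None,
    n_frames: int = 40,
    noise_level: float = DEFAULT_NOISE_LEVEL,
    seed: int = 0,
    intensities: dict | None = None,
) -> BScanStack:
    """Render a multi-frame stack with known motion and speckle.

    Frame k is the base image circularly translated by its true (axial,
    lateral) shift, with optional per-strip extra axial jitter, multiplied by
    gamma speckle of unit mean and SD ``noise_level``.  Ground-truth shifts,
    per-strip jitter and dropped-frame flags are stored in ``true_shifts``.
    Deterministic under a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    motion = motion or MotionModel(lateral_sd_px=0.0, axial_sd_px=0.0)
    rng = np.random.default_rng(seed)
    base = render_base_image(contours, intensities)
    h, w = base.shape

    if motion.axial_shifts is not None:
        dys = np.asarray(motion.axial_shifts, dtype=int)
        if dys.size != n_frames:
            raise ValueError("axial_shifts length must equal n_frames")
    else:
        dys = np.round(rng.normal(0.0, motion.axial_sd_px, n_frames)).astype(int)
    if motion.lateral_shifts is not None:
        dxs = np.asarray(motion.lateral_shifts, dtype=int)
        if dxs.size != n_frames:
            raise ValueError("lateral_shifts length must equal n_frames")
    else:
        dxs = np.round(rng.normal(0.0, motion.lateral_sd_px, n_frames)).astype(int)
    if np.any(np.abs(dys) >= h) or np.any(np.abs(dxs) >= w):
        raise ValueError("true shift exceeds the image bounds")

    strips = list(range(0, w, motion.strip_width_px))
    n_strips = len(strips)
    strip_jit = np.zeros((n_frames, n_strips), dtype=int)
    if motion.strip_jitter_sd_px > 0:
        strip_jit = np.round(
            rng.normal(0.0, motion.strip_jitter_sd_px, (n_frames, n_strips))
        ).astype(int)
    dropped = rng.random(n_frames) < motion.drop_prob

    frames = np.empty((n_frames, h, w))
    for k in range(n_frames):
        if dropped[k]:
            frames[k] = rng.uniform(0.0, 0.3, (h, w))
            continue
        f = np.roll(base, (dys[k], dxs[k]), axis=(0, 1))
        for s, col0 in enumerate(strips):
            if strip_jit[k, s]:
                sl = slice(col0, min(col0 + motion.strip_width_px, w))
                f[:, sl] = np.roll(f[:, sl], strip_jit[k, s], axis=0)
        if noise_level > 0:
            shape_k = 1.0 / noise_level**2
            f = f * rng.gamma(shape_k, 1.0 / shape_k, (h, w))
        frames[k] = f

    meta = {
        "nominal_length_mm": contours.meta.nominal_length_mm,
        "n_ascans": contours.meta.n_ascans,
        "axial_um_per_px": contours.meta.axial_um_per_px,
        "eye": contours.meta.eye,
        "orientation": contours.meta.orientation,
        "axial_length_mm": contours.meta.axial_length_mm,
        "scan_id": contours.meta.scan_id,
        "noise_level": noise_level,
        "seed": seed,
    }
    true_shifts = {
        "axial": dys,
        "lateral": dxs,
        "strip_axial": strip_jit,
        "strip_columns": np.array(strips),
        "dropped": dropped,
    }
    return BScanStack(frames=frames, meta=meta, true_shifts=true_shifts)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortRanges:
    """Population parameter ranges for synthetic cohorts.

    Defaults reproduce the study's group structure: 25 vs 30 participants,
    nasal:temporal GCL asymmetry centered at 1.20 (controls) and 1.45
    (albinism) with the albinism range strictly above the control range,
    roughly balanced sex, and axial lengths centered at 24.1 vs 23.2 mm.
    """

    control_rho_nt: tuple = (1.04, 1.36)
    albinism_rho_nt: tuple = (1.37, 1.53)
    control_rho_si: tuple = (0.96, 1.16)
    albinism_rho_si: tuple = (0.90, 1.08)
    control_age: tuple = (26.2, 6.9)  # mean, SD (years); truncated at age_limits
    albinism_age: tuple = (24.3, 11.9)
    age_limits: tuple = (8.0, 60.0)
    control_al: tuple = (24.08, 1.05)  # mean, SD (mm)
    albinism_al: tuple = (23.19, 1.63)
    al_limits: tuple = (19.0, 28.0)
    inter_eye_al_sd: float = 0.15
    p_female_control: float = 0.48
    p_female_albinism: float = 0.467
    pit_scale_range: tuple = (0.85, 1.10)  # per-participant pit-depth factor (controls)
    baseline_scale_range: tuple = (0.95, 1.05)
    albinism_grades: tuple = ("grade1", "grade2", "grade3", "grade4")
    albinism_single_eye_frac: float = 0.5
    center_offset_sd_mm: float = 0.10
    center_offset_max_mm: float = 0.25
    seg_noise_px: float = 0.4
    seg_bias_px: float = 0.03  # first repeat segmented slightly thicker
    observer_mark_sd_mm: float = 0.05
    observers: tuple = ("obs1", "obs2")

    def __post_init__(self) -> None:
        if self.albinism_rho_nt[0] <= self.control_rho_nt[1]:
            raise ValueError(
                "albinism rho_nt range must lie strictly above the control range"
            )


@dataclass
class ScanRecord:
    """One eye/orientation scan of one participant: two repeat segmentations
    of the same ground truth, plus foveal-localization inputs."""

    contours_rep1: SegmentationContours
    contours_rep2: SegmentationContours
    truth_center_mm: float  # raw scan coordinates
    truth: dict  # ground-truth ThicknessProfiles (anatomical axis)
    observer_marks_mm: list | None = None  # albinism only


@dataclass
class CohortData:
    """A synthetic cohort: demographics table, scans, and true phenotypes."""

    table: pd.DataFrame
    scans: dict  # (participant, eye, orientation) -> ScanRecord
    phenotypes: dict  # participant -> FoveaPhenotype


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    v = rng.normal(mean, sd, size)
    return np.clip(v, lo, hi)


def make_cohort(
    n_control: int = 25,
    n_albinism: int = 30,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    grid: ScanGrid | None = None,
    orientations: tuple = ("horizontal", "vertical"),
) -> CohortData:
    """Generate a control + albinism cohort with per-eye, per-orientation scans.

    Controls contribute both eyes; a configurable fraction of albinism
    participants contribute one eye only (as in the study's scan inventory).
    Each scan carries two repeat segmentations (independent contour noise,
    the first biased marginally thicker) and, for albinism, two observer
    foveal marks.  Ground-truth phenotype parameters are stored in the table
    for parameter-recovery tests.  Seed-deterministic throughout.
    """
    if n_control < 1 or n_albinism < 1:
        raise ValueError("each group needs at least one participant")
    ranges = ranges or CohortRanges()
    # nominal 7 mm scans keep ±2.5 mm coverage even at short axial lengths
    grid = grid or ScanGrid(nominal_length_mm=7.0)
    rng = np.random.default_rng(seed)

    rows = []
    scans: dict = {}
    phenotypes: dict = {}
    specs = [("control", i) for i in range(n_control)] + [
        ("albinism", i) for i in range(n_albinism)
    ]
    for group, i in specs:
        pid = f"{'CTRL' if group == 'control' else 'ALB'}_{i:03d}"
        if group == "control":
            age = float(np.round(_trunc_normal(rng, *ranges.control_age, *ranges.age_limits)))
            sex = "F" if rng.random() < ranges.p_female_control else "M"
            al = float(_trunc_normal(rng, *ranges.control_al, *ranges.al_limits))
            rho_nt = float(rng.uniform(*ranges.control_rho_nt))
            rho_si = float(rng.uniform(*ranges.control_rho_si))
            grade = "control"
            pit_scale = float(rng.uniform(*ranges.pit_scale_range))
            eyes = ("OD", "OS")
        else:
            age = float(np.round(_trunc_normal(rng, *ranges.albinism_age, *ranges.age_limits)))
            sex = "F" if rng.random() < ranges.p_female_albinism else "M"
            al = float(_trunc_normal(rng, *ranges.albinism_al, *ranges.al_limits))
            rho_nt = float(rng.uniform(*ranges.albinism_rho_nt))
            rho_si = float(rng.uniform(*ranges.albinism_rho_si))
            grade = str(rng.choice(list(ranges.albinism_grades)))
            pit_scale = 1.0
            single = rng.random() < ranges.albinism_single_eye_frac
            eyes = (str(rng.choice(["OD", "OS"])),) if single else ("OD", "OS")
        base_scale = float(rng.uniform(*ranges.baseline_scale_range))
        # pit depth varies relative to overall retinal size, so the pit can
        # never out-deepen a thinner participant's layers
        phen = phenotype_preset(grade, rho_nt=rho_nt, rho_si=rho_si).scaled(
            pit_factor=pit_scale * base_scale, baseline_factor=base_scale
        )
        phenotypes[pid] = phen

        al_od = al + float(rng.normal(0.0, ranges.inter_eye_al_sd))
        al_os = al + float(rng.normal(0.0, ranges.inter_eye_al_sd))
        al_by_eye = {"OD": np.clip(al_od, *ranges.al_limits),
                     "OS": np.clip(al_os, *ranges.al_limits)}
        rows.append(
            {
                "participant": pid,
                "group": group,
                "age_years": age,
                "sex": sex,
                "al_od_mm": round(float(al_by_eye["OD"]), 2) if "OD" in eyes else np.nan,
                "al_os_mm": round(float(al_by_eye["OS"]), 2) if "OS" in eyes else np.nan,
                "eyes": "+".join(eyes),
                "grade": grade,
                "rho_nt_true": rho_nt,
                "rho_si_true": rho_si,
                "pit_scale_true": pit_scale,
            }
        )

        for eye in eyes:
            for orientation in orientations:
                off = float(
                    np.clip(
                        rng.normal(0.0, ranges.center_offset_sd_mm),
                        -ranges.center_offset_max_mm,
                        ranges.center_offset_max_mm,
                    )
                )
                g = replace(
                    grid,
                    axial_length_mm=float(al_by_eye[eye]),
                    center_offset_mm=off,
                )
                common = dict(
                    phenotype=phen,
                    orientation=orientation,
                    grid=g,
                    eye=eye,
                    seg_noise_px=ranges.seg_noise_px,
                    rng=rng,
                    participant=pid,
                    scan_id=f"{pid}_{eye}_{orientation[0].upper()}",
                )
                c1, truth = make_boundary_profiles(
                    seg_bias_px=ranges.seg_bias_px, repeat=1, **common
                )
                c2, _ = make_boundary_profiles(seg_bias_px=0.0, repeat=2, **common)
                marks = None
                if group == "albinism":
                    marks = [
                        g.center_mm + float(rng.normal(0.0, ranges.observer_mark_sd_mm))
                        for _ in ranges.observers
                    ]
                scans[(pid, eye, orientation)] = ScanRecord(
                    contours_rep1=c1,
                    contours_rep2=c2,
                    truth_center_mm=g.center_mm,
                    truth=truth,
                    observer_marks_mm=marks,
                )

    table = pd.DataFrame(rows)
    return CohortData(table=table, scans=scans, phenotypes=phenotypes)
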