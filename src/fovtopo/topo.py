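"""Interpolated thickness grids, quadrant areas, and asymmetry metrics.

Thickness-vs-eccentricity profiles are resampled onto a fixed 100-µm grid
spanning ±2.5 mm of the foveal center (51 samples), then summarised per
quadrant as the area under the thickness curve (AUC, mm²) by trapezoidal
integration.  Nasal:temporal and superior:inferior AUC ratios quantify
topographic asymmetry of a layer; the percent contribution of the ganglion
cell layer (GCL) to the combined GCL+IPL (GCIPL) profiles how the two inner
layers share the measurement at each eccentricity.

Conventions
-----------
* Eccentricity is in mm, signed: positive = nasal (horizontal scans) or
  superior (vertical scans).  Thickness is in µm; AUC converts to mm².
* The foveal sample (eccentricity 0) belongs to both quadrants, so the two
  quadrant AUCs of one scan sum to the full ±2.5 mm integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ThicknessProfile",
    "CoverageError",
    "MissingQuadrantError",
    "interpolate_grid",
    "quadrant_auc",
    "summed_auc",
    "asymmetry_ratio",
    "gcl_fraction",
    "average_repeats",
    "mirror_profile",
    "QUADRANTS",
]

#: canonical quadrant names, in metrics-table order
QUADRANTS = ("temporal", "nasal", "inferior", "superior")


class CoverageError(ValueError):
    """Profile does not cover the required eccentricity range."""


class MissingQuadrantError(KeyError):
    """A four-quadrant summary was requested with a quadrant absent."""


@dataclass
class ThicknessProfile:
    """One layer's thickness as a function of position along a line scan.

    ``ecc_mm`` is strictly increasing.  Before foveal recentering it is the
    raw scan abscissa (origin at column 0); after
    :func:`fovtopo.fovea.eccentricity_axis` it is signed eccentricity with
    ``neg_label``/``pos_label`` naming the two quadrants.
    """

    ecc_mm: np.ndarray
    thickness_um: np.ndarray
    layer: str
    meta: object | None = None
    centered: bool = False
    gridded: bool = False
    neg_label: str | None = None
    pos_label: str | None = None

    def __post_init__(self) -> None:
        self.ecc_mm = np.asarray(self.ecc_mm, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if self.ecc_mm.shape != self.thickness_um.shape:
            raise ValueError("ecc_mm and thickness_um must have equal length")
        if self.ecc_mm.size >= 2 and not np.all(np.diff(self.ecc_mm) > 0):
            raise ValueError("eccentricity axis must be strictly increasing")

    @property
    def n(self) -> int:
        return self.ecc_mm.size

    def quadrant_of(self, sign: int) -> str | None:
        return self.pos_label if sign > 0 else self.neg_label


def grid_eccentricities(step_mm: float = 0.1, halfwidth_mm: float = 2.5) -> np.ndarray:
    """The fixed resampling grid: ±halfwidth inclusive at ``step_mm`` spacing."""
    n_side = round(halfwidth_mm / step_mm)
    if abs(n_side * step_mm - halfwidth_mm) > 1e-9:
        raise ValueError("halfwidth_mm must be an integer multiple of step_mm")
    return np.linspace(-halfwidth_mm, halfwidth_mm, 2 * n_side + 1)


def interpolate_grid(
    profile: ThicknessProfile,
    step_mm: float = 0.1,
    halfwidth_mm: float = 2.5,
) -> ThicknessProfile:
    """Linearly resample a centered profile at fixed 100-µm eccentricities.

    Raises :class:`CoverageError` naming the missing extent when the scan
    does not reach ±``halfwidth_mm``, mirroring the exclusion of scans that
    are too short to analyse.
    """
    if not profile.centered:
        raise ValueError("profile must be recentered on the fovea before gridding")
    grid = grid_eccentricities(step_mm, halfwidth_mm)
    lo, hi = profile.ecc_mm[0], profile.ecc_mm[-1]
    tol = 1e-9
    if lo > -halfwidth_mm + tol or hi < halfwidth_mm - tol:
        missing = []
        if lo > -halfwidth_mm + tol:
            missing.append(f"negative side reaches only {lo:+.3f} mm")
        if hi < halfwidth_mm - tol:
            missing.append(f"positive side reaches only {hi:+.3f} mm")
        raise CoverageError(
            f"scan covers [{lo:+.3f}, {hi:+.3f}] mm, needs ±{halfwidth_mm} mm: "
            + "; ".join(missing)
        )
    thickness = np.interp(grid, profile.ecc_mm, profile.thickness_um)
    return replace(profile, ecc_mm=grid, thickness_um=thickness, gridded=True)


def quadrant_auc(profile: ThicknessProfile, quadrant: str) -> float:
    """Trapezoidal area (mm²) under one quadrant of a gridded profile.

    The quadrant is the [0, +halfwidth] or [−halfwidth, 0] side whose label
    matches ``quadrant``; the eccentricity-0 sample is shared by both.
    """
    if not profile.gridded:
        raise ValueError("quadrant_auc requires a gridded profile (interpolate_grid)")
    if quadrant == profile.pos_label:
        mask = profile.ecc_mm >= -1e-12
    elif quadrant == profile.neg_label:
        mask = profile.ecc_mm <= 1e-12
    else:
        raise ValueError(
            f"quadrant {quadrant!r} not in this scan's quadrants "
            f"({profile.neg_label!r}, {profile.pos_label!r})"
        )
    x = profile.ecc_mm[mask]
    y = profile.thickness_um[mask] / 1000.0  # µm -> mm
    return float(np.trapezoid(y, x))


def summed_auc(aucs: Mapping[str, float]) -> float:
    """Sum of the four quadrant AUCs (both scan orientations of one eye)."""
    missing = [q for q in QUADRANTS if q not in aucs or aucs[q] is None or np.isnan(aucs[q])]
    if missing:
        raise MissingQuadrantError(
            f"cannot sum four-quadrant AUC, missing quadrant(s): {', '.join(missing)}"
        )
    return float(sum(aucs[q] for q in QUADRANTS))


def asymmetry_ratio(auc_positive: float, auc_negative: float) -> float:
    """Quadrant AUC ratio: nasal/temporal (horizontal) or superior/inferior."""
    if auc_negative <= 0:
        raise ZeroDivisionError("asymmetry ratio undefined: denominator quadrant AUC <= 0")
    return float(auc_positive) / float(auc_negative)


def gcl_fraction(
    gcl: ThicknessProfile,
    gcipl: ThicknessProfile,
    min_gcipl_um: float = 1.0,
) -> np.ndarray:
    """Percent contribution of the GCL to the GCIPL at each grid point.

    Points where the GCIPL is thinner than ``min_gcipl_um`` (the fully
    excavated foveal center) are masked as NaN rather than divided.
    """
    if not (gcl.gridded and gcipl.gridded):
        raise ValueError("gcl_fraction requires gridded profiles")
    if gcl.ecc_mm.shape != gcipl.ecc_mm.shape or not np.allclose(gcl.ecc_mm, gcipl.ecc_mm):
        raise ValueError("grid mismatch between GCL and GCIPL profiles")
    frac = np.full(gcl.n, np.nan)
    ok = gcipl.thickness_um >= min_gcipl_um
    frac[ok] = 100.0 * gcl.thickness_um[ok] / gcipl.thickness_um[ok]
    return frac


def average_repeats(first: ThicknessProfile, second: ThicknessProfile) -> ThicknessProfile:
    """Pointwise mean of two repeat measurements of the same scan."""
    if first.layer != second.layer:
        raise ValueError(f"layer mismatch: {first.layer!r} vs {second.layer!r}")
    if first.ecc_mm.shape != second.ecc_mm.shape or not np.allclose(
        first.ecc_mm, second.ecc_mm
    ):
        raise ValueError("repeat measurements are not on the same grid")
    for attr in ("gridded", "centered", "neg_label", "pos_label"):
        if getattr(first, attr) != getattr(second, attr):
            raise ValueError(f"metadata mismatch between repeats: {attr}")
    mean = 0.5 * (first.thickness_um + second.thickness_um)
    return replace(first, thickness_um=mean)


def mirror_profile(profile: ThicknessProfile) -> ThicknessProfile:
    """Flip a centered profile about the fovea, swapping the quadrant labels."""
    if not profile.centered:
        raise ValueError("mirror_profile requires a centered profile")
    return replace(
        profile,
        ecc_mm=-profile.ecc_mm[::-1],
        thickness_um=profile.thickness_um[::-1].copy(),
        neg_label=profile.pos_label,
        pos_label=profile.neg_label,
    )
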