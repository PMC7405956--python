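"""Boundary contours to physically scaled thickness profiles.

Segmentation exports give one axial (y) pixel coordinate per retinal
boundary per A-scan column.  This module converts boundary pairs into layer
thickness in µm using the device axial scale, and builds the lateral axis in
mm using the participant's axial length: the true scan length is the nominal
length times AL / 24 mm (the scanner's assumed axial length), divided by the
number of A-scans per B-scan.

Layers measured (top to bottom boundary pairs):

====== =====================================
TRT    ILM to RPE (total retinal thickness)
GCL    RNFL/GCL boundary to GCL/IPL boundary
IPL    GCL/IPL boundary to IPL/INL boundary
GCIPL  RNFL/GCL boundary to IPL/INL boundary
====== =====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .topo import ThicknessProfile

__all__ = [
    "BOUNDARIES",
    "LAYER_BOUNDS",
    "DEFAULT_AXIAL_UM_PER_PX",
    "ScanMeta",
    "ScaleModel",
    "SegmentationContours",
    "BoundaryOrderError",
    "lateral_scale_um_per_ascan",
    "thickness_profiles",
]

#: boundary names, anatomical top (vitread) to bottom (sclerad)
BOUNDARIES = ("ILM", "RNFL_GCL", "GCL_IPL", "IPL_INL", "OPL", "RPE")

#: (upper boundary, lower boundary) defining each reported layer
LAYER_BOUNDS: Mapping[str, tuple[str, str]] = {
    "TRT": ("ILM", "RPE"),
    "GCL": ("RNFL_GCL", "GCL_IPL"),
    "IPL": ("GCL_IPL", "IPL_INL"),
    "GCIPL": ("RNFL_GCL", "IPL_INL"),
}

# Device axial sampling.  Configuration, not recomputed from image content:
# the axial scale comes from the manufacturer specification of the scanner.
DEFAULT_AXIAL_UM_PER_PX = 3.24

ASSUMED_AXIAL_LENGTH_MM = 24.0
DEFAULT_N_ASCANS = 1000


class BoundaryOrderError(ValueError):
    """Two boundaries cross: the anatomically lower one sits above the upper."""


def lateral_scale_um_per_ascan(
    nominal_length_mm: float,
    axial_length_mm: float,
    n_ascans: int = DEFAULT_N_ASCANS,
    assumed_al_mm: float = ASSUMED_AXIAL_LENGTH_MM,
) -> float:
    """Axial-length-corrected lateral sampling, in µm per A-scan.

    The corrected scan length is ``nominal × (AL / assumed AL)``; dividing by
    the A-scans per B-scan gives the per-column spacing.

    >>> lateral_scale_um_per_ascan(6.0, 24.0)
    6.0
    """
    if nominal_length_mm <= 0 or axial_length_mm <= 0:
        raise ValueError("nominal scan length and axial length must be positive")
    if n_ascans <= 0 or assumed_al_mm <= 0:
        raise ValueError("n_ascans and assumed axial length must be positive")
    return nominal_length_mm * 1000.0 * (axial_length_mm / assumed_al_mm) / n_ascans


@dataclass
class ScanMeta:
    """Acquisition metadata carried with contours and thickness profiles."""

    scan_id: str = ""
    participant: str = ""
    eye: str | None = None  # "OD" | "OS"
    orientation: str | None = None  # "horizontal" | "vertical"
    nominal_length_mm: float = 6.0
    n_ascans: int = DEFAULT_N_ASCANS
    axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX
    axial_length_mm: float = ASSUMED_AXIAL_LENGTH_MM
    foveal: bool = True  # reviewer inclusion flag: scan represents the (incipient) fovea
    repeat: int = 1


@dataclass
class ScaleModel:
    """Physical pixel scales of one scan."""

    axial_um_per_px: float
    lateral_um_per_ascan: float

    def __post_init__(self) -> None:
        if self.axial_um_per_px <= 0 or self.lateral_um_per_ascan <= 0:
            raise ValueError("scales must be positive")

    @classmethod
    def from_meta(cls, meta: ScanMeta) -> "ScaleModel":
        return cls(
            axial_um_per_px=meta.axial_um_per_px,
            lateral_um_per_ascan=lateral_scale_um_per_ascan(
                meta.nominal_length_mm, meta.axial_length_mm, meta.n_ascans
            ),
        )


@dataclass
class SegmentationContours:
    """Per-boundary y(x) traces, one y pixel value per A-scan column."""

    boundaries: dict[str, np.ndarray]
    meta: ScanMeta = field(default_factory=ScanMeta)
    n_rows: int | None = None

    def __post_init__(self) -> None:
        missing = [b for b in BOUNDARIES if b not in self.boundaries]
        if missing:
            raise ValueError(f"missing boundary trace(s): {', '.join(missing)}")
        self.boundaries = {b: np.asarray(self.boundaries[b], dtype=float) for b in BOUNDARIES}
        n = {v.size for v in self.boundaries.values()}
        if len(n) != 1:
            raise ValueError("all boundary traces must have the same number of columns")

    @property
    def n_columns(self) -> int:
        return self.boundaries["ILM"].size

    def validate(self, tol_px: float = 1e-6) -> None:
        """Check the top-to-bottom boundary ordering at every column."""
        for upper, lower in zip(BOUNDARIES[:-1], BOUNDARIES[1:]):
            diff = self.boundaries[lower] - self.boundaries[upper]
            bad = np.flatnonzero(diff < -tol_px)
            if bad.size:
                col = int(bad[0])
                raise BoundaryOrderError(
                    f"boundary {lower} lies above {upper} at column {col} "
                    f"(by {-diff[col]:.3f} px)"
                )


def thickness_profiles(
    contours: SegmentationContours,
    scale: ScaleModel | None = None,
) -> dict[str, ThicknessProfile]:
    """Thickness profiles (µm vs mm) for TRT, GCL, IPL, and GCIPL.

    Thickness at a column is (lower − upper boundary) × axial µm/px; the
    abscissa is column index × lateral µm per A-scan, origin at column 0
    (recentred on the fovea later).  GCL + IPL equals GCIPL by construction,
    since both use the same boundary arithmetic.
    """
    contours.validate()
    if scale is None:
        scale = ScaleModel.from_meta(contours.meta)
    x_mm = np.arange(contours.n_columns) * scale.lateral_um_per_ascan / 1000.0
    out: dict[str, ThicknessProfile] = {}
    for layer, (upper, lower) in LAYER_BOUNDS.items():
        thickness = (
            contours.boundaries[lower] - contours.boundaries[upper]
        ) * scale.axial_um_per_px
        out[layer] = ThicknessProfile(
            ecc_mm=x_mm, thickness_um=thickness, layer=layer, meta=contours.meta
        )
    return out
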