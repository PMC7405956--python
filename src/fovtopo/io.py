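"""Readers and writers for the on-disk interchange formats.

* Contours CSV: ``column_px, ILM, RNFL_GCL, GCL_IPL, IPL_INL, OPL, RPE``
  (y in pixels, row 0 = image top), one row per A-scan column.
* B-scan stack: multi-page grayscale TIFF plus a JSON sidecar carrying scan
  metadata and (for phantoms) the true shifts.
* Thickness CSV: ``eccentricity_um, TRT, GCL, IPL, GCIPL``.
* Observer marks CSV: ``scan_id, observer, abscissa_mm``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layers import BOUNDARIES, ScanMeta, SegmentationContours
from .register import BScanStack

__all__ = [
    "write_contours_csv",
    "read_contours_csv",
    "write_stack",
    "read_stack",
    "write_thickness_csv",
    "read_observer_marks",
    "write_json",
]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def write_contours_csv(contours: SegmentationContours, path) -> None:
    df = pd.DataFrame({"column_px": np.arange(contours.n_columns)})
    for b in BOUNDARIES:
        df[b] = contours.boundaries[b]
    df.to_csv(path, index=False)


def read_contours_csv(path, meta: ScanMeta | None = None) -> SegmentationContours:
    df = pd.read_csv(path)
    missing = [b for b in BOUNDARIES if b not in df.columns]
    if missing:
        raise ValueError(f"contours file lacks column(s): {', '.join(missing)}")
    return SegmentationContours(
        boundaries={b: df[b].to_numpy(dtype=float) for b in BOUNDARIES},
        meta=meta or ScanMeta(),
    )


def write_stack(stack: BScanStack, tiff_path, sidecar_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(
        tiff_path, stack.frames.astype(np.float32), photometric="minisblack"
    )
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    payload = dict(stack.meta)
    if stack.true_shifts is not None:
        payload["true_shifts"] = {k: v for k, v in stack.true_shifts.items()}
    write_json(payload, sidecar)


def read_stack(tiff_path, sidecar_path=None) -> BScanStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    true_shifts = meta.pop("true_shifts", None)
    if true_shifts is not None:
        true_shifts = {k: np.asarray(v) for k, v in true_shifts.items()}
    return BScanStack(frames=frames, meta=meta, true_shifts=true_shifts)


def write_thickness_csv(profiles: dict, path) -> None:
    """Write a set of (commonly gridded) profiles sharing one abscissa."""
    layers = list(profiles)
    first = profiles[layers[0]]
    df = pd.DataFrame({"eccentricity_um": np.round(first.ecc_mm * 1000.0, 6)})
    for layer in layers:
        p = profiles[layer]
        if p.ecc_mm.shape != first.ecc_mm.shape or not np.allclose(p.ecc_mm, first.ecc_mm):
            raise ValueError("profiles do not share an abscissa")
        df[layer] = p.thickness_um
    df.to_csv(path, index=False)


def read_observer_marks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"scan_id", "observer", "abscissa_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"observer marks file needs columns {sorted(need)}")
    return df
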