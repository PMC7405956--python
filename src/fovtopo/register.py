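"""Frame and strip registration of multi-frame B-scan stacks, and averaging.

A line scan is acquired as tens of frames at one retinal location; eye
motion (drift, nystagmus) translates each frame and can shear within a
frame.  The processing chain is:

1. :func:`global_register` — translate every frame onto a chosen reference
   frame, using the argmax of the circular FFT cross-correlation.
2. :func:`strip_register` — split each frame into lateral strips (blocks of
   A-scan columns) and align each strip independently, correcting
   intra-frame axial drift.
3. :func:`select_and_average` — rank frames (or strips) by their normalized
   cross-correlation (NCC) with the reference, keep those with NCC ≥ 0.85,
   and average the best 30 per pixel.

NCC is computed on mean-subtracted, unit-variance data over the mutually
valid region only; regions rolled in from the opposite edge by a translation
are masked out of both NCC and the average.  Translation-only registration
is used deliberately: frame-to-frame B-scan motion is dominated by
translation, and integer-pixel shifts keep the phantom ground truth exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "BScanStack",
    "NoUnitsPassError",
    "ncc",
    "choose_reference",
    "global_register",
    "strip_register",
    "select_and_average",
    "make_strips",
    "DEFAULT_NCC_THRESHOLD",
    "DEFAULT_MAX_FRAMES",
    "DEFAULT_STRIP_WIDTH",
]

DEFAULT_NCC_THRESHOLD = 0.85
DEFAULT_MAX_FRAMES = 30
DEFAULT_STRIP_WIDTH = 64
MIN_STRIP_WIDTH = 8


class NoUnitsPassError(RuntimeError):
    """No frame/strip met the NCC threshold; the scan cannot be averaged."""


@dataclass
class BScanStack:
    """A stack of B-scan frames plus registration state.

    ``shifts`` are (dy, dx) applied (via circular roll) to bring each frame
    onto the reference; ``frame_valid`` masks the pixels of each aligned
    frame that did not wrap around an edge.  ``true_shifts`` carries phantom
    ground truth when the stack is synthetic.
    """

    frames: np.ndarray  # (n_frames, height, width)
    meta: dict = field(default_factory=dict)
    ref_index: int | None = None
    shifts: np.ndarray | None = None  # (n_frames, 2) int
    frame_ncc: np.ndarray | None = None  # (n_frames,)
    frame_valid: np.ndarray | None = None  # (n_frames, h, w) bool
    strip_slices: list | None = None
    strip_shifts: np.ndarray | None = None  # (n_frames, n_strips, 2)
    strip_ncc: np.ndarray | None = None  # (n_frames, n_strips)
    true_shifts: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation of two images over the valid region.

    Returns NaN for degenerate (constant) input, which callers treat as an
    automatic exclusion.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        a = a[mask]
        b = b[mask]
    a = a.ravel()
    b = b.ravel()
    if a.size < 2:
        return float("nan")
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _roll_mask(shape: tuple, dy: int, dx: int) -> np.ndarray:
    """Mask of pixels that are genuine (not wrapped) after roll by (dy, dx)."""
    h, w = shape
    mask = np.ones((h, w), dtype=bool)
    if dy > 0:
        mask[:dy, :] = False
    elif dy < 0:
        mask[dy:, :] = False
    if dx > 0:
        mask[:, :dx] = False
    elif dx < 0:
        mask[:, dx:] = False
    return mask


def _estimate_shift(ref: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer translation aligning ``moving`` to ``ref`` (argmax of the
    circular cross-correlation)."""
    shift, _, _ = phase_cross_correlation(
        ref, moving, upsample_factor=1, normalization=None
    )
    return int(round(shift[0])), int(round(shift[1]))


def choose_reference(stack: BScanStack, n_candidates: int = 10) -> int:
    """Default reference: the frame with the greatest mean pairwise NCC
    among ``n_candidates`` evenly sampled frames."""
    n = stack.n_frames
    idx = np.unique(np.linspace(0, n - 1, min(n_candidates, n)).round().astype(int))
    cand = [i for i in idx if stack.frames[i].std() > 0]
    if not cand:
        raise ValueError("all candidate reference frames are degenerate (constant)")
    if len(cand) == 1:
        return cand[0]
    score = []
    for i in cand:
        vals = [ncc(stack.frames[i], stack.frames[j]) for j in cand if j != i]
        vals = [v for v in vals if np.isfinite(v)]
        score.append(np.mean(vals) if vals else -np.inf)
    return cand[int(np.argmax(score))]


def global_register(stack: BScanStack, ref_index: int | None = None) -> BScanStack:
    """Translate every frame onto the reference frame.

    Each frame's shift is the argmax of its circular cross-correlation with
    the reference; the reference itself is unchanged (shift (0, 0), NCC 1).
    Constant frames cannot be correlated: they are kept with shift (0, 0)
    but flagged with NCC NaN so that selection excludes them.
    """
    if stack.n_frames < 2:
        raise ValueError("global registration needs at least 2 frames")
    if ref_index is None:
        ref_index = choose_reference(stack)
    ref = stack.frames[ref_index]
    if ref.std() == 0:
        raise ValueError(f"reference frame {ref_index} is degenerate (constant)")

    n = stack.n_frames
    aligned = np.empty_like(stack.frames)
    shifts = np.zeros((n, 2), dtype=int)
    valid = np.ones((n,) + stack.shape, dtype=bool)
    nccs = np.empty(n)
    for i in range(n):
        frame = stack.frames[i]
        if i == ref_index:
            aligned[i] = frame
            nccs[i] = 1.0
            continue
        if frame.std() == 0:
            aligned[i] = frame
            nccs[i] = float("nan")
            continue
        dy, dx = _estimate_shift(ref, frame)
        shifts[i] = (dy, dx)
        aligned[i] = np.roll(frame, (dy, dx), axis=(0, 1))
        valid[i] = _roll_mask(stack.shape, dy, dx)
        nccs[i] = ncc(ref[valid[i]], aligned[i][valid[i]])
    return replace(
        stack,
        frames=aligned,
        ref_index=ref_index,
        shifts=shifts,
        frame_ncc=nccs,
        frame_valid=valid,
    )


def make_strips(width: int, strip_width: int, min_width: int = MIN_STRIP_WIDTH) -> list:
    """Contiguous column blocks tiling the lateral extent.

    The last strip may be narrower; if narrower than ``min_width`` columns it
    is merged into its neighbor.
    """
    if strip_width < 1:
        raise ValueError("strip_width must be >= 1")
    edges = list(range(0, width, strip_width)) + [width]
    if len(edges) > 2 and edges[-1] - edges[-2] < min_width:
        edges.pop(-2)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def strip_register(
    stack: BScanStack,
    strip_width: int = DEFAULT_STRIP_WIDTH,
    min_width: int = MIN_STRIP_WIDTH,
) -> BScanStack:
    """Independently align lateral strips of each (globally aligned) frame.

    Each strip — a block of A-scan columns spanning the full depth — is
    translation-registered against the corresponding reference region, and
    its post-alignment NCC recorded.  Intra-frame axial drift thus gets
    corrected strip by strip.
    """
    if stack.ref_index is None:
        stack = global_register(stack)
    ref = stack.frames[stack.ref_index]
    strips = make_strips(stack.shape[1], strip_width, min_width)
    n, n_strips = stack.n_frames, len(strips)
    aligned = stack.frames.copy()
    valid = (
        stack.frame_valid.copy()
        if stack.frame_valid is not None
        else np.ones((n,) + stack.shape, dtype=bool)
    )
    s_shifts = np.zeros((n, n_strips, 2), dtype=int)
    s_ncc = np.empty((n, n_strips))
    for i in range(n):
        for k, sl in enumerate(strips):
            ref_strip = ref[:, sl]
            if i == stack.ref_index:
                s_ncc[i, k] = 1.0
                continue
            strip = aligned[i][:, sl]
            if strip.std() == 0 or ref_strip.std() == 0:
                s_ncc[i, k] = float("nan")
                continue
            dy, dx = _estimate_shift(ref_strip, strip)
            s_shifts[i, k] = (dy, dx)
            moved = np.roll(strip, (dy, dx), axis=(0, 1))
            vmask = valid[i][:, sl] & _roll_mask(strip.shape, dy, dx)
            aligned[i][:, sl] = moved
            valid[i][:, sl] = vmask
            s_ncc[i, k] = ncc(ref_strip[vmask], moved[vmask])
    return replace(
        stack,
        frames=aligned,
        frame_valid=valid,
        strip_slices=strips,
        strip_shifts=s_shifts,
        strip_ncc=s_ncc,
    )


def _rank_units(nccs: np.ndarray, threshold: float, max_units: int):
    """Indices of passing units, best NCC first; ties broken by lower index."""
    passing = [i for i, v in enumerate(nccs) if np.isfinite(v) and v >= threshold]
    order = sorted(passing, key=lambda i: (-nccs[i], i))
    return order[:max_units], order[max_units:], [
        i for i in range(len(nccs)) if i not in passing
    ]


def select_and_average(
    stack: BScanStack,
    threshold: float = DEFAULT_NCC_THRESHOLD,
    max_units: int = DEFAULT_MAX_FRAMES,
    level: str = "frame",
) -> tuple[np.ndarray, dict]:
    """Average the best-correlated frames (or strips) into the final image.

    Units with NCC ≥ ``threshold`` are ranked descending and the top
    ``max_units`` averaged per pixel (tie in NCC → earlier frame wins).  At
    ``level='strip'`` each strip position selects its frames independently,
    so parts of frames can enter the average; the coverage count per pixel is
    reported.  If no unit passes — anywhere, or for any strip position — the
    scan fails with :class:`NoUnitsPassError`, mirroring the exclusion of
    scans whose quality does not support averaging.
    """
    if level not in ("frame", "strip"):
        raise ValueError("level must be 'frame' or 'strip'")
    h, w = stack.shape
    acc = np.zeros((h, w))
    cov = np.zeros((h, w), dtype=int)
    valid = (
        stack.frame_valid
        if stack.frame_valid is not None
        else np.ones((stack.n_frames, h, w), dtype=bool)
    )
    report: dict = {"level": level, "threshold": threshold, "max_units": max_units,
                    "included": [], "excluded": []}

    if level == "frame":
        if stack.frame_ncc is None:
            raise ValueError("run global_register (and optionally strip_register) first")
        top, overflow, failed = _rank_units(stack.frame_ncc, threshold, max_units)
        if not top:
            raise NoUnitsPassError(
                f"no frame reached NCC >= {threshold}; scan excluded"
            )
        for i in top:
            acc += np.where(valid[i], stack.frames[i], 0.0)
            cov += valid[i]
            report["included"].append({"frame": i, "ncc": float(stack.frame_ncc[i])})
        for i in overflow + failed:
            v = float(stack.frame_ncc[i])
            reason = "over max_units" if i in overflow else "below threshold"
            report["excluded"].append({"frame": i, "ncc": v, "reason": reason})
    else:
        if stack.strip_ncc is None:
            raise ValueError("run strip_register before strip-level averaging")
        for k, sl in enumerate(stack.strip_slices):
            top, overflow, failed = _rank_units(stack.strip_ncc[:, k], threshold, max_units)
            if not top:
                raise NoUnitsPassError(
                    f"no frame's strip {k} (columns {sl.start}:{sl.stop}) reached "
                    f"NCC >= {threshold}; scan excluded"
                )
            for i in top:
                acc[:, sl] += np.where(valid[i][:, sl], stack.frames[i][:, sl], 0.0)
                cov[:, sl] += valid[i][:, sl]
                report["included"].append(
                    {"frame": i, "strip": k, "ncc": float(stack.strip_ncc[i, k])}
                )
            for i in overflow + failed:
                reason = "over max_units" if i in overflow else "below threshold"
                report["excluded"].append(
                    {"frame": i, "strip": k, "ncc": float(stack.strip_ncc[i, k]),
                     "reason": reason}
                )

    with np.errstate(invalid="ignore"):
        avg = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    report["coverage"] = cov
    report["coverage_min"] = int(cov.min())
    report["coverage_max"] = int(cov.max())
    report["n_included"] = len(report["included"])
    return avg, report
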