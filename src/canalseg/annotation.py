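"""Densification of sparse clinician tracings into dense canal masks.

Clinicians trace the canal on cross-sectional views at ~1 mm intervals;
the scan itself is sampled at 0.2-0.3 mm.  This module restores the
original slice interval by cubic interpolation of the binarised annotation
field along the slice axis: each (row, col) pixel position gets a cubic
interpolant through its annotated slice values, the field is clamped to
[0, 1] to suppress cubic overshoot, and thresholded at 0.5.  Annotated
slices are reproduced exactly (the interpolant passes through its data
points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import CanalSegError, FormatError
from .volume_io import BinaryMask

__all__ = [
    "TraceColorKey",
    "SparseAnnotation",
    "extract_canal_mask_from_tracing",
    "densify_annotation",
]


@dataclass(frozen=True)
class TraceColorKey:
    """Tracing color and per-channel tolerance for mask extraction."""

    color: tuple[int, int, int]
    tolerance: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise CanalSegError("tolerance must be >= 0")


@dataclass(frozen=True)
class SparseAnnotation:
    """Sparsely annotated canal slices along one axis of a volume.

    ``entries`` are (slice_index, 2D mask) with strictly increasing indices;
    ``axis`` is the slicing axis in the canonical (x, y, z) frame — default
    1 (anterior-posterior), the canonical axis closest to the clinical
    cross-sectional annotation direction for an arch-following canal.
    """

    entries: list[tuple[int, BinaryMask]]
    slice_spacing_mm: float
    annotation_interval_mm: float
    axis: int = 1

    def __post_init__(self) -> None:
        if self.annotation_interval_mm < self.slice_spacing_mm:
            raise CanalSegError("annotation interval must be >= slice spacing")
        idx = [i for i, _ in self.entries]
        if any(a >= b for a, b in zip(idx, idx[1:])):
            raise CanalSegError("slice indices must be strictly increasing")
        if self.axis not in (0, 1, 2):
            raise CanalSegError("axis must be 0, 1 or 2")


def extract_canal_mask_from_tracing(image: np.ndarray, key: TraceColorKey) -> BinaryMask:
    """Pixels whose channels all lie within ``key.tolerance`` of the trace
    color.  Input must be RGB (H, W, 3)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(
            f"tracing image must be RGB with 3 channels, got shape {image.shape}"
        )
    diff = np.abs(image.astype(np.int64) - np.asarray(key.color, dtype=np.int64))
    return BinaryMask(np.all(diff <= key.tolerance, axis=-1))


def densify_annotation(
    sparse: SparseAnnotation,
    n_slices: int,
    threshold: float = 0.5,
) -> BinaryMask:
    """Cubic interpolation of the sparse masks to every slice position.

    Returns a 3D mask with ``n_slices`` along ``sparse.axis``; slices before
    the first and after the last annotation stay empty.  Requires at least
    4 annotated slices for cubic support (fit fewer with a linear fallback
    by pre-densifying externally).
    """
    entries = sparse.entries
    if len(entries) < 4:
        raise CanalSegError(
            "cubic densification needs >= 4 annotated slices; "
            "annotate more slices or interpolate linearly"
        )
    idx = np.array([i for i, _ in entries])
    if idx[-1] >= n_slices or idx[0] < 0:
        raise CanalSegError("annotated slice index out of volume range")
    stack = np.stack([m.data.astype(np.float64) for _, m in entries], axis=0)
    spline = CubicSpline(idx.astype(np.float64), stack, axis=0, bc_type="natural")
    dense_idx = np.arange(idx[0], idx[-1] + 1)
    field = spline(dense_idx.astype(np.float64))
    field = np.clip(field, 0.0, 1.0)
    dense = field >= threshold
    # the interpolant passes through its nodes; enforce bitwise equality
    # against float round-off all the same
    pos = {int(i): k for k, (i, _) in enumerate(entries)}
    for j, i in enumerate(dense_idx):
        if int(i) in pos:
            dense[j] = entries[pos[int(i)]][1].data
    plane_shape = entries[0][1].data.shape
    shape3 = list(plane_shape)
    shape3.insert(sparse.axis, n_slices)
    out = np.zeros(shape3, dtype=bool)
    sl = [slice(None)] * 3
    sl[sparse.axis] = slice(int(idx[0]), int(idx[-1]) + 1)
    out[tuple(sl)] = np.moveaxis(dense, 0, sparse.axis)
    return BinaryMask(out)
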