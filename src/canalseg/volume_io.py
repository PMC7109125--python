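"""Volume and mask containers, NIfTI/DICOM readers, and geometry utilities.

Canonical axis convention used throughout the package:

* axis 0 = ``x``, left-right
* axis 1 = ``y``, anterior-posterior (anterior at low index)
* axis 2 = ``z``, inferior-superior (an axial slice is a fixed ``z``)

NIfTI volumes are reoriented to the closest RAS frame at read time so every
downstream stage (panorama projection, maxilla removal, annotation axes) can
reason in anatomical directions. Intensities are kept floating point: CBCT
units are scanner-arbitrary and are min-max normalised wherever a histogram
is needed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom
from skimage.transform import resize as _sk_resize

from .errors import CanalSegError, FormatError

__all__ = [
    "Volume",
    "BinaryMask",
    "BoundingBox",
    "read_volume",
    "write_volume",
    "read_mask",
    "downsample_half",
    "crop",
    "embed",
]


@dataclass(frozen=True)
class Volume:
    """A 3D scalar intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise FormatError(f"Volume data must be 3D, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise FormatError("Volume intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in mm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid (2D or 3D) aligned to the volume it annotates."""

    data: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise FormatError("mask values must be in {0, 1}")
            data = data.astype(bool)
        if data.ndim not in (2, 3):
            raise FormatError(f"mask must be 2D or 3D, got ndim={data.ndim}")
        spacing = self.spacing
        if spacing is not None:
            spacing = tuple(float(s) for s in spacing)
            if len(spacing) != data.ndim or any(s <= 0 for s in spacing):
                raise FormatError(f"bad mask spacing {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box: lo inclusive, hi exclusive, 0-based."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise CanalSegError("BoundingBox requires 3D lo/hi")
        if any(a >= b for a, b in zip(lo, hi)) or any(a < 0 for a in lo):
            raise CanalSegError(f"invalid box lo={lo} hi={hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.lo, self.hi))  # type: ignore[return-value]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))  # type: ignore[return-value]

    def contains(self, idx: Sequence[int]) -> bool:
        return all(a <= i < b for a, i, b in zip(self.lo, idx, self.hi))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI file or a directory holding one DICOM series.

    NIfTI volumes are reoriented to the closest canonical (RAS) frame.
    DICOM slices are sorted by slice position ascending; mixed spacing or
    orientation raises :class:`FormatError` naming the offending attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing)


def _read_dicom_series(directory: Path) -> Volume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:  # non-DICOM stray file
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{directory}: no DICOM slices with pixel data found")

    ref = slices[0]
    pixel_spacing = tuple(float(v) for v in ref.PixelSpacing)  # (row=dy, col=dx)
    orientation = tuple(float(v) for v in ref.ImageOrientationPatient)
    if not np.allclose(orientation, (1, 0, 0, 0, 1, 0), atol=1e-4):
        raise FormatError(
            "DICOM series: unsupported ImageOrientationPatient "
            f"{orientation}; only axial identity orientation is handled"
        )
    for ds in slices[1:]:
        if not np.allclose([float(v) for v in ds.PixelSpacing], pixel_spacing, atol=1e-6):
            raise FormatError("inconsistent DICOM series: PixelSpacing varies across slices")
        if not np.allclose(
            [float(v) for v in ds.ImageOrientationPatient], orientation, atol=1e-6
        ):
            raise FormatError(
                "inconsistent DICOM series: ImageOrientationPatient varies across slices"
            )

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zpos)
    if len(dz) == 0:
        raise FormatError("DICOM series has a single slice; a 3D volume is required")
    if np.any(dz <= 0) or not np.allclose(dz, dz.mean(), rtol=1e-3, atol=1e-4):
        raise FormatError(
            "inconsistent DICOM series: ImagePositionPatient slice gaps are not uniform"
        )

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (row=y, col=x); transpose to canonical (x, y), stack on z
    data = np.stack([p.T for p in planes], axis=2)
    spacing = (pixel_spacing[1], pixel_spacing[0], float(dz.mean()))
    return Volume(data, spacing)


def write_volume(vol: Volume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume (float) or mask (uint8 with values {0,1}) as NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
        spacing = vol.spacing or (1.0,) * vol.data.ndim
        if vol.data.ndim == 2:
            data = data[..., None]
            spacing = tuple(spacing) + (1.0,)
    else:
        data = vol.data
        spacing = vol.spacing
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask written by :func:`write_volume`."""
    vol = read_volume(path)
    vals = np.unique(vol.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise FormatError(f"{path}: mask voxel values must be exactly {{0,1}}, got {vals[:8]}")
    return BinaryMask(vol.data.astype(bool), vol.spacing)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def downsample_half(vol: Volume | BinaryMask) -> Volume | BinaryMask:
    """Resize every dimension by half (ceil for odd sizes, spacing doubled).

    Intensity volumes use linear interpolation; masks use nearest neighbour
    so values stay in {0,1}.
    """
    data = vol.data
    if any(n < 2 for n in data.shape):
        raise CanalSegError(f"cannot halve a dimension of size < 2 (shape {data.shape})")
    out_shape = tuple(-(-n // 2) for n in data.shape)
    if isinstance(vol, BinaryMask):
        out = _sk_resize(
            data.astype(np.float64), out_shape, order=0, anti_aliasing=False, preserve_range=True
        )
        spacing = vol.spacing
        spacing = tuple(2 * s for s in spacing) if spacing is not None else None
        return BinaryMask(out > 0.5, spacing)
    out = _sk_resize(data, out_shape, order=1, anti_aliasing=False, preserve_range=True)
    return Volume(out, tuple(2 * s for s in vol.spacing))


def crop(vol: Volume | BinaryMask, box: BoundingBox) -> Volume | BinaryMask:
    """Extract the half-open box; spacing unchanged."""
    shape = vol.data.shape
    if any(h > n for h, n in zip(box.hi, shape)):
        raise CanalSegError(f"box {box.lo}..{box.hi} exceeds volume shape {shape}")
    sub = vol.data[box.slices].copy()
    if isinstance(vol, BinaryMask):
        return BinaryMask(sub, vol.spacing)
    return Volume(sub, vol.spacing)


def embed(
    sub: Volume | BinaryMask,
    shape: tuple[int, int, int],
    lo: Sequence[int],
    fill: float = 0.0,
) -> Volume | BinaryMask:
    """Place ``sub`` into a ``fill``-valued grid of ``shape`` at offset ``lo``.

    Inverse of :func:`crop` on the cropped region.
    """
    lo = tuple(int(v) for v in lo)
    hi = tuple(a + n for a, n in zip(lo, sub.data.shape))
    if any(a < 0 for a in lo) or any(b > n for b, n in zip(hi, shape)):
        raise CanalSegError(f"embedding at {lo} exceeds target shape {shape}")
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    if isinstance(sub, BinaryMask):
        out = np.zeros(shape, dtype=bool)
        out[sl] = sub.data
        return BinaryMask(out, sub.spacing)
    out = np.full(shape, float(fill), dtype=np.float64)
    out[sl] = sub.data
    return Volume(out, sub.spacing)
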