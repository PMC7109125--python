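"""Automatic mandible ROI extraction from a head CBCT volume.

The pipeline isolates the mandible so downstream networks only see the
relevant third of the scan.  Working on a reconstructed panoramic projection
it (A) takes the central third, (B) binarises it at the teeth threshold,
(C) dilates and keeps the largest object (the tooth row), (D) restricts the
full-width panorama to the tooth height, (E) binarises at the bone
threshold, (F) complements and keeps the two largest background regions
(the corridors lateral of the jaw), (G) unites corridors and tooth row,
(H) extends that region upward to mark the maxilla, (I) removes the maxilla
from the 3D bone binarisation per panorama column and applies a 3D closing,
and (J) crops to the bounding box, masking everything outside the mandible.

Both thresholds come from a 3-level Otsu on the respective 2D image (bone =
first level, teeth = third); manual overrides bypass Otsu entirely for
scans where the automatic result is off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import (
    CanalSegError,
    DegenerateInputError,
    NoBoneDetectedError,
    NoTeethDetectedError,
)
from .volume_io import BinaryMask, BoundingBox, Volume, crop as _crop

__all__ = [
    "ThresholdSet",
    "PanoramicView",
    "ROIResult",
    "multi_otsu",
    "reconstruct_panorama",
    "center_third",
    "largest_components",
    "morph",
    "extract_mandible_roi",
]

HIST_BINS = 256


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered intensity thresholds; ``bone`` is the first level and
    ``teeth`` the third (highest) one."""

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if any(a >= b for a, b in zip(levels, levels[1:])):
            raise CanalSegError(f"thresholds must be strictly increasing: {levels}")
        object.__setattr__(self, "levels", levels)

    @property
    def bone(self) -> float:
        return self.levels[0]

    @property
    def teeth(self) -> float:
        return self.levels[-1]


@dataclass(frozen=True)
class PanoramicView:
    """2D projection of the volume: rows = z (inferior at row 0), columns =
    left-right position.  ``col_to_x`` maps each panorama column back to the
    x index of the (x, all-y) voxel column it aggregates."""

    image: np.ndarray  # (nz, ncols)
    col_to_x: np.ndarray  # (ncols,)
    spacing: tuple[float, float]  # (row=z, col=x) spacing in mm

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class ROIResult:
    mandible_mask: BinaryMask
    box: BoundingBox
    cropped: Volume
    thresholds: ThresholdSet
    intermediates: dict = field(default_factory=dict)


def _quantize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin min-max quantization: returns (histogram, bin centers)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateInputError("constant image: no histogram structure")
    edges = np.linspace(lo, hi, HIST_BINS + 1)
    hist, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return hist.astype(np.int64), centers


def _best_cuts(hist: np.ndarray, centers: np.ndarray, n_levels: int) -> list[int]:
    """Cut indices maximising between-class variance, exactly, in float64.

    Classes are bin ranges ``[c_k, c_{k+1})``; the score of a segmentation is
    ``sum_k W_k * mu_k^2`` (equivalent to between-class variance up to the
    global constant).  Solved by dynamic programming over cut positions,
    which is exact for every ``n_levels``; back-pointers recover the argmax.
    Ties resolve to the lowest cut indices.
    """
    w = hist / hist.sum()
    m = w * centers
    P = np.concatenate([[0.0], np.cumsum(w)])
    M = np.concatenate([[0.0], np.cumsum(m)])
    nbins = len(hist)
    ii, jj = np.meshgrid(np.arange(nbins + 1), np.arange(nbins + 1), indexing="ij")
    W = P[jj] - P[ii]
    Mu = M[jj] - M[ii]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where((ii < jj) & (W > 0), Mu**2 / np.where(W > 0, W, 1.0), np.where(ii < jj, 0.0, -np.inf))
    f = S[0].copy()  # best score of one class covering bins [0, c)
    back: list[np.ndarray] = []
    for _ in range(n_levels):
        g = f[:, None] + S
        back.append(np.argmax(g, axis=0))
        f = np.max(g, axis=0)
    cuts = []
    c = nbins
    for b in reversed(back):
        c = int(b[c])
        cuts.append(c)
    return sorted(cuts)


def multi_otsu(vol_or_image: Volume | np.ndarray, n_levels: int = 3) -> ThresholdSet:
    """Multi-level Otsu thresholds on the 256-bin min-max histogram.

    Maximises between-class intensity variance exactly (float64); each
    returned threshold is the bin-center value of the last bin of the class
    below it.  Raises :class:`DegenerateInputError` when fewer than
    ``n_levels + 1`` quantized intensity values are present.
    """
    data = vol_or_image.data if isinstance(vol_or_image, Volume) else np.asarray(vol_or_image)
    hist, centers = _quantize(data)
    if np.count_nonzero(hist) < n_levels + 1:
        raise DegenerateInputError(
            f"need at least {n_levels + 1} distinct quantized values, "
            f"got {np.count_nonzero(hist)}"
        )
    cuts = _best_cuts(hist, centers, n_levels)
    return ThresholdSet(tuple(float(centers[c - 1]) for c in cuts))


def reconstruct_panorama(vol: Volume) -> PanoramicView:
    """Maximum-intensity projection along the anterior-posterior axis.

    A curved dental-arch reformation could be substituted; the
    ``col_to_x`` map is what downstream steps rely on, not the projection
    model itself.
    """
    if vol.data.size == 0:
        raise CanalSegError("empty volume")
    image = vol.data.max(axis=1).T  # (nz, nx)
    return PanoramicView(
        image=image,
        col_to_x=np.arange(vol.data.shape[0]),
        spacing=(vol.spacing[2], vol.spacing[0]),
    )


def center_third(view: PanoramicView) -> PanoramicView:
    """Columns [floor(W/3), floor(2W/3)) of the panorama."""
    w = view.width
    if w < 3:
        raise CanalSegError(f"panorama too narrow for a central third (W={w})")
    lo, hi = w // 3, (2 * w) // 3
    return PanoramicView(
        image=view.image[:, lo:hi], col_to_x=view.col_to_x[lo:hi], spacing=view.spacing
    )


def largest_components(
    mask: BinaryMask | np.ndarray,
    k: int,
    connectivity: Literal["face", "full"] = "face",
) -> BinaryMask:
    """Union of the k largest connected components (ties -> lowest label)."""
    if k < 1:
        raise CanalSegError("k must be >= 1")
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    spacing = mask.spacing if isinstance(mask, BinaryMask) else None
    if not arr.any():
        warnings.warn("largest_components: empty mask", stacklevel=2)
        return BinaryMask(np.zeros_like(arr, dtype=bool), spacing)
    structure = ndimage.generate_binary_structure(arr.ndim, 1 if connectivity == "face" else arr.ndim)
    labels, n = ndimage.label(arr, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    # stable ordering: size descending, label index ascending
    order = sorted(range(1, n + 1), key=lambda lab: (-sizes[lab - 1], lab))
    keep = order[: min(k, n)]
    return BinaryMask(np.isin(labels, keep), spacing)


def morph(
    mask: BinaryMask | np.ndarray,
    op: Literal["dilate", "erode", "close", "complement"],
    radius_mm: float = 0.0,
    spacing: tuple[float, ...] | None = None,
) -> BinaryMask:
    """Morphology with a Euclidean ball/disk element of ``radius_mm``.

    Implemented through exact Euclidean distance transforms with physical
    ``sampling``, which is equivalent to a ball structuring element, handles
    anisotropic voxels, and runs in linear time regardless of radius.
    """
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if spacing is None:
        spacing = mask.spacing if isinstance(mask, BinaryMask) else None
    if spacing is None:
        spacing = (1.0,) * arr.ndim
    if op == "complement":
        return BinaryMask(~arr, spacing)
    if radius_mm < 0:
        raise CanalSegError("radius_mm must be >= 0")
    if radius_mm == 0:
        return BinaryMask(arr.copy(), spacing)
    if op == "dilate":
        out = _dilate(arr, radius_mm, spacing)
    elif op == "erode":
        out = _erode(arr, radius_mm, spacing)
    elif op == "close":
        out = _erode(_dilate(arr, radius_mm, spacing), radius_mm, spacing)
    else:
        raise CanalSegError(f"unknown morphology op {op!r}")
    return BinaryMask(out, spacing)


def _dilate(arr: np.ndarray, r: float, spacing) -> np.ndarray:
    if not arr.any():
        return arr.copy()
    return ndimage.distance_transform_edt(~arr, sampling=spacing) <= r


def _erode(arr: np.ndarray, r: float, spacing) -> np.ndarray:
    if arr.all():
        return arr.copy()
    return ndimage.distance_transform_edt(arr, sampling=spacing) > r


def extract_mandible_roi(
    vol: Volume,
    bone_threshold: float | None = None,
    teeth_threshold: float | None = None,
    dilation_radius_mm: float = 1.0,
    closing_radius_mm: float = 2.0,
    save_intermediates: bool = False,
) -> ROIResult:
    """Run the full panorama-guided mandible isolation pipeline.

    Manual ``bone_threshold`` / ``teeth_threshold`` overrides replace the
    Otsu estimates (both may be given independently). The returned
    ``cropped`` volume has voxels outside the mandible mask set to the
    volume minimum (air).
    """
    inter: dict = {}
    sx, sy, sz = vol.spacing

    pano = reconstruct_panorama(vol)
    pano_c3 = center_third(pano)

    try:
        if teeth_threshold is None:
            teeth_threshold = multi_otsu(pano_c3.image).teeth
        if bone_threshold is None:
            bone_probe = multi_otsu(pano_c3.image).bone  # refined on step D below
    except DegenerateInputError as exc:
        raise NoBoneDetectedError(f"no bone detected: {exc}") from exc

    # (B) teeth binarization of the central third
    B = pano_c3.image >= teeth_threshold
    if not B.any():
        raise NoTeethDetectedError(
            "no teeth detected above the teeth threshold; supply manual overrides"
        )
    # (C) dilate, keep largest object -> tooth row
    C = largest_components(
        morph(B, "dilate", dilation_radius_mm, spacing=pano.spacing).data, k=1
    ).data

    # (D) full-width panorama confined to the tooth height (z rows of C).
    # C is already dilated upward by step (C); padding only the bottom keeps
    # the band from opening an air sliver above the occlusal level that
    # would compete with the buccal corridors in step (F).
    rows = np.nonzero(C.any(axis=1))[0]
    pad = int(round(dilation_radius_mm / sz))
    r0, r1 = max(int(rows[0]) - pad, 0), min(int(rows[-1]) + 1, pano.image.shape[0])
    D = pano.image[r0:r1]

    # bone threshold refined on the confined area, as in the pipeline
    if bone_threshold is None:
        try:
            bone_threshold = multi_otsu(D).bone
        except DegenerateInputError:
            bone_threshold = bone_probe

    # (E) bone binarization of the confined band; (F) complement, two
    # largest background regions = corridors lateral of jaw and ramus
    E = D >= bone_threshold
    F_band = largest_components(~E, k=2).data
    F = np.zeros_like(pano.image, dtype=bool)
    F[r0:r1] = F_band

    # (G) corridors ∪ tooth row, in full panorama coordinates
    G = F.copy()
    col_offset = pano.width // 3
    G[:, col_offset : col_offset + C.shape[1]] |= C

    # (H) extend upward: everything above the top of G per column marks the
    # maxilla; columns inside G's span without content take an interpolated
    # cut height
    cols = np.nonzero(G.any(axis=0))[0]
    if len(cols) == 0:
        raise NoTeethDetectedError("empty corridor/teeth union; supply manual overrides")
    top = np.full(pano.width, -1, dtype=np.int64)
    for c in cols:
        top[c] = np.nonzero(G[:, c])[0][-1]
    span = np.arange(cols[0], cols[-1] + 1)
    filled = np.round(
        np.interp(span, cols, top[cols].astype(np.float64))
    ).astype(np.int64)
    cut = np.full(pano.width, np.iinfo(np.int64).max, dtype=np.int64)
    cut[span] = filled + 1  # first z row considered maxilla
    H = np.zeros_like(G)
    for c in span:
        H[cut[c] :, c] = True

    # (I) 3D bone binarization, maxilla removal per column, 3D closing,
    # largest component (stray supra-threshold noise voxels would otherwise
    # inflate the bounding box)
    bone3d = vol.data >= bone_threshold
    if not bone3d.any():
        raise NoBoneDetectedError("no voxels above the bone threshold")
    zs = np.arange(vol.data.shape[2])[None, None, :]
    cut_x = np.full(vol.data.shape[0], np.iinfo(np.int64).max, dtype=np.int64)
    cut_x[pano.col_to_x] = cut  # map panorama columns back to x voxel columns
    bone3d &= zs < cut_x[:, None, None]
    if not bone3d.any():
        raise NoBoneDetectedError("maxilla removal deleted all bone voxels")
    closed = morph(bone3d, "close", closing_radius_mm, spacing=vol.spacing).data
    mandible = largest_components(closed, k=1).data

    # (J) bounding box, crop, mask out everything else
    idx = [np.nonzero(mandible.any(axis=tuple(j for j in range(3) if j != i)))[0] for i in range(3)]
    box = BoundingBox(
        tuple(int(i[0]) for i in idx), tuple(int(i[-1]) + 1 for i in idx)
    )
    cropped = _crop(vol, box)
    fill = float(vol.data.min())
    out = cropped.data.copy()
    out[~mandible[box.slices]] = fill
    cropped = Volume(out, vol.spacing)

    if save_intermediates:
        inter = {
            "A": pano_c3.image,
            "B": B,
            "C": C,
            "D": D,
            "E": E,
            "F": F,
            "G": G,
            "H": H,
            "I": mandible,
        }

    return ROIResult(
        mandible_mask=BinaryMask(mandible, vol.spacing),
        box=box,
        cropped=cropped,
        thresholds=ThresholdSet(_ordered_levels(bone_threshold, teeth_threshold)),
        intermediates=inter,
    )


def _ordered_levels(bone: float, teeth: float) -> tuple[float, ...]:
    if not bone < teeth:
        raise CanalSegError(f"bone threshold {bone} must be below teeth threshold {teeth}")
    return (bone, teeth)
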