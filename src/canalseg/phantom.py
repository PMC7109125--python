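"""Seeded synthetic CBCT-like phantom with analytic ground-truth masks.

The phantom emulates the anatomy a cone-beam scan of the lower face presents
to the segmentation pipeline, with fully parametric geometry so every stage
has an analytic oracle:

* the mandible is a parabolic dental arch (axial cross-section) extruded
  vertically, with two posterior vertical rami, a dense cortical shell and a
  porous (here: uniform, lower-intensity) trabecular interior;
* one mandibular canal per side: a smooth piecewise-cubic parametric curve
  from a superior-posterior entry (mandibular-foramen analogue, medial ramus)
  to an anterior exit (mental-foramen analogue), rendered as a tube of
  ``canal_radius_mm`` wrapped in a thin bright cortical rim.  The lumen
  (nerve and vessel) sits just below the trabecular intensity — within the
  noise level, as in cone-beam scans where marrow and nerve contents are
  hard to tell apart — so the rim is the feature that makes the canal
  detectable;
* a row of high-intensity teeth (ellipsoids) on the superior arch surface;
* a separate maxillary arch above an air gap;
* a thin soft-tissue envelope and additive Gaussian noise.

Geometry scales with the grid (fractions of the field of view), while canal
radius, rim thickness, shell thickness and the maxillary gap are physical
(mm), mirroring how the corresponding structures behave across scanner
resolutions.  Intensities are arbitrary units in [0, 1]; CBCT does not
measure density on a calibrated scale, and the pipeline never assumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import distance_transform_edt

from .errors import CanalSegError, GenerationError
from .volume_io import BinaryMask, Volume

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "DEFAULT_INTENSITIES",
    "generate_phantom",
    "render_tracing_overlay",
    "sparse_annotation",
]

DEFAULT_INTENSITIES: Mapping[str, float] = {
    "air": 0.0,
    "soft_tissue": 0.06,
    "canal_lumen": 0.33,
    "trabecular": 0.35,
    "canal_rim": 0.58,
    "cortical": 0.62,
    "tooth": 0.95,
}

_ORDER = ["air", "soft_tissue", "canal_lumen", "trabecular", "canal_rim", "cortical", "tooth"]


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration for :func:`generate_phantom`.

    Defaults follow the package-wide desk-scale grid: (160, 160, 128) voxels
    at 0.4 mm, i.e. a 64 x 64 x 51 mm field of view.  The canal diameter of
    2.8 mm and its 0.5 mm cortical rim sit in the clinically reported range;
    rim thickness may be set to 0 to reproduce the hard "no visible cortical
    rim" case.
    """

    shape: tuple[int, int, int] = (160, 160, 128)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    seed: int = 0
    intensities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    canal_radius_mm: float = 1.4
    rim_thickness_mm: float = 0.5
    shell_thickness_mm: float = 1.0
    soft_tissue_mm: float = 0.5
    noise_sigma: float = 0.015
    maxilla_gap_mm: float = 4.0

    def __post_init__(self) -> None:
        if any(n < 48 for n in self.shape):
            raise CanalSegError(f"phantom shape must be >= 48 per axis, got {self.shape}")
        if self.maxilla_gap_mm <= 0:
            raise CanalSegError("maxilla_gap_mm must be > 0")
        if self.noise_sigma < 0 or self.canal_radius_mm <= 0 or self.rim_thickness_mm < 0:
            raise CanalSegError("invalid phantom scalar parameter")
        missing = set(_ORDER) - set(self.intensities)
        if missing:
            raise CanalSegError(f"intensities missing entries: {sorted(missing)}")


@dataclass(frozen=True)
class PhantomSample:
    """Generated volume plus its ground-truth masks.

    Invariants (checked at generation): canal ⊆ mandible, teeth ∩ canal = ∅,
    mandible ∩ maxilla = ∅.
    """

    volume: Volume
    canal_mask: BinaryMask
    mandible_mask: BinaryMask
    teeth_mask: BinaryMask
    maxilla_mask: BinaryMask
    config: PhantomConfig


def _arch_curve(nx: float, ny: float, half_width: float, y_anterior: float, y_posterior: float):
    """Return (f, a, cx): f maps signed x-offset u∈[-w, w] to arch y."""
    a = (y_posterior - y_anterior) / half_width**2
    cx = nx / 2.0

    def f(u: np.ndarray) -> np.ndarray:
        return y_anterior + a * np.asarray(u) ** 2

    return f, a, cx


def _band_mask_2d(nx: int, ny: int, curve_pts: np.ndarray, half_thickness: float) -> np.ndarray:
    """Axial 2D mask of points within ``half_thickness`` of the sampled curve.

    The curve is rasterised onto the grid and the Euclidean distance map of
    the rasterisation thresholded; the curve sampling is dense enough
    (sub-voxel steps) for the rasterisation error to stay below half a voxel.
    """
    seeds = np.zeros((nx, ny), dtype=bool)
    ij = np.round(curve_pts).astype(int)
    keep = (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
    seeds[ij[keep, 0], ij[keep, 1]] = True
    d = distance_transform_edt(~seeds)
    return d <= half_thickness


def _edt_inside(mask: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from each foreground voxel to the background.

    Computed on the tight bounding box (padded by one background layer) for
    speed; zero outside the mask.
    """
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    idx = [np.nonzero(mask.any(axis=tuple(j for j in range(3) if j != i)))[0] for i in range(3)]
    sl = tuple(slice(int(i[0]), int(i[-1]) + 1) for i in idx)
    sub = np.pad(mask[sl], 1, constant_values=False)
    d = distance_transform_edt(sub, sampling=spacing)
    out[sl] = d[1:-1, 1:-1, 1:-1]
    return out


def _near_mask(mask: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Voxels within ``radius_mm`` of the mask (the mask itself included)."""
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    pad = [int(np.ceil(radius_mm / s)) + 1 for s in spacing]
    idx = [np.nonzero(mask.any(axis=tuple(j for j in range(3) if j != i)))[0] for i in range(3)]
    lo = [max(int(i[0]) - p, 0) for i, p in zip(idx, pad)]
    hi = [min(int(i[-1]) + 1 + p, n) for i, p, n in zip(idx, pad, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    d = distance_transform_edt(~mask[sl], sampling=spacing)
    out = np.zeros(mask.shape, dtype=bool)
    out[sl] = d <= radius_mm
    return out


def _tube_masks(
    shape: tuple[int, int, int],
    centerline: np.ndarray,
    r_lumen: float,
    r_outer: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a tube around a densely sampled centerline: (lumen, rim)."""
    pad = int(np.ceil(r_outer)) + 2
    lo = np.maximum(np.floor(centerline.min(axis=0)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(centerline.max(axis=0)).astype(int) + pad + 1, shape)
    sub_shape = tuple(b - a for a, b in zip(lo, hi))
    seeds = np.zeros(sub_shape, dtype=bool)
    ijk = np.round(centerline).astype(int) - lo
    keep = np.all((ijk >= 0) & (ijk < np.array(sub_shape)), axis=1)
    seeds[tuple(ijk[keep].T)] = True
    d = distance_transform_edt(~seeds)
    lumen = np.zeros(shape, dtype=bool)
    outer = np.zeros(shape, dtype=bool)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    lumen[sl] = d <= r_lumen
    outer[sl] = d <= r_outer
    rim = outer & ~lumen
    return lumen, rim


def generate_phantom(cfg: PhantomConfig | None = None) -> PhantomSample:
    """Build the phantom; identical config (and seed) gives identical output."""
    cfg = cfg or PhantomConfig()
    nx, ny, nz = cfg.shape
    sx, sy, sz = cfg.spacing
    inten = cfg.intensities
    rng = np.random.default_rng(cfg.seed)

    # --- mandibular arch (body) ------------------------------------------
    w = 0.34 * nx
    f, a, cx = _arch_curve(nx, ny, w, 0.18 * ny, 0.80 * ny)
    u = np.linspace(-w, w, max(600, 8 * nx))
    body_curve = np.column_stack([cx + u, f(u)])
    t_body = 0.07 * nx
    body2d = _band_mask_2d(nx, ny, body_curve, t_body)
    z0, z1 = int(round(0.16 * nz)), int(round(0.40 * nz))
    body = np.zeros(cfg.shape, dtype=bool)
    body[:, :, z0:z1] = body2d[:, :, None]

    # --- teeth on the superior arch surface -------------------------------
    tooth_rx, tooth_rz = 0.022 * nx, 0.055 * nz
    tooth_cz = z1 + 0.3 * tooth_rz
    arc = np.linspace(-0.80 * w, 0.80 * w, 14)  # equal x-offset spacing along the arch
    teeth = np.zeros(cfg.shape, dtype=bool)
    zs = np.arange(nz)
    for uu in arc:
        tx, ty = cx + uu, float(f(uu))
        xlo, xhi = int(tx - tooth_rx) - 1, int(tx + tooth_rx) + 2
        ylo, yhi = int(ty - tooth_rx) - 1, int(ty + tooth_rx) + 2
        zlo, zhi = int(tooth_cz - tooth_rz) - 1, int(tooth_cz + tooth_rz) + 2
        gx, gy, gz = np.meshgrid(
            np.arange(max(xlo, 0), min(xhi, nx)),
            np.arange(max(ylo, 0), min(yhi, ny)),
            np.arange(max(zlo, 0), min(zhi, nz)),
            indexing="ij",
        )
        e = ((gx - tx) / tooth_rx) ** 2 + ((gy - ty) / tooth_rx) ** 2 + ((gz - tooth_cz) / tooth_rz) ** 2
        teeth[max(xlo, 0) : min(xhi, nx), max(ylo, 0) : min(yhi, ny), max(zlo, 0) : min(zhi, nz)] |= e <= 1.0
    teeth &= ~body  # teeth sit on, not inside, the bone
    teeth_top = int(np.max(np.nonzero(teeth.any(axis=(0, 1)))[0]))

    # --- maxillary arch above the air gap ---------------------------------
    wm = 0.90 * w
    fm, _, _ = _arch_curve(nx, ny, wm, 0.21 * ny, 0.78 * ny)
    um = np.linspace(-wm, wm, max(600, 8 * nx))
    max_curve = np.column_stack([cx + um, fm(um)])
    max2d = _band_mask_2d(nx, ny, max_curve, 0.06 * nx)
    gap_vox = cfg.maxilla_gap_mm / sz
    mz0 = int(round(teeth_top + gap_vox))
    mz1 = min(int(round(mz0 + 0.18 * nz)), nz)
    maxilla = np.zeros(cfg.shape, dtype=bool)
    maxilla[:, :, mz0:mz1] = max2d[:, :, None]

    # --- rami: vertical elliptic cylinders at the arch ends ---------------
    # The ramus top stays below the maxillary floor so the two bones are
    # separated by the air gap everywhere.
    ram_cx, ram_cy = 0.97 * w, f(0.97 * w) - 0.06 * ny
    ram_rx, ram_ry = 0.06 * nx, 0.12 * ny
    ram_top = min(int(round(0.57 * nz)), mz0 - 1)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rami2d = np.zeros((nx, ny), dtype=bool)
    for side in (-1.0, 1.0):
        e = ((xs - (cx + side * ram_cx)) / ram_rx) ** 2 + ((ys - ram_cy) / ram_ry) ** 2
        rami2d |= e <= 1.0
    rami = np.zeros(cfg.shape, dtype=bool)
    rami[:, :, z0:ram_top] = rami2d[:, :, None]

    mandible_solid = body | rami
    teeth &= ~mandible_solid

    # --- cortical shell vs trabecular interior ----------------------------
    shell = cfg.shell_thickness_mm
    interior_m = _edt_inside(mandible_solid, cfg.spacing) > shell
    interior_x = _edt_inside(maxilla, cfg.spacing) > shell

    # --- canals ------------------------------------------------------------
    r_lumen = cfg.canal_radius_mm / sx
    r_outer = r_lumen + cfg.rim_thickness_mm / sx
    canal = np.zeros(cfg.shape, dtype=bool)
    rim_all = np.zeros(cfg.shape, dtype=bool)
    path_u = np.array([0.98, 0.88, 0.75, 0.62, 0.50])  # |x offset| / w, entry -> exit
    path_z = np.array([0.46, 0.37, 0.335, 0.315, 0.325]) * nz
    for side in (-1.0, 1.0):
        pts = np.column_stack([cx + side * path_u * w, f(path_u * w), path_z])
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        spline = CubicSpline(t, pts, axis=0, bc_type="natural")
        n_samples = max(400, int(4 * t[-1]))  # sub-quarter-voxel steps
        samples = spline(np.linspace(0.0, t[-1], n_samples))
        lum, rim = _tube_masks(cfg.shape, samples, r_lumen, r_outer)
        if np.any((lum | rim) & ~mandible_solid):
            raise GenerationError(
                "canal tube exits the mandible: reduce canal_radius_mm/rim_thickness_mm "
                "or enlarge the grid"
            )
        canal |= lum
        rim_all |= rim

    # --- soft tissue envelope ---------------------------------------------
    bone_any = mandible_solid | teeth | maxilla
    soft = _near_mask(bone_any, cfg.spacing, cfg.soft_tissue_mm) & ~bone_any

    # --- paint intensities --------------------------------------------------
    vol = np.full(cfg.shape, inten["air"], dtype=np.float64)
    vol[soft] = inten["soft_tissue"]
    vol[mandible_solid & ~interior_m] = inten["cortical"]
    vol[interior_m] = inten["trabecular"]
    vol[maxilla & ~interior_x] = inten["cortical"]
    vol[interior_x] = inten["trabecular"]
    vol[teeth] = inten["tooth"]
    vol[rim_all] = inten["canal_rim"]
    vol[canal] = inten["canal_lumen"]
    if cfg.noise_sigma > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)

    sample = PhantomSample(
        volume=Volume(vol, cfg.spacing),
        canal_mask=BinaryMask(canal, cfg.spacing),
        mandible_mask=BinaryMask(mandible_solid, cfg.spacing),
        teeth_mask=BinaryMask(teeth, cfg.spacing),
        maxilla_mask=BinaryMask(maxilla, cfg.spacing),
        config=cfg,
    )
    _check_invariants(sample)
    return sample


def _check_invariants(s: PhantomSample) -> None:
    if np.any(s.canal_mask.data & ~s.mandible_mask.data):
        raise GenerationError("invariant violated: canal not contained in mandible")
    if np.any(s.teeth_mask.data & s.canal_mask.data):
        raise GenerationError("invariant violated: teeth intersect canal")
    if np.any(s.mandible_mask.data & s.maxilla_mask.data):
        raise GenerationError("invariant violated: mandible intersects maxilla")


def render_tracing_overlay(
    sample: PhantomSample,
    slice_index: int,
    trace_color: tuple[int, int, int] = (255, 0, 0),
    axis: int = 1,
) -> np.ndarray:
    """Grayscale slice as RGB with canal pixels replaced by ``trace_color``.

    Emulates the clinician tracing overlay the annotation stage extracts its
    color-keyed masks from.  ``axis`` selects the slicing direction (default
    anterior-posterior, matching the annotation workflow).
    """
    data = sample.volume.data
    n = data.shape[axis]
    if not 0 <= slice_index < n:
        raise IndexError(f"slice {slice_index} out of range for axis {axis} (n={n})")
    sl = np.take(data, slice_index, axis=axis)
    msl = np.take(sample.canal_mask.data, slice_index, axis=axis)
    lo, hi = data.min(), data.max()
    gray = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo)
    gray8 = np.clip(np.round(gray * 255), 0, 255).astype(np.uint8)
    rgb = np.stack([gray8] * 3, axis=-1)
    rgb[msl] = np.asarray(trace_color, dtype=np.uint8)
    return rgb


def sparse_annotation(
    sample: PhantomSample, interval_mm: float, axis: int = 1
) -> list[tuple[int, BinaryMask]]:
    """Subsample the dense canal mask at a clinician-like slice interval.

    Keeps every ``round(interval_mm / slice_spacing)``-th slice starting at
    the first canal-containing slice and continuing to the end of the
    volume (annotating empty slices past the canal end is how a tracer
    confirms the canal has terminated).
    """
    spacing = sample.volume.spacing[axis]
    if interval_mm < spacing:
        raise CanalSegError(
            f"annotation interval {interval_mm} mm is below the slice spacing {spacing} mm"
        )
    step = int(round(interval_mm / spacing))
    has = np.any(
        sample.canal_mask.data, axis=tuple(i for i in range(3) if i != axis)
    )
    idx = np.nonzero(has)[0]
    first = int(idx[0])
    n = sample.canal_mask.data.shape[axis]
    other_spacing = tuple(s for i, s in enumerate(sample.volume.spacing) if i != axis)
    return [
        (i, BinaryMask(np.take(sample.canal_mask.data, i, axis=axis), other_spacing))
        for i in range(first, n, step)
    ]
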