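"""Bone-volume-fraction mapping from grayscale MR volumes.

On a FLASH gradient-echo hip acquisition mineralized bone is hypointense
and marrow hyperintense, so a voxel's fractional bone occupancy can be
read off its grayscale value once local reference intensities for pure
bone and pure marrow are known.  `compute_bvf` estimates those references
with a windowed-percentile local-thresholding scheme inside the
periosteal segmentation and inverts the linear partial-volume mixing

    I = f * I_bone + (1 - f) * I_marrow   =>   BVF = (I_marrow - I) / (I_marrow - I_bone)

clamped to [0, 1].  The map is kept on the [0, 1] scale internally; the
conventional 0-100 display scale is a presentation choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BACKGROUND",
    "BONE_REGION",
    "SOFT_TISSUE",
    "GrayscaleVolume",
    "SegmentationMask",
    "BVFMap",
    "compute_bvf",
]

BACKGROUND = 0
BONE_REGION = 1
SOFT_TISSUE = 2

#: Image-axis convention used throughout: axis 0 = left-right (in-plane),
#: axis 1 = anterior-posterior (coronal slice index), axis 2 =
#: inferior-superior (in-plane).  Physical coordinates are 0-based voxel
#: index times voxel dimension, measured at voxel corners.
AXIS_LABELS = ("LR", "AP", "SI")


def _check_dims(voxel_dims) -> tuple[float, float, float]:
    dims = tuple(float(d) for d in voxel_dims)
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise ValueError("voxel_dims must be three positive lengths in mm")
    return dims


@dataclass
class GrayscaleVolume:
    """A 3-D grayscale image with anisotropic voxel dimensions in mm."""

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    orientation: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")
        self.voxel_dims = _check_dims(self.voxel_dims)


@dataclass
class SegmentationMask:
    """Label volume over {background, bone_region, soft_tissue}."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-D")
        bad = np.setdiff1d(np.unique(self.labels),
                           [BACKGROUND, BONE_REGION, SOFT_TISSUE])
        if bad.size:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)
        self.voxel_dims = _check_dims(self.voxel_dims)

    @property
    def bone(self) -> np.ndarray:
        return self.labels == BONE_REGION

    @property
    def body(self) -> np.ndarray:
        return self.labels != BACKGROUND


@dataclass
class BVFMap:
    """Per-voxel fractional occupancy of mineralized bone in [0, 1]."""

    bvf: np.ndarray
    voxel_dims: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bvf = np.asarray(self.bvf, dtype=np.float64)
        if self.bvf.ndim != 3:
            raise ValueError("BVF map must be 3-D")
        if not np.all(np.isfinite(self.bvf)):
            raise ValueError("BVF values must be finite")
        if self.bvf.min() < 0 or self.bvf.max() > 1:
            raise ValueError("BVF values must lie in [0, 1]")
        self.voxel_dims = _check_dims(self.voxel_dims)


def _window_radii(voxel_dims, radius_inplane: int) -> tuple[int, int, int]:
    """Per-axis window radii (voxels), scaled so windows are roughly cubic
    in physical space for anisotropic voxels."""
    d = np.asarray(voxel_dims)
    r_mm = radius_inplane * d.min()
    return tuple(max(1, int(round(r_mm / di))) for di in d)


def compute_bvf(
    volume: GrayscaleVolume,
    mask: SegmentationMask,
    window_radius: int = 10,
    percentiles: tuple[float, float] = (1.0, 99.0),
    min_window_voxels: int = 50,
    bone_is_dark: bool = True,
) -> BVFMap:
    """Map grayscale intensities to bone volume fraction in [0, 1].

    Reference intensities for pure bone (low percentile of the masked
    intensities when bone is dark) and pure marrow (high percentile) are
    estimated within cubic windows centred on a coarse lattice of
    bone-region voxels; each voxel uses the references of its nearest
    lattice point.  Windows with fewer than ``min_window_voxels``
    bone-region voxels, or with no intensity contrast, fall back to global
    references.  ``bone_is_dark=False`` flips the polarity for contrasts
    where bone is hyperintense.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    if volume.data.shape != mask.labels.shape:
        raise ValueError("volume and mask shapes differ")
    bone = mask.bone
    if not bone.any():
        raise ValueError("bone_region is empty")
    lo_pct, hi_pct = percentiles
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")

    data = volume.data
    vals = data[bone]
    g_lo, g_hi = np.percentile(vals, [lo_pct, hi_pct])
    if g_hi <= g_lo:
        warnings.warn(
            "no intensity contrast inside the bone region; returning an "
            "all-zero BVF map", RuntimeWarning, stacklevel=2,
        )
        return BVFMap(np.zeros_like(data), volume.voxel_dims,
                      meta={"degenerate": True})

    rx, ry, rz = _window_radii(volume.voxel_dims, window_radius)
    nx, ny, nz = data.shape
    # Lattice of window centres with stride = radius (windows overlap 2x).
    cx = np.arange(0, nx, rx) + min(rx // 2, nx - 1)
    cy = np.arange(0, ny, ry) + min(ry // 2, ny - 1)
    cz = np.arange(0, nz, rz) + min(rz // 2, nz - 1)
    cx = np.clip(cx, 0, nx - 1)
    cy = np.clip(cy, 0, ny - 1)
    cz = np.clip(cz, 0, nz - 1)

    lo_ref = np.full((cx.size, cy.size, cz.size), g_lo)
    hi_ref = np.full((cx.size, cy.size, cz.size), g_hi)
    for a, x0 in enumerate(cx):
        xs = slice(max(0, x0 - rx), min(nx, x0 + rx + 1))
        for b, y0 in enumerate(cy):
            ys = slice(max(0, y0 - ry), min(ny, y0 + ry + 1))
            for c, z0 in enumerate(cz):
                zs = slice(max(0, z0 - rz), min(nz, z0 + rz + 1))
                sel = bone[xs, ys, zs]
                if sel.sum() < min_window_voxels:
                    continue
                w = data[xs, ys, zs][sel]
                lo, hi = np.percentile(w, [lo_pct, hi_pct])
                if hi - lo <= 1e-12 * (g_hi - g_lo):
                    continue
                lo_ref[a, b, c] = lo
                hi_ref[a, b, c] = hi

    # Nearest-lattice-point reference assignment.
    ix = np.clip(np.arange(nx) // rx, 0, cx.size - 1)
    iy = np.clip(np.arange(ny) // ry, 0, cy.size - 1)
    iz = np.clip(np.arange(nz) // rz, 0, cz.size - 1)
    LO = lo_ref[np.ix_(ix, iy, iz)]
    HI = hi_ref[np.ix_(ix, iy, iz)]

    if bone_is_dark:
        i_bone, i_marrow = LO, HI
    else:
        i_bone, i_marrow = HI, LO
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (i_marrow - data) / (i_marrow - i_bone)
    frac = np.clip(np.nan_to_num(frac, nan=0.0), 0.0, 1.0)
    frac[~bone] = 0.0
    return BVFMap(frac, volume.voxel_dims,
                  meta={"window_radii": (rx, ry, rz),
                        "percentiles": (lo_pct, hi_pct),
                        "bone_is_dark": bone_is_dark})
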