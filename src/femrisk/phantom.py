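"""Parametric proximal-femur phantoms for end-to-end pipeline testing.

The phantom is a stylized proximal femur — a shaft cylinder, a neck
capsule at the neck-shaft angle, a spherical head and a lateral
trochanteric bulge — voxelised on a regular grid.  It carries a known
ground-truth bone-volume-fraction field (cortical shell at 1, correlated
trabecular interior, low-density medullary canal), a soft-tissue slab
whose lateral skin sits a configured pad away from the trochanter, and a
grayscale volume synthesised by the inverse of the partial-volume mixing
model used by the BVF mapper.  Every downstream measurement (BVF map, FE
strength, soft-tissue thickness) can therefore be checked against ground
truth, with all randomness flowing from a single seed.

The default geometry is deliberately desk-scale: a ~1.5 mm isotropic grid
of roughly 50 x 30 x 60 voxels so the full nonlinear FE pipeline runs in
minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .bvf import BACKGROUND, BONE_REGION, SOFT_TISSUE  # noqa: F401
from .bvf import BVFMap, GrayscaleVolume, SegmentationMask
from .fe.solve import fall_load_axis

__all__ = ["PhantomSpec", "Phantom", "generate_phantom",
           "COARSE_VOXEL_DIMS", "MRI_VOXEL_DIMS"]

#: Coarse isotropic grid for desk-scale FE runs.
COARSE_VOXEL_DIMS = (1.5, 1.5, 1.5)
#: In-plane 0.234 mm, 1.5 mm coronal slices (axis 1 = anterior-posterior).
MRI_VOXEL_DIMS = (0.234, 1.5, 0.234)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and imaging parameters of the synthetic femur.

    Lengths in mm.  ``trab_mean``/``trab_sd``/``trab_corr_mm`` describe
    the clipped correlated-Gaussian trabecular BVF field; ``stt_pad`` is
    the soft-tissue distance from the trochanter surface to the lateral
    skin.  Angles in degrees.
    """

    voxel_dims: tuple[float, float, float] = COARSE_VOXEL_DIMS
    head_radius: float = 14.0
    neck_radius: float = 9.5
    neck_length: float = 22.0
    neck_shaft_angle: float = 130.0
    shaft_radius: float = 11.0
    shaft_length: float = 50.0
    troch_radius: float = 10.0
    troch_offset: float = 6.0
    troch_elevation: float = 3.0
    cortical_thickness: float = 1.8
    trab_mean: float = 0.45
    trab_sd: float = 0.30
    trab_corr_mm: float = 3.0
    canal_radius_frac: float = 0.5
    canal_mean: float = 0.08
    stt_pad: float = 34.3
    medial_margin: float = 5.0
    ap_margin: float = 5.0
    patch_radius: float = 9.0
    diaphysis_tilt: float = 10.0
    internal_rotation: float = 15.0
    intensity_bone: float = 20.0
    intensity_marrow: float = 200.0
    intensity_soft: float = 150.0
    intensity_background: float = 5.0
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_radius", "neck_radius", "neck_length",
                     "shaft_radius", "shaft_length", "troch_radius",
                     "cortical_thickness", "stt_pad", "patch_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 90 < self.neck_shaft_angle < 160:
            raise ValueError("neck_shaft_angle must lie in (90, 160) degrees")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        if not 0 <= self.trab_mean <= 1:
            raise ValueError("trab_mean must lie in [0, 1]")
        if self.trab_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.intensity_marrow <= self.intensity_bone:
            raise ValueError("marrow must be brighter than bone "
                             "(FLASH contrast convention)")

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass
class Phantom:
    """A generated phantom with its ground truths and FE patch masks."""

    volume: GrayscaleVolume
    mask: SegmentationMask
    true_bvf: BVFMap
    stt_true_mm: float
    head_voxels: np.ndarray
    trochanter_voxels: np.ndarray
    distal_voxels: np.ndarray
    cortical_voxels: np.ndarray
    load_axis: np.ndarray
    spec: PhantomSpec
    geometry: dict = field(default_factory=dict)


def _segment_distance(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points (stacked in the last axis) to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    ap = P - a
    t = np.clip((ap @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(P - closest, axis=-1)


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the stylized femur phantom described by ``spec``.

    Deterministic given the spec (including its seed): two calls with
    equal specs return bit-identical volumes.
    """
    spec = spec or PhantomSpec()
    dx, dy, dz = spec.voxel_dims
    rng = np.random.default_rng(spec.seed)

    gamma = math.radians(180.0 - spec.neck_shaft_angle)
    neck_dir = np.array([-math.sin(gamma), 0.0, math.cos(gamma)])

    z_b = 2 * dz
    z_t = z_b + spec.shaft_length
    x_shaft = spec.medial_margin + spec.head_radius \
        + spec.neck_length * math.sin(gamma)
    p_neck0_z = z_t
    head_c_z = p_neck0_z + spec.neck_length * math.cos(gamma)
    z_top = head_c_z + spec.head_radius
    x_bone_max = x_shaft + spec.troch_offset + spec.troch_radius

    max_r = max(spec.head_radius, spec.shaft_radius + 1e-9, spec.troch_radius)
    ny = int(math.ceil((2 * max_r + 2 * spec.ap_margin) / dy))
    nz = int(math.ceil((z_top + 2 * dz) / dz)) + 1
    n_pad = int(round(spec.stt_pad / dx))
    nx = int(math.ceil(x_bone_max / dx)) + n_pad + 4
    if min(nx, ny, nz) < 8:
        raise ValueError("phantom geometry does not fit a usable grid; "
                         "voxels too coarse for the requested shapes")

    y_c = ny * dy / 2.0
    shaft_axis_xy = np.array([x_shaft, y_c])
    p_neck0 = np.array([x_shaft, y_c, p_neck0_z])
    head_c = p_neck0 + spec.neck_length * neck_dir
    troch_c = np.array([x_shaft + spec.troch_offset, y_c,
                        z_t + spec.troch_elevation])
    if head_c[0] - spec.head_radius < 0 or z_top + dz > nz * dz:
        raise ValueError("head/neck geometry does not fit the grid")

    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)

    r_xy = np.hypot(X - shaft_axis_xy[0], Y - shaft_axis_xy[1])
    shaft = (r_xy <= spec.shaft_radius) & (Z >= z_b) & (Z <= z_t)
    neck = _segment_distance(P, p_neck0, head_c) <= spec.neck_radius
    head = np.linalg.norm(P - head_c, axis=-1) <= spec.head_radius
    troch = np.linalg.norm(P - troch_c, axis=-1) <= spec.troch_radius
    bone = shaft | neck | head | troch
    if not bone.any():
        raise ValueError("phantom bone region is empty")

    depth = ndimage.distance_transform_edt(bone, sampling=spec.voxel_dims)
    shell = bone & (depth <= spec.cortical_thickness + 1e-9)
    interior = bone & ~shell
    canal = (interior & (Z <= z_t - 12.0)
             & (r_xy <= spec.canal_radius_frac * spec.shaft_radius))

    white = rng.standard_normal(bone.shape)
    sigma = tuple(spec.trab_corr_mm / d for d in spec.voxel_dims)
    corr = ndimage.gaussian_filter(white, sigma=sigma)
    sd = corr.std()
    corr = corr / sd if sd > 0 else corr

    true_bvf = np.zeros(bone.shape)
    true_bvf[shell] = 1.0
    base = np.where(canal, spec.canal_mean, spec.trab_mean)
    trab_field = np.clip(base + spec.trab_sd * corr, 0.0, 1.0)
    true_bvf[interior] = trab_field[interior]

    # Soft-tissue slab: lateral skin a configured pad beyond the trochanter.
    i_troch = int(np.nonzero(bone.any(axis=(1, 2)))[0].max())
    i_skin = i_troch + n_pad
    if i_skin > nx - 2:
        raise ValueError("soft-tissue pad does not fit the grid")
    body = np.zeros(bone.shape, dtype=bool)
    body[: i_skin + 1, :, :] = True
    body |= bone
    labels = np.where(body, SOFT_TISSUE, BACKGROUND).astype(np.uint8)
    labels[bone] = BONE_REGION
    stt_true = n_pad * dx

    intensity = np.full(bone.shape, spec.intensity_background)
    intensity[body] = spec.intensity_soft
    intensity[bone] = (true_bvf[bone] * spec.intensity_bone
                       + (1.0 - true_bvf[bone]) * spec.intensity_marrow)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, bone.shape)
    intensity = np.clip(intensity, 0.0, None)

    axis = fall_load_axis(spec.diaphysis_tilt, spec.internal_rotation)
    head_apex = head_c - spec.head_radius * axis
    troch_apex = troch_c + spec.troch_radius * axis
    head_voxels = bone & (np.linalg.norm(P - head_apex, axis=-1)
                          <= spec.patch_radius)
    troch_voxels = bone & (np.linalg.norm(P - troch_apex, axis=-1)
                           <= spec.patch_radius)
    k_min = int(np.nonzero(bone.any(axis=(0, 1)))[0].min())
    distal_voxels = bone.copy()
    distal_voxels[:, :, k_min + 2:] = False
    if not head_voxels.any() or not troch_voxels.any():
        raise ValueError("FE patches are empty; increase patch_radius")

    return Phantom(
        volume=GrayscaleVolume(intensity, spec.voxel_dims),
        mask=SegmentationMask(labels, spec.voxel_dims),
        true_bvf=BVFMap(true_bvf, spec.voxel_dims),
        stt_true_mm=stt_true,
        head_voxels=head_voxels,
        trochanter_voxels=troch_voxels,
        distal_voxels=distal_voxels,
        cortical_voxels=shell,
        load_axis=axis,
        spec=spec,
        geometry={
            "head_center_mm": head_c.tolist(),
            "trochanter_center_mm": troch_c.tolist(),
            "shaft_axis_x_mm": x_shaft,
            "grid": (nx, ny, nz),
            "skin_column": i_skin,
            "trochanter_column": i_troch,
        },
    )
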