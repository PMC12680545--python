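"""Trochanteric soft-tissue thickness from segmentation masks.

The soft-tissue thickness (STT) that attenuates a sideways-fall impact is
the least distance between the greater trochanter's surface and the skin,
taken on the coronal slice where that distance is smallest.  Distances
are straight-line Euclidean in physical millimetres, anisotropy-aware.

By default the trochanter is localised as the lateral-most bone surface
within the proximal (superior) third of the bone mask; an explicit
trochanter label overrides this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["STTResult", "measure_stt"]


@dataclass(frozen=True)
class STTResult:
    """Least trochanter-to-skin distance.

    ``endpoints`` are ((x, z) on the trochanter surface, (x, z) on the
    skin) as in-plane voxel indices of the selected coronal slice.
    """

    stt_mm: float
    slice_index: int
    endpoints: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "stt_mm": self.stt_mm,
            "slice_index": self.slice_index,
            "endpoints": [list(self.endpoints[0]), list(self.endpoints[1])],
        }


def _boundary_2d(mask2d: np.ndarray) -> np.ndarray:
    """Pixels of a 2-D mask that touch its complement (image edges do not
    count as boundary: the body may extend beyond the field of view)."""
    eroded = ndimage.binary_erosion(mask2d, border_value=1)
    return mask2d & ~eroded


def measure_stt(
    bone_mask: np.ndarray,
    body_mask: np.ndarray,
    voxel_dims: tuple[float, float, float],
    trochanter_mask: np.ndarray | None = None,
    proximal_fraction: float = 1.0 / 3.0,
    lateral_sign: int = +1,
) -> STTResult:
    """Least distance (mm) from the greater trochanter to the skin.

    Coronal slices are indexed along axis 1 (anterior-posterior); in-plane
    axes are 0 (left-right) and 2 (inferior-superior).  For every coronal
    slice containing candidate trochanter surface pixels the minimum
    Euclidean distance to the skin outline is computed, and the smallest
    value over slices is returned.

    Without an explicit ``trochanter_mask`` the trochanter is taken as the
    bone surface in the superior ``proximal_fraction`` of the bone's
    extent, on the lateral side of the bone centroid (``lateral_sign``
    selects which left-right direction is lateral).
    """
    bone = np.asarray(bone_mask, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    if bone.shape != body.shape or bone.ndim != 3:
        raise ValueError("bone and body masks must be 3-D with equal shapes")
    if not bone.any() or not body.any():
        raise ValueError("bone and body masks must be non-empty")
    if lateral_sign not in (-1, 1):
        raise ValueError("lateral_sign must be +1 or -1")
    if np.any(bone & ~body):
        raise ValueError("trochanter/bone lies outside the body mask")
    dx, _, dz = (float(d) for d in voxel_dims)

    if trochanter_mask is not None:
        troch = np.asarray(trochanter_mask, dtype=bool)
        if troch.shape != bone.shape:
            raise ValueError("trochanter mask shape mismatch")
        if not troch.any():
            raise ValueError("trochanter mask is empty")
        candidate = troch
        x_gate = None
    else:
        zs = np.nonzero(bone.any(axis=(0, 1)))[0]
        z_lo = zs.max() - proximal_fraction * (zs.max() - zs.min())
        candidate = bone.copy()
        candidate[:, :, : int(np.ceil(z_lo))] = False
        if not candidate.any():
            raise ValueError("no bone in the proximal band; cannot localise "
                             "the trochanter")
        x_centroid = np.argwhere(bone)[:, 0].mean()
        x_gate = x_centroid

    best: STTResult | None = None
    for y in range(bone.shape[1]):
        cand2d = candidate[:, y, :]
        if not cand2d.any():
            continue
        bone2d = bone[:, y, :]
        body2d = body[:, y, :]
        troch_pix = _boundary_2d(bone2d) & cand2d
        skin_pix = _boundary_2d(body2d)
        if x_gate is not None:
            xs = np.arange(bone.shape[0])
            lateral = (lateral_sign * (xs - x_gate) > 0)[:, None]
            troch_pix = troch_pix & lateral
            skin_pix = skin_pix & lateral
        if not troch_pix.any() or not skin_pix.any():
            continue
        dist, (fx, fz) = ndimage.distance_transform_edt(
            ~skin_pix, sampling=(dx, dz), return_indices=True)
        d_at = dist[troch_pix]
        i = int(np.argmin(d_at))
        tx, tz = np.argwhere(troch_pix)[i]
        d_min = float(d_at[i])
        if best is None or d_min < best.stt_mm:
            best = STTResult(
                stt_mm=d_min,
                slice_index=y,
                endpoints=((int(tx), int(tz)),
                           (int(fx[tx, tz]), int(fz[tx, tz]))),
            )
    if best is None:
        raise ValueError("no coronal slice contains both a trochanter "
                         "surface and a skin outline")
    return best
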