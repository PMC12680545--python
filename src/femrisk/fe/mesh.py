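"""Voxel hexahedral mesh built directly from a bone-volume-fraction map.

Every retained voxel becomes one hex8 element with edge lengths equal to
the voxel dimensions.  Voxels below the BVF cutoff are removed, and only
the largest 6-connected component is kept so that floating fragments
cannot make the stiffness matrix singular.  Node and element numbering is
lexicographic in grid index (x fastest), hence deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..bvf import BVFMap

__all__ = ["VoxelMesh", "build_mesh", "nodes_in_voxel_mask",
           "surface_node_mask", "surface_patch_nodes"]


@dataclass
class VoxelMesh:
    """Hexahedral mesh of retained voxels.

    ``node_grid_ids`` are sorted flat corner-grid indices (grid of shape
    ``shape + 1`` per axis, x fastest); ``elem_nodes`` indexes into them.
    """

    shape: tuple[int, int, int]
    voxel_dims_mm: tuple[float, float, float]
    elem_ijk: np.ndarray          # (nel, 3) int voxel indices
    elem_bvf: np.ndarray          # (nel,) float
    node_grid_ids: np.ndarray     # (nn,) int64, sorted
    elem_nodes: np.ndarray        # (nel, 8) int32 into node_grid_ids
    meta: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return int(self.elem_ijk.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.node_grid_ids.shape[0])

    @property
    def voxel_dims_m(self) -> tuple[float, float, float]:
        return tuple(d * 1e-3 for d in self.voxel_dims_mm)

    def node_grid_coords(self) -> np.ndarray:
        """(nn, 3) integer corner-grid coordinates of the mesh nodes."""
        nx, ny, nz = self.shape
        sx, sy = nx + 1, ny + 1
        ids = self.node_grid_ids
        i = ids % sx
        j = (ids // sx) % sy
        k = ids // (sx * sy)
        return np.stack([i, j, k], axis=1)

    def node_coords_m(self) -> np.ndarray:
        """(nn, 3) physical node coordinates in metres (corner convention)."""
        return self.node_grid_coords() * np.asarray(self.voxel_dims_m)

    def retained_voxel_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[tuple(self.elem_ijk.T)] = True
        return mask


_CORNER_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int64)


def build_mesh(bvf_map: BVFMap, cutoff: float = 0.01) -> VoxelMesh:
    """Mesh the voxels with BVF >= cutoff; keep the largest 6-connected part."""
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must satisfy 0 <= cutoff < 1")
    bvf = bvf_map.bvf
    retained = bvf >= cutoff if cutoff > 0 else bvf > 0
    if not retained.any():
        raise ValueError(
            f"no voxels at or above BVF cutoff {cutoff}; "
            f"map maximum is {bvf.max():.4f}"
        )
    labels, n_comp = ndimage.label(
        retained, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = int(np.argmax(counts))  # ties -> smallest label, deterministic
        component = labels == keep
    else:
        component = retained

    # np.argwhere is lexicographic in (i, j, k); re-sort x fastest.
    ijk = np.argwhere(component)
    nx, ny, nz = bvf.shape
    order = np.lexsort((ijk[:, 0], ijk[:, 1], ijk[:, 2]))
    ijk = ijk[order]

    sx, sy = nx + 1, ny + 1
    corners = ijk[:, None, :] + _CORNER_OFFSETS[None, :, :]
    flat = (corners[..., 0] + sx * (corners[..., 1] + sy * corners[..., 2]))
    node_ids = np.unique(flat)
    elem_nodes = np.searchsorted(node_ids, flat).astype(np.int32)

    return VoxelMesh(
        shape=(nx, ny, nz),
        voxel_dims_mm=tuple(bvf_map.voxel_dims),
        elem_ijk=ijk,
        elem_bvf=bvf[tuple(ijk.T)].astype(np.float64),
        node_grid_ids=node_ids,
        elem_nodes=elem_nodes,
        meta={"cutoff": cutoff, "n_components": int(n_comp)},
    )


def nodes_in_voxel_mask(mesh: VoxelMesh, voxel_mask: np.ndarray) -> np.ndarray:
    """Sorted mesh-node indices belonging to retained voxels inside a mask."""
    voxel_mask = np.asarray(voxel_mask, dtype=bool)
    if voxel_mask.shape != mesh.shape:
        raise ValueError("voxel mask shape does not match the mesh grid")
    sel = voxel_mask[tuple(mesh.elem_ijk.T)]
    if not sel.any():
        return np.empty(0, dtype=np.int64)
    return np.unique(mesh.elem_nodes[sel]).astype(np.int64)


def surface_node_mask(mesh: VoxelMesh) -> np.ndarray:
    """Boolean mask of mesh nodes on the free surface.

    An interior node of a voxel mesh is shared by all eight incident
    elements; any node with fewer is on the surface.
    """
    counts = np.bincount(mesh.elem_nodes.ravel(), minlength=mesh.n_nodes)
    return counts < 8


def surface_patch_nodes(mesh: VoxelMesh, voxel_mask: np.ndarray) -> np.ndarray:
    """Surface nodes of the retained voxels inside a patch mask."""
    nodes = nodes_in_voxel_mask(mesh, voxel_mask)
    surface = surface_node_mask(mesh)
    return nodes[surface[nodes]]
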