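"""Eight-node trilinear hexahedral element for voxel meshes.

Isotropic linear elasticity, 2x2x2 Gauss integration, engineering-shear
Voigt ordering [exx, eyy, ezz, gxy, gyz, gzx].  Voxel elements are
axis-aligned rectangular boxes, so the Jacobian is diagonal and constant.
Local node order is lexicographic in the (x, y, z) corner offsets with x
fastest, matching the global mesh numbering.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NODE_OFFSETS",
    "elasticity_matrix",
    "hex8_stiffness",
    "centroid_b_matrix",
    "b_matrix_at",
    "equivalent_strain",
]

#: Corner offsets of the 8 local nodes, x fastest.
NODE_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float)

_SIGNS = 2.0 * NODE_OFFSETS - 1.0


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic Hooke matrix (engineering shear convention)."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN/dxi at a natural coordinate, shape (8, 3)."""
    s = _SIGNS
    x, y, z = xi
    g = np.empty((8, 3))
    g[:, 0] = s[:, 0] * (1 + s[:, 1] * y) * (1 + s[:, 2] * z) / 8.0
    g[:, 1] = (1 + s[:, 0] * x) * s[:, 1] * (1 + s[:, 2] * z) / 8.0
    g[:, 2] = (1 + s[:, 0] * x) * (1 + s[:, 1] * y) * s[:, 2] / 8.0
    return g


def _b_from_grad(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) from physical shape gradients."""
    B = np.zeros((6, 24))
    for i in range(8):
        bx, by, bz = dndx[i]
        c = 3 * i
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def b_matrix_at(xi, dims) -> np.ndarray:
    """B matrix at natural coordinate ``xi`` for a box of edge lengths ``dims``."""
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("element dimensions must be positive")
    dndx = _shape_gradients(np.asarray(xi, dtype=float)) * (2.0 / dims)
    return _b_from_grad(dndx)


def centroid_b_matrix(dims) -> np.ndarray:
    """Strain-displacement matrix evaluated at the element centroid."""
    return b_matrix_at((0.0, 0.0, 0.0), dims)


def hex8_stiffness(E: float, nu: float, dims) -> np.ndarray:
    """24x24 stiffness of an axis-aligned box element; scales linearly in E."""
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0):
        raise ValueError("element dimensions must be positive")
    D = elasticity_matrix(E, nu)
    det_j = float(np.prod(dims)) / 8.0
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for x in (-g, g):
        for y in (-g, g):
            for z in (-g, g):
                B = b_matrix_at((x, y, z), dims)
                K += B.T @ D @ B * det_j
    return 0.5 * (K + K.T)


def equivalent_strain(strain: np.ndarray, nu: float) -> np.ndarray:
    """Scalar equivalent strain driving the tissue-softening law.

    Von Mises (second deviatoric invariant) measure of the small-strain
    tensor, normalised by 3/(2(1+nu)) so that a uniaxial *stress* state
    returns exactly the axial strain.  ``strain`` has engineering shears
    in its last axis of length 6.
    """
    strain = np.asarray(strain, dtype=float)
    normal = strain[..., :3]
    mean = normal.mean(axis=-1, keepdims=True)
    dev = normal - mean
    shear = strain[..., 3:] / 2.0
    j2 = (dev ** 2).sum(axis=-1) + 2.0 * (shear ** 2).sum(axis=-1)
    evm = np.sqrt(np.maximum(2.0 / 3.0 * j2, 0.0))
    return evm * 3.0 / (2.0 * (1.0 + nu))
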