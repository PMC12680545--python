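"""Displacement-controlled sideways-fall simulation on a voxel mesh.

The femoral head is driven along the fall load axis against a trochanter
constrained along that axis (the surface the hip lands on) with the
distal shaft cut fully fixed.  Tissue modulus softens with local strain
through a hyperbolic-secant law, so the head reaction force rises to a
maximum and then falls; that maximum is the bone strength.

Per displacement increment the softened moduli are resolved by Picard
(secant-modulus) iteration: solve the linear elastic problem, update each
element's modulus E = E0 * BVF * sech(k * eps_eq) from the equivalent
strain at its centroid, repeat until the moduli settle.  Oblique
single-direction constraints are imposed exactly by rotating the affected
nodes into an orthonormal basis whose first axis is the load axis, which
keeps the stiffness matrix symmetric positive definite.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import LinearOperator, cg, splu, spsolve

from .hex8 import centroid_b_matrix, equivalent_strain, hex8_stiffness
from .mesh import VoxelMesh, surface_node_mask

__all__ = [
    "MaterialLaw",
    "SidewaysFallSetup",
    "ForceDisplacementCurve",
    "StrengthResult",
    "PeakForce",
    "fall_load_axis",
    "apply_sideways_fall_bcs",
    "solve_nonlinear",
    "solve_linear",
    "bone_strength",
    "FESystem",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaterialLaw:
    """Tissue material parameters.

    E0    tissue modulus at full mineralisation, Pa (15 GPa default);
    nu    Poisson ratio;
    k     secant-degradation rate per unit equivalent strain.  The element
          modulus is E0 * BVF * sech(k * eps_eq); with k = 120 the uniaxial
          tissue-level response peaks near 1% strain.
    """

    E0: float = 15e9
    nu: float = 0.3
    k: float = 120.0

    def __post_init__(self) -> None:
        if not self.E0 > 0:
            raise ValueError("E0 must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if not self.k > 0:
            raise ValueError("degradation rate k must be positive")

    def modulus(self, bvf: np.ndarray, eps_eq: np.ndarray,
                softening_floor: float = 0.01) -> np.ndarray:
        """Element modulus E0 * BVF * sech(k * eps_eq).

        The secant factor is floored at ``softening_floor`` (crushed
        tissue retains a small residual stiffness), which also keeps the
        stiffness contrast bounded for the iterative solver.
        """
        arg = np.minimum(self.k * np.asarray(eps_eq, dtype=float), 50.0)
        sech = np.maximum(1.0 / np.cosh(arg), softening_floor)
        return self.E0 * np.asarray(bvf, dtype=float) * sech


def fall_load_axis(diaphysis_tilt: float = 10.0,
                   internal_rotation: float = 15.0) -> np.ndarray:
    """Fall load axis: the ground normal rotated into the image frame.

    With the shaft along the inferior-superior axis the ground normal of a
    sideways fall is the left-right axis; it is rotated extrinsically by
    the diaphysis tilt about the anterior-posterior axis and then by the
    internal rotation about the inferior-superior axis.
    """
    t = math.radians(diaphysis_tilt)
    r = math.radians(internal_rotation)
    ry = np.array([[math.cos(t), 0.0, math.sin(t)],
                   [0.0, 1.0, 0.0],
                   [-math.sin(t), 0.0, math.cos(t)]])
    rz = np.array([[math.cos(r), -math.sin(r), 0.0],
                   [math.sin(r), math.cos(r), 0.0],
                   [0.0, 0.0, 1.0]])
    return rz @ ry @ np.array([1.0, 0.0, 0.0])


@dataclass
class SidewaysFallSetup:
    """Boundary-condition description for the sideways-fall simulation.

    Node sets index into the mesh: the head patch is driven along the load
    axis, the trochanter patch is fixed along it (lateral components
    free), and the distal shaft cut is fully fixed for stability.  ``pins``
    are optional extra (node, component) zero constraints used by simple
    test geometries to remove rigid-body modes.
    """

    head_nodes: np.ndarray
    trochanter_nodes: np.ndarray
    distal_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    diaphysis_tilt: float = 10.0
    internal_rotation: float = 15.0
    load_axis: np.ndarray | None = None
    pins: tuple[tuple[int, int], ...] = ()
    gauge_length_m: float | None = None

    def __post_init__(self) -> None:
        self.head_nodes = np.unique(np.asarray(self.head_nodes, dtype=np.int64))
        self.trochanter_nodes = np.unique(
            np.asarray(self.trochanter_nodes, dtype=np.int64))
        self.distal_nodes = np.unique(np.asarray(self.distal_nodes, dtype=np.int64))
        if self.head_nodes.size == 0 or self.trochanter_nodes.size == 0:
            raise ValueError("head and trochanter patches must be non-empty")
        for a, b, names in (
            (self.head_nodes, self.trochanter_nodes, "head/trochanter"),
            (self.head_nodes, self.distal_nodes, "head/distal"),
            (self.trochanter_nodes, self.distal_nodes, "trochanter/distal"),
        ):
            if np.intersect1d(a, b).size:
                raise ValueError(f"patches overlap: {names}")

    def resolved_axis(self) -> np.ndarray:
        if self.load_axis is not None:
            a = np.asarray(self.load_axis, dtype=float)
            n = np.linalg.norm(a)
            if not n > 0:
                raise ValueError("load_axis must be a non-zero vector")
            return a / n
        return fall_load_axis(self.diaphysis_tilt, self.internal_rotation)


@dataclass
class ForceDisplacementCurve:
    """Head displacement vs total head reaction force, one row per step."""

    displacement_mm: np.ndarray
    force_kN: np.ndarray
    apparent_strain: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_kN = np.asarray(self.force_kN, dtype=float)
        self.apparent_strain = np.asarray(self.apparent_strain, dtype=float)
        if self.displacement_mm.size == 0:
            raise ValueError("curve is empty")
        if np.any(np.diff(self.displacement_mm) <= 0):
            raise ValueError("displacements must be strictly increasing")
        if self.displacement_mm[0] != 0.0:
            raise ValueError("curve must start at zero displacement")
        if not np.all(np.isfinite(self.force_kN)):
            raise ValueError("forces must be finite")


@dataclass(frozen=True)
class PeakForce:
    strength_kN: float
    strain_at_peak: float


@dataclass
class StrengthResult:
    """Outcome of the sideways-fall simulation."""

    strength_kN: float
    strain_at_peak: float
    curve: ForceDisplacementCurve
    diagnostics: dict = field(default_factory=dict)


def bone_strength(curve: ForceDisplacementCurve) -> PeakForce:
    """Maximum of the force-displacement curve and the strain at which it occurs."""
    i = int(np.argmax(curve.force_kN))
    return PeakForce(float(curve.force_kN[i]), float(curve.apparent_strain[i]))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _orthonormal_basis(axis: np.ndarray) -> np.ndarray:
    """3x3 orthonormal basis with the given axis as its first column."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(a)))] = 1.0
    t1 = np.cross(a, e)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(a, t1)
    return np.column_stack([a, t1, t2])


class FESystem:
    """Reusable assembly machinery for one mesh.

    A shared unit-modulus element stiffness is scaled by each element's
    modulus; elements touching nodes whose degrees of freedom are rotated
    into the load-axis basis carry their own pre-transformed copy.
    """

    def __init__(self, mesh: VoxelMesh, nu: float,
                 rotated_nodes: np.ndarray | None = None,
                 axis: np.ndarray | None = None):
        self.mesh = mesh
        self.nu = float(nu)
        dims_m = np.asarray(mesh.voxel_dims_m)
        self.ke_unit = hex8_stiffness(1.0, nu, dims_m)
        self.bc = centroid_b_matrix(dims_m)
        self.n_dof = 3 * mesh.n_nodes

        en = mesh.elem_nodes.astype(np.int64)
        edof = (np.repeat(en * 3, 3, axis=1)
                + np.tile(np.arange(3), 8)[None, :])
        self.edof = edof                                   # (nel, 24)
        self.rows = np.repeat(edof, 24, axis=1).ravel()
        self.cols = np.tile(edof, (1, 24)).ravel()
        # Precomputed assembly map: the global CSR values are a fixed
        # linear function of the element moduli, K.data = A_map @ E, so
        # each assembly is one sparse matrix-vector product.
        key = self.rows * self.n_dof + self.cols
        order = np.argsort(key, kind="stable")
        sk = key[order]
        starts = np.nonzero(np.r_[True, sk[1:] != sk[:-1]])[0]
        uk = sk[starts]
        self._csr_indices = (uk % self.n_dof).astype(np.int32)
        csr_rows = uk // self.n_dof
        self._csr_indptr = np.searchsorted(
            csr_rows, np.arange(self.n_dof + 1)).astype(np.int64)
        self._order = order
        self._starts = starts
        self._assembly_map = None   # built lazily (needs special ke's)

        self.rotated_nodes = (np.unique(np.asarray(rotated_nodes, np.int64))
                              if rotated_nodes is not None and len(rotated_nodes)
                              else np.empty(0, np.int64))
        self.R = _orthonormal_basis(axis) if self.rotated_nodes.size else np.eye(3)
        self._special_idx = np.empty(0, np.int64)
        self._ke_special = np.empty((0, 576))
        if self.rotated_nodes.size:
            rot_set = np.zeros(mesh.n_nodes, dtype=bool)
            rot_set[self.rotated_nodes] = True
            touched = rot_set[en].any(axis=1)
            self._special_idx = np.nonzero(touched)[0]
            ke_sp = np.empty((self._special_idx.size, 576))
            for out, e in enumerate(self._special_idx):
                T = np.eye(24)
                for ln, node in enumerate(en[e]):
                    if rot_set[node]:
                        T[3 * ln:3 * ln + 3, 3 * ln:3 * ln + 3] = self.R
                ke_sp[out] = (T.T @ self.ke_unit @ T).ravel()
            self._ke_special = ke_sp

    def _build_assembly_map(self):
        nel = self.mesh.n_elements
        unit = np.tile(self.ke_unit.ravel(), (nel, 1))
        if self._special_idx.size:
            unit[self._special_idx] = self._ke_special
        elem_of_entry = np.repeat(np.arange(nel), 576)[self._order]
        counts = np.diff(np.r_[self._starts, self._order.size])
        seg_id = np.repeat(np.arange(self._starts.size), counts)
        A = csr_matrix(
            (unit.ravel()[self._order], (seg_id, elem_of_entry)),
            shape=(self._starts.size, nel))
        return A

    def assemble(self, elem_E: np.ndarray):
        """Global stiffness (CSR) in the (possibly rotated) working frame."""
        if self._assembly_map is None:
            self._assembly_map = self._build_assembly_map()
        vals = self._assembly_map @ np.asarray(elem_E, dtype=float)
        return csr_matrix((vals, self._csr_indices, self._csr_indptr),
                          shape=(self.n_dof, self.n_dof))

    def to_physical(self, u: np.ndarray) -> np.ndarray:
        """Rotate a working-frame vector back to image-frame components."""
        if not self.rotated_nodes.size:
            return u
        out = u.copy()
        idx = self.rotated_nodes
        dofs = (3 * idx[:, None] + np.arange(3)[None, :]).ravel()
        out[dofs] = (u[dofs].reshape(-1, 3) @ self.R.T).ravel()
        return out

    def element_strains(self, u_phys: np.ndarray) -> np.ndarray:
        """Centroid strain (engineering Voigt) per element, from a
        physical-frame displacement vector in metres."""
        return u_phys[self.edof] @ self.bc.T


# ---------------------------------------------------------------------------
# Linear solves with Dirichlet constraints
# ---------------------------------------------------------------------------

class _DirichletSolver:
    """Solve K u = 0 subject to prescribed dofs.

    Small reduced systems are solved directly (sparse LU).  Larger ones
    use conjugate gradients preconditioned by an exact sparse LU of a
    *reference* stiffness: because the softened matrices stay spectrally
    close to the reference, CG converges in a handful of iterations, and
    the expensive factorisation happens once.  The reference is refreshed
    whenever CG needs more than ``refactor_iters`` iterations.
    """

    def __init__(self, n_dof: int, cons_idx: np.ndarray, rtol: float = 1e-6,
                 direct_threshold: int = 6000, refactor_iters: int = 120):
        self.cons = np.unique(np.asarray(cons_idx, dtype=np.int64))
        if self.cons.size != np.asarray(cons_idx).size:
            raise ValueError("duplicate constrained degrees of freedom")
        mask = np.ones(n_dof, dtype=bool)
        mask[self.cons] = False
        self.free = np.nonzero(mask)[0]
        self.rtol = rtol
        self.direct_threshold = direct_threshold
        self.refactor_iters = refactor_iters
        self._lu = None
        self._sub = None            # cached submatrix gather maps
        self.cg_iters: list[int] = []

    @staticmethod
    def _factor(Kff):
        return splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A",
                    options={"SymmetricMode": True})

    def _submatrices(self, K):
        """Extract K_ff and K_fc.  The sparsity pattern of K is fixed
        across secant iterations, so the extraction is reduced to a
        cached gather of K.data after the first call."""
        free, cons = self.free, self.cons
        if self._sub is None:
            pos = csr_matrix(
                (np.arange(1, K.nnz + 1, dtype=np.float64),
                 K.indices, K.indptr), shape=K.shape)
            pff = pos[free][:, free]
            pfc = pos[free][:, cons]
            self._sub = {
                "nnz": K.nnz,
                "ff": (pff.data.astype(np.int64) - 1, pff.indices,
                       pff.indptr, pff.shape),
                "fc": (pfc.data.astype(np.int64) - 1, pfc.indices,
                       pfc.indptr, pfc.shape),
            }
        if self._sub["nnz"] != K.nnz:      # different pattern: rebuild
            self._sub = None
            return self._submatrices(K)
        g, ind, ptr, shp = self._sub["ff"]
        Kff = csr_matrix((K.data[g], ind, ptr), shape=shp)
        g, ind, ptr, shp = self._sub["fc"]
        Kfc = csr_matrix((K.data[g], ind, ptr), shape=shp)
        return Kff, Kfc

    def solve(self, K, cons_vals: np.ndarray,
              x0_full: np.ndarray | None = None) -> np.ndarray:
        free, cons = self.free, self.cons
        Kff, Kfc = self._submatrices(K)
        rhs = -Kfc @ cons_vals
        u = np.zeros(K.shape[0])
        u[cons] = cons_vals
        if free.size == 0:
            return u
        if free.size <= self.direct_threshold:
            u[free] = spsolve(Kff.tocsc(), rhs)
            return u

        if self._lu is None:
            self._lu = self._factor(Kff)
        M = LinearOperator(Kff.shape, matvec=self._lu.solve)
        x0 = x0_full[free] if x0_full is not None else None
        n_it = 0

        def _count(_):
            nonlocal n_it
            n_it += 1

        x, info = cg(Kff, rhs, x0=x0, rtol=self.rtol, atol=0.0,
                     M=M, maxiter=2000, callback=_count)
        if info != 0 or n_it > self.refactor_iters:
            self._lu = self._factor(Kff)
            if info != 0:
                M = LinearOperator(Kff.shape, matvec=self._lu.solve)
                x, info = cg(Kff, rhs, x0=x, rtol=self.rtol, atol=0.0,
                             M=M, maxiter=2000, callback=_count)
        if info != 0:
            res = float(np.linalg.norm(Kff @ x - rhs)
                        / max(np.linalg.norm(rhs), 1e-300))
            raise RuntimeError(
                f"linear solve failed to converge (relative residual {res:.2e})")
        self.cg_iters.append(n_it)
        u[free] = x
        return u


def solve_linear(mesh: VoxelMesh, elem_E: np.ndarray, nu: float,
                 prescribed_idx: np.ndarray, prescribed_vals: np.ndarray,
                 rtol: float = 1e-10) -> np.ndarray:
    """One linear elastic solve with arbitrary prescribed dofs (image frame).

    Used for patch tests and simple static checks; returns the full
    displacement vector in metres.
    """
    sys_ = FESystem(mesh, nu)
    K = sys_.assemble(np.asarray(elem_E, dtype=float))
    order = np.argsort(np.asarray(prescribed_idx))
    idx = np.asarray(prescribed_idx, dtype=np.int64)[order]
    vals = np.asarray(prescribed_vals, dtype=float)[order]
    solver = _DirichletSolver(sys_.n_dof, idx, rtol=rtol,
                              direct_threshold=200_000)
    return solver.solve(K, vals)


# ---------------------------------------------------------------------------
# Boundary conditions and the nonlinear driver
# ---------------------------------------------------------------------------

@dataclass
class BoundaryConditions:
    """Constrained-system description produced by `apply_sideways_fall_bcs`."""

    axis: np.ndarray
    rotated_nodes: np.ndarray
    cons_idx: np.ndarray          # constrained dofs, working frame, sorted
    head_dof_pos: np.ndarray      # positions of head along-axis dofs in cons_idx
    gauge_length_m: float

    def values(self, head_displacement_m: float) -> np.ndarray:
        vals = np.zeros(self.cons_idx.size)
        vals[self.head_dof_pos] = head_displacement_m
        return vals


def apply_sideways_fall_bcs(mesh: VoxelMesh,
                            setup: SidewaysFallSetup) -> BoundaryConditions:
    """Resolve the setup into constrained degrees of freedom.

    Head-patch nodes are driven along the load axis (lateral components
    free); trochanter-patch nodes are fixed along the axis; distal nodes
    are fully fixed; pins are zeroed on their stated component.  All
    patch nodes must lie on the mesh surface.
    """
    for nodes, name in ((setup.head_nodes, "head"),
                        (setup.trochanter_nodes, "trochanter"),
                        (setup.distal_nodes, "distal")):
        if nodes.size and (nodes.min() < 0 or nodes.max() >= mesh.n_nodes):
            raise ValueError(f"{name} patch references nodes outside the mesh")
    surface = surface_node_mask(mesh)
    for nodes, name in ((setup.head_nodes, "head"),
                        (setup.trochanter_nodes, "trochanter")):
        if not surface[nodes].all():
            raise ValueError(f"{name} patch includes interior (non-surface) nodes")

    axis = setup.resolved_axis()
    rotated = np.union1d(setup.head_nodes, setup.trochanter_nodes)

    head_dofs = 3 * setup.head_nodes          # along-axis dof in rotated basis
    troch_dofs = 3 * setup.trochanter_nodes
    distal_dofs = (3 * setup.distal_nodes[:, None]
                   + np.arange(3)[None, :]).ravel()
    pin_dofs = np.array([3 * n + c for n, c in setup.pins], dtype=np.int64)
    if pin_dofs.size and np.intersect1d(pin_dofs, np.concatenate(
            [head_dofs, troch_dofs, distal_dofs])).size:
        raise ValueError("pins overlap patch constraints")

    cons = np.concatenate([head_dofs, troch_dofs, distal_dofs, pin_dofs])
    if np.unique(cons).size != cons.size:
        raise ValueError("constrained dofs are not unique")
    order = np.argsort(cons)
    cons_sorted = cons[order]
    head_positions = np.nonzero(np.isin(cons_sorted, head_dofs))[0]

    if setup.gauge_length_m is not None:
        gauge = float(setup.gauge_length_m)
    else:
        coords = mesh.node_coords_m()
        gauge = float(abs(
            (coords[setup.head_nodes].mean(axis=0)
             - coords[setup.trochanter_nodes].mean(axis=0)) @ axis))
    if not gauge > 0:
        raise ValueError("gauge length along the load axis is zero")

    return BoundaryConditions(axis=axis, rotated_nodes=rotated,
                              cons_idx=cons_sorted,
                              head_dof_pos=head_positions,
                              gauge_length_m=gauge)


def solve_nonlinear(mesh: VoxelMesh, setup: SidewaysFallSetup,
                    law: MaterialLaw | None = None,
                    target_strain: float = 0.03, n_steps: int = 30,
                    cg_rtol: float = 1e-6, picard_tol: float = 0.01,
                    picard_maxiter: int = 25,
                    force_tol: float = 0.005,
                    softening_floor: float = 0.01,
                    direct_threshold: int = 6000) -> StrengthResult:
    """Run the displacement-controlled simulation to the target apparent
    strain and return the bone strength (curve maximum).

    Apparent strain is the prescribed head displacement divided by the
    initial head-to-trochanter gauge length along the load axis.

    Softening is treated as irreversible damage: an element's secant
    factor can only decrease along the loading path (micro-damage does
    not heal when a crushed neighbourhood sheds load).  This makes the
    secant-modulus iteration monotone — moduli are non-increasing and
    bounded below by the softening floor — so it converges without the
    load/unload flickering a naive secant update exhibits.  An increment
    is accepted when the largest relative modulus decrease falls below
    ``picard_tol`` or the head reaction force is stable to ``force_tol``.
    """
    if n_steps < 5:
        raise ValueError("n_steps must be >= 5")
    if not target_strain > 0:
        raise ValueError("target_strain must be positive")
    law = law or MaterialLaw()

    bc = apply_sideways_fall_bcs(mesh, setup)
    sys_ = FESystem(mesh, law.nu, rotated_nodes=bc.rotated_nodes, axis=bc.axis)
    solver = _DirichletSolver(sys_.n_dof, bc.cons_idx, rtol=cg_rtol,
                              direct_threshold=direct_threshold)
    head_dofs_global = 3 * setup.head_nodes

    E_e = law.modulus(mesh.elem_bvf, np.zeros(mesh.n_elements),
                      softening_floor)
    u = np.zeros(sys_.n_dof)
    disp = [0.0]
    forces = [0.0]
    strains = [0.0]
    equilibrium = []
    picard_counts = []
    converged_flags = []

    for step in range(1, n_steps + 1):
        d = target_strain * bc.gauge_length_m * step / n_steps
        vals = bc.values(d)
        x0 = u * (step / (step - 1)) if step > 1 else None
        K = None
        converged = False
        f_prev = None
        for it in range(1, picard_maxiter + 1):
            K = sys_.assemble(E_e)
            u = solver.solve(K, vals, x0_full=x0)
            x0 = u
            f_it = float((K @ u)[3 * setup.head_nodes].sum())
            eps = sys_.element_strains(sys_.to_physical(u))
            eq = equivalent_strain(eps, law.nu)
            E_target = law.modulus(mesh.elem_bvf, eq, softening_floor)
            # irreversible damage: secant moduli never recover
            E_new = np.minimum(E_e, E_target)
            change = float(np.max((E_e - E_new)
                                  / np.maximum(E_e, 1e-300)))
            f_change = (abs(f_it - f_prev) / max(abs(f_it), 1e-30)
                        if f_prev is not None else np.inf)
            f_prev = f_it
            log.debug("step %d picard %d: modulus change %.4f, "
                      "force change %.5f", step, it, change, f_change)
            if change < picard_tol or f_change < force_tol:
                converged = True
                break
            E_e = E_new
        if not converged:
            warnings.warn(
                f"Picard iteration did not settle at step {step} "
                f"(last modulus change {change:.3f})", RuntimeWarning,
                stacklevel=2)
        picard_counts.append(it)
        converged_flags.append(converged)

        r = K @ u
        f_head = float(r[head_dofs_global].sum())      # along-axis component
        r_phys = sys_.to_physical(r)
        net = np.linalg.norm(r_phys.reshape(-1, 3).sum(axis=0))
        equilibrium.append(net / max(abs(f_head), 1e-30))

        disp.append(d * 1e3)
        forces.append(f_head / 1e3)
        strains.append(d / bc.gauge_length_m)
        log.debug("step %d/%d: d=%.4g mm F=%.4g kN (picard %d)",
                  step, n_steps, d * 1e3, f_head / 1e3, it)

    curve = ForceDisplacementCurve(np.array(disp), np.array(forces),
                                   np.array(strains))
    peak = bone_strength(curve)
    return StrengthResult(
        strength_kN=peak.strength_kN,
        strain_at_peak=peak.strain_at_peak,
        curve=curve,
        diagnostics={
            "picard_iterations": picard_counts,
            "picard_converged": converged_flags,
            "equilibrium_residual": equilibrium,
            "cg_iterations": solver.cg_iters,
            "gauge_length_mm": bc.gauge_length_m * 1e3,
            "load_axis": bc.axis.tolist(),
            "n_elements": mesh.n_elements,
            "n_nodes": mesh.n_nodes,
        },
    )
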