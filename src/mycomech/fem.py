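"""Finite-element simulation of the cylinder compression test.

A 3-D total-Lagrangian formulation with tri-linear hexahedra (full 2×2×2
Gauss quadrature) and the compressible Neo-Hookean energy of
:mod:`mycomech.neohooke`, compressed by a rigid horizontal stamp enforced
through frictionless node-wise penalty contact.  The specimen is a
structured butterfly-pattern hexahedral cylinder whose top face may be
slightly slanted, reflecting how free-standing specimens settle during
growth.

Boundary conditions: the bottom face is fixed vertically but laterally
free (frictionless platen), with two in-plane pins removing the remaining
rigid-body modes.  This choice admits the exact homogeneous uniaxial
solution, so the solver can be verified against the closed-form nominal
stress A·|λ S33(λ)| on any mesh.  A fully clamped bottom is available for
qualitative barreling studies.

Stress measure conventions: internal forces use the first Piola–Kirchhoff
stress P = F S with S = 2 ∂w/∂C; reported equivalent stress is the von
Mises norm of the Cauchy stress σ = J⁻¹ P Fᵀ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .neohooke import NeoHookeParams, small_strain_moduli

__all__ = [
    "CylinderMesh",
    "ContactConfig",
    "SolverConfig",
    "FEMResult",
    "ElementInversionError",
    "NewtonError",
    "build_cylinder_mesh",
    "assemble",
    "apply_penalty_contact",
    "run_compression",
    "equivalent_stress",
    "export_vtk",
    "read_vtk_summary",
]


class ElementInversionError(RuntimeError):
    """An element reached a non-positive deformation Jacobian."""


class NewtonError(RuntimeError):
    """Newton iteration failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# mesh


@dataclass
class CylinderMesh:
    """Structured hexahedral cylinder with named boundary node sets."""

    nodes: np.ndarray          # (n, 3) reference coordinates, mm
    hexes: np.ndarray          # (e, 8) connectivity, VTK hexahedron order
    bottom_nodes: np.ndarray   # node ids on z = 0
    top_nodes: np.ndarray      # node ids on the (possibly slanted) top face
    top_faces: np.ndarray      # (f, 4) quad connectivity of the top face
    diameter: float
    height: float
    slant_deg: float
    cross_section_area: float  # polygonal bottom-face area, mm²

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def volume(self) -> float:
        """Reference volume by Gauss integration (also checks Jacobians)."""
        _, detJ = _reference_gradients(self.nodes, self.hexes)
        return float(detJ.sum())


def _quad_mesh_disc(radius: float, n_core: int, n_ring: int):
    """Butterfly quad mesh of a disc: a square core plus four blended blocks."""
    if n_core < 2 or n_core % 2:
        raise ValueError("core resolution must be an even number >= 2")
    if n_ring < 1:
        raise ValueError("ring resolution must be >= 1")
    a = 0.5 * radius
    key_to_id: dict[tuple[int, int], int] = {}
    pts: list[tuple[float, float]] = []

    def node(x: float, y: float) -> int:
        key = (round(x * 1e8), round(y * 1e8))
        if key not in key_to_id:
            key_to_id[key] = len(pts)
            pts.append((x, y))
        return key_to_id[key]

    quads: list[list[int]] = []
    # core square
    xs = np.linspace(-a, a, n_core + 1)
    for i in range(n_core):
        for j in range(n_core):
            quads.append(
                [
                    node(xs[i], xs[j]),
                    node(xs[i + 1], xs[j]),
                    node(xs[i + 1], xs[j + 1]),
                    node(xs[i], xs[j + 1]),
                ]
            )
    # four transition blocks, each a rotation of the +x block
    ts = np.linspace(0.0, 1.0, n_core + 1)
    rs = np.linspace(0.0, 1.0, n_ring + 1)
    for base in (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi):
        cb, sb = math.cos(base), math.sin(base)

        def pos(t: float, r: float) -> tuple[float, float]:
            xi, yi = a, a * (2.0 * t - 1.0)           # inner: core edge
            th = (2.0 * t - 1.0) * math.pi / 4.0       # outer: circular arc
            xo, yo = radius * math.cos(th), radius * math.sin(th)
            x = (1 - r) * xi + r * xo
            y = (1 - r) * yi + r * yo
            return cb * x - sb * y, sb * x + cb * y

        for j in range(n_core):
            for k in range(n_ring):
                quads.append(
                    [
                        node(*pos(ts[j], rs[k])),
                        node(*pos(ts[j], rs[k + 1])),
                        node(*pos(ts[j + 1], rs[k + 1])),
                        node(*pos(ts[j + 1], rs[k])),
                    ]
                )
    pts_arr = np.array(pts)
    quads_arr = np.array(quads, dtype=np.int64)
    # enforce counter-clockwise orientation quad by quad
    p = pts_arr[quads_arr]
    area2 = np.zeros(len(quads_arr))
    for i in range(4):
        x0, y0 = p[:, i, 0], p[:, i, 1]
        x1, y1 = p[:, (i + 1) % 4, 0], p[:, (i + 1) % 4, 1]
        area2 += x0 * y1 - x1 * y0
    flip = area2 < 0
    quads_arr[flip] = quads_arr[flip][:, ::-1]
    total_area = float(np.abs(area2).sum() / 2.0)
    return pts_arr, quads_arr, total_area


def build_cylinder_mesh(
    diameter: float,
    height: float,
    slant_deg: float = 0.0,
    n_azimuthal: int = 4,
    n_radial: int = 2,
    n_axial: int = 4,
) -> CylinderMesh:
    """Structured butterfly-pattern hexahedral cylinder mesh.

    ``n_azimuthal`` is the number of divisions per core-square side (must be
    even so nodes exist on the x/y axes, which the rigid-mode pins rely on),
    ``n_radial`` the number of layers in the outer ring, ``n_axial`` the
    number of element layers along the height.  A non-zero ``slant_deg``
    shears node heights by z → z (1 + tan(slant) x / L0), so the top face
    becomes the plane z = L0 + tan(slant) x while the bottom stays flat and
    the volume is preserved.
    """
    if not (0.0 <= slant_deg < 10.0):
        raise ValueError("slant angle must lie in [0, 10) degrees")
    if n_axial < 1:
        raise ValueError("axial resolution must be >= 1")
    pts2d, quads, area = _quad_mesh_disc(diameter / 2.0, n_azimuthal, n_radial)
    n2d = pts2d.shape[0]
    zs = np.linspace(0.0, height, n_axial + 1)
    nodes = np.empty((n2d * (n_axial + 1), 3))
    for layer, z in enumerate(zs):
        nodes[layer * n2d:(layer + 1) * n2d, :2] = pts2d
        nodes[layer * n2d:(layer + 1) * n2d, 2] = z
    hexes = np.empty((quads.shape[0] * n_axial, 8), dtype=np.int64)
    for layer in range(n_axial):
        lo, hi = layer * n2d, (layer + 1) * n2d
        block = slice(layer * quads.shape[0], (layer + 1) * quads.shape[0])
        hexes[block, :4] = quads + lo
        hexes[block, 4:] = quads + hi
    if slant_deg > 0:
        shear = math.tan(math.radians(slant_deg))
        nodes[:, 2] *= 1.0 + shear * nodes[:, 0] / height
    bottom = np.arange(n2d)
    top = np.arange(n_axial * n2d, (n_axial + 1) * n2d)
    top_faces = quads + n_axial * n2d
    mesh = CylinderMesh(
        nodes=nodes,
        hexes=hexes,
        bottom_nodes=bottom,
        top_nodes=top,
        top_faces=top_faces,
        diameter=diameter,
        height=height,
        slant_deg=slant_deg,
        cross_section_area=area,
    )
    # fail fast on inverted reference elements
    _, detJ = _reference_gradients(nodes, hexes)
    if np.any(detJ <= 0):
        raise ValueError("mesh has non-positive reference Jacobians")
    return mesh


# ---------------------------------------------------------------------------
# element kernels (vectorized over all elements, loop over Gauss points)

_GP = np.array(
    [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
    dtype=float,
) / math.sqrt(3.0)
_SIGNS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dξ_j at one natural point, shape (8, 3)."""
    s = _SIGNS
    f = 1.0 + s * xi  # (8, 3) factors (1 + s_j ξ_j)
    dN = np.empty((8, 3))
    dN[:, 0] = s[:, 0] * f[:, 1] * f[:, 2] / 8.0
    dN[:, 1] = s[:, 1] * f[:, 0] * f[:, 2] / 8.0
    dN[:, 2] = s[:, 2] * f[:, 0] * f[:, 1] / 8.0
    return dN


def _reference_gradients(nodes: np.ndarray, hexes: np.ndarray):
    """Reference shape gradients and volume weights at all Gauss points.

    Returns ``grads`` of shape (ngp, e, 8, 3) with ∂N_a/∂X_i and ``dV`` of
    shape (ngp, e) (detJ × weight, unit weights for 2×2×2 Gauss).
    """
    Xe = nodes[hexes]  # (e, 8, 3)
    grads = np.empty((_GP.shape[0], hexes.shape[0], 8, 3))
    dV = np.empty((_GP.shape[0], hexes.shape[0]))
    for g, xi in enumerate(_GP):
        dN = _shape_gradients(xi)  # (8, 3)
        Jm = np.einsum("eai,aj->eij", Xe, dN)  # (e, 3, 3)
        det = np.linalg.det(Jm)
        dV[g] = det
        invJ = np.linalg.inv(Jm)
        grads[g] = np.einsum("aj,eji->eai", dN, invJ)
    return grads, dV


def _stress_and_tangent(F: np.ndarray, params: NeoHookeParams):
    """Second PK stress S and material tangent ℂ = 2 dS/dC, batched over e."""
    C = np.einsum("eki,ekj->eij", F, F)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ElementInversionError("non-positive deformation Jacobian")
    Ci = np.linalg.inv(C)
    I = np.eye(3)
    c, d = params.c, params.d
    S = 2.0 * c * (I - Ci) + (2.0 * d * (J - 1.0) * J)[:, None, None] * Ci
    gamma = 2.0 * c - 2.0 * d * (J**2 - J)
    beta = 2.0 * d * (2.0 * J - 1.0) * J
    CC = (
        np.einsum("e,eik,ejl->eijkl", gamma, Ci, Ci, optimize=True)
        + np.einsum("e,eil,ejk->eijkl", gamma, Ci, Ci, optimize=True)
        + np.einsum("e,eij,ekl->eijkl", beta, Ci, Ci, optimize=True)
    )
    return S, CC, J


def assemble(
    mesh: CylinderMesh,
    params: NeoHookeParams,
    u: np.ndarray,
    ref_data=None,
    need_tangent: bool = True,
):
    """Internal force vector and (optionally) consistent tangent stiffness.

    ``u`` is the flat (3n,) displacement vector.  Returns ``(f_int, K)``
    with K a CSR matrix, or ``(f_int, None)``.  ``ref_data`` caches the
    reference-configuration gradients from :func:`_reference_gradients`.
    """
    if ref_data is None:
        ref_data = _reference_gradients(mesh.nodes, mesh.hexes)
    grads, dV = ref_data
    ne = mesh.n_elements
    ue = u.reshape(-1, 3)[mesh.hexes]  # (e, 8, 3)
    f_el = np.zeros((ne, 8, 3))
    K_el = np.zeros((ne, 24, 24)) if need_tangent else None
    I = np.eye(3)
    for g in range(grads.shape[0]):
        G = grads[g]  # (e, 8, 3): ∂N_a/∂X_j
        F = I + np.einsum("eai,eaj->eij", ue, G)
        S, CC, _ = _stress_and_tangent(F, params)
        P = np.einsum("eik,ekj->eij", F, S)
        f_el += np.einsum("eij,eaj,e->eai", P, G, dV[g])
        if need_tangent:
            # A_iJkL = δ_ik S_JL + F_iM ℂ_MJLQ F_kQ
            A = np.einsum("ik,ejl->eijkl", I, S) + np.einsum(
                "eim,emjlq,ekq->eijkl", F, CC, F, optimize=True
            )
            Ke = np.einsum(
                "eaj,eijkl,ebl,e->eaibk", G, A, G, dV[g], optimize=True
            )
            K_el += Ke.reshape(ne, 24, 24)
    ndof = 3 * mesh.n_nodes
    f_int = np.zeros(ndof)
    edof = (3 * mesh.hexes[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    np.add.at(f_int, edof.ravel(), f_el.reshape(ne, 24).ravel())
    if not need_tangent:
        return f_int, None
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sparse.coo_matrix(
        (K_el.ravel(), (rows, cols)), shape=(ndof, ndof)
    ).tocsr()
    return f_int, K


# ---------------------------------------------------------------------------
# contact


@dataclass(frozen=True)
class ContactConfig:
    """Frictionless rigid-stamp penalty contact.

    Per-node penalty stiffness κ_a = penalty_factor · E · A_a / L0, with E
    the small-strain Young's modulus of the material and A_a the consistent
    nodal area of the top face — area weighting makes a uniform penetration
    equivalent to a uniform pressure, which keeps the homogeneous uniaxial
    state an exact solution.  ``kappa_per_area`` (N/mm³) overrides the
    automatic rule when set.
    """

    penalty_factor: float = 1000.0
    kappa_per_area: float | None = None

    def nodal_stiffness(
        self, mesh: CylinderMesh, params: NeoHookeParams
    ) -> np.ndarray:
        areas = _top_nodal_areas(mesh)
        if self.kappa_per_area is not None:
            if self.kappa_per_area <= 0:
                raise ValueError("penalty stiffness must be positive")
            return self.kappa_per_area * areas
        if self.penalty_factor <= 0:
            raise ValueError("penalty factor must be positive")
        E, _ = small_strain_moduli(params)
        return self.penalty_factor * E * areas / mesh.height


def _top_nodal_areas(mesh: CylinderMesh) -> np.ndarray:
    """Consistent (row-sum) nodal areas of the top face, per top node."""
    gp2 = np.array([[sx, sy] for sy in (-1, 1) for sx in (-1, 1)]) / math.sqrt(3.0)
    signs = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    areas = np.zeros(mesh.n_nodes)
    X = mesh.nodes[mesh.top_faces]  # (f, 4, 3)
    for xi in gp2:
        f = 1.0 + signs * xi
        N = f[:, 0] * f[:, 1] / 4.0
        dN = np.column_stack(
            [signs[:, 0] * f[:, 1] / 4.0, signs[:, 1] * f[:, 0] / 4.0]
        )
        t1 = np.einsum("fai,a->fi", X, dN[:, 0])
        t2 = np.einsum("fai,a->fi", X, dN[:, 1])
        dA = np.linalg.norm(np.cross(t1, t2), axis=1)
        np.add.at(areas, mesh.top_faces.ravel(), np.outer(dA, N).ravel())
    return areas[mesh.top_nodes]


def apply_penalty_contact(
    z_current: np.ndarray, stamp_height: float, kappa: np.ndarray
):
    """Nodal penalty forces against the rigid plane z = stamp_height.

    ``z_current`` are current heights of the candidate (top-face) nodes and
    ``kappa`` their penalty stiffnesses.  Penetration g = z − h > 0 draws a
    downward force κ g.  Returns ``(forces, active)`` with downward-positive
    force magnitudes; the stamp reaction is their sum.
    """
    g = z_current - stamp_height
    active = g > 0
    forces = np.where(active, kappa * g, 0.0)
    return forces, active


# ---------------------------------------------------------------------------
# solver


@dataclass(frozen=True)
class SolverConfig:
    """Newton/load-stepping controls for :func:`run_compression`."""

    target_travel: float = 10.0      # total stamp travel, mm
    step: float | None = None        # stamp increment, mm (default L0/100)
    newton_tol: float = 1e-9         # relative residual tolerance
    max_iterations: int = 30
    max_halvings: int = 8
    clamp_bottom: bool = False       # True: clamp bottom in-plane (barreling)

    def __post_init__(self) -> None:
        if not (0.0 < self.newton_tol <= 1e-2):
            raise ValueError("newton_tol must lie in (0, 1e-2]")
        if self.target_travel <= 0:
            raise ValueError("target travel must be positive")


@dataclass
class FEMResult:
    """Stamp travel vs reaction, final fields, and the convergence log."""

    travel: np.ndarray              # stamp displacement from first contact, mm
    reaction: np.ndarray            # total stamp reaction force, N
    displacement: np.ndarray        # (n, 3) final nodal displacements, mm
    von_mises: np.ndarray           # (e,) final equivalent Cauchy stress, MPa
    mesh: CylinderMesh
    converged: bool
    log: list = field(default_factory=list)


def _fixed_dofs(mesh: CylinderMesh, clamp_bottom: bool) -> np.ndarray:
    fixed = [3 * n + 2 for n in mesh.bottom_nodes]
    if clamp_bottom:
        for n in mesh.bottom_nodes:
            fixed += [3 * n, 3 * n + 1]
        return np.unique(fixed)
    xy = mesh.nodes[mesh.bottom_nodes, :2]
    r = np.hypot(xy[:, 0], xy[:, 1])
    center = mesh.bottom_nodes[int(np.argmin(r))]
    if r.min() > 1e-6 * mesh.diameter:
        raise ValueError("no bottom node on the axis to pin")
    on_x = mesh.bottom_nodes[
        (np.abs(xy[:, 1]) < 1e-6 * mesh.diameter) & (xy[:, 0] > 0)
    ]
    if on_x.size == 0:
        raise ValueError("no bottom node on the +x axis to pin rotation")
    spinner = on_x[int(np.argmax(mesh.nodes[on_x, 0]))]
    fixed += [3 * center, 3 * center + 1, 3 * spinner + 1]
    return np.unique(fixed)


def run_compression(
    mesh: CylinderMesh,
    params: NeoHookeParams,
    contact: ContactConfig = ContactConfig(),
    solver: SolverConfig = SolverConfig(),
) -> FEMResult:
    """Quasi-static stamp compression by Newton iteration with load stepping.

    The stamp starts touching the highest point of the top face and moves
    down in uniform increments (default L0/100), each solved by Newton
    iteration on the total-Lagrangian residual; steps that fail to converge
    or invert an element are retried with halved increments.  Returns the
    stamp travel/reaction history and the final equivalent-stress field.
    """
    ndof = 3 * mesh.n_nodes
    ref_data = _reference_gradients(mesh.nodes, mesh.hexes)
    kappa = contact.nodal_stiffness(mesh, params)
    fixed = _fixed_dofs(mesh, solver.clamp_bottom)
    free = np.setdiff1d(np.arange(ndof), fixed)
    top = mesh.top_nodes
    top_z_dofs = 3 * top + 2
    z_ref = mesh.nodes[top, 2]

    h0 = float(z_ref.max())
    step = solver.step if solver.step is not None else mesh.height / 100.0
    u = np.zeros(ndof)
    travel_hist = [0.0]
    reaction_hist = [0.0]
    log: list = []
    converged = True

    travel = 0.0
    current_step = step
    n_halved = 0
    while travel < solver.target_travel - 1e-12:
        current_step = min(current_step, solver.target_travel - travel)
        h = h0 - (travel + current_step)
        try:
            u_new, n_iter, reaction, active_ids = _newton_solve(
                u, h, mesh, params, kappa, ref_data, free, top, top_z_dofs,
                z_ref, solver,
            )
        except (NewtonError, ElementInversionError) as err:
            n_halved += 1
            if n_halved > solver.max_halvings:
                log.append({"travel": travel, "status": f"abandoned: {err}"})
                converged = False
                break
            current_step /= 2.0
            log.append({"travel": travel, "status": f"halved step: {err}"})
            continue
        u = u_new
        travel += current_step
        travel_hist.append(travel)
        reaction_hist.append(reaction)
        log.append(
            {
                "travel": travel,
                "iterations": n_iter,
                "reaction": reaction,
                "active_set": active_ids,
            }
        )
        if n_halved and current_step < step:
            current_step = min(2.0 * current_step, step)

    vm = equivalent_stress(mesh, params, u, ref_data)
    return FEMResult(
        travel=np.array(travel_hist),
        reaction=np.array(reaction_hist),
        displacement=u.reshape(-1, 3),
        von_mises=vm,
        mesh=mesh,
        converged=converged,
        log=log,
    )


def _newton_solve(
    u0, h, mesh, params, kappa, ref_data, free, top, top_z_dofs, z_ref, solver
):
    u = u0.copy()
    for it in range(solver.max_iterations):
        f_int, K = assemble(mesh, params, u, ref_data=ref_data)
        z_cur = z_ref + u[top_z_dofs]
        fc, active = apply_penalty_contact(z_cur, h, kappa)
        resid = f_int.copy()
        resid[top_z_dofs] += fc  # downward contact reaction on the body
        scale = max(float(fc.sum()), 1.0)
        rnorm = float(np.linalg.norm(resid[free]))
        if rnorm <= solver.newton_tol * scale:
            return u, it, float(fc.sum()), set(top[active].tolist())
        Kc = sparse.coo_matrix(
            (kappa[active], (top_z_dofs[active], top_z_dofs[active])),
            shape=K.shape,
        ).tocsr()
        Kt = (K + Kc)[free][:, free].tocsc()
        # symmetric-mode SuperLU is much faster on these SPD-like tangents;
        # one refinement pass recovers the accuracy a plain solve would give
        lu = splu(Kt, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
        rhs = -resid[free]
        du = lu.solve(rhs)
        du += lu.solve(rhs - Kt @ du)
        if not np.all(np.isfinite(du)):
            raise NewtonError("singular tangent system")
        u[free] += du
    raise NewtonError(
        f"no convergence in {solver.max_iterations} iterations "
        f"(residual {rnorm:.3e}, tol {solver.newton_tol * scale:.3e})"
    )


def equivalent_stress(
    mesh: CylinderMesh, params: NeoHookeParams, u: np.ndarray, ref_data=None
) -> np.ndarray:
    """Per-element von Mises Cauchy stress (Gauss-point average), MPa."""
    if ref_data is None:
        ref_data = _reference_gradients(mesh.nodes, mesh.hexes)
    grads, _ = ref_data
    ue = u.reshape(-1, 3)[mesh.hexes]
    I = np.eye(3)
    vm = np.zeros(mesh.n_elements)
    for g in range(grads.shape[0]):
        G = grads[g]
        F = I + np.einsum("eai,eaj->eij", ue, G)
        S, _, J = _stress_and_tangent(F, params)
        cauchy = np.einsum("eik,ekl,ejl->eij", F, S, F) / J[:, None, None]
        dev = cauchy - np.trace(cauchy, axis1=1, axis2=2)[:, None, None] / 3.0 * I
        vm += np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))
    return vm / grads.shape[0]


# ---------------------------------------------------------------------------
# export (legacy ASCII VTK — universally readable, text-only)


def export_vtk(
    path,
    mesh: CylinderMesh,
    displacement: np.ndarray | None = None,
    von_mises: np.ndarray | None = None,
) -> None:
    """Write mesh + fields as a legacy ASCII VTK unstructured grid."""
    from pathlib import Path

    lines = [
        "# vtk DataFile Version 3.0",
        "mycomech compression simulation",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    lines += ["8 " + " ".join(str(i) for i in h) for h in mesh.hexes]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["12"] * mesh.n_elements
    if displacement is not None:
        disp = np.asarray(displacement, float).reshape(-1, 3)
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{x:.9g}" for x in p) for p in disp]
    if von_mises is not None:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        lines.append("SCALARS von_mises_MPa double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in np.asarray(von_mises, float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_summary(path) -> dict:
    """Parse a legacy ASCII VTK file back into arrays (round-trip checks)."""
    from pathlib import Path

    tokens = Path(path).read_text().split("\n")
    out: dict = {"field_names": []}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            out["n_points"] = n
            pts = [list(map(float, tokens[i + 1 + k].split())) for k in range(n)]
            out["points"] = np.array(pts)
            i += n
        elif line.startswith("CELLS"):
            out["n_cells"] = int(line.split()[1])
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            out["field_names"].append(name)
            n = out["n_points"]
            vec = [list(map(float, tokens[i + 1 + k].split())) for k in range(n)]
            out[name] = np.array(vec)
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            out["field_names"].append(name)
            n = out["n_cells"]
            vals = [float(tokens[i + 2 + k]) for k in range(n)]  # skip LOOKUP_TABLE
            out[name] = np.array(vals)
            i += n + 1
        i += 1
    return out
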