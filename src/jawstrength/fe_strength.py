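"""Desk-scale linear-elastic finite-element jaw strength estimation.

A watertight jaw surface is filled with linear (constant-strain)
tetrahedra, the small-strain isotropic elasticity problem is assembled and
solved sparsely, and per-element von Mises stress summarises how hard the
bone works under a standard unit load.  The strength score is the
reciprocal of a volume-weighted stress quantile, in 1/(N mm^-2): a jaw that
develops half the stress under the same load is twice as strong.  Because
the model is linear, strength halves exactly when the applied loads double.

Units are N and mm throughout, so the Young's modulus is in MPa
(17 GPa cortical bone = 17000 MPa, Poisson ratio 0.3, homogeneous over the
whole mesh including the teeth).

Three load cases mirror the jaw datasets:

* ``dentary_bite_load``   — posterior cut-surface nodes fully fixed, unit
  downward (-y) force at the bite point (10th tooth apex);
* ``mandible_muscle_load`` — articular-region nodes fixed, bite-point node
  constrained vertically, nodal forces at the four muscle insertion regions
  along each line of action, proportional to the muscle force fractions and
  totalling 1 N;
* ``mandible_no_muscle``  — articular region fixed, unit bite-point load.

Node sets are selected by coordinate predicates in the canonical
orientation (anterior -x, occlusal +y).  These boundary conditions are this
package's own reconstruction of standard lizard-jaw FE practice and are
recorded with every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay, cKDTree
import trimesh

from .core_io import (
    DEFAULT_POISSON_RATIO,
    DEFAULT_YOUNG_MODULUS_MPA,
    DegenerateInputError,
    SurfaceMesh,
    ValidationError,
)

__all__ = [
    "TetMesh",
    "Material",
    "LoadCase",
    "FEStrengthResult",
    "tetrahedralise",
    "solve_elasticity",
    "strength_score",
    "build_load_case",
    "RigidBodyModeError",
]


class RigidBodyModeError(DegenerateInputError):
    """The constraint set leaves unconstrained rigid-body motion."""


# ---------------------------------------------------------------------------
# Point-in-mesh test (vertical ray parity, bucketed on a 2D grid)
# ---------------------------------------------------------------------------


def points_in_mesh(
    vertices: np.ndarray, faces: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Ray-parity containment test for a closed triangle mesh.

    Casts a +z ray from each query point and counts crossings; an odd count
    means inside.  Triangles are bucketed on a uniform 2D grid in the x-y
    plane so each query only tests nearby triangles.  Query coordinates are
    nudged by a sub-tolerance jitter so rays never pass exactly through
    triangle edges of axis-aligned geometry.
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=np.int64)
    P = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    tri = V[F]  # (f, 3, 3)
    scale = float(np.ptp(V, axis=0).max())
    P[:, 0] += 3.7e-8 * scale
    P[:, 1] += 6.1e-8 * scale

    lo = tri[:, :, :2].min(axis=1)
    hi = tri[:, :, :2].max(axis=1)
    cell = max(np.median(hi - lo), 1e-6 * scale)
    origin = V[:, :2].min(axis=0) - cell

    def cell_of(xy):
        return np.floor((xy - origin) / cell).astype(np.int64)

    clo, chi = cell_of(lo), cell_of(hi)
    spans = (chi - clo + 1).prod(axis=1)
    tri_ids = np.repeat(np.arange(len(F)), spans)
    # enumerate covered cells per triangle
    cells = np.empty((spans.sum(), 2), dtype=np.int64)
    pos = 0
    for f in range(len(F)):
        xs = np.arange(clo[f, 0], chi[f, 0] + 1)
        ys = np.arange(clo[f, 1], chi[f, 1] + 1)
        g = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
        cells[pos : pos + len(g)] = g
        pos += len(g)
    ncols = int(cells[:, 1].max() - cells[:, 1].min() + 3)
    key = cells[:, 0] * ncols + cells[:, 1]
    order = np.argsort(key, kind="stable")
    key_sorted, tri_sorted = key[order], tri_ids[order]

    pc = cell_of(P[:, :2])
    pkey = pc[:, 0] * ncols + pc[:, 1]
    starts = np.searchsorted(key_sorted, pkey, side="left")
    ends = np.searchsorted(key_sorted, pkey, side="right")
    counts = ends - starts
    q_idx = np.repeat(np.arange(len(P)), counts)
    flat = (starts[:, None] + _ragged_range(counts)).ravel()
    flat = flat[flat >= 0]
    t_idx = tri_sorted[flat]

    # 2D barycentric test + crossing height, on candidate pairs
    a, b, c = tri[t_idx, 0], tri[t_idx, 1], tri[t_idx, 2]
    p = P[q_idx]
    d1 = b[:, :2] - a[:, :2]
    d2 = c[:, :2] - a[:, :2]
    dp = p[:, :2] - a[:, :2]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    ok = np.abs(det) > 1e-14 * scale**2
    u = np.where(ok, (dp[:, 0] * d2[:, 1] - dp[:, 1] * d2[:, 0]) / np.where(ok, det, 1), -1)
    v = np.where(ok, (d1[:, 0] * dp[:, 1] - d1[:, 1] * dp[:, 0]) / np.where(ok, det, 1), -1)
    hit = (u >= 0) & (v >= 0) & (u + v <= 1)
    z = a[:, 2] + u * (b[:, 2] - a[:, 2]) + v * (c[:, 2] - a[:, 2])
    above = hit & (z > p[:, 2])
    crossings = np.zeros(len(P), dtype=np.int64)
    np.add.at(crossings, q_idx[above], 1)
    return (crossings % 2).astype(bool)


def _ragged_range(counts: np.ndarray) -> np.ndarray:
    m = counts.max() if counts.size else 0
    r = np.tile(np.arange(m), (counts.size, 1))
    return np.where(r < counts[:, None], r, -(10**9))


# ---------------------------------------------------------------------------
# Tetrahedralisation
# ---------------------------------------------------------------------------


@dataclass
class TetMesh:
    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) node indices, positively oriented

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if np.any(self.volumes() <= 0):
            raise ValidationError("tet mesh contains non-positive volumes")

    def volumes(self) -> np.ndarray:
        n = self.nodes
        t = self.tets
        a = n[t[:, 1]] - n[t[:, 0]]
        b = n[t[:, 2]] - n[t[:, 0]]
        c = n[t[:, 3]] - n[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def max_edge(self) -> float:
        n, t = self.nodes, self.tets
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return max(
            float(np.linalg.norm(n[t[:, i]] - n[t[:, j]], axis=1).max())
            for i, j in pairs
        )


def tetrahedralise(surface: SurfaceMesh, target_edge: float) -> TetMesh:
    """Fill a watertight surface with tetrahedra (characteristic edge
    ``target_edge`` mm).

    The surface is subdivided until no edge exceeds the target, a
    body-centred interior grid at the target spacing is filtered to points
    safely inside the surface, and the Delaunay tetrahedralisation of the
    combined point set is clipped to elements whose centroid lies inside the
    surface.
    """
    if target_edge <= 0:
        raise ValidationError("target_edge must be positive")
    tm = surface.to_trimesh()
    if not tm.is_watertight:
        raise ValidationError("surface must be watertight for tetrahedralisation")
    v, f = trimesh.remesh.subdivide_to_size(
        tm.vertices, tm.faces, max_edge=target_edge
    )
    refined = trimesh.Trimesh(vertices=v, faces=f, process=False)

    h = target_edge
    lo = tm.bounds[0] - 0.5 * h
    hi = tm.bounds[1] + 0.5 * h
    axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # body-centred second lattice for better tet quality
    grid = np.vstack([grid, grid + 0.5 * h])
    inside = points_in_mesh(tm.vertices, tm.faces, grid)
    grid = grid[inside]
    if grid.size:
        tree = cKDTree(refined.vertices)
        d, _ = tree.query(grid, k=1)
        grid = grid[d > 0.5 * h]

    points = np.vstack([refined.vertices, grid])
    tri = Delaunay(points)
    tets = tri.simplices
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    flip = vol < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    vol = np.abs(vol)
    keep = vol > 1e-9 * h**3
    centroids = points[tets].mean(axis=1)
    keep &= points_in_mesh(tm.vertices, tm.faces, centroids)
    tets = tets[keep]
    if tets.shape[0] == 0:
        raise DegenerateInputError("tetrahedralisation produced no elements")
    used = np.unique(tets)
    remap = -np.ones(points.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TetMesh(points[used], remap[tets])


# ---------------------------------------------------------------------------
# Elasticity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (MPa)."""

    young_modulus: float = DEFAULT_YOUNG_MODULUS_MPA
    poisson_ratio: float = DEFAULT_POISSON_RATIO

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValidationError("Young's modulus must be positive")
        if not (-1.0 < self.poisson_ratio < 0.5):
            raise ValidationError("Poisson ratio must lie in (-1, 0.5)")

    def stiffness_voigt(self) -> np.ndarray:
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.diag_indices(3)] += 2 * mu
        C[3, 3] = C[4, 4] = C[5, 5] = mu
        return C


@dataclass
class LoadCase:
    """Constraints and loads for one analysis.

    ``fixed_dofs`` maps global dof index (3*node + axis) to its prescribed
    displacement (usually zero); ``forces`` is an (n_nodes, 3) nodal force
    array in N.
    """

    name: str
    fixed_dofs: dict[int, float]
    forces: np.ndarray
    meta: dict = field(default_factory=dict)

    def validate(self, n_nodes: int) -> None:
        if len(self.fixed_dofs) < 6:
            raise RigidBodyModeError(
                f"load case {self.name!r}: fewer than 6 constrained dofs "
                "cannot remove rigid-body motion"
            )
        total = float(np.linalg.norm(np.asarray(self.forces).sum(axis=0)))
        if not np.isfinite(total):
            raise ValidationError(f"load case {self.name!r}: non-finite forces")


@dataclass
class FEStrengthResult:
    """Displacements, element von Mises stress field and bookkeeping."""

    case: str
    displacements: np.ndarray  # (n_nodes, 3) mm
    von_mises: np.ndarray  # (n_tets,) N/mm^2
    element_volumes: np.ndarray
    strain_energy: float
    external_work: float
    summary: dict = field(default_factory=dict)


def _element_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (m, 4, 3) and volumes for linear tets."""
    x0 = nodes[tets[:, 0]]
    J = np.stack(
        [nodes[tets[:, i]] - x0 for i in (1, 2, 3)], axis=2
    )  # (m, 3, 3) columns are edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    invJ = np.linalg.inv(J)
    ref = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    # gradient of N_a = invJ^T @ refgrad_a
    grads = np.einsum("mji,aj->mai", invJ, ref)
    return grads, vol


def _element_b_matrices(grads: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices (m, 6, 12); order xx,yy,zz,xy,yz,zx."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def solve_elasticity(
    mesh: TetMesh, material: Material, case: LoadCase
) -> FEStrengthResult:
    """Assemble and solve the linear tetrahedral elasticity problem.

    Returns nodal displacements and the per-element von Mises stress
    (constant within each linear element).  Strain energy and the work of
    the applied loads are reported for the equilibrium check.
    """
    case.validate(mesh.n_nodes)
    C = material.stiffness_voigt()
    grads, vol = _element_gradients(mesh.nodes, mesh.tets)
    B = _element_b_matrices(grads)
    ke = np.einsum("mia,ij,mjb,m->mab", B, C, B, vol, optimize=True)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    ).tocsr()

    f = np.asarray(case.forces, dtype=float).reshape(-1)
    if f.size != 3 * mesh.n_nodes:
        raise ValidationError("force array shape does not match the mesh")
    ndof = 3 * mesh.n_nodes
    fixed = np.fromiter(case.fixed_dofs.keys(), dtype=np.int64)
    if fixed.size and (fixed.min() < 0 or fixed.max() >= ndof):
        raise ValidationError("constraint references an invalid dof")
    vals = np.fromiter(case.fixed_dofs.values(), dtype=float)
    free = np.setdiff1d(np.arange(ndof), fixed)
    u = np.zeros(ndof)
    u[fixed] = vals
    rhs = f[free] - K[free][:, fixed] @ vals
    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as exc:
        raise RigidBodyModeError(
            f"load case {case.name!r}: singular stiffness matrix "
            f"(insufficient constraints?): {exc}"
        ) from exc
    u[free] = lu.solve(rhs)
    if not np.all(np.isfinite(u)):
        raise RigidBodyModeError(
            f"load case {case.name!r}: solution is not finite; constraints "
            "do not remove all rigid-body modes"
        )

    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    stress = np.einsum("ij,mjb,mb->mi", C, B, ue, optimize=True)
    sxx, syy, szz, sxy, syz, szx = stress.T
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    energy = 0.5 * float(u @ (K @ u))
    # external work: applied loads plus reactions acting through prescribed
    # (possibly nonzero) boundary displacements
    reactions = (K @ u - f)[fixed] if fixed.size else np.zeros(0)
    work = 0.5 * float(f @ u) + 0.5 * float(reactions @ vals)
    return FEStrengthResult(
        case=case.name,
        displacements=u.reshape(-1, 3),
        von_mises=vm,
        element_volumes=vol,
        strain_energy=energy,
        external_work=work,
        summary={"material": material, "n_tets": mesh.n_tets},
    )


def strength_score(result: FEStrengthResult, quantile: float = 0.5) -> float:
    """Strength = 1 / (volume-weighted quantile of element von Mises stress),
    in 1/(N mm^-2) under the case's standard load."""
    if not (0 < quantile < 1):
        raise ValidationError("quantile must lie in (0, 1)")
    vm = result.von_mises
    if vm.size == 0 or float(vm.max()) <= 0:
        raise DegenerateInputError("zero stress field; strength undefined")
    order = np.argsort(vm)
    cumvol = np.cumsum(result.element_volumes[order])
    idx = int(np.searchsorted(cumvol, quantile * cumvol[-1]))
    sigma = float(vm[order][min(idx, vm.size - 1)])
    result.summary["quantile"] = quantile
    result.summary["sigma_summary"] = sigma
    return 1.0 / sigma


# ---------------------------------------------------------------------------
# Load-case construction for jaw geometries
# ---------------------------------------------------------------------------

CASES = ("dentary_bite_load", "mandible_muscle_load", "mandible_no_muscle")


def _nearest_node(nodes: np.ndarray, point: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(nodes - np.asarray(point), axis=1)))


def build_load_case(
    case: str,
    mesh: TetMesh,
    bite_point: np.ndarray,
    muscles=None,
    bite_force: float = 1.0,
    total_muscle_force: float = 1.0,
    support_fraction: float = 0.08,
) -> LoadCase:
    """Construct one of the three standard jaw load cases.

    The jaw must be in canonical orientation (anterior -x, occlusal +y).
    The support region (posterior cut surface for the dentary, articular
    region for the mandible) is the set of nodes within
    ``support_fraction`` of the jaw length from the posterior extreme.
    """
    if case not in CASES:
        raise ValidationError(f"unknown load case {case!r}")
    nodes = mesh.nodes
    length = nodes[:, 0].max() - nodes[:, 0].min()
    post = nodes[:, 0] >= nodes[:, 0].max() - support_fraction * length
    support = np.where(post)[0]
    if support.size < 3:
        raise DegenerateInputError("support region selected fewer than 3 nodes")
    fixed: dict[int, float] = {}
    for n in support:
        for ax in range(3):
            fixed[3 * n + ax] = 0.0
    forces = np.zeros_like(nodes)
    bite_node = _nearest_node(nodes, bite_point)
    meta = {"support_nodes": support.size, "bite_node": bite_node}

    if case == "dentary_bite_load" or case == "mandible_no_muscle":
        forces[bite_node, 1] = -bite_force
    else:  # mandible_muscle_load
        if not muscles:
            raise ValidationError("mandible_muscle_load requires a muscle model")
        # bite point reacts vertically against the food item
        fixed[3 * bite_node + 1] = 0.0
        radius = 0.05 * length
        for m in muscles:
            d = np.linalg.norm(nodes - m.insertion, axis=1)
            region = np.where(d <= radius)[0]
            if region.size == 0:
                region = np.array([_nearest_node(nodes, m.insertion)])
            fvec = m.line_of_action * (total_muscle_force * m.force_proportion)
            forces[region] += fvec / region.size
            meta[f"nodes_{m.name}"] = region.size
    return LoadCase(case, fixed, forces, meta)
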