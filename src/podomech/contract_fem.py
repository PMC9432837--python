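"""Eigenstrain finite-element model of a contracting cell process.

A podocyte cell process is idealised as half of a cylinder capped by a
quarter of a sphere (radius 4 um) bonded to an elastic hydrogel slab
(100 x 100 x 10 um, base fixed, sides traction-free).  Contraction of the
actomyosin network is modelled as an anisotropic stress-free eigenstrain
prescribed in the cell volume — by default 10% along the process axis (x),
8% laterally (y) and 2% vertically (z), scalable by a contraction level —
resisted by the elastic stresses it induces in cell and substrate.  Both
materials are isotropic linear-elastic (cell 1.0 kPa, nu = 0.3; substrate
0.2-6.0 kPa or rigid).

Discretisation is a structured trilinear hexahedral (voxel) mesh, graded
away from the cell, assembled and solved with scipy.sparse.  Two mirror
symmetries (the open end of the process at x = 0 and the midplane y = 0)
reduce the computation to a quarter model.  Small-strain kinematics make
every output exactly linear in the contraction level, which the tests
exploit.

Units: lengths in microns, moduli and stresses in kPa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# Voigt order [xx, yy, zz, yz, xz, xy] with engineering shear strains
_VOIGT_XZ = 4

# corner offsets of the 8-node hex in (i, j, k) grid steps
_HEX_CORNERS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)])
_XI = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)], dtype=float)

MAT_SUBSTRATE, MAT_CELL = 0, 1


class SolverError(RuntimeError):
    """The linear system could not be solved (e.g. unconstrained model)."""


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------

@dataclass
class ContractionModel:
    """Geometry, moduli and eigenstrain level of the contraction model.

    ``substrate_modulus`` may be a positive modulus in kPa, the string
    ``"rigid"`` (glass: interface displacements fixed, no substrate mesh)
    or None (free-floating cell, used for patch tests).  ``eigenstrain``
    is the full-contraction stress-free strain; the applied eigenstrain is
    ``contraction_level * eigenstrain``.  ``mesh_resolution`` is the number
    of elements across the cell radius.
    """

    cell_modulus: float = 1.0
    cell_poisson: float = 0.3
    substrate_modulus: float | str | None = 0.9
    substrate_poisson: float = 0.3
    cell_radius: float = 4.0
    cell_length: float = 16.0            # cylindrical portion; footprint 20 um
    substrate_size: tuple = (100.0, 100.0)
    substrate_thickness: float = 10.0
    eigenstrain: tuple = (-0.10, -0.08, -0.02)
    contraction_level: float = 1.0
    mesh_resolution: int = 4

    def __post_init__(self) -> None:
        if self.cell_modulus <= 0:
            raise ValueError("cell modulus must be positive")
        if isinstance(self.substrate_modulus, str):
            if self.substrate_modulus != "rigid":
                raise ValueError("substrate_modulus must be a number, "
                                 "'rigid', or None")
        elif self.substrate_modulus is not None:
            if self.substrate_modulus <= 0:
                raise ValueError("substrate modulus must be positive")
        for nu in (self.cell_poisson, self.substrate_poisson):
            if not (0.0 < nu < 0.5):
                raise ValueError("Poisson ratio must be in (0, 0.5)")
        if max(abs(e) for e in self.eigenstrain) >= 0.5:
            raise ValueError("|eigenstrain| must be < 0.5")
        if self.cell_length < self.cell_radius:
            raise ValueError("degenerate geometry: cell_length < cell_radius")
        if self.mesh_resolution < 3:
            raise ValueError("need at least 3 elements across the radius")

    @property
    def footprint_length(self) -> float:
        """Half-length of the footprint in the quarter model (um)."""
        return self.cell_length + self.cell_radius

    def applied_eigenstrain(self) -> np.ndarray:
        ev = np.zeros(6)
        ev[:3] = self.contraction_level * np.asarray(self.eigenstrain)
        return ev

    def to_json(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["substrate_size"] = list(self.substrate_size)
        d["eigenstrain"] = list(self.eigenstrain)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ContractionModel":
        with open(path) as fh:
            d = json.load(fh)
        d["substrate_size"] = tuple(d["substrate_size"])
        d["eigenstrain"] = tuple(d["eigenstrain"])
        return cls(**d)


@dataclass
class HexMesh:
    """Structured, graded voxel mesh of the quarter model."""

    nodes: np.ndarray                 # (N, 3) um
    elements: np.ndarray              # (E, 8) node indices
    material: np.ndarray              # (E,) MAT_SUBSTRATE / MAT_CELL
    elem_dims: np.ndarray             # (E, 3) box edge lengths
    elem_centers: np.ndarray          # (E, 3)
    h: float                          # fine spacing (um)
    volume_fraction: np.ndarray = None  # (E,) cell-material fill fraction
    quality: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def _graded_steps(span: float, h0: float, ratio: float = 1.6) -> np.ndarray:
    """Monotone increasing steps covering ``span`` starting near h0."""
    steps, total, h = [], 0.0, h0
    while total < span - 1e-9:
        h_next = min(h, span - total)
        steps.append(h_next)
        total += h_next
        h *= ratio
    # rescale so the steps sum exactly to span
    steps = np.asarray(steps)
    return steps * (span / steps.sum())


def _axis_coords(fine_extent: float, total_extent: float, h: float):
    n_fine = int(round(fine_extent / h))
    fine = np.arange(n_fine + 1) * h
    if total_extent > fine[-1] + 1e-9:
        coarse = fine[-1] + np.cumsum(
            _graded_steps(total_extent - fine[-1], 1.5 * h))
        return np.concatenate([fine, coarse])
    return fine


def build_mesh(model: ContractionModel) -> HexMesh:
    """Conforming voxel mesh of cell (+ substrate) in the quarter domain.

    The cell region (z > 0) and substrate slab (z < 0) share the grid's
    interface nodes at z = 0, so bonding is perfect by construction.  An
    element belongs to the cell iff its centroid lies inside the
    half-cylinder/quarter-sphere shape; z > 0 elements outside the cell are
    void.  The fine spacing is cell_radius / mesh_resolution near the cell,
    grading geometrically toward the remote substrate boundaries.
    """
    R, L = model.cell_radius, model.cell_length
    h = R / model.mesh_resolution
    half_x = model.substrate_size[0] / 2.0
    half_y = model.substrate_size[1] / 2.0
    if model.footprint_length + h > half_x or R + h > half_y:
        raise ValueError("substrate too small for the cell footprint")

    with_substrate = model.substrate_modulus is not None and \
        model.substrate_modulus != "rigid"

    xs = _axis_coords(min(half_x, L + R + 2 * h), half_x, h)
    ys = _axis_coords(min(half_y, R + 2 * h), half_y, h)
    z_cell = np.arange(int(round(R / h)) + 1) * h
    if with_substrate:
        n_top = 2                                 # fine layers below interface
        z_down = np.concatenate([
            np.arange(1, n_top + 1) * h,
            n_top * h + np.cumsum(_graded_steps(
                model.substrate_thickness - n_top * h, 1.5 * h))])
        zs = np.concatenate([-z_down[::-1], z_cell])
    else:
        xs = xs[xs <= L + R + 2 * h + 1e-9]
        ys = ys[ys <= R + 2 * h + 1e-9]
        zs = z_cell

    nx, ny, nz = len(xs), len(ys), len(zs)
    node_id = -np.ones((nx, ny, nz), dtype=int)

    # sub-sampled cell-material volume fraction of a box (cut-cell scheme:
    # boundary elements carry fractional stiffness/eigenstrain, smoothing
    # the voxel representation of the curved cell surface)
    q = (np.arange(4) + 0.5) / 4.0
    qx, qy, qz = np.meshgrid(q, q, q, indexing="ij")
    q_off = np.column_stack([qx.ravel(), qy.ravel(), qz.ravel()])

    def cell_fraction(x0, x1, y0, y1, z0, z1) -> float:
        pts = q_off * [x1 - x0, y1 - y0, z1 - z0] + [x0, y0, z0]
        cyl = (pts[:, 0] <= L) & (pts[:, 1] ** 2 + pts[:, 2] ** 2 <= R * R)
        cap = (pts[:, 0] > L) & ((pts[:, 0] - L) ** 2 + pts[:, 1] ** 2
                                 + pts[:, 2] ** 2 <= R * R)
        return float(np.mean(cyl | cap))

    elems, mats, dims, centers, fracs = [], [], [], [], []
    for k in range(nz - 1):
        zc = 0.5 * (zs[k] + zs[k + 1])
        for j in range(ny - 1):
            yc = 0.5 * (ys[j] + ys[j + 1])
            for i in range(nx - 1):
                xc = 0.5 * (xs[i] + xs[i + 1])
                if zc < 0:
                    mat = MAT_SUBSTRATE
                    frac = 1.0
                else:
                    frac = cell_fraction(xs[i], xs[i + 1], ys[j], ys[j + 1],
                                         zs[k], zs[k + 1])
                    if frac <= 0.0:
                        continue
                    mat = MAT_CELL
                corner_ids = []
                for di, dj, dk in _HEX_CORNERS:
                    ii, jj, kk = i + di, j + dj, k + dk
                    if node_id[ii, jj, kk] < 0:
                        node_id[ii, jj, kk] = -2   # mark used
                    corner_ids.append((ii, jj, kk))
                elems.append(corner_ids)
                mats.append(mat)
                fracs.append(frac)
                dims.append((xs[i + 1] - xs[i], ys[j + 1] - ys[j],
                             zs[k + 1] - zs[k]))
                centers.append((xc, yc, zc))

    used = np.argwhere(node_id == -2)
    for n, (ii, jj, kk) in enumerate(used):
        node_id[ii, jj, kk] = n
    nodes = np.column_stack([xs[used[:, 0]], ys[used[:, 1]], zs[used[:, 2]]])
    elements = np.array([[node_id[ii, jj, kk] for ii, jj, kk in e]
                         for e in elems], dtype=int)
    dims = np.asarray(dims)
    mats = np.asarray(mats)
    aspect = dims.max(axis=1) / dims.min(axis=1)
    quality = {
        "n_nodes": len(nodes),
        "n_elements": len(elements),
        "n_cell_elements": int((mats == MAT_CELL).sum()),
        "n_substrate_elements": int((mats == MAT_SUBSTRATE).sum()),
        "n_interface_nodes": int(np.sum(np.abs(nodes[:, 2]) < 1e-12)),
        "max_aspect_ratio": float(aspect.max()),
        "fine_spacing_um": h,
    }
    return HexMesh(nodes=nodes, elements=elements, material=mats,
                   elem_dims=dims, elem_centers=np.asarray(centers),
                   h=h, volume_fraction=np.asarray(fracs), quality=quality)


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _elastic_moduli(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def _hex_B(dims, xi) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) of a box hex at local point xi."""
    dx, dy, dz = dims
    scale = np.array([2.0 / dx, 2.0 / dy, 2.0 / dz])
    dN = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        dN[a, 0] = 0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2])
        dN[a, 1] = 0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2])
        dN[a, 2] = 0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1])
    dN *= scale
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c] = dN[a, 0]
        B[1, c + 1] = dN[a, 1]
        B[2, c + 2] = dN[a, 2]
        B[3, c + 1] = dN[a, 2]; B[3, c + 2] = dN[a, 1]   # yz
        B[4, c] = dN[a, 2];     B[4, c + 2] = dN[a, 0]   # xz
        B[5, c] = dN[a, 1];     B[5, c + 1] = dN[a, 0]   # xy
    return B


_GP = np.array([[sx / np.sqrt(3), sy / np.sqrt(3), sz / np.sqrt(3)]
                for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])


def _element_matrices(dims, D, sigma_star=None):
    """Stiffness (24x24), eigenstrain load (24,), center B (6x24)."""
    detJ = dims[0] * dims[1] * dims[2] / 8.0
    Ke = np.zeros((24, 24))
    fe = np.zeros(24)
    for xi in _GP:
        B = _hex_B(dims, xi)
        Ke += B.T @ D @ B * detJ
        if sigma_star is not None:
            fe += B.T @ sigma_star * detJ
    B0 = _hex_B(dims, np.zeros(3))
    return Ke, fe, B0


# ---------------------------------------------------------------------------
# solution
# ---------------------------------------------------------------------------

@dataclass
class FieldSolution:
    """Displacements, element Cauchy stresses, and derived summaries."""

    model: ContractionModel
    mesh: HexMesh
    displacements: np.ndarray          # (N, 3) um
    element_stress: np.ndarray         # (E, 6) kPa, Voigt
    equilibrium_residual: float        # |K u - f| / |f| over free dofs
    reaction_imbalance: np.ndarray     # net reaction force components, kPa*um^2

    @property
    def _has_substrate(self) -> bool:
        return bool((self.mesh.material == MAT_SUBSTRATE).any())

    def stress_at(self, points: np.ndarray, smoothing: float = 0.5,
                  material: int | None = None) -> np.ndarray:
        """Mollified Cauchy stress (Voigt, kPa) at fixed material points.

        Element-center stresses are averaged with a Gaussian kernel of
        fixed physical width ``smoothing`` (um), weighted by element
        material volume.  Because the kernel scale is physical rather than
        mesh-tied, values at fixed points converge under mesh refinement
        even though raw pointwise stresses at the bonded contact line are
        singular in linear elasticity.  ``material`` restricts the average
        to one side of the interface.
        """
        mesh = self.mesh
        sel = (np.ones(mesh.n_elements, bool) if material is None
               else mesh.material == material)
        if not sel.any():
            raise ValueError("no elements of the requested material")
        c = mesh.elem_centers[sel]
        vol = mesh.elem_dims[sel].prod(axis=1) * mesh.volume_fraction[sel]
        s = self.element_stress[sel]
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty((len(pts), 6))
        for i, p in enumerate(pts):
            w = vol * np.exp(-0.5 * np.sum((c - p) ** 2, axis=1)
                             / smoothing**2)
            out[i] = (w @ s) / w.sum()
        return out

    def max_principal_cauchy(self, smoothing: float = 0.5,
                             sample_step: float = 0.5) -> float:
        """Largest principal Cauchy stress (kPa) in the cell.

        The mollified stress is sampled on a fixed grid of cell-interior
        points (eroded from the lateral surface by ``0.4`` um so the kernel
        stays centred in cell material) and the maximum eigenvalue over the
        grid is returned.
        """
        model = self.model
        R, L = model.cell_radius, model.cell_length
        margin = 0.4
        xs = np.arange(0.0, L + R - margin + 1e-9, sample_step)
        ys = np.arange(0.0, R - margin + 1e-9, sample_step)
        zs = np.arange(0.25, R - margin + 1e-9, sample_step)
        pts = []
        for x in xs:
            ax = 0.0 if x <= L else x - L
            for y in ys:
                for z in zs:
                    if ax * ax + y * y + z * z <= (R - margin) ** 2:
                        pts.append((x, y, z))
        sv = self.stress_at(np.asarray(pts), smoothing=smoothing,
                            material=MAT_CELL)
        T = np.zeros((len(sv), 3, 3))
        T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = sv[:, 0], sv[:, 1], sv[:, 2]
        T[:, 1, 2] = T[:, 2, 1] = sv[:, 3]
        T[:, 0, 2] = T[:, 2, 0] = sv[:, 4]
        T[:, 0, 1] = T[:, 1, 0] = sv[:, 5]
        return float(np.linalg.eigvalsh(T)[:, 2].max())

    def interface_shear_at(self, points_xy: np.ndarray,
                           depth: float = 0.5,
                           smoothing: float = 0.5) -> np.ndarray:
        """Interfacial shear sigma_zx (kPa) at xy points near the z=0 plane.

        Evaluated at a fixed shallow depth below the interface in the
        substrate (or, for a rigid substrate, just above it in the cell),
        where the field is regular; mollified per ``stress_at``.
        """
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        # y -> -y mirror symmetry: evaluate at |y|
        xy = np.column_stack([np.abs(pts[:, 0]), np.abs(pts[:, 1])])
        if self._has_substrate:
            z = -abs(depth)
            material = MAT_SUBSTRATE
        else:
            z = abs(depth)
            material = MAT_CELL
        p3 = np.column_stack([xy, np.full(len(xy), z)])
        return self.stress_at(p3, smoothing=smoothing,
                              material=material)[:, _VOIGT_XZ]

    def peak_interface_shear(self, smoothing: float = 0.5,
                             sample_step: float = 0.25):
        """Peak |sigma_zx| (kPa) over the cell footprint and its location.

        The interfacial shear field is sampled on a fixed grid over the
        footprint (extended by half a kernel width on an elastic substrate,
        where the field continues smoothly past the contact line); returns
        ``(peak, (x, y))``.
        """
        model = self.model
        R, L = model.cell_radius, model.cell_length
        margin = 0.5 * smoothing if self._has_substrate else -0.25
        xs = np.arange(0.0, L + R + margin + 1e-9, sample_step)
        ys = np.arange(0.0, R + margin + 1e-9, sample_step)
        pts = []
        for x in xs:
            ax = 0.0 if x <= L else x - L
            for y in ys:
                if np.hypot(ax, y) <= R + margin:
                    pts.append((x, y))
        pts = np.asarray(pts)
        vals = self.interface_shear_at(pts, smoothing=smoothing)
        k = int(np.argmax(np.abs(vals)))
        return float(np.abs(vals[k])), (float(pts[k, 0]), float(pts[k, 1]))


def solve_contraction(model: ContractionModel,
                      mesh: HexMesh | None = None) -> FieldSolution:
    """Solve small-strain elastic equilibrium with eigenstrain in the cell.

    Boundary conditions: substrate base fully fixed, substrate sides and
    all cell surfaces traction-free, symmetry conditions on the x = 0 and
    y = 0 planes.  For ``substrate_modulus == "rigid"`` the cell's z = 0
    footprint is fixed instead; for ``substrate_modulus is None`` the cell
    floats freely (only symmetry planes plus one vertical pin), which is
    the eigenstrain patch-test configuration.
    """
    if mesh is None:
        mesh = build_mesh(model)
    nodes, elements = mesh.nodes, mesh.elements
    n_dof = 3 * len(nodes)

    D_cell = _elastic_moduli(model.cell_modulus, model.cell_poisson)
    with_substrate = model.substrate_modulus is not None and \
        model.substrate_modulus != "rigid"
    D_sub = (_elastic_moduli(model.substrate_modulus,
                             model.substrate_poisson)
             if with_substrate else None)
    sigma_star = D_cell @ model.applied_eigenstrain()

    # element dofs
    edofs = (3 * elements[:, :, None]
             + np.arange(3)[None, None, :]).reshape(len(elements), 24)

    # group elements by (dims, material) so each unique box stiffness is
    # computed once
    keys = np.column_stack([np.round(mesh.elem_dims, 12), mesh.material])
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    rows, cols, vals = [], [], []
    f = np.zeros(n_dof)
    B0_by_combo, sstar_by_combo = {}, {}
    for combo in np.unique(inv):
        sel = np.flatnonzero(inv == combo)
        mat = mesh.material[sel[0]]
        dims = mesh.elem_dims[sel[0]]
        D = D_cell if mat == MAT_CELL else D_sub
        ss = sigma_star if mat == MAT_CELL else None
        Ke, fe, B0 = _element_matrices(dims, D, ss)
        B0_by_combo[combo] = B0
        sstar_by_combo[combo] = (sigma_star if mat == MAT_CELL
                                 else np.zeros(6))
        ed = edofs[sel]
        frac = mesh.volume_fraction[sel]
        rows.append(np.repeat(ed, 24, axis=1).ravel())
        cols.append(np.tile(ed, 24).ravel())
        vals.append((frac[:, None] * Ke.ravel()[None, :]).ravel())
        if ss is not None:
            np.add.at(f, ed.ravel(), (frac[:, None] * fe[None, :]).ravel())
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_dof, n_dof)).tocsr()

    # Dirichlet constraints
    fixed = np.zeros(n_dof, dtype=bool)
    tol = 1e-9
    sym_x = np.abs(nodes[:, 0]) < tol
    sym_y = np.abs(nodes[:, 1]) < tol
    fixed[3 * np.flatnonzero(sym_x)] = True          # u_x = 0 on x = 0
    fixed[3 * np.flatnonzero(sym_y) + 1] = True      # u_y = 0 on y = 0
    if with_substrate:
        base = np.abs(nodes[:, 2] + model.substrate_thickness) < tol
        for c in range(3):
            fixed[3 * np.flatnonzero(base) + c] = True
    elif model.substrate_modulus == "rigid":
        foot = np.abs(nodes[:, 2]) < tol
        for c in range(3):
            fixed[3 * np.flatnonzero(foot) + c] = True
    else:
        # free-floating patch-test configuration: pin vertical motion of
        # the node at the origin (last remaining rigid-body mode)
        origin = int(np.argmin(np.linalg.norm(nodes, axis=1)))
        fixed[3 * origin + 2] = True

    free = ~fixed
    if not fixed.any():
        raise SolverError("model has no constraints; system is singular")
    K_ff = K[free][:, free]
    try:
        u_free = spla.spsolve(K_ff.tocsc(), f[free])
    except RuntimeError as exc:        # pragma: no cover - singular factor
        raise SolverError(str(exc)) from exc
    if not np.isfinite(u_free).all():
        raise SolverError("singular system: non-finite solution")
    u = np.zeros(n_dof)
    u[free] = u_free

    residual_vec = K @ u - f
    f_norm = np.linalg.norm(f[free])
    residual = float(np.linalg.norm(residual_vec[free])
                     / (f_norm if f_norm > 0 else 1.0))
    reactions = residual_vec[fixed]
    fixed_idx = np.flatnonzero(fixed)
    imbalance = np.array([reactions[fixed_idx % 3 == c].sum()
                          for c in range(3)])

    # element-center Cauchy stress sigma = D (B u - eps*)
    stress = np.empty((len(elements), 6))
    for combo in B0_by_combo:
        sel = np.flatnonzero(inv == combo)
        mat = mesh.material[sel[0]]
        D = D_cell if mat == MAT_CELL else D_sub
        strains = u[edofs[sel]] @ B0_by_combo[combo].T
        eps_star = (model.applied_eigenstrain()
                    if mat == MAT_CELL else np.zeros(6))
        stress[sel] = (strains - eps_star) @ D.T

    return FieldSolution(model=model, mesh=mesh,
                         displacements=u.reshape(-1, 3),
                         element_stress=stress,
                         equilibrium_residual=residual,
                         reaction_imbalance=imbalance)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def footprint_half_width(model: ContractionModel, x: float) -> float:
    """Half-width of the cell footprint at axial position x (um)."""
    x = abs(x)
    R, L = model.cell_radius, model.cell_length
    if x <= L:
        return R
    if x <= L + R:
        return float(np.sqrt(max(R * R - (x - L) ** 2, 0.0)))
    raise ValueError(f"x = {x} um outside the cell footprint")


def interface_shear_profile(solution: FieldSolution,
                            x_position: float | None = None) -> pd.DataFrame:
    """Interfacial shear sigma_zx vs y at a fixed axial position.

    The mollified interface field (see ``FieldSolution.interface_shear_at``)
    is sampled on a fixed fine y-grid spanning the footprint width at
    ``x_position`` (default: mid-length of the cylindrical portion).
    By the model's y -> -y mirror symmetry sigma_zx is an even function of
    y.  Returns columns ``y_um`` and ``sigma_zx_kpa``.
    """
    model = solution.model
    if x_position is None:
        x_position = model.cell_length / 2.0
    half_w = footprint_half_width(model, x_position)   # bounds check
    y_half = np.arange(0.0, half_w + 1e-9, 0.1)
    s_half = solution.interface_shear_at(
        np.column_stack([np.full_like(y_half, abs(x_position)), y_half]))
    y_full = np.concatenate([-y_half[:0:-1], y_half])
    s_full = np.concatenate([s_half[:0:-1], s_half])
    df = pd.DataFrame({"y_um": y_full, "sigma_zx_kpa": s_full})
    df.attrs["x_position_um"] = float(abs(x_position))
    return df


def cell_width_change(solution: FieldSolution) -> float:
    """Signed lateral width change of the cell midsection (um).

    Twice the lateral (y) displacement of the footprint-edge node at the
    mid-length of the cylindrical portion (negative = narrowing).
    """
    model = solution.model
    nodes = solution.mesh.nodes
    target = np.array([model.cell_length / 2.0, model.cell_radius, 0.0])
    node = int(np.argmin(np.linalg.norm(nodes - target, axis=1)))
    return float(2.0 * solution.displacements[node, 1])


def stiffness_sweep(moduli, levels, model: ContractionModel | None = None,
                    mesh_resolution: int | None = None) -> pd.DataFrame:
    """Solve the model over substrate moduli x contraction levels.

    Returns one row per combination with the peak interfacial shear, the
    maximum principal Cauchy stress in the cell, and the width change.
    Monotonicity of the stress measures in the substrate modulus (at each
    level) is recorded in ``DataFrame.attrs["monotone_in_modulus"]``.
    """
    moduli = list(moduli)
    levels = list(levels)
    if not moduli or not levels:
        raise ValueError("moduli and levels must be non-empty")
    if model is None:
        model = ContractionModel()
    if mesh_resolution is not None:
        model = replace(model, mesh_resolution=mesh_resolution)

    rows = []
    for Es in moduli:
        m = replace(model, substrate_modulus=Es)
        mesh = build_mesh(m)
        for lvl in levels:
            sol = solve_contraction(replace(m, contraction_level=lvl), mesh)
            peak, (px, py) = sol.peak_interface_shear()
            rows.append({
                "substrate_modulus_kpa": Es,
                "contraction_level": lvl,
                "max_abs_sigma_zx_kpa": peak,
                "peak_shear_x_um": px,
                "peak_shear_y_um": py,
                "max_principal_cauchy_kpa": sol.max_principal_cauchy(),
                "cell_width_change_um": cell_width_change(sol),
            })
    table = pd.DataFrame(rows)
    flags = {}
    numeric = [m for m in moduli if not isinstance(m, str)]
    for lvl in levels:
        sub = table[(table.contraction_level == lvl)
                    & table.substrate_modulus_kpa.isin(numeric)]
        sub = sub.sort_values("substrate_modulus_kpa")
        flags[lvl] = {
            "sigma_zx_increasing": bool(
                np.all(np.diff(sub.max_abs_sigma_zx_kpa) > 0)),
            "principal_increasing": bool(
                np.all(np.diff(sub.max_principal_cauchy_kpa) > 0)),
        }
    table.attrs["monotone_in_modulus"] = flags
    return table


def export_vtk(solution: FieldSolution, path) -> None:
    """Write the mesh, displacements and stresses as a legacy-ASCII VTK file."""
    mesh = solution.mesh
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n"
                 "podomech contraction solution\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        for e in mesh.elements:
            fh.write("8 " + " ".join(map(str, e)) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["12"] * mesh.n_elements) + "\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n"
                 "VECTORS displacement float\n")
        for u in solution.displacements:
            fh.write(f"{u[0]:.6g} {u[1]:.6g} {u[2]:.6g}\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n"
                 "SCALARS sigma_zx float 1\nLOOKUP_TABLE default\n")
        for s in solution.element_stress[:, _VOIGT_XZ]:
            fh.write(f"{s:.6g}\n")
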