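"""Shared finite-element kernels (internal).

Lowest-order simplicial elements assembled with vectorized numpy:

* P1 (continuous piecewise linear) for the drug concentration — mass,
  stiffness, convection and boundary (Robin) matrices;
* RT0 (lowest-order Raviart–Thomas, flux-normalized facet DOFs) together
  with P0 pressures for the mixed Darcy system.

Everything is weighted so the same kernels serve the full 3d mesh (weight
1) and the axisymmetric full-profile-disk mesh (weight pi*|rho|, rho the
signed distance to the optic axis; each profile half contributes half a
revolution).  An axisymmetric meridional field has the extra divergence
term u_rho / rho which is folded into the weighted divergence matrix.

All geometry enters in SI metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh

# -- quadrature -------------------------------------------------------------

# degree-2 rule on the reference tetrahedron (4 points)
_A = 0.5854101966249685
_B = 0.1381966011250105
TET_QP = np.array([
    [_B, _B, _B], [_A, _B, _B], [_B, _A, _B], [_B, _B, _A],
])
TET_QW = np.full(4, 0.25)

# degree-4 rule on the reference triangle (6 points)
_P1 = 0.0915762135097707
_P2 = 0.4459484909159649
TRI_QP = np.array([
    [_P1, _P1], [1 - 2 * _P1, _P1], [_P1, 1 - 2 * _P1],
    [_P2, _P2], [1 - 2 * _P2, _P2], [_P2, 1 - 2 * _P2],
])
TRI_QW = np.array([0.1099517436553219] * 3 + [0.2233815896780115] * 3)

# 3-point Gauss on [0, 1] (degree 5) for boundary edges
EDGE_QP = 0.5 + np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)]) / 2.0
EDGE_QW = np.array([5.0, 8.0, 5.0]) / 18.0

# degree-2 rule on a boundary triangle (3 midedge points)
BTRI_QP = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])
BTRI_QW = np.full(3, 1.0 / 3.0)


def _ref_qp(dim: int) -> tuple[np.ndarray, np.ndarray]:
    return (TET_QP, TET_QW) if dim == 3 else (TRI_QP, TRI_QW)


def p1_basis_at(qp: np.ndarray) -> np.ndarray:
    """P1 barycentric basis values at reference points, shape (nq, dim+1)."""
    lam0 = 1.0 - qp.sum(axis=1)
    return np.column_stack([lam0, *qp.T])


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell geometric factors shared by all assemblies (SI units)."""

    verts: np.ndarray          # (nc, dim+1, dim) cell vertex coordinates, m
    vols: np.ndarray           # (nc,) simplex measures, m^dim
    grads: np.ndarray          # (nc, dim+1, dim) constant P1 gradients, 1/m
    qpoints: np.ndarray        # (nc, nq, dim) physical quadrature points
    qweights: np.ndarray       # (nc, nq) physical weights incl. axisym 2*pi*rho
    axisym: bool

    @property
    def nq(self) -> int:
        return self.qpoints.shape[1]


def cell_geometry(mesh: Mesh) -> CellGeometry:
    dim = mesh.dim
    verts = mesh.vertices_m[mesh.cells]                  # (nc, dim+1, dim)
    e = verts[:, 1:, :] - verts[:, :1, :]                # (nc, dim, dim)
    if dim == 3:
        vols = np.einsum("nij,nij->n",
                         e[:, 0:1, :],
                         np.cross(e[:, 1, :], e[:, 2, :])[:, None, :]) / 6.0
    else:
        vols = 0.5 * (e[:, 0, 0] * e[:, 1, 1] - e[:, 0, 1] * e[:, 1, 0])
    einv = np.linalg.inv(e)                              # (nc, dim, dim)
    gr = np.transpose(einv, (0, 2, 1))                   # rows: grad lam_{1..dim}
    grads = np.concatenate([-gr.sum(axis=1, keepdims=True), gr], axis=1)
    qp, qw = _ref_qp(dim)
    lam = p1_basis_at(qp)                                # (nq, dim+1)
    qpoints = np.einsum("qi,nid->nqd", lam, verts)
    qweights = np.abs(vols)[:, None] * qw[None, :]
    axisym = mesh.mode == "axisymmetric-2d"
    if axisym:
        qweights = qweights * (np.pi * np.abs(qpoints[:, :, 1]))
    return CellGeometry(verts=verts, vols=vols, grads=grads,
                        qpoints=qpoints, qweights=qweights, axisym=axisym)


def _scatter(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Assemble per-cell dense blocks (nc, nl, nl) into a global CSR matrix."""
    cells = mesh.cells
    nl = cells.shape[1]
    rows = np.repeat(cells, nl, axis=1).ravel()
    cols = np.tile(cells, (1, nl)).ravel()
    mat = sp.coo_matrix((local.ravel(), (rows, cols)),
                        shape=(mesh.n_vertices, mesh.n_vertices))
    return mat.tocsr()


# -- P1 operators -----------------------------------------------------------

def p1_mass(mesh: Mesh, geo: CellGeometry) -> sp.csr_matrix:
    qp, _ = _ref_qp(mesh.dim)
    lam = p1_basis_at(qp)                                # (nq, nl)
    local = np.einsum("nq,qi,qj->nij", geo.qweights, lam, lam)
    return _scatter(mesh, local)


def p1_lumped_mass(mesh: Mesh, geo: CellGeometry) -> np.ndarray:
    qp, _ = _ref_qp(mesh.dim)
    lam = p1_basis_at(qp)
    local = np.einsum("nq,qi->ni", geo.qweights, lam)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.cells.ravel(), local.ravel())
    return out


def p1_stiffness(mesh: Mesh, geo: CellGeometry, diffusivity) -> sp.csr_matrix:
    """int D grad(u) . grad(v) (weighted); ``diffusivity`` is a scalar or an
    SPD (dim x dim) tensor in m^2/s."""
    D = np.asarray(diffusivity, dtype=float)
    if D.ndim == 0:
        Dg = D * geo.grads
    else:
        if D.shape != (mesh.dim, mesh.dim):
            raise ValueError(f"diffusion tensor must be {mesh.dim}x{mesh.dim}")
        if (abs(D - D.T).max() > 1e-12 * abs(D).max()
                or np.any(np.linalg.eigvalsh(D) <= 0)):
            raise ValueError("diffusion tensor must be symmetric positive definite")
        Dg = np.einsum("de,nie->nid", D, geo.grads)
    w = geo.qweights.sum(axis=1)                         # int of weight over cell
    local = np.einsum("n,nid,njd->nij", w, Dg, geo.grads)
    return _scatter(mesh, local)


def p1_convection(mesh: Mesh, geo: CellGeometry,
                  vel_at_qp: np.ndarray) -> sp.csr_matrix:
    """int (v . grad(u)) w (weighted); ``vel_at_qp`` has shape (nc, nq, dim)."""
    qp, _ = _ref_qp(mesh.dim)
    lam = p1_basis_at(qp)
    vdotg = np.einsum("nqd,njd->nqj", vel_at_qp, geo.grads)
    local = np.einsum("nq,qi,nqj->nij", geo.qweights, lam, vdotg)
    return _scatter(mesh, local)


def p1_load(mesh: Mesh, geo: CellGeometry, f_at_qp: np.ndarray) -> np.ndarray:
    """Load vector int f phi_i (weighted); ``f_at_qp`` shape (nc, nq)."""
    qp, _ = _ref_qp(mesh.dim)
    lam = p1_basis_at(qp)
    local = np.einsum("nq,nq,qi->ni", geo.qweights, f_at_qp, lam)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.cells.ravel(), local.ravel())
    return out


def integrate_p1(mesh: Mesh, geo: CellGeometry, nodal: np.ndarray) -> float:
    """Exact integral of a P1 field (weighted measure)."""
    qp, _ = _ref_qp(mesh.dim)
    lam = p1_basis_at(qp)
    vals = np.einsum("qi,ni->nq", lam, nodal[mesh.cells])
    return float(np.sum(geo.qweights * vals))


# -- boundary (facet) machinery --------------------------------------------

@dataclass(frozen=True)
class FacetGeometry:
    """Quadrature data on a set of boundary facets (SI units).

    ``qpoints`` (nf, nq, dim) physical points; ``qweights`` (nf, nq) include
    the axisymmetric revolution weight; ``normals`` (nf, dim) unit outward
    normals; ``lam`` (nq, dim) P1 trace basis values at the facet points.
    """

    facets: np.ndarray
    qpoints: np.ndarray
    qweights: np.ndarray
    normals: np.ndarray
    areas: np.ndarray          # facet measure: m^2 (3d) / m (2d, unweighted)
    wareas: np.ndarray         # weighted measure: m^2 incl. 2*pi*rho in 2d
    lam: np.ndarray


def facet_geometry(mesh: Mesh, facets: np.ndarray) -> FacetGeometry:
    verts = mesh.vertices_m[facets]                      # (nf, dim, dim)
    centers_all = mesh.vertices_m[mesh.cells].mean(axis=1)
    # owner cell for orientation: match facet to the unique cell containing it
    owner = _facet_owner(mesh, facets)
    cellc = centers_all[owner]
    if mesh.dim == 3:
        t1 = verts[:, 1] - verts[:, 0]
        t2 = verts[:, 2] - verts[:, 0]
        nvec = np.cross(t1, t2)
        areas = 0.5 * np.linalg.norm(nvec, axis=1)
        normals = nvec / np.linalg.norm(nvec, axis=1)[:, None]
        lam = np.column_stack([1 - BTRI_QP.sum(axis=1), *BTRI_QP.T])
        qpoints = np.einsum("qi,nid->nqd", lam, verts)
        qweights = areas[:, None] * BTRI_QW[None, :]
    else:
        t1 = verts[:, 1] - verts[:, 0]
        areas = np.linalg.norm(t1, axis=1)
        normals = np.column_stack([t1[:, 1], -t1[:, 0]]) / areas[:, None]
        lam = np.column_stack([1 - EDGE_QP, EDGE_QP])
        qpoints = np.einsum("qi,nid->nqd", lam, verts)
        qweights = areas[:, None] * EDGE_QW[None, :]
    # orient outward: away from the owner cell center
    sgn = np.sign(np.einsum("nd,nd->n",
                            normals, verts.mean(axis=1) - cellc))
    sgn[sgn == 0] = 1.0
    normals = normals * sgn[:, None]
    wareas = qweights.sum(axis=1)
    if mesh.mode == "axisymmetric-2d":
        qweights = qweights * (np.pi * np.abs(qpoints[:, :, 1]))
        wareas = qweights.sum(axis=1)
    return FacetGeometry(facets=facets, qpoints=qpoints, qweights=qweights,
                         normals=normals, areas=areas, wareas=wareas, lam=lam)


def _facet_owner(mesh: Mesh, facets: np.ndarray) -> np.ndarray:
    """Index of the unique cell owning each boundary facet."""
    nl = mesh.cells.shape[1]
    if nl == 4:
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    else:
        local = [(1, 2), (2, 0), (0, 1)]
    allf = np.concatenate([mesh.cells[:, f] for f in local], axis=0)
    owner_of = np.tile(np.arange(mesh.n_cells), len(local))
    key_all = np.sort(allf, axis=1)
    key_q = np.sort(facets, axis=1)
    # dictionary via structured void view
    def _view(a):
        a = np.ascontiguousarray(a)
        return a.view([("", a.dtype)] * a.shape[1]).ravel()
    va, vq = _view(key_all), _view(key_q)
    order = np.argsort(va)
    pos = np.searchsorted(va, vq, sorter=order)
    return owner_of[order[pos]]


def facet_p1_mass(mesh: Mesh, fg: FacetGeometry,
                  coeff_at_qp: np.ndarray) -> sp.csr_matrix:
    """Boundary mass matrix int coeff * phi_i phi_j over the given facets."""
    local = np.einsum("nq,qi,qj->nij", fg.qweights * coeff_at_qp, fg.lam, fg.lam)
    nl = fg.facets.shape[1]
    rows = np.repeat(fg.facets, nl, axis=1).ravel()
    cols = np.tile(fg.facets, (1, nl)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()


def facet_p1_load(mesh: Mesh, fg: FacetGeometry,
                  g_at_qp: np.ndarray) -> np.ndarray:
    """Boundary load vector int g * phi_i over the given facets."""
    local = np.einsum("nq,qi->ni", fg.qweights * g_at_qp, fg.lam)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, fg.facets.ravel(), local.ravel())
    return out


# -- RT0 facet enumeration and operators ------------------------------------

@dataclass(frozen=True)
class RT0Space:
    """Global RT0 facet space with flux-normalized DOFs.

    ``facets`` (nf, dim) sorted vertex tuples; ``cell_facets`` (nc, dim+1)
    global facet index per local facet; ``cell_signs`` +-1, +1 when the
    global facet orientation points out of the cell; boundary facets carry
    the mesh marker in ``facet_marker`` (interior facets: -1).
    """

    facets: np.ndarray
    cell_facets: np.ndarray
    cell_signs: np.ndarray
    facet_marker: np.ndarray
    facet_area: np.ndarray          # unweighted simplex measure of the facet
    facet_warea: np.ndarray         # weighted measure (axisym: 2*pi*rho_bar*L)
    facet_center: np.ndarray
    is_boundary: np.ndarray

    @property
    def n_dofs(self) -> int:
        return len(self.facets)


def build_rt0(mesh: Mesh) -> RT0Space:
    nl = mesh.cells.shape[1]
    if nl == 4:
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    else:
        local = [(1, 2), (2, 0), (0, 1)]
    allf = np.concatenate([mesh.cells[:, f] for f in local], axis=0)
    key = np.sort(allf, axis=1)
    uniq, inverse, counts = np.unique(key, axis=0,
                                      return_inverse=True, return_counts=True)
    cell_facets = inverse.reshape(len(local), mesh.n_cells).T
    verts = mesh.vertices_m[uniq]
    if mesh.dim == 3:
        nvec = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
        area = 0.5 * np.linalg.norm(nvec, axis=1)
        gnormal = nvec / (2.0 * area)[:, None]
    else:
        t = verts[:, 1] - verts[:, 0]
        area = np.linalg.norm(t, axis=1)
        gnormal = np.column_stack([t[:, 1], -t[:, 0]]) / area[:, None]
    fcenter = verts.mean(axis=1)
    cellc = mesh.vertices_m[mesh.cells].mean(axis=1)
    out = fcenter[cell_facets] - cellc[:, None, :]
    signs = np.sign(np.einsum("nld,nld->nl", gnormal[cell_facets], out))
    signs[signs == 0] = 1.0

    is_boundary = counts == 1
    # boundary DOFs are oriented outward: force the owning cell's sign to +1
    # so a positive boundary flux always means flow leaving the domain
    signs[is_boundary[cell_facets]] = 1.0
    marker = np.full(len(uniq), -1, dtype=int)
    bkey = np.sort(mesh.boundary_facets, axis=1)

    def _view(a):
        a = np.ascontiguousarray(a)
        return a.view([("", a.dtype)] * a.shape[1]).ravel()

    vu = _view(uniq)
    vb = _view(bkey)
    order = np.argsort(vu)
    pos = np.searchsorted(vu, vb, sorter=order)
    marker[order[pos]] = mesh.facet_markers

    warea = area.copy()
    if mesh.mode == "axisymmetric-2d":
        # int over edge of pi*|rho| dl, exact for straight edges even when
        # an edge crosses the axis (piecewise-linear |rho|)
        y1, y2 = verts[:, 0, 1], verts[:, 1, 1]
        cross = y1 * y2 < 0
        mean_abs = np.where(
            cross,
            (y1**2 + y2**2) / (2.0 * np.maximum(np.abs(y2 - y1), 1e-300)),
            0.5 * (np.abs(y1) + np.abs(y2)),
        )
        warea = np.pi * mean_abs * area
    return RT0Space(facets=uniq, cell_facets=cell_facets, cell_signs=signs,
                    facet_marker=marker, facet_area=area, facet_warea=warea,
                    facet_center=fcenter, is_boundary=is_boundary)


def rt0_basis_at(mesh: Mesh, geo: CellGeometry, rt: RT0Space,
                 qp_phys: np.ndarray) -> np.ndarray:
    """RT0 basis fields at physical in-cell points.

    Returns shape (nc, nq, nl, dim): value of local basis ``l`` of cell
    ``n`` at point ``q``.  Basis ``l`` (flux-normalized over its facet):
    sigma * (x - p_l) / (dim * |K|).
    """
    dim = mesh.dim
    vols = np.abs(geo.vols)
    diff = qp_phys[:, :, None, :] - geo.verts[:, None, :, :]
    scale = (rt.cell_signs / (dim * vols[:, None]))[:, :, None]
    return diff * scale[:, None, :, :].transpose(0, 1, 2, 3)


def rt0_velocity_at(mesh: Mesh, geo: CellGeometry, rt: RT0Space,
                    flux: np.ndarray, qp_phys: np.ndarray) -> np.ndarray:
    """Evaluate the RT0 field with DOF vector ``flux`` at in-cell points."""
    basis = rt0_basis_at(mesh, geo, rt, qp_phys)
    coeff = flux[rt.cell_facets]                         # (nc, nl)
    return np.einsum("nqld,nl->nqd", basis, coeff)


def rt0_mass(mesh: Mesh, geo: CellGeometry, rt: RT0Space,
             coeff: float) -> sp.csr_matrix:
    """Velocity mass block M = int coeff * u . v (weighted), coeff = mu/kappa."""
    basis = rt0_basis_at(mesh, geo, rt, geo.qpoints)     # (nc, nq, nl, dim)
    local = coeff * np.einsum("nq,nqid,nqjd->nij", geo.qweights, basis, basis)
    nl = rt.cell_facets.shape[1]
    rows = np.repeat(rt.cell_facets, nl, axis=1).ravel()
    cols = np.tile(rt.cell_facets, (1, nl)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(rt.n_dofs, rt.n_dofs)).tocsr()


def rt0_div(mesh: Mesh, geo: CellGeometry, rt: RT0Space) -> sp.csr_matrix:
    """Divergence coupling B with B[f, K] = int_K div_w(phi_f) w dx.

    In 3d this is just the orientation sign (flux normalization).  In the
    axisymmetric profile the weighted divergence of a meridional field is
    div2(u) + u_rho/rho, integrated against the revolution weight pi*|rho|;
    u_rho = sign(rho) * u_y since the radial direction flips across the
    axis.
    """
    nl = rt.cell_facets.shape[1]
    if mesh.mode == "full-3d":
        vals = rt.cell_signs
    else:
        vols = np.abs(geo.vols)
        # term1: div2(phi) (constant sign/|K|) times the weighted cell measure
        term1 = rt.cell_signs / vols[:, None] * geo.qweights.sum(axis=1)[:, None]
        # term2: pi * int sign(rho) * phi_y dA (plain measure)
        basis = rt0_basis_at(mesh, geo, rt, geo.qpoints)  # (nc, nq, nl, 2)
        plain_w = vols[:, None] * _ref_qp(2)[1][None, :]
        sgn = np.sign(geo.qpoints[:, :, 1])
        term2 = np.pi * np.einsum("nq,nqi->ni", plain_w * sgn, basis[:, :, :, 1])
        vals = term1 + term2
    rows = rt.cell_facets.ravel()
    cols = np.repeat(np.arange(mesh.n_cells), nl)
    return sp.coo_matrix((vals.ravel(), (rows, cols)),
                         shape=(rt.n_dofs, mesh.n_cells)).tocsr()
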