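"""Patient-adaptable vitreous geometry.

The vitreous body is described by a modified Limacon profile in the plane
containing the optic axis,

    R(q, phi) = q1 + q2*cos(phi_hat) + q3*cos(phi_hat)**3,
    x = R*cos(phi) + mx,   y = R*sin(phi),

revolved about the optic (x-) axis.  ``phi_hat`` is the polar angle measured
about the Limacon center ``(mx, 0)``.  The four scalars ``(q1, q2, q3, mx)``
are fitted to ultrasound profile points by damped least squares, which is
enough to personalize the domain to a patient scan.

The boundary of the revolved solid is partitioned into three anatomical
parts: the retina (posterior, most of the surface), the impermeable lens cap
(anterior), and the hyaloid membrane annulus between them where aqueous
humor enters.  Meshes are structured: a Kuhn-subdivided cube (3d) or square
(axisymmetric profile) is mapped smoothly onto the unit ball / disk and
then radially onto the Limacon solid or its full profile disk, so
refinement is a single integer and boundary facets inherit their anatomical
marker from the profile angle.

Units: lengths are millimetres throughout this module; the PDE modules
convert to SI metres via :data:`MM`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

__all__ = [
    "MM",
    "RETINA",
    "LENS",
    "HYALOID",
    "AXIS",
    "MARKER_NAMES",
    "USPointSet",
    "LimaconParams",
    "FitResult",
    "BoundarySpec",
    "VitreousDomain",
    "Mesh",
    "limacon_radius",
    "profile_point",
    "polar_convert",
    "fit_limacon",
    "generate_synthetic_us_points",
    "build_domain",
    "build_mesh",
    "read_us_points_csv",
    "write_us_points_csv",
    "load_geometry_yaml",
    "save_geometry_yaml",
]

#: millimetre in metres; the single mm -> SI conversion point for the package.
MM = 1.0e-3

# Boundary markers (also used in VTU exports as the `boundary_id` field).
RETINA, LENS, HYALOID, AXIS = 1, 2, 3, 0
MARKER_NAMES = {RETINA: "retina", LENS: "lens", HYALOID: "hyaloid", AXIS: "axis"}


# --------------------------------------------------------------------------
# profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LimaconParams:
    """Fitted shape coefficients of the vitreous profile (mm).

    ``q1`` is the mean radius, ``q2``/``q3`` the first/third cosine
    deformations, and ``mx`` the axial offset of the Limacon center from the
    coordinate origin.  A valid parameter set has ``q1 > 0`` and a strictly
    positive radius for every angle (closed, non-degenerate profile).
    """

    q1: float
    q2: float
    q3: float
    mx: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.q1, self.q2, self.q3, self.mx])):
            raise ValueError("limacon parameters must be finite")
        if self.q1 <= 0:
            raise ValueError(f"q1 must be positive, got {self.q1}")
        if self.min_radius() <= 0:
            raise ValueError("degenerate profile: R(q, phi) <= 0 for some phi")

    def min_radius(self) -> float:
        phi = np.linspace(0.0, np.pi, 2001)
        return float(np.min(limacon_radius(self, phi)))

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3, self.mx])


def limacon_radius(params: LimaconParams, phi_hat) -> np.ndarray | float:
    """Radius R(q, phi_hat) = q1 + q2 cos(phi_hat) + q3 cos^3(phi_hat)."""
    c = np.cos(phi_hat)
    return params.q1 + params.q2 * c + params.q3 * c**3


def profile_point(params: LimaconParams, phi) -> np.ndarray:
    """Cartesian profile point(s) ``(R cos(phi) + mx, R sin(phi))`` in mm."""
    phi = np.asarray(phi, dtype=float)
    r = limacon_radius(params, phi)
    return np.stack([r * np.cos(phi) + params.mx, r * np.sin(phi)], axis=-1)


@dataclass(frozen=True)
class USPointSet:
    """Ultrasound profile points ``(x, y)`` in mm extracted from a B-scan."""

    points: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y) mm")
        if pts.shape[0] < 8:
            raise ValueError("need at least 8 profile points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("profile points must be finite")
        # collinearity check: rank of centered coordinates
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise ValueError("profile points are collinear")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


def polar_convert(points: USPointSet, mx: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert scan points to polar coordinates about the center ``(mx, 0)``.

    Returns ``(r, phi_hat)`` with ``phi_hat`` in [0, 2*pi).  The arccos of
    the normalized x-offset only covers [0, pi]; the sign of y recovers the
    full angle.
    """
    x, y = points.points[:, 0], points.points[:, 1]
    dx = x - mx
    r = np.hypot(dx, y)
    if np.any(r < 1e-12):
        bad = np.nonzero(r < 1e-12)[0]
        raise ValueError(
            f"point(s) {bad.tolist()} coincide with the Limacon center ({mx}, 0); "
            "polar conversion is undefined there"
        )
    phi = np.arccos(np.clip(dx / r, -1.0, 1.0))
    phi = np.where(y < 0, 2.0 * np.pi - phi, phi)
    return r, phi


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Limacon least-squares fit (all lengths mm)."""

    params: LimaconParams
    residuals: np.ndarray
    max_abs_residual: float
    rms_residual: float
    converged: bool


def _fit_residual_jacobian(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    q1, q2, q3, mx = theta
    dx = x - mx
    r = np.hypot(dx, y)
    c = dx / r
    res = r - (q1 + q2 * c + q3 * c**3)
    # d res / d mx: both r and cos(phi_hat) depend on mx
    dRdc = q2 + 3.0 * q3 * c**2
    jac = np.column_stack([
        -np.ones_like(r),
        -c,
        -(c**3),
        -dx / r + dRdc * (y**2 / r**3),
    ])
    return res, jac


def fit_limacon(points: USPointSet, init: LimaconParams | None = None) -> FitResult:
    """Least-squares fit of ``(q1, q2, q3, mx)`` to ultrasound points.

    Minimizes ``sum_i (r_i - R(q, phi_hat_i(mx)))**2`` with a trust-region
    reflective solver and the analytic residual Jacobian.  The default
    initial guess is the data centroid (for ``mx``) and the mean radius
    about it (for ``q1``), with ``q2 = q3 = 0``.
    """
    x, y = points.points[:, 0], points.points[:, 1]
    if init is None:
        mx0 = float(np.mean(x))
        q10 = float(np.mean(np.hypot(x - mx0, y)))
        theta0 = np.array([q10, 0.0, 0.0, mx0])
    else:
        theta0 = init.as_array()

    sol = least_squares(
        lambda t: _fit_residual_jacobian(t, x, y)[0],
        theta0,
        jac=lambda t: _fit_residual_jacobian(t, x, y)[1],
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    converged = bool(sol.status > 0)
    try:
        params = LimaconParams(*sol.x)
    except ValueError:
        # degenerate iterate: report the last point but flag non-convergence
        params = LimaconParams(max(sol.x[0], 1e-6), 0.0, 0.0, sol.x[3])
        converged = False
    res = _fit_residual_jacobian(sol.x, x, y)[0]
    return FitResult(
        params=params,
        residuals=res,
        max_abs_residual=float(np.max(np.abs(res))),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        converged=converged,
    )


def generate_synthetic_us_points(
    params: LimaconParams, n: int = 164, noise_sd: float = 0.0, seed: int = 0
) -> USPointSet:
    """Synthetic ultrasound point set: the study's stand-in for a B-scan.

    ``n`` points on the profile at equally spaced angles with i.i.d. radial
    Gaussian noise of standard deviation ``noise_sd`` mm.  The default
    ``n = 164`` matches the number of points extracted per clinical scan.
    Deterministic for a given ``seed``.
    """
    if n < 8:
        raise ValueError("need n >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = limacon_radius(params, phi) + rng.normal(0.0, noise_sd, size=n)
    pts = np.column_stack([r * np.cos(phi) + params.mx, r * np.sin(phi)])
    return USPointSet(points=pts, source_label=f"synthetic(seed={seed})")


# --------------------------------------------------------------------------
# domain with labeled boundary parts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundarySpec:
    """Angular partition of the profile circle into anatomical arcs.

    Angles are measured from the posterior pole (``phi_hat = 0``, retina
    side); the anterior pole (lens) is at ``phi_hat = pi``.  The lens is the
    anterior cap subtending ``2 * lens_half_angle``; the hyaloid membrane is
    the pair of ``hyaloid_width`` arcs flanking it (one annulus after
    revolution); the retina is the remainder.  All angles in radians.
    """

    lens_half_angle: float = np.deg2rad(30.0)
    hyaloid_width: float = np.deg2rad(10.0)

    def __post_init__(self) -> None:
        if not 0 < self.lens_half_angle < np.pi / 2:
            raise ValueError("lens_half_angle must be in (0, pi/2)")
        if not 0 < self.hyaloid_width < np.pi / 2 - 1e-12:
            raise ValueError("hyaloid_width must be in (0, pi/2)")
        if self.lens_half_angle + self.hyaloid_width >= np.pi:
            raise ValueError("lens + hyaloid arcs overlap the posterior pole")

    @property
    def ranges(self) -> dict[str, list[tuple[float, float]]]:
        """Disjoint arc ranges covering [0, 2*pi), keyed by part name."""
        a = np.pi - self.lens_half_angle          # lens edge (upper half)
        b = a - self.hyaloid_width                # hyaloid outer edge
        return {
            "retina": [(0.0, b), (2.0 * np.pi - b, 2.0 * np.pi)],
            "hyaloid": [(b, a), (2.0 * np.pi - a, 2.0 * np.pi - b)],
            "lens": [(a, 2.0 * np.pi - a)],
        }

    def classify(self, phi_hat: np.ndarray) -> np.ndarray:
        """Marker for each profile angle (uses the upper-half symmetry)."""
        p = np.abs(np.mod(np.asarray(phi_hat, dtype=float), 2.0 * np.pi))
        p = np.where(p > np.pi, 2.0 * np.pi - p, p)
        a = np.pi - self.lens_half_angle
        b = a - self.hyaloid_width
        out = np.full(p.shape, RETINA, dtype=int)
        out[p > a] = LENS
        out[(p > b) & (p <= a)] = HYALOID
        return out


@dataclass(frozen=True)
class VitreousDomain:
    """Revolved Limacon solid with anatomically labeled boundary.

    ``macula_center`` sits on the retina at the posterior pole, optionally
    rotated by ``macula_offset`` radians in the xy-plane (toward the optic
    nerve for a nasal offset); the optic axis is +x, pointing from the lens
    to the retina.
    """

    params: LimaconParams
    boundary_spec: BoundarySpec = field(default_factory=BoundarySpec)
    macula_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.boundary_spec.classify(np.array([self.macula_offset]))[0] != RETINA:
            raise ValueError("macula_center must lie on the retina arc")

    @property
    def optic_axis(self) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0])

    @property
    def macula_center(self) -> np.ndarray:
        """Macula center m (mm, 3d), on the boundary surface."""
        xy = profile_point(self.params, self.macula_offset)
        return np.array([xy[0], xy[1], 0.0])

    @property
    def center(self) -> np.ndarray:
        """Limacon center (mx, 0, 0) in mm."""
        return np.array([self.params.mx, 0.0, 0.0])

    def radius_at(self, phi_hat) -> np.ndarray | float:
        return limacon_radius(self.params, phi_hat)

    # -- measures (high-order 1d quadrature oracles, mm^2 / mm^3) ---------
    def profile_area(self) -> float:
        """Area of the 2d profile region, 0.5 * int R^2 dphi."""
        f = lambda p: 0.5 * limacon_radius(self.params, p) ** 2
        val, _ = quad(f, 0.0, 2.0 * np.pi, limit=200)
        return float(val)

    def volume(self) -> float:
        """Volume of the revolved solid, (2*pi/3) * int R^3 sin(phi) dphi."""
        f = lambda p: limacon_radius(self.params, p) ** 3 * np.sin(p)
        val, _ = quad(f, 0.0, np.pi, limit=200)
        return float(2.0 * np.pi / 3.0 * val)

    def arc_length(self, phi0: float, phi1: float) -> float:
        """Arc length of the profile curve between two angles (mm)."""
        def ds(p):
            c = np.cos(p)
            r = limacon_radius(self.params, p)
            dr = -self.params.q2 * np.sin(p) - 3 * self.params.q3 * c**2 * np.sin(p)
            return np.sqrt(r**2 + dr**2)
        val, _ = quad(ds, phi0, phi1, limit=200)
        return float(val)

    def surface_point(self, phi_hat: float, meridian: float = 0.0) -> np.ndarray:
        """3d boundary point at profile angle ``phi_hat`` and revolution
        angle ``meridian`` (0 = the +y half of the xy-plane)."""
        r = limacon_radius(self.params, phi_hat)
        s = r * np.sin(phi_hat)
        return np.array([
            self.params.mx + r * np.cos(phi_hat),
            s * np.cos(meridian),
            s * np.sin(meridian),
        ])

    def contains(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Vectorized point-in-solid test (pts in mm, shape (..., 3))."""
        pts = np.asarray(pts, dtype=float)
        d = pts - self.center
        rho = np.linalg.norm(d, axis=-1)
        with np.errstate(invalid="ignore"):
            cphi = np.where(rho > 0, d[..., 0] / np.maximum(rho, 1e-300), 1.0)
        R = self.params.q1 + self.params.q2 * cphi + self.params.q3 * cphi**3
        return rho <= R - tol

    def boundary_distance(self, pt: np.ndarray) -> float:
        """Signed radial margin of a 3d point: R(phi_hat) - rho (mm, > 0
        inside).  A cheap interior-margin proxy, exact on rays."""
        d = np.asarray(pt, dtype=float) - self.center
        rho = float(np.linalg.norm(d))
        if rho == 0.0:
            return float(self.params.q1 + min(0.0, self.params.q2))
        cphi = d[0] / rho
        return float(self.params.q1 + self.params.q2 * cphi
                     + self.params.q3 * cphi**3 - rho)


def build_domain(
    params: LimaconParams,
    boundary_spec: BoundarySpec | None = None,
    macula_offset: float = 0.0,
) -> VitreousDomain:
    """Assemble the labeled vitreous domain (validates the arc partition)."""
    spec = boundary_spec if boundary_spec is not None else BoundarySpec()
    ranges = spec.ranges
    total = sum(hi - lo for arcs in ranges.values() for lo, hi in arcs)
    if not np.isclose(total, 2.0 * np.pi, atol=1e-9):
        raise ValueError("boundary arcs do not cover the full circle")
    return VitreousDomain(params=params, boundary_spec=spec,
                          macula_offset=macula_offset)


# --------------------------------------------------------------------------
# structured meshing
# --------------------------------------------------------------------------

MeshMode = Literal["axisymmetric-2d", "full-3d"]

# Kuhn subdivision of the unit cube into six tetrahedra sharing the main
# diagonal (conforming across a translated grid).
_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


@dataclass(frozen=True)
class Mesh:
    """Simplicial mesh of the vitreous (vertices in mm).

    ``cells``: (nc, 4) tet connectivity in 3d or (nc, 3) triangles of the
    full 2d profile disk in axisymmetric mode (where the revolution weight
    is pi*|rho|, each profile half contributing half a revolution).
    ``boundary_facets`` are the facets on the geometric boundary with
    ``facet_markers`` from {RETINA, LENS, HYALOID}.
    """

    vertices: np.ndarray
    cells: np.ndarray
    boundary_facets: np.ndarray
    facet_markers: np.ndarray
    mode: MeshMode
    domain: VitreousDomain

    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def vertices_m(self) -> np.ndarray:
        """Vertices in SI metres (the PDE modules work in SI)."""
        return self.vertices * MM

    def cell_volumes(self) -> np.ndarray:
        """Signed simplex measures in mm^dim (positive for valid meshes)."""
        v = self.vertices[self.cells]
        if self.dim == 3:
            a, b, c = (v[:, i + 1] - v[:, 0] for i in range(3))
            return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
        a, b = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def measure(self) -> float:
        """Domain measure: volume (mm^3) in 3d, profile area (mm^2) in 2d."""
        return float(np.sum(self.cell_volumes()))

    def boundary_facets_of(self, marker: int) -> np.ndarray:
        return self.boundary_facets[self.facet_markers == marker]


def _ball_map_3d(c: np.ndarray) -> np.ndarray:
    """Smooth bijection of the cube [-1,1]^3 onto the unit ball."""
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    return np.column_stack([
        x * np.sqrt(1 - y**2 / 2 - z**2 / 2 + y**2 * z**2 / 3),
        y * np.sqrt(1 - z**2 / 2 - x**2 / 2 + z**2 * x**2 / 3),
        z * np.sqrt(1 - x**2 / 2 - y**2 / 2 + x**2 * y**2 / 3),
    ])


def _disk_map_2d(c: np.ndarray) -> np.ndarray:
    """Smooth bijection of the square [-1,1]^2 onto the unit disk."""
    a, b = c[:, 0], c[:, 1]
    return np.column_stack([a * np.sqrt(1 - b**2 / 2), b * np.sqrt(1 - a**2 / 2)])


def _limacon_map(u: np.ndarray, params: LimaconParams) -> np.ndarray:
    """Radial map of the unit ball/half-disk onto the Limacon solid/profile.

    The solid is star-shaped about its center (mx, 0[, 0]); each unit-ball
    point at radius rho and direction u-hat lands at rho * R(phi_hat) along
    the same direction.  cos(phi_hat) is simply the x-component of u-hat.
    """
    rho = np.linalg.norm(u, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cphi = np.where(rho > 0, u[:, 0] / np.maximum(rho, 1e-300), 1.0)
    R = params.q1 + params.q2 * cphi + params.q3 * cphi**3
    out = u * R[:, None]
    out[:, 0] += params.mx
    return out


def _grid_3d(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Kuhn tetrahedralization of an n^3 cube grid on [-1, 1]^3."""
    s = np.linspace(-1.0, 1.0, n + 1)
    X, Y, Z = np.meshgrid(s, s, s, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vid = np.arange((n + 1) ** 3).reshape(n + 1, n + 1, n + 1)
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    cells = []
    for path in _KUHN_PATHS:
        steps = np.zeros((4, 3), dtype=int)
        for m, ax in enumerate(path):
            steps[m + 1] = steps[m]
            steps[m + 1, ax] += 1
        tet = [vid[i + d[0], j + d[1], k + d[2]] for d in steps]
        cells.append(np.column_stack(tet))
    return verts, np.vstack(cells)


def _grid_2d(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated (2n x 2n) grid on [-1,1]^2 (full profile square).

    The symmetry axis (rho = 0) falls on grid lines, so no cell straddles
    it — the axisymmetric revolution weight |rho| is smooth within every
    cell and the weighted quadratures stay exact.
    """
    s = np.linspace(-1.0, 1.0, 2 * n + 1)
    X, Y = np.meshgrid(s, s, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel()])
    vid = np.arange((2 * n + 1) ** 2).reshape(2 * n + 1, 2 * n + 1)
    i, j = np.meshgrid(np.arange(2 * n), np.arange(2 * n), indexing="ij")
    i, j = i.ravel(), j.ravel()
    t1 = np.column_stack([vid[i, j], vid[i + 1, j], vid[i + 1, j + 1]])
    t2 = np.column_stack([vid[i, j], vid[i + 1, j + 1], vid[i, j + 1]])
    return verts, np.vstack([t1, t2])


def _fix_orientation(verts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    v = verts[cells]
    if verts.shape[1] == 3:
        a, b, c = (v[:, i + 1] - v[:, 0] for i in range(3))
        vol = np.einsum("ij,ij->i", a, np.cross(b, c))
    else:
        a, b = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]
        vol = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    flip = vol < 0
    cells = cells.copy()
    cells[flip, 0], cells[flip, 1] = cells[flip, 1], cells[flip, 0].copy()
    return cells


def _boundary_facets(cells: np.ndarray) -> np.ndarray:
    """Facets (sorted vertex tuples) that belong to exactly one cell."""
    nv = cells.shape[1]
    if nv == 4:
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    else:
        local = [(1, 2), (2, 0), (0, 1)]
    facets = np.concatenate([cells[:, f] for f in local], axis=0)
    key = np.sort(facets, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return facets[idx[counts == 1]]


def build_mesh(domain: VitreousDomain, h: float, mode: MeshMode = "full-3d") -> Mesh:
    """Conforming simplicial mesh of the vitreous with marked boundary.

    ``h`` is the target edge length in mm.  The structured construction
    guarantees every boundary facet lies exactly on the Limacon surface and
    inherits the marker of its profile arc.
    """
    if h <= 0:
        raise ValueError("target edge length h must be positive")
    params = domain.params
    rbar = float(np.mean(limacon_radius(params, np.linspace(0, np.pi, 181))))
    if mode == "full-3d":
        n = max(4, int(np.ceil(2.0 * rbar / h)))
        uverts, cells = _grid_3d(n)
        ball = _ball_map_3d(uverts)
        verts = _limacon_map(ball, params)
    elif mode == "axisymmetric-2d":
        n = max(4, int(np.ceil(rbar / h)))
        uverts, cells = _grid_2d(n)
        disk = _disk_map_2d(uverts)
        verts = _limacon_map(disk, params)
    else:
        raise ValueError(f"unknown mesh mode {mode!r}")

    cells = _fix_orientation(verts, cells)
    bfacets = _boundary_facets(cells)

    # classify facets by the profile angle of their centroid
    cent = verts[bfacets].mean(axis=1)
    d = cent - (np.array([params.mx, 0.0, 0.0]) if verts.shape[1] == 3
                else np.array([params.mx, 0.0]))
    if verts.shape[1] == 3:
        s = np.hypot(d[:, 1], d[:, 2])
    else:
        s = np.abs(d[:, 1])
    phi = np.arctan2(s, d[:, 0])
    markers = domain.boundary_spec.classify(phi)

    mesh = Mesh(vertices=verts, cells=cells, boundary_facets=bfacets,
                facet_markers=markers, mode=mode, domain=domain)
    vols = mesh.cell_volumes()
    if np.any(vols <= 0):
        raise RuntimeError(
            f"mesher produced {int(np.sum(vols <= 0))} inverted cells "
            f"(n={n}, mode={mode}); geometry: {params}"
        )
    for marker in (RETINA, LENS, HYALOID):
        if not np.any(markers == marker):
            raise RuntimeError(
                f"boundary part {MARKER_NAMES[marker]!r} received no facets "
                f"at h={h}; refine the mesh"
            )
    return mesh


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_us_points_csv(path: str | Path, source_label: str | None = None) -> USPointSet:
    """Read ultrasound points from CSV with header ``x_mm,y_mm``.

    Lines starting with ``#`` are treated as comments.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:2] != ["x_mm", "y_mm"]:
                    raise ValueError(
                        f"{path}: expected header 'x_mm,y_mm', got {line!r}"
                    )
                continue
            parts = line.split(",")
            rows.append((float(parts[0]), float(parts[1])))
    return USPointSet(points=np.array(rows),
                      source_label=source_label or path.name)


def write_us_points_csv(points: USPointSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x_mm,y_mm\n")
        for x, y in points.points:
            fh.write(f"{x:.9g},{y:.9g}\n")


def save_geometry_yaml(domain: VitreousDomain, path: str | Path) -> None:
    """Round-trippable YAML of the fitted geometry and boundary partition."""
    import yaml

    data = {
        "limacon": {
            "q1": float(domain.params.q1),
            "q2": float(domain.params.q2),
            "q3": float(domain.params.q3),
            "mx": float(domain.params.mx),
        },
        "boundary_spec": {
            "lens_half_angle_deg": float(np.rad2deg(domain.boundary_spec.lens_half_angle)),
            "hyaloid_width_deg": float(np.rad2deg(domain.boundary_spec.hyaloid_width)),
        },
        "macula_offset_deg": float(np.rad2deg(domain.macula_offset)),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_geometry_yaml(path: str | Path) -> VitreousDomain:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    lim = data["limacon"]
    spec = BoundarySpec(
        lens_half_angle=np.deg2rad(data["boundary_spec"]["lens_half_angle_deg"]),
        hyaloid_width=np.deg2rad(data["boundary_spec"]["hyaloid_width_deg"]),
    )
    return build_domain(
        LimaconParams(lim["q1"], lim["q2"], lim["q3"], lim["mx"]),
        boundary_spec=spec,
        macula_offset=np.deg2rad(data.get("macula_offset_deg", 0.0)),
    )
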