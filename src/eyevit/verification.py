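"""Verification machinery: manufactured solutions and conservation audits.

The solver stack is verified against closed-form references:

* **Manufactured solutions** for the transport solver.  The spatial study
  uses a steady trigonometric concentration field with the matching
  forcing; integrating the strongly A-stable scheme from the interpolated
  exact state settles onto the discrete elliptic solution, so the measured
  L2 error is purely spatial and its slope against the mesh size gives the
  spatial order (expected 2).  The temporal study manufactures a solution
  that is linear in space — exactly representable by the elements, so the
  error against the time step is purely temporal (expected order 2).
* **A radial Darcy oracle**: a spherical shell with prescribed influx on
  the inner sphere and the retinal Robin condition on the outer one has
  the closed form p(r) = A + B/r; the mixed solver is compared against it
  on a structured annulus mesh in axisymmetric mode.
* **A discrete flux audit**: initial mass must equal remaining mass plus
  the cumulative retinal and hyaloid boundary losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _fem
from .darcy_flow import FlowParams, assemble_darcy, solve_darcy
from .functionals import DAY
from .geometry import (
    HYALOID,
    MM,
    RETINA,
    LimaconParams,
    Mesh,
    VitreousDomain,
    build_domain,
    build_mesh,
)
from .transport import (
    ConcentrationField,
    ThetaScheme,
    TransportOperators,
    TransportParams,
    _SubstepSolver,
    _substep,
    assemble_transport,
)

__all__ = [
    "MMSCase",
    "ConvergenceReport",
    "spatial_mms_case",
    "temporal_mms_case",
    "run_mms",
    "convergence_study",
    "flux_audit",
    "FluxAuditReport",
    "annulus_mesh",
    "radial_shell_solution",
]


# --------------------------------------------------------------------------
# manufactured solutions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MMSCase:
    """Closed-form concentration field with compatible forcing.

    ``c_exact(points_m, t)`` and ``forcing(points_m, t)`` are vectorized
    over points; Dirichlet data is imposed on the whole boundary from the
    exact solution.  ``velocity`` is a constant drift (m/s) entering both
    the solver (as a settling-style transport term) and the forcing.
    """

    c_exact: Callable[[np.ndarray, float], np.ndarray]
    forcing: Callable[[np.ndarray, float], np.ndarray]
    D: float
    velocity: np.ndarray
    T: float
    label: str = "mms"


def _domain_for_mms() -> VitreousDomain:
    # modest sphere-like domain; the study only needs a fixed geometry
    return build_domain(LimaconParams(10.0, 1.0, 0.0, 0.0))


def spatial_mms_case(D: float = 1.0e-9, drift: float = 2.0e-7,
                     mode: str = "axisymmetric-2d") -> MMSCase:
    """Steady trigonometric field with forcing balancing the full operator.

    Axisymmetric profile: c* = cos(a x) cos(b rho), with the axisymmetric
    Laplacian c_xx + c_rr + c_r/r.  Full 3d: c* = cos(a x) cos(b y)
    cos(b z).  The horizon spans several diffusive relaxation times so the
    A-stable scheme settles onto the discrete elliptic solution and the
    measured error is purely spatial.
    """
    a = 2.0 * np.pi / 0.02           # one period across the eye, 1/m
    b = 1.5 * np.pi / 0.02

    if mode == "axisymmetric-2d":
        def c_exact(p, t):
            return np.cos(a * p[..., 0]) * np.cos(b * p[..., 1])

        def forcing(p, t):
            x, r = p[..., 0], p[..., 1]
            cax, car = np.cos(a * x), np.cos(b * r)
            # c_r / r is even in r with limit -b^2 c at the axis
            with np.errstate(invalid="ignore", divide="ignore"):
                cr_over_r = np.where(
                    np.abs(r) < 1e-12,
                    -(b**2) * cax,
                    -b * np.sin(b * r) / np.where(np.abs(r) < 1e-12, 1.0, r) * cax,
                )
            lap = -(a**2 + b**2) * cax * car + cr_over_r
            gx = -a * np.sin(a * x) * car
            return -D * lap + drift * gx
    else:
        def c_exact(p, t):
            return (np.cos(a * p[..., 0]) * np.cos(b * p[..., 1])
                    * np.cos(b * p[..., 2]))

        def forcing(p, t):
            c = c_exact(p, t)
            lap = -(a**2 + 2 * b**2) * c
            gx = (-a * np.sin(a * p[..., 0]) * np.cos(b * p[..., 1])
                  * np.cos(b * p[..., 2]))
            return -D * lap + drift * gx

    v = np.array([drift, 0.0, 0.0])
    # horizon ~ 10 diffusive relaxation times of the slowest mode
    T = 10.0 / (D * (np.pi / 0.02) ** 2)
    return MMSCase(c_exact=c_exact, forcing=forcing, D=D, velocity=v,
                   T=T, label=f"spatial-trig-{mode}")


def temporal_mms_case(D: float = 1.0e-9, drift: float = 2.0e-7,
                      rate: float = 0.35) -> MMSCase:
    """Separable field c* = exp(-rate * t) * (1 + x/L): linear in space.

    The spatial part lies exactly in the P1 space, so the discretization
    error is purely temporal.  ``rate`` is per second on an O(10 s)
    horizon.
    """
    L = 0.01

    def c_exact(p, t):
        return np.exp(-rate * t) * (1.0 + p[..., 0] / L)

    def forcing(p, t):
        # dc/dt + v . grad c - D lap c;  lap of a linear field is zero
        return (-rate * c_exact(p, t)
                + np.exp(-rate * t) * drift / L)

    v = np.array([drift, 0.0, 0.0])
    return MMSCase(c_exact=c_exact, forcing=forcing, D=D, velocity=v,
                   T=10.0, label="temporal-linear")


def run_mms(case: MMSCase, mesh: Mesh, dt: float) -> float:
    """Integrate the case to T on the given mesh/step; return the L2 error.

    Dirichlet data from the exact solution on the whole boundary; the
    constant drift is supplied through the settling-velocity hook.
    """
    speed = float(np.linalg.norm(case.velocity))
    gdir = case.velocity / speed if speed > 0 else np.array([1.0, 0.0, 0.0])
    tp = TransportParams(D=case.D, P=0.0, k=1.0, v_settle=speed,
                         gravity_dir=tuple(gdir[: 3]))
    ops = assemble_transport(
        mesh, None, tp, gravity_dir=gdir[: mesh.dim] if mesh.dim == 2 else gdir,
        dirichlet_marker="all",
        forcing=lambda p, t: case.forcing(p, t),
        dirichlet_value=lambda p, t: case.c_exact(p, t),
    )
    scheme = ThetaScheme(dt_macro=dt)
    solver = _SubstepSolver(ops, scheme.theta * scheme.alpha * dt)
    C = case.c_exact(mesh.vertices_m, 0.0)
    t = 0.0
    while t < case.T - 1e-9:
        step = min(dt, case.T - t)
        if abs(step - dt) > 1e-12:
            s2 = _SubstepSolver(ops, scheme.theta * scheme.alpha * step)
        else:
            s2 = solver
        for dt_sub, wi, we in scheme.substeps(step):
            C, _ = _substep(s2, ops, C, t, dt_sub, wi, we)
            t += dt_sub
    geo = ops.geo
    qp, _ = _fem._ref_qp(mesh.dim)
    lam = _fem.p1_basis_at(qp)
    Ch = np.einsum("qi,ni->nq", lam, C[mesh.cells])
    Cx = case.c_exact(geo.qpoints, case.T)
    err2 = float(np.sum(geo.qweights * (Ch - Cx) ** 2))
    norm2 = float(np.sum(geo.qweights * Cx**2))
    return np.sqrt(err2 / max(norm2, 1e-300))


@dataclass
class ConvergenceReport:
    """Observed orders from nested refinement studies."""

    h_values: np.ndarray
    spatial_errors: np.ndarray
    spatial_order: float | None
    dt_values: np.ndarray
    temporal_errors: np.ndarray
    temporal_order: float | None

    def to_frame(self):
        import pandas as pd

        n = max(len(self.h_values), len(self.dt_values))
        def pad(a):
            a = list(a)
            return a + [np.nan] * (n - len(a))
        return pd.DataFrame({
            "h_mm": pad(self.h_values),
            "spatial_L2_error": pad(self.spatial_errors),
            "dt_s": pad(self.dt_values),
            "temporal_L2_error": pad(self.temporal_errors),
        })


def _slope(x: np.ndarray, err: np.ndarray) -> float | None:
    if np.any(np.diff(err) >= 0):
        return None                      # non-monotone: report raw table only
    A = np.vstack([np.log(x), np.ones_like(x)]).T
    sol, *_ = np.linalg.lstsq(A, np.log(err), rcond=None)
    return float(sol[0])


def convergence_study(
    mode: str = "axisymmetric-2d",
    levels: int = 3,
    h0: float = 0.6,
    dt0: float = 2.0,
    case_space: MMSCase | None = None,
    case_time: MMSCase | None = None,
) -> ConvergenceReport:
    """Observed spatial and temporal orders on nested refinements.

    Spatial: the steady trigonometric case at mesh sizes h0 / 2^k with a
    fixed macro step (the A-stable scheme settles onto the discrete steady
    state, so time errors vanish).  Temporal: the space-exact linear case
    on one coarse mesh at steps dt0 / 2^k.
    """
    if levels < 3:
        raise ValueError("need at least 3 refinement levels")
    dom = _domain_for_mms()
    case_s = case_space or spatial_mms_case(mode=mode)
    case_t = case_time or temporal_mms_case()

    hs, errs_s = [], []
    for k in range(levels):
        h = h0 / 2**k
        mesh = build_mesh(dom, h, mode)
        errs_s.append(run_mms(case_s, mesh, dt=case_s.T / 8.0))
        hs.append(h)

    mesh_t = build_mesh(dom, h0, mode)
    dts, errs_t = [], []
    for k in range(levels):
        dt = dt0 / 2**k
        errs_t.append(run_mms(case_t, mesh_t, dt=dt))
        dts.append(dt)

    return ConvergenceReport(
        h_values=np.array(hs), spatial_errors=np.array(errs_s),
        spatial_order=_slope(np.array(hs), np.array(errs_s)),
        dt_values=np.array(dts), temporal_errors=np.array(errs_t),
        temporal_order=_slope(np.array(dts), np.array(errs_t)),
    )


# --------------------------------------------------------------------------
# mass-balance audit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxAuditReport:
    """Drug-mass bookkeeping over one transport run."""

    initial_mass: float
    remaining_mass: float
    retina_cum: float
    hyaloid_cum: float
    imbalance_rel: float
    passed: bool

    def breakdown(self) -> dict:
        return {
            "initial_kg": self.initial_mass,
            "remaining_kg": self.remaining_mass,
            "retina_outflux_kg": self.retina_cum,
            "hyaloid_outflux_kg": self.hyaloid_cum,
            "imbalance_rel": self.imbalance_rel,
        }


def flux_audit(result, tol: float = 0.01) -> FluxAuditReport:
    """Check initial mass = remaining + retinal + hyaloid cumulative losses.

    ``result`` is an :class:`~eyevit.transport.AdvanceResult`.  Raises on
    imbalance beyond ``tol`` with the per-boundary breakdown.
    """
    m0 = result.series.m0
    mT = float(result.series.j_omega[-1] * m0)
    ret = float(result.retina_outflux_cum[-1])
    hya = float(result.hyaloid_outflux_cum[-1])
    imb = abs(m0 - mT - ret - hya) / m0
    rep = FluxAuditReport(initial_mass=m0, remaining_mass=mT, retina_cum=ret,
                          hyaloid_cum=hya, imbalance_rel=imb,
                          passed=bool(imb <= tol))
    if not rep.passed:
        raise AssertionError(
            f"mass imbalance {imb:.3%} exceeds {tol:.1%}: {rep.breakdown()}"
        )
    return rep


# --------------------------------------------------------------------------
# radial Darcy oracle (concentric spheres)
# --------------------------------------------------------------------------

def annulus_mesh(r_in: float, r_out: float, h: float) -> Mesh:
    """Structured full-annulus mesh (axisymmetric profile of a spherical
    shell), inner circle marked hyaloid (prescribed influx), outer retina.
    Radii and h in mm."""
    nr = max(2, int(np.ceil((r_out - r_in) / h)))
    na = max(8, int(np.ceil(2.0 * np.pi * r_out / h)))
    r = np.linspace(r_in, r_out, nr + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, na, endpoint=False)
    R, PHI = np.meshgrid(r, phi, indexing="ij")
    verts = np.column_stack([(R * np.cos(PHI)).ravel(), (R * np.sin(PHI)).ravel()])
    vid = np.arange((nr + 1) * na).reshape(nr + 1, na)
    i, j = np.meshgrid(np.arange(nr), np.arange(na), indexing="ij")
    i, j = i.ravel(), j.ravel()
    jp = (j + 1) % na
    t1 = np.column_stack([vid[i, j], vid[i + 1, j], vid[i + 1, jp]])
    t2 = np.column_stack([vid[i, j], vid[i + 1, jp], vid[i, jp]])
    cells = np.vstack([t1, t2])

    from .geometry import Mesh as _Mesh, _boundary_facets, _fix_orientation

    cells = _fix_orientation(verts, cells)
    bf = _boundary_facets(cells)
    rad = np.linalg.norm(verts[bf].mean(axis=1), axis=1)
    markers = np.where(rad > 0.5 * (r_in + r_out), RETINA, HYALOID)
    dom = build_domain(LimaconParams(r_out, 0.0, 0.0, 0.0))
    return _Mesh(vertices=verts, cells=cells, boundary_facets=bf,
                 facet_markers=markers, mode="axisymmetric-2d", domain=dom)


def radial_shell_solution(r_m: np.ndarray, Q: float, r_out: float,
                          fp: FlowParams) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (p, v_r) for total flux Q through concentric spheres
    with the Robin outer condition; radii in metres."""
    v_out = Q / (4.0 * np.pi * r_out**2)
    p_out = fp.Pv + v_out / fp.conductance
    p = p_out + (fp.mu / fp.kappa) * (Q / (4.0 * np.pi)) * (1.0 / r_m - 1.0 / r_out)
    v = Q / (4.0 * np.pi * r_m**2)
    return p, v


def solve_radial_shell(r_in: float = 5.0, r_out: float = 10.0,
                       h: float = 0.5, Q: float = 4.0e-12,
                       fp: FlowParams | None = None):
    """Solve the concentric-sphere Darcy problem on the annulus mesh and
    return (relative weighted-L2 pressure error, flow field)."""
    fp = fp or FlowParams()
    mesh = annulus_mesh(r_in, r_out, h)
    v_in = Q / (4.0 * np.pi * (r_in * MM) ** 2)
    sysm = assemble_darcy(mesh, fp, inflow=lambda pts: np.full(len(pts), v_in))
    flow = solve_darcy(sysm)
    cent = mesh.vertices[mesh.cells].mean(axis=1)
    r_c = np.linalg.norm(cent, axis=1) * MM
    p_exact, _ = radial_shell_solution(r_c, Q, r_out * MM, fp)
    w = flow.geo.qweights.sum(axis=1)
    err = np.sqrt(np.sum(w * (flow.pressure - p_exact) ** 2))
    ref = np.sqrt(np.sum(w * (p_exact - fp.Pv) ** 2))
    return err / ref, flow
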