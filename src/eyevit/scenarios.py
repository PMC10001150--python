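"""Clinical scenario translation and end-to-end simulation runs.

Turns clinical descriptions — where the needle enters, at which angles, how
the patient holds their head, which drug — into simulator inputs, and runs
the resulting 30-day drug-distribution experiment:

geometry fit -> mesh -> Darcy flow -> initial bolus -> transport -> J
functionals.

Coordinate conventions (left eye): the optic x-axis points from the lens to
the retina, y is the horizontal axis (positive toward the side the needle
enters, the +y half of the xy-plane), z is vertical.  The penetration angle
``psi_xy`` is measured between the needle direction and the optic axis in
the xy-plane; ``psi_z`` is measured against the z-axis (90 deg = needle in
the xy-plane).  Gravity for the head orientations of a patient with the
face forward: standing -z, lying on the back +x (toward the posterior
pole), lying on the left side -y, on the right side +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .darcy_flow import FlowField, FlowParams, assemble_darcy, calibrate_inflow, solve_darcy
from .functionals import DAY, FunctionalEvaluator, FunctionalSeries, MaculaRegion
from .geometry import (
    MM,
    BoundarySpec,
    LimaconParams,
    Mesh,
    VitreousDomain,
    build_domain,
    build_mesh,
)
from .transport import (
    AdvanceResult,
    ThetaScheme,
    TransportParams,
    advance,
    make_initial_bolus,
)

__all__ = [
    "InjectionSpec",
    "HeadOrientationSchedule",
    "ScenarioConfig",
    "ScenarioResult",
    "ScenarioRunner",
    "ORIENTATIONS",
    "head_orientation_to_gravity",
    "limbus_angle",
    "entry_point",
    "needle_direction",
    "needle_tip_position",
    "angles_toward",
    "run_scenario",
    "sweep",
]

#: gravity direction per head orientation, left-eye convention (unit vectors)
ORIENTATIONS = {
    "standing": np.array([0.0, 0.0, -1.0]),
    "back": np.array([1.0, 0.0, 0.0]),
    "left": np.array([0.0, -1.0, 0.0]),
    "right": np.array([0.0, 1.0, 0.0]),
}


def head_orientation_to_gravity(orientation: str) -> np.ndarray:
    """Unit gravity vector in eye coordinates for a head orientation."""
    try:
        return ORIENTATIONS[orientation].copy()
    except KeyError:
        raise ValueError(
            f"unknown head orientation {orientation!r}; "
            f"expected one of {sorted(ORIENTATIONS)}"
        ) from None


@dataclass(frozen=True)
class InjectionSpec:
    """Needle entry and bolus description.

    ``limbus_distance`` is measured as arc length (mm) along the globe
    surface from the limbus ring toward the posterior pole; the limbus is
    taken as the hyaloid/retina junction ring of the boundary partition.
    ``psi_xy`` and ``psi_z`` are the penetration angles in degrees; the
    needle tip (entry + depth * direction) must end up inside the vitreous.
    The default bolus is 1.25 mg in a 0.05 mL ball (bevacizumab
    convention), radius 2.285 mm.
    """

    limbus_distance: float = 3.5
    needle_depth: float = 5.0
    psi_xy: float = 50.0
    psi_z: float = 90.0
    bolus_radius: float = 2.285
    dose: float = 1.25e-6          # kg

    def __post_init__(self) -> None:
        if self.needle_depth < 0:
            raise ValueError("needle_depth must be >= 0")
        if not 0 < self.psi_xy < 180:
            raise ValueError("psi_xy must lie in (0, 180) degrees")
        if not 0 < self.psi_z < 180:
            raise ValueError("psi_z must lie in (0, 180) degrees")
        if self.bolus_radius <= 0 or self.dose <= 0:
            raise ValueError("bolus_radius and dose must be positive")


def limbus_angle(dom: VitreousDomain) -> float:
    """Profile angle of the limbus ring (hyaloid/retina junction)."""
    spec = dom.boundary_spec
    return np.pi - spec.lens_half_angle - spec.hyaloid_width


def entry_point(inj: InjectionSpec, dom: VitreousDomain) -> np.ndarray:
    """Scleral entry point (mm, 3d) at the given arc distance behind the
    limbus, in the +y meridian of the xy-plane."""
    phi_l = limbus_angle(dom)
    target = inj.limbus_distance

    def f(phi):
        return dom.arc_length(phi, phi_l) - target

    max_arc = dom.arc_length(0.0, phi_l)
    if target <= 0 or target >= max_arc:
        raise ValueError(
            f"limbus_distance {target} mm outside the retina arc "
            f"(0, {max_arc:.1f}) mm"
        )
    phi_e = brentq(f, 1e-9, phi_l - 1e-9, xtol=1e-12)
    return dom.surface_point(phi_e, meridian=0.0)


def needle_direction(psi_xy_deg: float, psi_z_deg: float) -> np.ndarray:
    """Unit needle direction from the penetration angles.

    psi_z is the angle against +z; psi_xy the angle between the xy-plane
    projection and the optic (+x) axis, the needle heading inward from the
    +y side (negative y-component).
    """
    pxy = math.radians(psi_xy_deg)
    pz = math.radians(psi_z_deg)
    return np.array([
        math.sin(pz) * math.cos(pxy),
        -math.sin(pz) * math.sin(pxy),
        math.cos(pz),
    ])


def angles_toward(entry_mm: np.ndarray, target_mm: np.ndarray) -> tuple[float, float]:
    """Penetration angles (psi_xy, psi_z) in degrees aiming the needle from
    ``entry_mm`` at ``target_mm`` (e.g., the vitreous center)."""
    d = np.asarray(target_mm, dtype=float) - np.asarray(entry_mm, dtype=float)
    d = d / np.linalg.norm(d)
    psi_z = math.degrees(math.acos(np.clip(d[2], -1, 1)))
    psi_xy = math.degrees(math.atan2(-d[1], d[0]))
    return psi_xy, psi_z


def needle_tip_position(inj: InjectionSpec, dom: VitreousDomain) -> np.ndarray:
    """Bolus center: entry + needle_depth * direction (mm, 3d).

    Rejects tips outside the vitreous with the boundary margin in the
    diagnostic.
    """
    e = entry_point(inj, dom)
    tip = e + inj.needle_depth * needle_direction(inj.psi_xy, inj.psi_z)
    margin = dom.boundary_distance(tip)
    if margin <= 0:
        raise ValueError(
            f"needle tip {np.round(tip, 2)} lies outside the vitreous "
            f"(radial margin {margin:.2f} mm); shorten the needle or "
            "change the angles"
        )
    return tip


@dataclass(frozen=True)
class HeadOrientationSchedule:
    """Ordered (duration_s, orientation) segments covering the horizon."""

    segments: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for dur, ori in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            head_orientation_to_gravity(ori)

    @property
    def total(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def gravity_segments(self) -> list[tuple[float, np.ndarray]]:
        return [(d, head_orientation_to_gravity(o)) for d, o in self.segments]

    @classmethod
    def constant(cls, orientation: str, horizon_s: float) -> "HeadOrientationSchedule":
        return cls(segments=((horizon_s, orientation),))

    @classmethod
    def daily_alternation(
        cls, first: str, second: str, horizon_s: float
    ) -> "HeadOrientationSchedule":
        """Half-day ``first`` / half-day ``second``, repeated daily."""
        half = 0.5 * DAY
        segs = []
        t = 0.0
        while t < horizon_s - 1e-6:
            for ori in (first, second):
                if t >= horizon_s - 1e-6:
                    break
                d = min(half, horizon_s - t)
                segs.append((d, ori))
                t += d
        return cls(segments=tuple(segs))


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one virtual experiment."""

    limacon: LimaconParams = field(
        default_factory=lambda: LimaconParams(11.0, 1.5, 0.5, 1.0))
    boundary_spec: BoundarySpec = field(default_factory=BoundarySpec)
    macula_offset: float = 0.0
    mesh_h: float = 1.0
    mesh_mode: str = "full-3d"
    flow: FlowParams = field(default_factory=FlowParams)
    transport: TransportParams = field(default_factory=TransportParams)
    injection: InjectionSpec = field(default_factory=InjectionSpec)
    schedule: HeadOrientationSchedule | None = None
    horizon: float = 30.0 * DAY
    dt_macro: float = 0.25 * DAY
    macula_radius: float = 2.0
    label: str = "scenario"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.dt_macro <= 0:
            raise ValueError("horizon and dt_macro must be positive")
        if self.schedule is not None and self.schedule.total < self.horizon - 1e-6:
            raise ValueError("head schedule shorter than the horizon")
        if self.mesh_mode not in ("full-3d", "axisymmetric-2d"):
            raise ValueError(f"unknown mesh mode {self.mesh_mode!r}")

    def domain(self) -> VitreousDomain:
        return build_domain(self.limacon, self.boundary_spec, self.macula_offset)

    def requires_3d(self) -> tuple[bool, str]:
        """Whether the scenario breaks rotational symmetry, and why."""
        if abs(self.injection.psi_z - 90.0) > 1e-9:
            return True, "psi_z != 90 deg tilts the needle out of the xy-plane"
        if self.transport.v_settle > 0 and self.schedule is not None:
            for _, ori in self.schedule.segments:
                g = head_orientation_to_gravity(ori)
                if abs(g[1]) > 1e-12 or abs(g[2]) > 1e-12:
                    return True, f"lateral gravity ({ori}) breaks symmetry"
        dom = self.domain()
        tip = needle_tip_position(self.injection, dom)
        if np.hypot(tip[1], tip[2]) > 1e-6:
            return True, "off-axis bolus center breaks symmetry"
        return False, ""


@dataclass
class ScenarioResult:
    """Outcome of one scenario run."""

    config: ScenarioConfig
    series: FunctionalSeries
    advance: AdvanceResult
    flow_summary: dict
    bolus_center: np.ndarray
    summary: dict


class ScenarioRunner:
    """Caches the geometry, mesh, Darcy flow and functional weights shared
    by a family of scenarios (the flow is injection-independent, so sweeps
    re-solve only the transport stage)."""

    def __init__(self, cfg: ScenarioConfig):
        self.base = cfg
        self.domain = cfg.domain()
        self.mesh = build_mesh(self.domain, cfg.mesh_h, cfg.mesh_mode)
        fp = cfg.flow
        if fp.c_pflow == 0.0 and fp.vitreous_fraction > 0:
            fp = calibrate_inflow(self.domain, fp)
        self.flow_params = fp
        self.flow = solve_darcy(assemble_darcy(self.mesh, fp))
        center = self.domain.macula_center
        if self.mesh.dim == 2:
            center = center[:2]
        self.region = MaculaRegion(center=center, radius=cfg.macula_radius)
        self.evaluator = FunctionalEvaluator(self.mesh, self.region)

    def _check_shares_context(self, cfg: ScenarioConfig) -> None:
        same = (
            cfg.limacon == self.base.limacon
            and cfg.boundary_spec == self.base.boundary_spec
            and cfg.mesh_h == self.base.mesh_h
            and cfg.mesh_mode == self.base.mesh_mode
            and cfg.macula_radius == self.base.macula_radius
        )
        if not same:
            raise ValueError("scenario does not share the runner's geometry/mesh")

    def run(self, cfg: ScenarioConfig | None = None) -> ScenarioResult:
        cfg = cfg or self.base
        self._check_shares_context(cfg)
        needs_3d, why = cfg.requires_3d()
        if needs_3d and cfg.mesh_mode == "axisymmetric-2d":
            raise ValueError(f"axisymmetric mode refused: {why}")

        tip3 = needle_tip_position(cfg.injection, self.domain)
        tip = tip3[: self.mesh.dim]
        C0 = make_initial_bolus(self.mesh, tip, cfg.injection.bolus_radius,
                                cfg.injection.dose)
        scheme = ThetaScheme(dt_macro=cfg.dt_macro)
        schedule = (cfg.schedule.gravity_segments()
                    if cfg.schedule is not None else None)
        res = advance(C0, self.flow, cfg.transport, scheme, cfg.horizon,
                      self.region, gravity_schedule=schedule,
                      evaluator=self.evaluator)
        res.series.validate()
        summary = {
            "label": cfg.label,
            **res.series.summary(),
            "mass_imbalance": res.mass_imbalance(),
            "retina_outflux_fraction":
                float(res.retina_outflux_cum[-1] / res.series.m0),
            "hyaloid_outflux_fraction":
                float(res.hyaloid_outflux_cum[-1] / res.series.m0),
        }
        return ScenarioResult(config=cfg, series=res.series, advance=res,
                              flow_summary=self.flow.summary(),
                              bolus_center=tip3, summary=summary)


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """End-to-end single-scenario run (geometry -> mesh -> flow -> bolus ->
    transport -> functionals)."""
    return ScenarioRunner(cfg).run(cfg)


def sweep(
    cfgs: Sequence[ScenarioConfig],
    baseline: str | None = None,
    runner: ScenarioRunner | None = None,
) -> pd.DataFrame:
    """Run a family of scenarios sharing geometry and tabulate summaries.

    Returns a long-format table with one row per scenario; relative
    differences of the final functionals are computed against the scenario
    labeled ``baseline`` (default: the first).
    """
    if len(cfgs) < 2:
        raise ValueError("a sweep needs at least two configurations")
    horizons = {c.horizon for c in cfgs}
    if len(horizons) > 1:
        raise ValueError("sweep configurations must share the horizon")
    runner = runner or ScenarioRunner(cfgs[0])
    rows = []
    for cfg in cfgs:
        rows.append(runner.run(cfg).summary)
    df = pd.DataFrame(rows)
    base_label = baseline if baseline is not None else cfgs[0].label
    if base_label not in set(df["label"]):
        raise ValueError(f"baseline {base_label!r} not among scenario labels")
    base = df[df["label"] == base_label].iloc[0]
    for col in ("J_omega_final", "J_M_omega_final", "J_R_final",
                "peak_J_M_fraction"):
        denom = base[col] if base[col] != 0 else np.nan
        df[f"rel_diff_{col}"] = (df[col] - base[col]) / denom
    return df
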