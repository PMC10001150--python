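"""Scenario translation and end-to-end run tests."""

import numpy as np
import pytest

import eyevit as ev
from eyevit import scenarios as sc
from eyevit import transport as tr
from eyevit.functionals import DAY, MaculaRegion


class TestNeedleGeometry:
    def test_zero_depth_tip_is_entry(self, eye_domain):
        inj = sc.InjectionSpec(needle_depth=1e-12)
        tip = sc.needle_tip_position(inj, eye_domain)
        assert tip == pytest.approx(sc.entry_point(inj, eye_domain), abs=1e-9)

    def test_standard_position_safely_interior(self, eye_domain):
        """3.5 mm behind the limbus, 5 mm deep at (50, 90) degrees: the tip
        is strictly interior, > 1 mm from the retina."""
        tip = sc.needle_tip_position(sc.InjectionSpec(), eye_domain)
        assert eye_domain.boundary_distance(tip) > 1.0

    def test_center_position_reaches_vitreous_center(self, eye_domain):
        """10 mm from the limbus, ~10 mm deep, aimed at the center: the tip
        lands within 2 mm of the domain centroid."""
        e = sc.entry_point(sc.InjectionSpec(limbus_distance=10.0), eye_domain)
        centroid = eye_domain.center
        pxy, pz = sc.angles_toward(e, centroid)
        depth = float(np.linalg.norm(centroid - e))
        assert depth == pytest.approx(10.0, abs=2.5)
        inj = sc.InjectionSpec(limbus_distance=10.0, needle_depth=10.0,
                               psi_xy=pxy, psi_z=pz)
        tip = sc.needle_tip_position(inj, eye_domain)
        assert np.linalg.norm(tip - centroid) < 2.0

    def test_tip_outside_rejected_with_margin(self, eye_domain):
        inj = sc.InjectionSpec(needle_depth=40.0)
        with pytest.raises(ValueError, match="margin"):
            sc.needle_tip_position(inj, eye_domain)

    def test_angle_ordering_moves_tip_from_macula(self, eye_domain):
        """Larger psi_xy (and psi_z away from 90) puts the bolus farther
        from the macula — the geometric driver of the angle study."""
        m = eye_domain.macula_center
        d = [np.linalg.norm(sc.needle_tip_position(
            sc.InjectionSpec(psi_xy=a), eye_domain) - m) for a in (25, 50, 75)]
        assert d[0] < d[2] and d[1] < d[2]
        dz = [np.linalg.norm(sc.needle_tip_position(
            sc.InjectionSpec(psi_z=z), eye_domain) - m)
            for z in (90, 115, 140)]
        assert dz[0] < dz[1] < dz[2]

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            sc.InjectionSpec(psi_xy=0.0)
        with pytest.raises(ValueError):
            sc.InjectionSpec(psi_z=180.0)


class TestHeadOrientations:
    @pytest.mark.parametrize("ori,expected", [
        ("standing", (0, 0, -1)),
        ("back", (1, 0, 0)),
        ("left", (0, -1, 0)),
        ("right", (0, 1, 0)),
    ])
    def test_gravity_vectors(self, ori, expected):
        assert sc.head_orientation_to_gravity(ori) == pytest.approx(expected)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sc.head_orientation_to_gravity("upside-down")

    def test_schedule_switches_exactly_at_half_day(self):
        sched = sc.HeadOrientationSchedule(
            segments=((12 * 3600.0, "standing"), (12 * 3600.0, "back")))
        segs = sched.gravity_segments()
        assert segs[0][0] == pytest.approx(12 * 3600.0)
        assert segs[0][1] == pytest.approx((0, 0, -1))
        assert segs[1][1] == pytest.approx((1, 0, 0))

    def test_daily_alternation_covers_horizon(self):
        sched = sc.HeadOrientationSchedule.daily_alternation(
            "standing", "back", 30 * DAY)
        assert sched.total == pytest.approx(30 * DAY)
        assert len(sched.segments) == 60


@pytest.fixture(scope="module")
def axi_runner():
    """Axisymmetric runner with an on-axis aimed injection (fast path)."""
    cfg = _axi_config()
    return sc.ScenarioRunner(cfg)


def _axi_config(**kw):
    base = sc.ScenarioConfig(mesh_h=0.9, mesh_mode="axisymmetric-2d",
                             horizon=10 * DAY, dt_macro=0.5 * DAY,
                             injection=_on_axis_injection(), label="axi")
    from dataclasses import replace
    return replace(base, **kw) if kw else base


def _on_axis_injection(**kw):
    """Injection whose tip lands exactly on the optic axis."""
    dom = ev.build_domain(ev.LimaconParams(11.0, 1.5, 0.5, 1.0))
    e = sc.entry_point(sc.InjectionSpec(limbus_distance=6.0), dom)
    target = np.array([-2.0, 0.0, 0.0])
    pxy, pz = sc.angles_toward(e, target)
    depth = float(np.linalg.norm(target - e))
    return sc.InjectionSpec(limbus_distance=6.0, needle_depth=depth,
                            psi_xy=pxy, psi_z=pz, **kw)


class TestRunScenario:
    def test_deterministic_outputs(self, axi_runner):
        r1 = axi_runner.run()
        r2 = axi_runner.run()
        csv1 = r1.series.to_dataframe().to_csv(index=False)
        csv2 = r2.series.to_dataframe().to_csv(index=False)
        assert csv1 == csv2

    def test_dose_doubling_scales_only_j_m(self, axi_runner):
        from dataclasses import replace
        cfg = axi_runner.base
        r1 = axi_runner.run(cfg)
        inj2 = replace(cfg.injection, dose=2.0 * cfg.injection.dose)
        r2 = axi_runner.run(replace(cfg, injection=inj2, label="double"))
        assert r2.series.j_omega == pytest.approx(r1.series.j_omega, rel=1e-9)
        assert r2.series.j_m_omega_cum == pytest.approx(
            r1.series.j_m_omega_cum, rel=1e-9)
        assert r2.series.peak_j_m == pytest.approx(2.0 * r1.series.peak_j_m,
                                                   rel=1e-9)

    def test_partition_identity_each_run(self, axi_runner):
        r = axi_runner.run()
        total = (r.series.j_omega[-1] + r.series.j_m_omega_cum[-1]
                 + r.series.j_r[-1])
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_axisym_mode_refused_for_asymmetric_scenarios(self):
        cfg = _axi_config(injection=sc.InjectionSpec(psi_z=115.0))
        with pytest.raises(ValueError, match="refused"):
            sc.ScenarioRunner(_axi_config()).run(cfg)

    def test_pure_diffusion_peak_time_scaling(self, eye_domain):
        """Flow off: the J_M peak time is near the free-space diffusion
        estimate r^2 / (6 D) for the bolus-to-macula distance.

        The free-space estimate presumes an open boundary; the retinal
        Robin coefficient is set to the half-space transparency value
        sqrt(D / (pi t_peak)) so the wall neither reflects (piling drug
        up, delaying the peak) nor over-absorbs (advancing it).
        """
        inj = _on_axis_injection()
        D = 3e-10
        r = np.linalg.norm(np.array([-2.0, 0.0, 0.0])
                           - eye_domain.macula_center) * 1e-3
        t_est_s = r**2 / (6.0 * D)
        P_transparent = np.sqrt(D / (np.pi * t_est_s))
        cfg = sc.ScenarioConfig(
            mesh_h=0.7, mesh_mode="axisymmetric-2d",
            flow=ev.FlowParams(vitreous_fraction=0.0),
            transport=tr.TransportParams(D=D, P=P_transparent),
            injection=inj, horizon=6 * DAY, dt_macro=0.125 * DAY,
            label="pure-diffusion")
        res = sc.ScenarioRunner(cfg).run()
        assert res.series.peak_time_days == pytest.approx(t_est_s / DAY,
                                                          rel=0.3)


class TestSymmetry:
    def test_mirror_injection_leaves_functionals_unchanged(self, mid3d_mesh,
                                                           mid3d_flow):
        """Mirroring the bolus across the xz-plane (gravity off) changes no
        J functional by more than 1%.  (The structured mesh is not exactly
        mirror-symmetric, so this also bounds the discretization
        asymmetry.)"""
        from eyevit.functionals import FunctionalEvaluator
        region = MaculaRegion(center=mid3d_mesh.domain.macula_center,
                              radius=2.0)
        evl = FunctionalEvaluator(mid3d_mesh, region)
        tp = tr.TransportParams()
        scheme = tr.ThetaScheme(dt_macro=0.5 * DAY)
        center = np.array([-1.0, 5.0, 0.0])
        out = []
        for c in (center, center * np.array([1.0, -1.0, 1.0])):
            C0 = tr.make_initial_bolus(mid3d_mesh, c, 3.2, 1.25e-6)
            res = tr.advance(C0, mid3d_flow, tp, scheme, 8 * DAY, region,
                             evaluator=evl)
            out.append(res.series)
        assert out[1].j_omega[-1] == pytest.approx(out[0].j_omega[-1],
                                                   rel=0.01)
        assert out[1].j_m_omega_cum[-1] == pytest.approx(
            out[0].j_m_omega_cum[-1], rel=0.01)

    def test_gravity_off_orientations_identical(self, coarse3d_mesh,
                                                coarse3d_flow):
        """v_settle = 0: all head orientations produce the same dynamics."""
        from eyevit.functionals import FunctionalEvaluator
        region = MaculaRegion(center=coarse3d_mesh.domain.macula_center,
                              radius=2.0)
        evl = FunctionalEvaluator(coarse3d_mesh, region)
        C0 = tr.make_initial_bolus(coarse3d_mesh,
                                   np.array([-1.0, 5.0, 0.0]), 2.285, 1.25e-6)
        series = []
        for ori in ("standing", "back", "left", "right"):
            sched = [(8 * DAY, sc.head_orientation_to_gravity(ori))]
            res = tr.advance(C0, coarse3d_flow, tr.TransportParams(),
                             tr.ThetaScheme(dt_macro=1.0 * DAY), 8 * DAY,
                             region, gravity_schedule=sched, evaluator=evl)
            series.append(res.series)
        for s in series[1:]:
            assert s.j_omega == pytest.approx(series[0].j_omega, rel=1e-12)
            assert s.j_m == pytest.approx(series[0].j_m, rel=1e-10)


class TestSweep:
    def test_self_sweep_zero_relative_differences(self, axi_runner):
        from dataclasses import replace
        cfg = axi_runner.base
        df = sc.sweep([cfg, replace(cfg, label="again")], runner=axi_runner)
        row = df[df["label"] == "again"].iloc[0]
        for col in df.columns:
            if col.startswith("rel_diff"):
                assert row[col] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_horizons_rejected(self, axi_runner):
        from dataclasses import replace
        cfg = axi_runner.base
        with pytest.raises(ValueError, match="horizon"):
            sc.sweep([cfg, replace(cfg, horizon=5 * DAY, label="short")],
                     runner=axi_runner)

    def test_single_config_rejected(self, axi_runner):
        with pytest.raises(ValueError, match="at least two"):
            sc.sweep([axi_runner.base], runner=axi_runner)


class TestAxisym3dConsistency:
    def test_j_m_series_agree_within_5_percent(self, eye_domain,
                                               mid3d_mesh, mid3d_flow):
        """A symmetric scenario gives matching J_M trajectories in
        axisymmetric and coarse full-3d runs (5%)."""
        from eyevit.functionals import FunctionalEvaluator
        inj = _on_axis_injection()
        tip = sc.needle_tip_position(inj, eye_domain)
        tp = tr.TransportParams()
        scheme = tr.ThetaScheme(dt_macro=0.5 * DAY)
        T = 10 * DAY

        mesh2 = ev.build_mesh(eye_domain, 0.55, "axisymmetric-2d")
        from eyevit.darcy_flow import calibrate_inflow
        fp = calibrate_inflow(eye_domain, ev.FlowParams())
        flow2 = ev.solve_darcy(ev.assemble_darcy(mesh2, fp))
        reg2 = MaculaRegion(center=eye_domain.macula_center[:2], radius=2.0)
        C0 = tr.make_initial_bolus(mesh2, tip[:2], 2.285, 1.25e-6)
        res2 = tr.advance(C0, flow2, tp, scheme, T, reg2)

        reg3 = MaculaRegion(center=eye_domain.macula_center, radius=2.0)
        C0b = tr.make_initial_bolus(mid3d_mesh, tip, 2.285, 1.25e-6)
        res3 = tr.advance(C0b, mid3d_flow, tp, scheme, T, reg3)

        jm2 = res2.series.j_m_omega_cum[-1]
        jm3 = res3.series.j_m_omega_cum[-1]
        assert jm3 == pytest.approx(jm2, rel=0.05)
        assert res3.series.j_omega[-1] == pytest.approx(
            res2.series.j_omega[-1], rel=0.05)
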