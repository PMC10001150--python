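# eyevit — a Virtual Eye for intravitreal drug-distribution simulation

`eyevit` simulates where an intravitreally injected anti-VEGF drug
(bevacizumab, ranibizumab, aflibercept, ...) goes during the month between
two injections. It is aimed at researchers in ocular pharmacokinetics and
mathematical ophthalmology who want to compare injection positions and
angles, patient head positions, and drugs of different molecular weight
*in silico* before (or instead of) animal or clinical experiments.

## Model

The vitreous body Ω is a porous gel bounded by the retina Γ_R, the
impermeable lens Γ_L, and the hyaloid membrane Γ_H through which a small
fraction of the aqueous humor enters. Its shape is a modified Limaçon of
revolution,

    R(q, φ) = q1 + q2·cos(φ̂) + q3·cos³(φ̂),

whose four scalars (q1, q2, q3, mx) are fitted by damped least squares to
ultrasound profile points, so the geometry is patient-adaptable.

Two PDEs are solved in sequence:

1. **Aqueous flow** (steady Darcy): v = −(κ/μ)∇p, div v = 0, with no flux
   through the lens, a Poiseuille inflow profile over the hyaloid annulus
   (calibrated so the vitreous through-flow is 10% of the 2.5 µL/min
   aqueous production), and a Robin permeability condition
   n·v = K_RCS (p − P_v)/L on the retina. Discretized with lowest-order
   Raviart–Thomas fluxes and elementwise-constant pressures; the saddle
   system is solved by a Schur-complement CG iteration on the pressure.

2. **Drug transport** (convection–diffusion over 30 days):
   ∂C/∂t + (v·∇)C − ∇·(D∇C) = 0, with a Robin retina condition
   −D ∂C/∂n = P·C + (n·v)(k−1)·C, zero flux at the lens, and C = 0 on the
   hyaloid. Continuous piecewise-linear elements in space; the strongly
   A-stable fractional-step θ scheme (θ = 1 − √2/2) in time, with
   ILU-preconditioned GMRES for the sub-step systems. Gravity enters as an
   additional settling-drift term with a head-orientation schedule;
   anisotropic (constant SPD tensor) diffusion is supported.

Therapy quality is quantified by four functionals: J_Ω(t) (fraction of the
dose still in the vitreous), J_M(t) (drug amount in the macular ball
B_r(m) ∩ Ω, r = 2 mm), J_{M,Ω}(T) (time-integrated macular fraction, t in
days), and J_R(T) = 1 − J_Ω − J_{M,Ω} (fraction lost through the retina).

## Worked example

An on-axis injection aimed at the posterior pole, axisymmetric mode
(seconds to run):

```python
import numpy as np
import eyevit as ev
from eyevit import scenarios as sc
from eyevit.functionals import DAY

dom = ev.build_domain(ev.LimaconParams(11.0, 1.5, 0.5, 1.0))
entry = sc.entry_point(sc.InjectionSpec(limbus_distance=6.0), dom)
pxy, pz = sc.angles_toward(entry, np.array([-2.0, 0.0, 0.0]))
inj = sc.InjectionSpec(
    limbus_distance=6.0, psi_xy=pxy, psi_z=pz,
    needle_depth=float(np.linalg.norm(np.array([-2.0, 0, 0]) - entry)))
cfg = sc.ScenarioConfig(mesh_h=0.8, mesh_mode="axisymmetric-2d",
                        injection=inj, horizon=30 * DAY,
                        dt_macro=0.25 * DAY, label="example")
result = sc.run_scenario(cfg)
print(result.summary)
```

Output (abridged):

```
J_omega_final:        0.0197      # 2.0% of the dose still in the vitreous at day 30
J_M_omega_final:      0.0163      # time-integrated macular fraction, 1.6%
J_R_final:            0.9641      # 96.4% cleared through the retina
peak_J_M_kg:          1.50e-09    # peak drug amount in the 2 mm macular ball
peak_time_days:       8.75        # the macular amount peaks ~9 days after injection
mass_imbalance:       4.1e-04     # discrete mass-balance audit (< 1%)
```

The Darcy stage reports a calibrated hyaloid influx of 4.167e-12 m³/s
(0.25 µL/min) that exits entirely through the retina (mass balance to
1e-14) with peak interior speeds of ~3e-7 m/s near the inflow annulus.

The same configuration expressed as YAML runs from the shell:

```sh
eyevit run --config scenario.yaml --out results/
eyevit report results/
```

and the angle/diffusion studies are sweeps over such configs
(`eyevit sweep --configs a.yaml b.yaml --out sweep.csv`). `eyevit verify`
writes the manufactured-solution convergence table (observed orders ≈ 2 in
mesh size and time step).

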