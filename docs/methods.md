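# Methods

This note documents the model, the numerical choices, and the design
decisions behind `eyevit`, in the spirit of a solver manual: what is
computed, under which assumptions, and what the defaults mean.

## Geometry

The vitreous is a solid of revolution of a modified Limaçon profile
R(q, φ̂) = q1 + q2 cos φ̂ + q3 cos³ φ̂ about the optic (x-) axis, with the
profile center offset by mx. The four scalars are estimated from
ultrasound profile points by trust-region least squares on the radial
residuals r_i − R(q, φ̂_i(mx)); both the radius r_i and the polar angle φ̂_i
depend on mx, and the analytic Jacobian accounts for this. The default
initial guess (centroid and mean radius) recovers exact synthetic data to
1e-8 mm and beats a 20⁴ brute-force grid on noisy data.

The default "average eye" is q = (11, 1.5, 0.5) mm, mx = 1 mm: axial
extent 22 mm (lens apex at x = −8 mm, posterior pole at x = +14 mm),
equatorial diameter 22 mm, volume ≈ 5.7 mL. The anterior cap subtending
60° about the anterior pole is the lens; two 10° flanking arcs form the
hyaloid annulus; the remainder (≈ 88% of the surface) is retina. All three
angles are configurable. The macula m is the posterior pole, optionally
rotated toward the optic nerve; the macular region is B_r(m) ∩ Ω with
r = 2 mm.

**Meshing.** Structured and mapping-based: a Kuhn-subdivided cube grid is
mapped smoothly onto the unit ball (spherified-cube map) and then radially
onto the Limaçon solid, which is star-shaped about its center. Boundary
facets therefore lie exactly on the surface and inherit their anatomical
marker from the profile angle of their centroid. The axisymmetric mode
meshes the *full* profile disk (area πR² for a circle) with revolution
weight π|ρ|, each profile half contributing half a revolution; the
symmetry axis falls on mesh lines so the weighted quadratures stay exact.
Axisymmetric mode is a fast path for rotationally symmetric scenarios
only; the runner refuses it when the needle tilts out of the xy-plane,
the bolus is off-axis, or gravity is lateral.

## Aqueous flow (Darcy)

v = −(κ/μ)∇p with div v = 0. Boundary conditions: n·v = 0 on the lens
(essential on the flux space); a Poiseuille profile
n·v = −c_pflow (R²_pflow − r²_pflow) over the hyaloid annulus, where
r_pflow is the 3-d distance to the circle of revolution through the
midpoint of the lens-edge-to-retina-edge gap and R_pflow is half that gap;
and the Robin relation n·v = (K_RCS/L)(p − P_v) on the retina.

Discretization: lowest-order Raviart–Thomas facet fluxes (flux-normalized
DOFs, boundary DOFs oriented outward) with elementwise-constant pressure.
The Robin term is a diagonal facet resistance; the episcleral pressure
P_v enters the right-hand side. The saddle system is solved by CG on the
pressure Schur complement with exact (sparse-LU) inner velocity solves and
a lumped-Schur preconditioner Bᵀ diag(A)⁻¹ B — a sparse cell-neighbor
Laplacian spectrally equivalent to the Schur complement (~50 CG
iterations at 1e-10 on the production mesh). The Robin term makes the pressure
unique; no gauge fixing is applied, and CG convergence asserts this. A
direct factorization of the (block-equilibrated) saddle system is kept as
a cross-check and agrees to 1e-8.

The solver is verified against the closed-form concentric-spheres solution
p(r) = A + B/r (relative weighted-L2 error 4e-7 at h = 0.5 mm) and
conserves mass between hyaloid influx and retinal outflux to 1e-14.

**Parameter defaults** (the underlying study prints none of these):

| parameter | default | rationale |
|---|---|---|
| κ (vitreous permeability) | 6e-14 m² | hydraulic conductivity κ/μ ≈ 8.4e-11 m²/(Pa·s) reported for vitreous |
| μ (aqueous viscosity) | 7e-4 Pa·s | water at ~34 °C |
| P_v (episcleral pressure) | 1200 Pa | ≈ 9 mmHg |
| K_RCS/L (retinal conductance) | 4e-12 m/(Pa·s) | few-mmHg transretinal drop at physiologic flow |
| vitreous through-flow | 10% of 2.5 µL/min | the minor aqueous outflow route; c_pflow is calibrated to it |

c_pflow is calibrated so the 1-d quadrature of the Poiseuille profile over
the revolved annulus equals the target flow; the prescribed facet fluxes
are rescaled to reproduce that total exactly on any mesh (coarse facet
quadrature would otherwise clip a few percent off the clamped parabola).

## Drug transport

∂C/∂t + (v·∇)C − ∇·(D∇C) = 0, with C = 0 on the hyaloid (no upstream
diffusion against the inflow), zero flux at the lens, and the retinal
Robin condition −D ∂C/∂n = (P + (n·v)(k−1)) C. The grouping of the
advective terms in the retinal condition is ambiguous as typeset in the
literature; the implemented reading treats (P + (n·v)k)C as the *total*
outflux (advective plus diffusive), and a `robin_total_flux` switch
selects the alternative where that expression is the diffusive flux alone.
With the default partition coefficient k = 1 the two readings coincide.

Space: P1 elements (with the axisymmetric weight where applicable),
degree-2 quadrature. Convection is assembled in non-divergence form with
the RT0 Darcy velocity evaluated at quadrature points; no SUPG
stabilization is applied by default because the cell Péclet numbers at
default resolution are O(10⁻²)–O(10⁻¹) (speeds ≤ 3e-7 m/s, h ≈ 1 mm,
D ≥ 2e-11 m²/s).

Time: the fractional-step θ scheme with θ = 1 − √2/2 and sub-step
implicitness α = (1 − 2θ)/(1 − θ), β = 1 − α. This classical choice makes
the implicit coefficient αθΔt identical in all three sub-steps, so one ILU
factorization serves the whole horizon; the scheme is second-order and
strongly A-stable (verified: observed temporal order 1.96 on a
space-exact manufactured solution; bounded at 10× steps). Sub-systems are
solved by ILU-preconditioned GMRES to a 1e-10 relative residual. Macro
step: 0.25 days by default (0.5 days in the test context), halved during
the first day to resolve the bolus transient.

The initial bolus is a uniform ball (default: 1.25 mg in 0.05 mL, radius
2.285 mm — the bevacizumab convention) interpolated onto mesh nodes and
scaled by lumped-mass quadrature, which preserves the dose exactly
(the lumped masses are the P1 basis integrals). All four therapy
functionals are dose-invariant by construction except J_M, which is
proportional to the dose.

Gravity settling: an additional drift v_settle · g(t) with a
piecewise-constant orientation schedule (standing −z; lying on the back
+x; left/right ∓y, left-eye convention, entry meridian +y). The default
Stokes estimate 2Δρ g a²/(9μ) for a ~5 nm, 148 kDa antibody gives
2.7e-11 m/s — micrometres per day, which is why head orientation barely
matters for dissolved drug. A larger value can be passed to emulate
settling suspensions. Convection is re-assembled at orientation switches
when the settling speed is nonzero.

**Transport defaults**: D = 4e-11 m²/s (bevacizumab, measured in rabbit
vitreous; 2e-11 and 8e-11 are the comparison values), k = 1, and retinal
drug permeability P = 5e-9 m/s. P is not printed in the underlying study;
the default was fixed a priori from the Robin-eigenvalue structure of a
near-diffusion-limited retina (Biot number Pa/D ≈ 1–3 over the studied D
range, month-scale washout) and sits in the literature range for
macromolecules. It was not adjusted afterwards.

## Functionals

J_Ω(t) = ∫C(t)/∫C(0); J_M(t) = ∫_{B_r(m)∩Ω} C(t); J_{M,Ω}(T) =
∫₀ᵀ J_M/∫C(0) dt with **t measured in days** (the study's plotting unit;
the time unit is not stated with the formula, and the partition below
inherits this choice); J_R(T) = 1 − J_Ω(T) − J_{M,Ω}(T). The conservation
form of J_R is used because the printed drug-fate partitions satisfy it;
the typeset formula (with + J_{M,Ω}) does not produce a partition.
J_{M,Ω} overestimates the drug able to act at the macula because transport
into the region takes time; this caveat carries over from the source
model.

Ball–domain intersections are integrated by quadrature-point membership
with one level of midpoint cell subdivision near the sphere; a point
exactly on the sphere counts as inside. The region functional is
precomputed as a fixed weight vector, so repeated evaluation is a dot
product. Verified against the interior-ball volume, the two-sphere
intersection formula for a boundary-centered ball (1%), and region
saturation.

## Verification

* **Spatial order**: steady trigonometric manufactured solution (with the
  correct axisymmetric Laplacian c_xx + c_ρρ + c_ρ/ρ in profile mode) and
  a horizon of ~10 diffusive relaxation times, so the A-stable scheme
  settles onto the discrete elliptic solution and the measured L2 error is
  purely spatial. Observed order ≥ 1.9 (superconvergent on the finest
  structured levels).
* **Temporal order**: a separable solution linear in space (exactly
  representable in P1) isolates the time error; observed order ≈ 1.96.
* **Mass audit**: every run tracks the retinal outflux by boundary
  quadrature of (P + (n·v)k)C and the hyaloid loss by the Dirichlet
  reaction (the residual of the unconstrained equations at constrained
  nodes, which is the exact discrete flux); initial mass = remaining +
  retinal + hyaloid within 0.1% at default resolution, and the defect
  shrinks under refinement.

## What the synthetic data does and does not emulate

The synthetic ultrasound fixture places 164 points (the per-scan count of
the clinical protocol) on a known Limaçon with radial Gaussian noise; it
exercises the fitting pipeline but contains no segmentation artifacts,
probe distortion, or inter-patient variability, so passing fit tests
bounds algorithmic error only, not clinical geometry error. The
physiological defaults above are literature-sourced, not patient-fitted;
quantities that depend on them (absolute peak times, clearance fractions)
are model outputs under those defaults. The orderings the model produces —
steeper injection angles deliver less drug to the macula, exposure
decreases monotonically as the needle tilts out of the optic plane,
heavier (slower-diffusing) molecules linger longer in the vitreous, head
orientation is irrelevant for dissolved drug — are robust to these
defaults; the absolute macular-exposure percentages are not, and are
additionally sensitive to the time-unit convention in J_{M,Ω} noted above.

## Known limitations

* Homogeneous vitreous; no liquefaction, no viscoelasticity, no
  fluid–structure interaction.
* No drug–VEGF binding or degradation kinetics (transport only); the
  hyaloid is a perfect sink (no anterior-chamber coupling).
* Pure Galerkin transport: small negative undershoots (≤ 0.5% of the
  initial concentration) near the bolus edge at coarse resolution.
* The structured mesh is not exactly mirror-symmetric (Kuhn subdivision
  picks a diagonal), so mirrored scenarios differ by the discretization
  asymmetry, ~1% in the functionals at h = 1.25 mm.
* Anisotropic diffusion supports a constant SPD tensor only (no fiber
  orientation field).
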