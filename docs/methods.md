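# Methods

This note records the model, the numerical choices and their rationale, and
what the tests do and do not demonstrate.

## Tissue model

Both urethral layers are isotropic, nearly incompressible, one-term Ogden
solids on the isochoric principal stretches,
W = (2μ/α²)·Σᵢ(λ̄ᵢ^α − 3) + κ/2·(J − 1)², with λ̄ᵢ = J^(−1/3)·λᵢ.
Several Ogden conventions circulate; this one is adopted because under it
μ is exactly the small-strain shear modulus (linearising W gives shear
modulus μ independent of α), which is the only reading under which a
statement like "μ = 20 kPa, α = 6.178" is meaningful on its own. The
closed-form incompressible uniaxial nominal stress is then
P(λ) = (2μ/α)(λ^(α−1) − λ^(−α/2−1)); `alpha = 2` recovers the neo-Hookean
model exactly, which the tests assert to machine precision.

Parameters: μ = 20 kPa for the dense connective lining, μ = 1.1 kPa for
the spongiosum, α = 6.178 shared by both layers. Incompressibility is
enforced weakly by the volumetric penalty with κ = bulk_factor·μ,
bulk_factor = 1000 by default. No bulk behaviour is measured for these
tissues; the penalty is a numerical regularisation of the incompressible
limit, and tests probing that limit (the rigid-disc response) tighten
bulk_factor rather than reinterpreting the default. Viscoelasticity is out
of scope: the identification operates on near-equilibrium curves.

The titanium device body (E = 114 000 MPa, ν = 0.315) is seven orders of
magnitude stiffer than the tissue and is treated as kinematically rigid in
the simulations; its linear-elastic material object carries the printed
constants (converted to kPa internally) as metadata and supports the unit
system through a small-strain stress evaluation.

Units are mm–kPa throughout; forces are per unit out-of-plane thickness
(mN/mm).

## Parameter identification

For fixed α the uniaxial model is linear in μ, so the least-squares
optimal μ has a closed form (variable projection). The fit therefore
reduces to a one-dimensional search in α, run from five log-uniform
multi-starts within the bounds plus the user's initial guess, followed by
a bounded two-parameter least-squares polish. This avoids the long
μ–α trade-off valley that defeats naive two-parameter descent from remote
starts, makes the fit exactly scale-equivariant (scaling the stresses by c
scales μ̂ by c and leaves α̂ unchanged), and recovers generating parameters
from noise-free synthetic curves to better than 0.1% from arbitrary
admissible starts. Misfit is measured on nominal stress, the quantity a
tensile test reports. A `fit_ogden_shared` variant fits several curves
jointly with a common exponent, covering the shared-α reading of a
two-layer identification.

The synthetic-curve generator evaluates the closed form on a uniform
stretch grid (default [1, 1.5], 50 points) and optionally applies
independent multiplicative Gaussian noise with a prescribed coefficient of
variation. It emulates a median tensile curve with homoscedastic relative
noise; it does not emulate specimen-to-specimen variability, preload
artefacts, toe-region gauge effects or relaxation residues, so parameter
recovery on these curves demonstrates the correctness and conditioning of
the inverse analysis, not the fidelity of any particular experiment.

## Geometry and meshing

The cross-section (outer radius 5 mm, elliptical lumen with full axes
1.6 mm and 8 mm — semi-axes 0.8/4.0 mm, the only reading that fits inside
the outer radius — and a 0.14 mm lining) is meshed with a structured
O-grid: the ellipse is sampled uniformly in arc length, the lining is
extruded along the local normal in at least two conforming element layers,
and the spongiosum fills straight rays to the outer circle. The offset
band is valid because the lining thickness (0.14 mm) stays below the
minimum curvature radius of the ellipse at its tips (b²/a = 0.16 mm); the
geometry validator rejects thicker linings. Elements near the tips are
strongly graded — the price of a conforming thin band around a 5:1
ellipse. The resting elliptical shape is taken as the stress-free
reference. Quarter-symmetry meshes carry exact axis nodes; full meshes are
generated by reflecting the quarter rows so that symmetry holds to
round-off.

## Solver

Plane-strain, quasi-static, total-Lagrangian with internal forces
integrated on the deformed configuration. 4-node quadrilaterals with 2×2
Gauss integration of the deviatoric term and the volumetric penalty
evaluated at the element centroid (selective reduced integration). This
avoids volumetric locking while keeping the deviatoric term fully
integrated (no hourglass modes); the consequence, visible in the tests, is
that incompressibility is controlled in the element mean (|J̄ − 1| < 0.01
in the device runs) while pointwise J inside the few nearly degenerate
tip elements can deviate much further under full occlusion. An implicit
scheme is used rather than explicit dynamics: at this scale determinism,
equilibrium certification at every output state, and tight tolerances
matter more than robustness to extreme distortion.

The global tangent is assembled from forward finite differences of the
exact element internal-force vector (step 10⁻⁷ mm), batched over all
elements and all eight element dofs in one vectorised evaluation; follower
pressure loads contribute an analytic load stiffness, and contact blocks
are differenced the same way. The residual, not the tangent, defines
equilibrium, so this costs a constant factor in assembly time and no
accuracy. Newton convergence is measured as the free-dof residual norm
relative to the largest of the internal, external and contact force norms
(full vectors, so pure-Dirichlet problems scale by their reactions);
default tolerance 10⁻⁶. The line search tolerates a bounded residual
spike at full step length — routine for follower loads and fresh contact —
backtracks on element inversion, and rejects trial iterates that deepen
contact penetration far beyond its current level. Load stepping marches
between ramp targets with halving on failure and 1.5× regrowth on success;
the floor sits a few halvings below the nominal cutback budget because
contact engagement on tissue this soft (the lumen snaps shut at ~0.1 kPa
of the 8 kPa ramp) locally demands increments of ~10⁻⁴ of the ramp while
the rest runs at full step.

### Contact

Normal contact is a penalty (default stiffness 100·max(μ)/element size,
giving penetrations at the 10⁻³ mm gap-tolerance scale at working contact
pressures) with a C¹-smooth quadratic activation over the first gap
tolerance. Friction is penalty-regularised Coulomb: an elastic stick force
saturated smoothly (tanh) at μ_f·N, with spatial anchor points
return-mapped after each converged load step — friction is therefore
treated incrementally per step, an approximation documented here because
anchors do not persist through unloading (no unloading occurs in these
scenarios). Converged states with penetration beyond ten gap tolerances
raise an instability error rather than returning silently.

Three conditions: (i) rigid circles for the intraluminal device — the gap
to the union of circles is smoothed by a log-sum-exp softmin (width
5·10⁻³ mm) with matching blended normals, which keeps Newton stable where
the arm tips deploy tangentially to the body; (ii) a rigid plane, used for
elementary checks and as the quarter-symmetry reduction of lumen
self-contact (mirror symmetry makes the symmetry plane the contact plane
and eliminates relative slip, so the 0.02 self-friction coefficient is
exactly irrelevant in quarter mode); (iii) node-to-segment self-contact of
the lumen boundary in full-model mode, normal-only — the 0.02 coefficient
caps tangential tractions at 2% of normal ones on a nearly slip-free
closing motion, well below discretisation error. Self-contact pairing is
refreshed on every residual evaluation while the iterate is far from
equilibrium and frozen once the residual falls below 10⁻³ of its reference,
because re-pairing below discretisation accuracy can cycle between two
equivalent assignments and stall the polish phase.

## Device scenarios

**Cuff.** The wrapped band-plus-blister is idealised as a uniform follower
pressure on the outer boundary equal to the blister pressure (default
8 kPa, the upper end of the 6–8 kPa clinical band), ramped linearly in 40
steps. Rationale: the fibre-reinforced supporting band is nearly
inextensible, so at the mid-section — where the headline metrics are
evaluated — the blister pressure is transmitted essentially unchanged.

**Shaft.** Insertion and fixation are collapsed into one contact-driven
expansion: a central rigid circle grows from an inscribed radius to the
device radius (3.5 mm) over the first 70% of the ramp, then four rigid arm
tips (radius 0.5 mm, one per quadrant at 45°) translate radially outward
until they protrude by δ beyond the body. The arm expansion δ is not a
printed quantity for the real device; the default is 0.5 mm with a
{0.25, 0.5, 1.0} mm sensitivity sweep in the tests, and only ordering
properties (tensile stress monotone in δ; tensile-dominated versus the
compressive cuff) are asserted, never absolute shaft magnitudes. The valve
threshold pressure (16 kPa) and device length are carried as metadata; the
valve, its magnetics and urine flow are outside the mechanical scope.

## Stimulation metrics

Compressive strain is |min principal logarithmic strain|·100, tensile
strain max(0, max principal log strain)·100; compressive/tensile stress
are the corresponding extreme principal Cauchy stresses clipped at zero;
hydrostatic pressure is −tr σ/3, positive in compression so that reported
values are positive for a squeezed tissue. The logarithmic strain measure
and the compression-positive pressure sign are adopted conventions,
recorded here because the quantities being reproduced do not name theirs.
Summaries are five-number box-plot statistics with 1.5·IQR whiskers
clipped to the data range, using a weighted generalisation of the linear
rank-interpolation ("type 7") quantile with reference-configuration area
weights at the integration points; weighting by current area or by count
changes the medians by well under the reproduction tolerances, and the
choice is toggleable through the `weights` argument of `summarise`.
Lumen closure is 1 − (deformed/initial cavity polygon area), with the
quarter polyline closed through the origin.

## Problem sizes and verification scope

The reference runs use the quarter-symmetry cross-section at 0.2 mm
elements (330 elements, 368 nodes; mesh-sensitivity checks at 0.25 and
0.15 mm move the reported medians by under 1%), 40 load steps for the
cuff and 60 for the shaft. The solver-versus-oracle comparison uses the
two-layer annulus at 0.1 mm elements (1932 elements), where the
inner-radius displacement matches the semi-analytic tube solution to
0.04% and element-mean radial stress to under 2% of the load scale. The
quarter/full symmetry comparison runs both models at 0.4 mm and agrees on
the section medians to 0.1%.

One reproduction bound is not met and is reported as such rather than
adjusted: the area-weighted median compressive strain over the occluded
cuff section. In plane strain with near-incompressible tissue, in-plane
straining is kinematically bounded by the cavity the lumen provides
(≈10 mm² against 68 mm² of tissue), so once the lumen is closed most of
the section sits in a nearly hydrostatic state and the median compressive
strain settles near 6%. A three-dimensional cuff additionally extrudes
tissue axially from under the cuff, which compresses the whole mid-section
through its thickness and drives the median strain several-fold higher.
The stress-like medians (compressive stress and hydrostatic pressure
≈ the applied 8 kPa) are insensitive to this reduction and meet their
bounds; the strain median is a documented limitation of the plane-strain
idealisation, not a tunable discrepancy.

## Known limitations

* Plane strain cannot represent axial tissue extrusion (above) or the 3-D
  wrapping mechanics of the cuff band; metrics are section-local.
* Friction is incremental per load step and self-contact is normal-only;
  both are small-μ_f approximations appropriate to these scenarios but not
  to high-friction or cyclic loading.
* The shaft scenario's absolute magnitudes depend on the unprinted arm
  expansion δ and tip geometry; only ordering statements are claimed.
* The penalty formulation admits gap-tolerance-scale penetrations and
  pointwise (sub-element) volumetric deviations at strongly distorted
  elements; element-mean quantities are the controlled ones.
* The synthetic tensile curves and the idealised geometry mean that
  passing tests certify the numerics and the stated model, not predictive
  accuracy for any individual urethra.
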