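# aussim

Plane-strain finite-element analysis of the mechanical stimulation that
artificial urinary sphincters (AUS) impose on urethral tissue.

Artificial sphincters restore continence either by squeezing the urethra
from outside (extraluminal cuff devices, inflated to a 6–8 kPa blister
pressure) or by occupying the lumen and pinning themselves to the wall with
expanding shaft arms (intraluminal valve devices). Both actions load the
urethral wall mechanically, and excessive compressive or tensile
stimulation is implicated in vasoconstriction, atrophy and erosion — the
dominant failure modes of these implants. `aussim` quantifies that
stimulation on a cross-section of the urethra: it builds a two-layer
hyperelastic model of the wall, applies either device scenario through a
nonlinear contact solver, and reports the stimulation metrics used to
compare devices — compressive/tensile principal strain and stress and
hydrostatic pressure, summarised as area-weighted box-plot statistics.

## Model

The urethral wall is a 5 mm radius cylinder with an elliptical lumen
(full axes 1.6 mm × 8 mm) lined by a 0.14 mm band of dense connective
tissue; the remaining wall is spongiosum. Both layers are isotropic,
nearly incompressible, one-term Ogden solids,

$$W = \frac{2\mu}{\alpha^2}\left(\bar\lambda_1^{\alpha} +
\bar\lambda_2^{\alpha} + \bar\lambda_3^{\alpha} - 3\right)
+ \frac{\kappa}{2}(J-1)^2 ,$$

with μ = 20 kPa (lining), μ = 1.1 kPa (spongiosum) and α = 6.178 for both
layers; μ equals the small-strain shear modulus in this convention, and the
incompressible uniaxial nominal stress is
P(λ) = (2μ/α)(λ^(α−1) − λ^(−α/2−1)). The parameters are identified from
uniaxial tensile curves by variable-projection least squares
(`aussim.identification`), and the structural response is verified against
a semi-analytic solution for the inflation of a two-layer incompressible
tube (`aussim.semi_analytic`).

The solver (`aussim.solver`) uses 4-node quadrilaterals with selective
reduced integration of the volumetric penalty, follower pressure loads,
penalty contact ("hard" normal contact, regularised Coulomb friction:
0.02 for lumen self-contact, 0.1 between device and tissue), Newton
iteration with finite-difference consistent tangents, and adaptive load
incrementation. Device scenarios live in `aussim.devices`:

* **cuff** — uniform external pressure ramped to 8 kPa, occluding the
  lumen through self-contact;
* **shaft** — a rigid Ø7 mm cylinder expanding inside the lumen, followed
  by four rigid arm tips protruding a further δ (default 0.5 mm) to pin
  the device by stretching the wall.

## Worked example

```python
from aussim import URETHRA_LINING, URETHRA_SPONGIOSUM
from aussim.devices import CuffScenario, cuff_loading
from aussim.geometry import CrossSectionSpec, build_cross_section
from aussim.postprocess import stimulation_report
from aussim.solver import solve

mesh = build_cross_section(CrossSectionSpec(), target_element_size=0.2)
loading, contacts = cuff_loading(CuffScenario(pressure_kPa=8.0, n_steps=40), mesh)
states = solve(mesh, {"lining": URETHRA_LINING, "spongiosum": URETHRA_SPONGIOSUM},
               loading, contacts=contacts)
report = stimulation_report(states[-1], mesh)
print(f"lumen closure fraction    {report.lumen_closure_fraction:.3f}")
print(f"median compressive strain {report.compressive_strain.median:.2f} %")
print(f"median compressive stress {report.compressive_stress.median:.2f} kPa")
print(f"median hydrostatic press. {report.hydrostatic_pressure.median:.2f} kPa")
print(f"median tensile stress     {report.tensile_stress.median:.3f} kPa")
```

prints

```
lumen closure fraction    0.998
median compressive strain 6.30 %
median compressive stress 8.19 kPa
median hydrostatic press. 8.06 kPa
median tensile stress     0.000 kPa
```

The 8 kPa cuff fully occludes the lumen and transmits essentially the full
blister pressure into the wall (median compressive stress and hydrostatic
pressure ≈ 8 kPa) while producing no tensile stress — the cuff is a purely
compressive stimulus. Running the shaft scenario instead
(`aussim.devices.shaft_loading`) reverses the picture: a much lower median
compressive stress but substantial tensile stress and strain from the wall
stretching, which is the mechanical signature of the pinning fixation.

The same simulations are available from the shell:

```sh
aussim fit --mu 20 --alpha 6.178          # parameter-recovery self-check
aussim simulate-cuff --pressure 8 --element-size 0.2 --steps 40
aussim simulate-shaft --delta 0.5
aussim simulate-inflation --pressure 2
aussim run config.yaml                    # fully configured run
```

Each run writes a deterministic stimulation report (CSV), the mesh and
final fields (legacy VTK) and a convergence log into the output directory.

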