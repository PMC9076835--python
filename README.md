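# pappus

Mechanical modelling and image/AFM analysis of the dandelion pappus
actuator — the small disk of tissue (the *apical plate*) at the top of a
dandelion fruit that opens and closes the parachute of hairs in response
to humidity.

The package is aimed at plant biomechanics researchers who want to
reproduce, perturb, or extend the actuator analysis without any wet-lab
inputs: every stage can be exercised on the published parameter tables and
on synthetic data generated in-package.

## What it computes

**Forward model.** The hydrated longitudinal section of the apical plate
is built parametrically from nine measured lengths (plate diameter *D* and
height *H*, podium radius *R* and height *H*<sub>pod</sub>, side-region
size *W*<sub>side</sub> × *H*<sub>side</sub>, vasculature width
*W*<sub>vasc</sub>, basal cavity diameter *D*<sub>cavity</sub>, and the
prescribed vascular-base displacement *d*<sub>vasc</sub>). Four tissue
regions — floral podium, vasculature, lipid-rich sides, and cortex —
surround a central cavity. Dehydration is modelled as plane-strain,
isotropic, linear elasticity with a region-wise shrinkage eigenstrain

> ε\* = (√(1 − s) − 1) · I,

where *s* is the region's intrinsic swelling factor (fractional area lost
if dried in isolation). Region stiffness is proportional to measured
relative cell-wall density; all regions share one Poisson ratio (ν = 0.29).
The model's main output is the **holding angle θ**: the tilt, away from
vertical, of the line from the plate's upper corner to the lowest point of
the side region's lateral edge in the dry state. Larger θ = wider-held
(open) pappus.

**Around the model:**

- `pappus.fitting` — calibrates the four swelling factors to measured
  regional expansions (Nelder–Mead over a cached stiffness factorization);
- `pappus.sensitivity` — one-at-a-time dimensionless sensitivities of θ
  and first-order (delta-method) prediction of correlations between θ and
  co-varying geometric parameters;
- `pappus.strainmap` — landmark-based deformation mapping between dry and
  wet images: Delaunay triangulation, wet/dry area ratios with outline and
  overlap exclusions, neighbourhood smoothing, principal stretches (SVD of
  the per-triangle deformation gradient), 40 %-overlap region assignment,
  circularity (4π·Area/Perimeter²);
- `pappus.afm` — AFM force-curve processing: baseline flattening, contact
  point, tip–sample separation, Sneddon conical-indenter fit
  *F* = *E*/(1 − ν²) · (2 tan α/π) · δ² (α = 18°, ν = 0.5), 160 nN
  adhesion filtering, per-region median moduli;
- `pappus.synth` — seeded generators for landmark sets with known regional
  area factors, seven-segment Sneddon force curves, and correlated samples
  of the geometric parameters.

## Worked example

```python
from pappus import solve_reference_state, substitute_materials, MaterialParams

state = solve_reference_state(target_edge=3.0)
print(f"holding angle theta = {state.theta:.1f} deg")
for region, rec in state.area_change.items():
    print(f"{region:12s} wet/dry area ratio = {rec['wet_over_dry']:.2f}")

inverted = solve_reference_state(
    materials=substitute_materials(MaterialParams(),
                                   {"vasculature": "side", "podium": "side"}),
    target_edge=3.0)
print(f"vasculature+podium built from side tissue: theta = {inverted.theta:.1f} deg")
```

prints

```
holding angle theta = 17.9 deg
podium       wet/dry area ratio = 1.78
vasculature  wet/dry area ratio = 1.25
side         wet/dry area ratio = 2.10
cortex       wet/dry area ratio = 1.70
vasculature+podium built from side tissue: theta = -16.1 deg
```

The reference model opens the pappus by about 18°; the stiff, low-swelling
vasculature expands least (≈ 25 % in area versus 70–110 % elsewhere),
anchoring the surrounding tissue — and giving the vasculature and podium
the highly swelling side-region material inverts the actuator (negative θ).

A command-line interface mirrors the library
(`pappus solve|geometry|fit|sensitivity|strainmap|afm|synth`, see
`pappus --help`).

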