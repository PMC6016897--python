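# valvegeom

Parametric geometry of the fully open human pulmonary valve.

The pulmonary valve has three semilunar cusps (anterior, left, right) on a
roughly circular annulus. When the valve is fully open the three cusps line
the wall of the outflow tract, and each cusp can be idealized as **one third
of a circular cylindrical shell** whose free (upper) edge is a smooth arch.
`valvegeom` implements that idealization as a small library and CLI for
people who need clean, parameterized valve surfaces: computational-anatomy
and cardiac-simulation groups who want a geometric starting point before
adding tissue mechanics, and anyone reproducing or extending published
valve morphometrics.

## The model

One cusp of an *n*-cusp valve (n = 3 for the pulmonary valve) is the
surface

```
(θ, ζ)  ↦  ( r cos θ,  r sin θ,  ζ · h sin(kθ) ),
θ ∈ [0, 2π/n],   ζ ∈ [0, 1],
```

with the valve axis along +z and the annulus in the plane z = 0. The
parameters come from two measurable lengths:

- **W** — cusp width, the arc length along the annulus between the two
  commissures. Since one cusp subtends 2π/n, the annulus radius is
  `r = W·n/(2π)`.
- **h** — maximum cusp height, reached at the cusp midline.

The free edge is a sine arch in the *developed* (flattened) plane,
`z(x) = h·sin(πx/W)` with `x = rθ` the arc-length coordinate, which pins
the edge to zero at both commissures; on the cylinder this means a
wavenumber `k = πr/W = n/2`. Because a cylinder is developable, flattening
is an isometry and the cusp area has the closed form

```
A_cusp = ∫₀^W h sin(πx/W) dx = 2hW/π.
```

The full valve is n copies of the cusp rotated about the axis by multiples
of 2π/n. The effective orifice ("valve flap") area is obtained from the
total cusp area via the cadaveric literature ratio flap : valve = 1 : 1.55.

The package covers: cusp construction from (W, h, n), least-squares fitting
of the sine free edge to sampled boundary points, derived morphometrics
(annulus diameter/circumference, cusp/valve/orifice areas) with descriptive
z-scores against a bundled cadaveric reference table, triangulated mesh
generation and export (binary/ASCII STL, OBJ, PLY, legacy VTK), and
synthetic morphometric cohorts for end-to-end testing. Tissue mechanics,
valve closure, and the cardiac cycle are out of scope.

## Worked example

The reference instance uses W = 20.211 mm, h = 14.20 mm, n = 3:

```sh
$ valvegeom measure
cusp area (mm^2)                182.7075
annulus diameter (mm)            19.3001
annulus circumference (mm)       60.6330
valve area (mm^2)               548.1224
orifice (flap) area (mm^2)      353.6273
flap-to-valve ratio               1.5500
number of cusps                        3

comparison with cadaveric reference (mean ± SD):
               metric    value ref_mean  ref_sd       z  within_1sd
            cusp_area 182.7075 238.7100 63.4700 -0.8823        True
     annulus_diameter  19.3001  18.2000  3.2000  0.3438        True
annulus_circumference  60.6330  57.1770 10.0530  0.3438        True
         orifice_area 353.6273 456.6000 106.6200 -0.9658        True
```

Reading the numbers: the 20.211 mm width yields an annulus radius of
9.65 mm, hence a 19.3 mm diameter and a 60.633 mm ring circumference; one
cusp carries 2hW/π ≈ 182.71 mm² of shell surface, the three-cusp valve
548.12 mm², and dividing by the 1.55 area ratio gives a 353.63 mm²
effective orifice. All four metrics sit well within one standard deviation
of the cadaveric reference means, which is the model's plausibility check.

Mesh export and boundary fitting from the same defaults:

```sh
valvegeom generate --out valve.stl --resolution 128x64   # assembled valve
valvegeom fit edge_points.txt --measure                  # fit sine edge, then measure
valvegeom cohort --n 1000 --seed 42 --out cohort.csv     # synthetic cohort
```

The same operations are available as library functions
(`make_cusp`, `valve_areas`, `fit_sine_boundary`, `assemble_valve`,
`write_mesh`, `sample_cohort`).

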