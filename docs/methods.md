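# Methods

## Model and assumptions

The fully open pulmonary valve is modelled as n identical cusps
(default n = 3) tiling a circular cylindrical shell of radius r about the
valve axis. The assumptions inherited from the underlying anatomical
idealization are:

1. **Symmetry** — the cusps are identical and related by rotations of
   2π/n about the axis (for n = 3, the cusp midlines are 120° apart), so a
   single cusp determines the valve.
2. **Cylindrical shell** — in the fully open configuration each cusp lies
   on the cylinder x² + y² = r²; the model covers this configuration only,
   not closure or motion through the cardiac cycle.
3. **Smooth free edge** — the unattached upper boundary is even and
   smooth, and is represented by a single-arch sine. In the developed
   plane, z(x) = h·sin(πx/W) for x ∈ [0, W].
4. **No mechanics** — no thickness, elasticity, stress–strain behaviour,
   external force field, or cusp contact/coaptation is modelled.

The surface of one cusp is

    (θ, ζ) ↦ (r cos θ, r sin θ, ζ·h·sin(kθ)),  θ ∈ [0, 2π/n], ζ ∈ [0, 1].

The interior coordinate ζ scales the local free-edge height, so the
parameter domain is a fixed rectangle regardless of shape — this makes
structured meshing trivial and is equivalent to bounding z by the edge
curve directly.

## Parameters

| symbol | meaning | units | default | origin |
|---|---|---|---|---|
| W | cusp width (annulus arc between commissures) | mm | 20.211 | published model instance |
| h | maximum cusp height (free edge to attachment midpoint) | mm | 14.20 | published model instance |
| n | number of cusps | – | 3 | tricuspid pulmonary valve |
| r | annulus radius, derived: r = W·n/(2π) | mm | 9.650 | arc-length relation x = rθ |
| k | free-edge wavenumber, derived: k = πr/W = n/2 | – | 1.5 | edge pinned at both commissures |
| ratio | flap : valve area ratio | – | 1.55 | cadaveric literature value |

The library always derives k = n/2 exactly. The published instance prints
the equivalent constant as 9650π/20211 ≈ 1.499994 — the exact value rounded
through the printed width — and the `CuspParameters` constructor accepts a
caller-supplied wavenumber only if it closes the edge at the far commissure
to relative 1e−6; the 9650π/20211 constant deviates from 3/2 by 4.3e−6 and
is therefore treated as a rounded citation, not a constructible parameter.

Defaults are noted because the reference width/height (20.211, 14.20) are a
single model instance, not population means: the bundled per-cusp
morphometric table has widths ≈ 21.4–21.6 mm and heights ≈ 11.8–12.1 mm.
The library takes dimensions as inputs and does not attempt to reconcile
the two; the cohort generator uses the population table, the measurement
defaults use the model instance.

## Derived morphometrics

- circumference C = 2πr = n·W; diameter D = 2r.
- cusp area A = 2hW/π (exact; developability makes the 3-D shell area equal
  the flattened area under the sine).
- valve area = n·A; orifice (flap) area = valve area / ratio. "Orifice
  area" and "flap area" name the same quantity; the report uses one field.
- Comparison with the bundled cadaveric mean ± SD row is by descriptive
  z-scores z = (value − mean)/SD with an |z| ≤ 1 flag; no inference is
  implied.

The closed form for the reference instance gives 182.707 mm² per cusp; the
published comparison row lists 182.6220 mm², 0.05% lower, plausibly from a
coarse numerical integration whose discretization is not stated. The
library reports the closed form as canonical and provides the mesh
quadrature (`cusp_area_quadrature`) as an independent route that approaches
it from below under refinement.

## Free-edge fitting

`fit_sine_boundary` fits z(x) = A·sin(πx/W) to sampled (x, z) points.

- **W fixed**: linear least squares in A, with SE(A) from the residual
  variance and the Gram sum Σ sin²(πxᵢ/W).
- **W free**: bounded nonlinear least squares (`scipy.optimize.least_squares`,
  trust-region reflective; ftol = xtol = gtol = 1e−15) over (A, W) with
  A ≥ 0 and W > 0. The objective has spurious minima where W is an integer
  fraction of the truth (sine aliasing); the optimizer therefore starts at
  W₀ = 2·x_peak (twice the abscissa of the largest sampled height), which is
  a consistent estimator of the correct basin centre whenever the samples
  cover the cusp, falling back to 2·(x range) if the peak sits at x = 0.
  Standard errors come from the residual variance and (JᵀJ)⁻¹ at the optimum.

Noiseless samples of a true sine are recovered to relative 1e−9 or better;
the three-point instance {(0,0), (W/2, A), (W, 0)} is recovered to machine
precision. With additive Gaussian noise the 3·SE interval around the true
amplitude covers ≈ 99.7% of replicates, which the test suite checks at the
≥ 99% level over 500 seeded replicates (500 points, σ = 0.2 mm).

## Meshing and export

A cusp mesh is a structured grid over the (θ, ζ) rectangle, each quad split
into two triangles wound counter-clockwise seen from outside the cylinder
(outward radial normals). The grid columns at the commissures collapse to
points (edge height → 0); vertices are welded at 1e−9 mm and collapsed
faces dropped, so exported meshes contain no degenerate triangles. The
assembled valve is n rotated copies welded along the shared commissure
lines; it is an open surface (no annulus cap or sinus walls), exactly what
the parameterization defines.

Triangulated area converges to 2hW/π at second order in the angular step
(empirical order ≈ 2.00 over refinement doublings; relative error ≈ 1e−6
at a 1024×512 grid). Because the surface is ruled in ζ, the z-resolution
does not affect the area error.

Formats follow each format's own convention: OBJ indices are 1-based on
disk (0-based in memory); STL stores an unindexed triangle soup with
float32 coordinates in the binary variant; PLY and legacy-VTK POLYDATA
store indexed triangles. ASCII writers print 17 significant digits so
round-trips are exact at float64. All writes go to a temporary file in the
target directory followed by an atomic rename, so a failed run never
leaves a partial file.

## Synthetic cohorts

`sample_cohort` draws per-cusp (width, height) pairs from independent
normal distributions with the bundled per-cusp mean ± SD, truncated at
zero by resampling (a length cannot be nonpositive; with the default
parameters the truncated mass is < 1e−6, so the bias is negligible).
Normality is the conventional reading of a "mean ± SD" report; no
distribution family or width–height covariance is published, so draws are
independent. `sample_boundary_points` places x uniformly on [0, W] and adds
Gaussian noise to the exact edge height. All sampling takes an explicit
integer seed and is bit-for-bit reproducible.

What the generator does **not** emulate: measurement protocol artefacts,
inter-cusp correlation within a heart, pathological shapes (stenosis,
distorted lobular edges), or non-Gaussian population tails. Passing the
recovery and cohort tests therefore shows the pipeline is correct and
well-calibrated under the stated distributional model, not that the model
captures every feature of cadaveric data.

## Numerical choices

- Closed-form identities are tested at relative 1e−12; fitted or iterative
  quantities at 1e−6 unless stated otherwise.
- Domain checks tolerate 1e−9 (scaled) at interval endpoints so that exact
  endpoint samples from `linspace` are accepted.
- The far-commissure edge height is clipped at zero (sin(π) evaluates to
  ≈ 1.2e−16, which would otherwise leak a negative height of ~1e−15 mm).
- Vertex welding uses coordinate rounding at 1e−9 mm; commissure seams in
  the assembly coincide to ~1e−15 mm, far inside that tolerance.
- Problem sizes in the test suite (mesh grids up to 1024×512, 500 fit
  replicates, 10⁴-per-cusp cohorts) were chosen as the smallest sizes at
  which the asymptotic claims (second-order convergence, 3·SE coverage,
  3·SE mean agreement) are comfortably resolved.

## Known limitations

- The model is a single-surface geometric idealization: no thickness,
  mechanics, or dynamics, and the assembled valve does not model cusp
  coaptation — adjacent cusps meet only along commissure lines.
- Real cusps are not symmetric; per-cusp differences in the population
  table (≈ 1% in width, ≈ 2% in height) are ignored by the symmetric
  assembly.
- The sine free edge is a one-parameter arch; real free edges deviate from
  it, and the fit reports residual RMS so users can judge adequacy.
- The flap-to-valve ratio 1.55 is a literature constant applied uniformly;
  it is exposed as an input rather than derived from the geometry.
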