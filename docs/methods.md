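# Methods

## Detection model

A fluorophore at depth `x` µm below the block-face is imaged through the
tissue above it. Both the excitation light travelling in and the emitted
light travelling out are absorbed and scattered; `cryoslice` folds both
paths, and the interface transmission and fluorophore yield factors, into
two composite parameters — the unattenuated cell intensity `I_fluo`
(gray levels) and the effective attenuation coefficient `µ_T` (cm⁻¹) —
so the camera sees `I(x) = I_fluo·exp(−µ_T·x)` (one-dimensional
Beer–Lambert propagation along the optical axis). A cell is detected
when `I(x) ≥ T`, inclusively at the boundary. Scattering is *not*
separated from absorption: there is no point-spread function, lateral
blur, or subsurface-haze removal in the model, and cells are treated as
points.

Consequences used throughout:

* `X_optimal = −ln(T/I_fluo)/µ_T` — the largest slice thickness at which
  the dimmest position in a slice (its bottom edge) still reaches `T`.
  Undefined for `I_fluo < T`; such cells are lost at every thickness and
  the code raises a dedicated error instead of returning a number.
* `I_optimal = T·exp(µ_T·X)` — the exact inverse (round trip verified to
  1e-9 relative).
* Uniform cell placement gives the piecewise sensitivity
  `Sens(X) = min(1, X_optimal/X)`, the expected count
  `n = min(N, ceil((e/X)·N))` with `e = X_optimal` the subsurface-tail
  length, and the correction `Count(X_opt) = Count(X)/Sens(X)`. The
  correction returns a real number; rounding is left to reporting so the
  bias of intermediate rounding is not compounded.
* Mixed brightnesses: `Sens = Σ (N_j/N)·Sens(I_fluo,j)` over intensity
  groups, with below-threshold groups contributing zero. Non-uniform
  depth densities: the ratio of integrals of `p(x)` over `[0, X_opt]`
  and `[0, X]`, evaluated by trapezoidal quadrature on the stored grid
  (default grid resolution 0.1 µm; the two cut points are added as
  interpolation nodes so the result is deterministic and grid-testable).

### Units

`µ_T` is stored in cm⁻¹ — the unit in which practitioners quote it — and
all depths/thicknesses are µm. The 1e-4 cm/µm factor is applied in the
attenuation exponent only (`surface_intensity` and the two closed-form
inverses that mirror it), never elsewhere.

## Virtual volumes (what the generators emulate)

`build_compliant_volume` constructs the reference condition under which
the closed-form results are exact: a slab of `S` µm with one cell per
1 µm depth bin (so `N = S`), every cell with the same `I_fluo` and
`µ_T`, each at a distinct lateral grid position so signals can never
merge. Cells sit at bin *centres* (depth `i − 0.5` µm). This makes the
discrete breakpoint of a simulated sweep equal to
`floor(X_optimal + 0.5)` — the number of detectable depth bins — which
is how the simulators reproduce integer breakpoints (35, 51, 66, 44 µm)
alongside the continuous formula values (34.99, 51.26, 66.22, 44.15 µm).
Both are exposed: `optimal_thickness` returns the continuous value,
`discrete_optimal_thickness` the binned one.

Perturbed volumes add zero-mean normal deviates per cell: to `µ_T`
(tissue inhomogeneity; clipped below at 1 cm⁻¹) or to `I_fluo`
(brightness variability; clipped below at 0). The clips keep parameters
physical while preserving the stated mean and spread for realistic
sigmas; cells pushed below `T` become permanently undetectable, exactly
as the mixture model predicts (`Φ((T−I)/σ)` of them).

Overlap volumes draw `N = round(Density·area)` cells with uniform depths
and uniform positions on a discrete lateral column grid, so cells can
share a column and their subsurface tails can merge. Defaults are
configuration, not claims: `S = 1000` µm, area 1 cm², and a 100×100
column grid (the lateral extent over which signals merge is not an
identified physical quantity here; the grid sets the collision rate and
hence the slope of the linear decline, while the breakpoint is
grid-independent). Within a shared column, depths closer than 1 µm are
redrawn, which is what guarantees that 1 µm sectioning resolves every
cell.

## Digital sectioning

Block-faces are imaged at depths 0, X, 2X, … (the face before the first
cut is imaged) until the slab is consumed; a cell exactly at a cut plane
counts as just exposed (x = 0, maximal brightness). At each face every
remaining above-threshold cell is marked detected, and a cell counts
once however many faces see its tail:

* **Identity counting** (non-overlapping volumes): de-duplication by cell
  id, valid because lateral positions are unique.
* **Overlap counting**: cells sharing a column are counted separately
  only if a block-face falls between them — implemented as the number of
  distinct disappearance events (distinct slab indices) among detectable
  cells per column. This operator is a modelling choice: it is the
  grouping a 3-D connected-component pass over the rendered signal would
  approximate, it provably yields 100% sensitivity at X = 1 µm for
  ≥ 1 µm-separated placements, and it reproduces the
  linear-then-hyperbolic curve shape. Other merge rules (e.g. merging
  any overlapping signal intervals) would count fewer cells.

Sweeps rerun the sectioning on one frozen volume across thicknesses (or
build one compliant volume per intensity for the fixed-thickness sweep);
stochastic conditions are averaged over a seed list, 10 replicates by
default, with the per-point standard deviation reported. The empirical
breakpoint is the largest swept thickness with sensitivity ≥ 1 −
tolerance (default tolerance 0), and the sub-optimal tail is summarised
by the OLS slope of log Sens vs log X.

### Finite-slab edge effects

When `S` is not a multiple of `X`, the final partial slab is thinner
than `X` and loses nothing, so measured sensitivities sit slightly above
`X_opt/X` — by up to roughly `e·(1 − rem/X)/S`. The suite therefore
compares simulated tails against the reciprocal law at divisor
thicknesses or on deep volumes, and the slope tests use sizes where the
bias is below the asserted tolerance: `S = 10000` µm for the compliant
−1.00 ± 0.02 check, and `S = 3000` µm with the fit restricted to the
fully sub-optimal range (75, 150] µm for the perturbed-volume slopes
(just above `X_opt` the perturbed curves are still curved because the
per-cell tail lengths straddle X; beyond the longest tail the decline is
exactly reciprocal). These sizes are the package's study conditions, not
tuning: the properties they verify are scale-invariant statements.

## Stack rendering and the slice-skipping pipeline

`render_image_stack` writes one image per block-face: each surviving
cell contributes `I(x)` at its lateral pixel (single-pixel footprint by
default; a disc radius is available for stress tests), co-located
contributions sum, and optional additive Gaussian noise is clipped at
zero. Stacks serialize as 16-bit multi-page TIFF plus a YAML sidecar
(slice thickness, pixel size, provenance); gray levels are rounded to
integers on write.

The pipeline emulates thicker sectioning by keeping every k-th slice
(anchor at slice 0; an offset flag exists because counts shift slightly
with phase), then counts cells by thresholding and 3-D
connected-component labelling (26-connectivity by default,
6-connectivity available) so a cell's multi-slice tail is one component.
Counts are normalised by the skip-1 reference to give the calibration
curve, which plugs into the same breakpoint/slope diagnostics as the
simulated curves.

Parameter estimation from a thin-slice stack: `µ_T` comes from a
log-linear fit of a component's per-slice peak intensity versus distance
above its brightest (deepest) slice — the slice in which the cell is cut
is excluded since the signal vanishes abruptly there — and `I_fluo` is
the mean component peak. The peak sees the cell at its last block-face,
i.e. up to one native slice *into* the slab, so the intensity estimate
carries a downward bias bounded by the factor `exp(−µ_T·X_native)`; the
derived thickness recommendation inherits it (conservative by up to one
native slice). The detection threshold `T` is a required user input: it
is a property of the imaging chain and is not auto-estimated.

## What the synthetic data does not show

Passing tests demonstrate internal consistency of model, simulators and
pipeline — not agreement with real acquisitions. The renderer omits
optical blur, autofluorescence background structure, tiling,
registration error and spectral cross-talk; cells are single pixels;
noise is i.i.d. Gaussian. Claims about real microsphere/stem-cell
datasets (absolute counts, correlation coefficients, RMS errors,
recovery rates) require the original animal acquisitions and are out of
scope.

## Numerical choices and degenerate inputs

* Detection boundary inclusive (`≥ T`); intensity exactly `T` at depth 0
  is detected and gives `X_optimal = 0`.
* `expected_count` evaluates the ceiling with a 1e-9 guard so exact
  ratios are not pushed to the next integer by float noise.
* Depth-distribution quadrature requires the grid to cover the slice and
  raises on a zero denominator (no mass in the slice).
* Empty volumes, empty mixtures, empty component lists, non-positive
  parameters and missing metadata fields raise typed errors naming the
  offending quantity.
* All generators are pure functions of (parameters, seed) using
  `numpy.random.default_rng`; every CLI output records seeds.

## Known limitations

* The overlap merge operator is one defensible formalisation (see
  above); absolute overlap sensitivities depend on the unidentified
  lateral merge scale, so only the curve shape, the breakpoint, and the
  density ordering are asserted.
* The intensity estimator's slab-position bias (above) means
  thickness recommendations from calibration stacks are conservative
  rather than centred.
* Sensitivities above 16-bit TIFF precision: sub-integer gray detail is
  lost on file round trips; in-memory stacks keep full precision.
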