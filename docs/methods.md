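# Methods

## Coordinate and unit conventions

All modules share one frame: x runs along the channel axis, y across the
gel (normal to the monolayer at rest), z along the optical axis. Arrays are
indexed (z, y, x); voxel centers sit at (i + 0.5) × voxel size; every
physical quantity is in micrometres (µm), concentrations in the user's
units (ng/mL or nM), diffusivities in m²/s at the API surface.

## Phantom model

The phantom renders one gel growth region of the reference device
(defaults: 37 regions per device, trapezoidal posts with 60° base angle —
supplementary to the ~120° contact angle of liquid collagen on treated
PDMS — 100 µm nearest-point spacing, 50 µm base width, 30 µm depth into
the gel, 1.3 mm gel width, ~160 µm imaging depth over 19 sections).

Channels:

- **reflectance** — gel 0.2, PDMS (posts and everything outside the strip)
  0.8 on a normalized scale; constant over depth. These levels give the
  strongly bimodal intensity histogram the boundary detector requires
  (mode separation ≫ 4× the intra-mode spread).
- **cytosolic** — a monolayer band (12 µm thick, intensity 1.0) along a
  natural cubic spline through 4 control points, plus each sprout as a
  flat-capped cylinder of uniform intensity with its axis in the xy-plane
  at mid-depth.
- **nuclear** — ellipsoidal nuclei (default semi-axes 3.5/3.5/6 µm;
  endothelial-scale 4/5.5/8 µm in the validation fixtures) at deterministic
  positions t_i = (i+½)L/n along each sprout axis.
- **transmitted** — 1 − 0.5 × cell occupancy; PDMS is treated as
  transparent.

Structures are rasterized with sub-voxel supersampling (8×3×3 per voxel
for cylinders, 8×4×4 for nuclei) so voxel sums converge to the analytic
integrals (≤ ~1% discretization at the fixture scale). A volume-normalized
Gaussian blur emulates the optics; its σ is specified in µm (default
2.0 µm) rather than voxels, because with ~8 µm z-sections a per-voxel σ
would be strongly anisotropic and push mass outside the stack. Noise is
additive Gaussian only, matching the Gaussian background-fit step of the
preprocessing chain; shot noise is out of scope.

Ground truth is computed independently of rendering: for a straight
monolayer and a normal sprout, closed forms
M = sπρ²(L−d), J = sπρ²(L²−d²)/2 (offset d); for tilted sprouts or curved
monolayers, a deterministic cylindrical quadrature against a dense
polyline; for nuclei, exact ellipsoid plane-cap formulas (cap volume
fraction (2−3τ+τ³)/4 and first moment 3(1−τ²)²/16 of the unit ball). The
aspect ratio's lateral term uses deterministic in-plane sampling of the
cross-sections.

What the phantom does *not* emulate: branching/anastomosing topology,
lumens, uneven illumination, depth-dependent attenuation, or shot noise.
Passing the phantom suite therefore demonstrates correctness of the
geometry/metrics chain under the stated image model, not robustness to
every artifact of real confocal data.

## Preprocessing

Per z-slice 2D median filter (window 3 px), per-channel min/max
normalization to [0, 1], then Gaussian background removal on the
fluorescence channels. The background mode is fit robustly
(median + 1.4826·MAD with 4σ clipping), the threshold is µ + kσ with k = 3
(99.87% one-sided suppression; `background_k_sigma` in the config). Voxels
at or below threshold are zeroed; voxels above it have µ subtracted.
Removing the pedestal (rather than keeping supra-threshold values
untouched) keeps the integral metrics unbiased by the background level;
the estimate-then-eliminate cycle is idempotent.

Min/max normalization gives every stack its own affine intensity scale, so
`normalize_grayscale` records the applied transform and `compute_metrics`
rescales M and J back to the acquisition scale; otherwise a single bright
voxel would silently rescale a region's metrics and cross-region
comparisons would be meaningless. AR is dimensionless and unaffected.
Normalization precedes background estimation (declared order).

## Gel boundary detection and registration

The reflectance channel is mean-projected over z (boundaries and posts
span the depth). After a bimodality check (Otsu split; mode separation
≥ 2× intra-mode SD required), each straight boundary line (offset, angle)
is found by multi-start Nelder–Mead maximizing the separation score — the
absolute difference of mean intensity between the two sides of the line
within a band around it, with pixel membership blended linearly over one
pixel so the objective is smooth. The search runs twice: the first pass
locates the lines and the post footprints; the second re-optimizes with
the post footprints excluded, because the bright post bases on the gel
side of the line provably bias the difference-of-means optimum a few
pixels into the gel. An explicit initial simplex perturbs the angle by
1.5°; Nelder–Mead's default relative perturbation of a zero angle would
never explore that dimension.

Post bases are localized along each line from the brightness profile of a
shallow band just inside the gel, with sub-pixel edge interpolation and an
analytic correction for the trapezoid taper (the averaged-profile crossing
sits mean-depth × tan(edge-from-vertical angle) inside the true base
corner; the edge angle includes the detected line rotation). Interior base
corners serve as landmarks; a 2D Kabsch fit gives the rigid transform
mapping the 48-h frame onto the 0-h frame (residual > 10 µm or rotation
≥ 10° flags a probable region mismatch).

## Monolayer fit

The fit signal is a weighted combination (default 0.7/0.3) of the
z-projected cytosolic channel and the *inverted* transmitted channel
(cells attenuate transmitted light; `invert_transmitted` in the config).
The monolayer is a natural cubic spline through 4 control points at fixed,
evenly spaced x positions whose only degree of freedom is the normal
offset — the curve is single-valued and fold-free by construction. The
objective is the band integral: mean signal within a normal distance
(default 10 µm) of the curve, normalized by the straight-reference band
area (2 × halfwidth × span). Normalizing by the *actual* curved-band area
would penalize curve length and demonstrably flatten curved fits, while
the restricted parameterization already precludes the long-curve
degeneracy that area normalization would guard against. Multi-start
Nelder–Mead (starts at the strip edge and coarser offsets into the gel) is
followed by a refinement pass at half the band width, which removes the
positional plateau left when the band is wider than the monolayer. Ties
between starts break toward the initialization and are flagged.

## Metrics

The integration region V is the gel strip between the detected boundary
lines, minus the post polygons, restricted to normal distances
r ≥ 10 µm past the monolayer (the offset excludes the bright cell
aggregation band around the monolayer; `offset_um` in the config). The
distance field uses exact nearest-point projection onto a densely sampled
spline polyline, signed toward the gel; u is the arclength of the nearest
point. Integrals run over the full 3D stack with per-axis voxel volumes
(anisotropic voxels handled exactly); r and u are constant over z.

AR = (Σ s·r / M) ÷ (Σ s·|u−ū| / M) with ū the signal-weighted mean of u.
This definition is dimensionless, increases with directional penetration
and decreases with lateral spreading. AR is undefined (NaN, flagged) when
M = 0 and capped (default 100, flagged) when the lateral spread falls
below half a pixel. Differentials are growth-positive:
Δ = value(48 h) − value(0 h). The monolayer is fit at 0 h (it defines the
reference wall) and carried into the 48-h frame through the rigid
registration; refitting at 48 h is config-selectable.

## Transport model

2D plan view: two media channels run along x with 1D plug advection
(u = Q / (channel width × height)), the gel strip between them is purely
diffusive, trapezoidal post footprints block the gel edges (the lateral
cross-section change they cause is what bends the profiles away from
linearity). Finite volumes with harmonic-mean interface diffusivities and
first-order upwind advection give an M-matrix, so the discrete maximum
principle holds unconditionally. Boundary conditions: Dirichlet source and
sink at the channel inlets, pure convective outflow at the outlets
(no diffusive flux through the outlet face), no-flux side walls, and an
optional Dirichlet sink at both ends of the gel strip representing the
large gel mass at the filling ports. A zero (or None) flow rate selects
the fixed-concentration idealization: the strip edges are held at the
channel concentrations and only diffusion acts, which reduces to the exact
linear cross-gel profile on a uniform strip. Default diffusivities are
5×10⁻¹¹ m²/s in both gel and medium (a ~40 kDa growth factor); defaults
use a 25 µm grid (≥ 4 nodes per gel gap enforced). Reaction/binding terms
and time dependence are out of scope.

Per-region gradient steepness is reported two ways: `mode="mid"`
(|dC/dy| at the mid-gel row; grid-robust, used for uniformity and
convergence checks) and `mode="max"` (maximum across the gel; sensitive to
the port-sink steepening in the outermost regions). The axial-uniformity
statistic compares the first and last *interior* regions, excluding the
two outermost on each side that the ports perturb.

Design calculators: Young–Laplace ΔP = γ(1/Rx + 1/Rz) with flat directions
contributing zero; the lateral Péclet number u·(h/L)·h/D and the axial
form u·L/D (both appear in the literature for this geometry; with
unreported channel velocity the often-quoted Pe ≈ 50 cannot be pinned
down, so both are exposed and neither is asserted).

## Ensemble statistics and the cell-event model

Devices are the independent replication unit: the condition mean is the
mean of device means and the condition SE is the SD of device means over
√(number of devices). Tests against the matched basal control default to
Welch's t-test (classic pooled form selectable); significance markers are
* p<0.1, ** p<0.05, *** p<0.005.

The generator treats each region's response as a sum of independent
exponential cell-level contributions — gamma distributed by construction —
in two regimes reflecting the two ways "noise scales with the mean" can be
read: `constant-cv` fixes the gamma shape at 1/CV² for every device
(SD ∝ mean; the multiplicative-noise regime the integral metrics show),
and `constant-fano` fixes the per-event scale so variance ∝ mean. Device
means are log-uniform across their range. Default simulated conditions:
14 devices × 37 regions, CV 0.4, means spanning one decade — at these
settings the SD-on-mean OLS gives r² ≈ 0.95 and slope ≈ 0.4.

The allocation model minimizes SE²(m, n) = σ_m²/m + σ_d²/(m·n) over
integer devices m and regions-per-device n subject to the budget
m(n + overhead) ≤ k_total, where the per-device overhead (default 5
region-equivalents) prices fabrication/seeding/imaging of an extra device.
Without an overhead term the stated SE model is minimized trivially at
n = 1 (pure device replication), which contradicts the rationale for
ensemble devices — the cost model is what makes the question non-trivial.
For fixed m the SE is non-increasing in n, so the optimizer searches m
with n maximal (n = 1 when σ_d = 0); it agrees exactly with brute-force
enumeration, and the continuous relaxation has the closed form
n* = (σ_d/σ_m)·√overhead — the intrinsic/extrinsic variance ratio σ_d²/σ_m²
sets how many regions each device should carry. Ties prefer more devices.

## Validation scale and error budget

The test fixtures use a desk-scale single region: 160 µm gel strip, 60 µm
channel margin, 5 z-sections over 40 µm, 1.25 µm xy pixels (the reference
device's pixel scale), one 80 µm × 10 µm-radius sprout with 5 nuclei of
semi-axes 4/5.5/8 µm, background noise N(0.1, 0.05), blur σ 1.5 µm. At
this scale the residual error sources — rasterization (≤1%), median-filter
erosion of compact objects, blur mass crossing the 10 µm offset, and the
~0.13% Gaussian-tail survivors of the k = 3σ threshold — sum to well under
the 5% recovery tolerance for M and J in both channels, while 20 seeded
phantom pairs process in about two minutes. Boundary detection recovers
lines to ≪ 1 px and the monolayer to ~0.5 µm on these fixtures.

## Known limitations

- The monolayer is a single-valued curve fit on the z-projection, not a 3D
  surface; monolayer deformation over time is not tracked (the 0-h curve
  anchors r).
- Sprout-level morphology (counts, branching, anastomoses) is deliberately
  out of scope; the metrics are integrative.
- The boundary model is two straight lines; curved or broken gel
  interfaces are not represented.
- The transport domain is 2D; vertical gradients and 3D meniscus effects
  are not modeled.
- Registration assumes small stage shifts (< ~10° rotation) and intact
  post landmarks at both timepoints.
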