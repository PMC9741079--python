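# Methods

## Channel geometry

A channel profile is an ordered sequence of spheres (center in Å, local
radius in Å), the representation tunnel-detection tools export.  Each
consecutive pair of nodes bounds a *section* modelled as a truncated cone
with radii r₁, r₂ and height h equal to the straight-line distance between
the two centers; a cylinder is the r₁ = r₂ case.  Per section

- volume V = ⅓·π·h·(r₁² + r₁r₂ + r₂²),
- lateral surface S = π·(r₁ + r₂)·√((r₁ − r₂)² + h²),

and totals are plain sums: over sections for a channel, over channels for a
protein (a `longest_only` switch restricts totals to the single longest
channel; it is off by default because a protein's reported channels are all
part of its tunnel system).  End caps are never included — the quantity of
interest is the side wall area of the tunnel.  A formula for S sometimes
appears in print without the radical over (r₁ − r₂)² + h²; that variant has
units of length³ and cannot be an area, so this package uses the standard
frustum lateral area above.

Both formulas are additive under subdivision of a section at any
intermediate point with linearly interpolated radius, so totals are
independent of sampling density along straight, linearly tapered stretches.
The test suite verifies the closed forms against numeric
surface-/solid-of-revolution integration of the piecewise-linear radius
profile (independent `scipy.integrate.quad` oracles) to 1e−6 relative, and
subdivision invariance to 1e−9 relative.

## Temperature-class statistics

Species are binned by optimum growth temperature: `<50` (strictly below
50 °C), `50-80` (both endpoints included), `>80` (strictly above 80 °C).
Putting the boundary temperatures in the middle class keeps the outer
class labels literally true.

Per temperature class and dimension the summary is n, arithmetic mean,
sample SD (n−1 denominator; flagged undefined for n < 2) and *amplitude* =
max − min, the variability statistic.  Variability is *tested* with the
two-sample variance-ratio F test: F = s²_larger/s²_smaller with (n−1, n−1)
degrees of freedom and two-sided p = min(1, 2·P(F ≥ f)).  The amplitude
itself is summarized descriptively rather than tested — the range has no
convenient exact null distribution, while the variance ratio is the
standard F-testable measure of spread, and the two move together under the
generator's model.  The F test is two-sided because no direction of change
is assumed a priori.

Each (enzyme, subunit, dimension) panel compares the `50-80` and `>80`
classes against the `<50` reference, so the Bonferroni family size is m = 2
per panel (configurable); adjusted p = min(1, m·p).  Class *means* are
compared with Welch's t test (no equal-variance assumption — the point of
the analysis is precisely that variances differ), adjusted the same way, to
establish that location does not shift while spread contracts.  The
headline descriptive statistic is the amplitude fold ratio
amplitude(`<50`)/amplitude(`>80`); a zero denominator is flagged as
undefined (NaN), not infinity.  Trend lines of each dimension against T_opt
are unweighted ordinary least squares (slope, intercept, R²); a constant
response is reported as slope 0 with R² = 0 rather than an error.

## Clearance-field tracer

The built-in tracer stands in for external tunnel-detection software at toy
scale.  The clearance at a point is the distance to the nearest atom
surface, clearance(p) = minᵢ(‖p − atomᵢ‖ − vdWᵢ), with van der Waals radii
from a fixed table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, default
1.70 Å).  Clearance is evaluated *exactly* at every voxel center of a
regular grid over the atom bounding box padded on all sides; the default
spacing is 0.5 Å (allowed range 0.25–2.0 Å) and the default pad 5 Å
(minimum 3 Å).  The accelerated evaluation queries one k-d tree per
distinct radius value — exact because minᵢ(dᵢ − rᵢ) decomposes over groups
of equal radius — and is tested for bit-identical agreement with the brute
force definition.

A channel is the *widest-bottleneck* path: over 26-connected voxels with
clearance ≥ `min_radius` (default 0.9 Å, slightly under a water-sized
probe, so that near-blocking constrictions terminate the search), maximize
the minimum clearance along the path from the start voxel to any voxel on
the padded-box boundary.  The search is a widest-path Dijkstra with
deterministic tie-breaking (larger bottleneck, then fewer steps, then
lexicographic voxel index).  The path's voxel centers with their clearances
form an ordinary channel profile, so traced channels feed directly into the
frustum measurements.  An independent value-only route — binary search over
clearance thresholds with 26-connected component labelling
(`scipy.ndimage.label`) — is shipped alongside and must agree exactly with
the Dijkstra bottleneck; the two routes share no search code.  The widest-
bottleneck objective (rather than shortest path) was chosen because the
bottleneck radius is the downstream quantity of interest.  The tracer makes
no claim of reproducing any particular external tool's output numerically,
and does not enumerate multiple tunnels.

Discretization bounds the recovered bottleneck error: the start and exit of
the optimal corridor are quantized to voxel centers, so halving the spacing
changes the bottleneck by at most the coarser spacing (verified in tests).

## Synthetic data

**Dimension tables.**  The generator emulates the qualitative structure of
interest: T_opt drawn uniformly within each class band over 18–110 °C;
dimension values normal with a temperature-independent mean (an optional
per-dimension slope adds drift) and an SD that decays log-linearly in T_opt
from σ₀ at the center of the `<50` band to κ·σ₀ at the center of the `>80`
band.  κ (default 0.25) is exposed rather than hard-coded because only the
*pattern* — several-fold wider ranges in the coolest class — is specified
by the scientific setting, not a numeric dispersion per class.  With equal
per-class n the expected amplitude ratio roughly equals the SD ratio 1/κ,
so κ = 0.25 centers the fold ratio near 4, inside the 2–7-fold band of
interest (confirmed by simulation: median ≈ 4.0 over 200 replicates).
Default n = 30 per class gives the F test essentially full power at
κ = 0.25 while keeping mean-test rejections at the nominal error rate.
Defaults for the means and σ₀ (length 400 ± 60 Å, surface 4000 ± 600 Å²,
volume 3000 ± 450 Å³ in the coolest class) are order-of-magnitude choices
for a summed multi-tunnel system; all satisfy μ > 6σ₀ so truncation at zero
(implemented by redraw) is negligible.  Species names are synthetic
placeholders.

What the generator does **not** emulate: phylogenetic correlation between
species, measurement error from structure prediction, skewed or
heavy-tailed dimension distributions, and any coupling between length,
surface and volume (they are drawn independently, whereas real tunnel
dimensions are strongly correlated).  Passing tests therefore demonstrate
that the pipeline recovers the variance-contraction signal under an
idealized sampling model, not that real enzyme datasets satisfy the F
test's normality assumptions.

**Tube structures.**  A toy channel-bearing "protein": wall pseudo-atoms
(vdW 1.70 Å) on rings of radius R(z) + vdW around the z axis, so the axis
clearance at a ring plane is exactly R(z); ring spacing and in-ring arc
spacing equal the `atom_spacing` (≤ 2 Å enforced — beyond that the wall
leaks probe-sized gaps); optional end caps close the tube.  The generator
returns the exact ground-truth centerline profile (axis samples at every
ring and radius-profile breakpoint), whose frustum measurements match the
closed-form sums over the breakpoints to 1e−9 — an internal consistency
check tying the generator to the geometry module.

## Problem sizes and numerical choices

Default validation sizes: 100 random profiles for the integration oracle,
20 tubes (radii 1.5–3 Å, 18 Å long, 0.5 Å grid) for tracer recovery with a
±0.6 Å tolerance (grid quantization plus rim effects), 10,000 replicates
for F-test calibration, 200 replicates for the contraction statistics.
All generators take explicit seeds and are pure functions of their
parameters; identical seeds give byte-identical outputs.  Grids are capped
(default 4×10⁶ voxels) with an error suggesting a larger spacing.

## Known limitations

- The tracer returns a single channel per start point; no tunnel
  enumeration, no pocket detection, no arc-length smoothing of the
  centerline.
- The F test assumes normal within-class distributions; no robust
  alternatives (Levene/Brown–Forsythe) are currently offered.
- mmCIF structures are not read; PDB only, all atoms used.
- Reanalysis of external measurement tables requires the user to supply a
  column mapping; nothing is assumed about third-party headers.
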