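# tunnelmetrics

Geometry and statistics for molecular tunnels (channels) in enzymes, aimed
at one question from thermal-adaptation biology: does the *variability* of
tunnel dimensions across species shrink as the optimum growth temperature
(T_opt) of the source organism rises?  The motivating system is the
methanogenesis enzymes Mmr (methyl-coenzyme M reductase) and Hdr
(heterodisulfide reductase) from archaea growing anywhere between 18 °C and
110 °C, analyzed per subunit.

The package is for structural bioinformaticians who have channel centerline
profiles (from MOLE, CAVER or similar — ordered spheres with center and
local radius) and species metadata, and want reproducible dimension totals
and class-level variability statistics; every stage also runs end-to-end on
built-in synthetic data, so no external tunnel software is required.

## The model

**Geometry.** A channel is an ordered sphere chain; each consecutive pair
bounds a section treated as a truncated cone (a cylinder when r₁ = r₂) of
height h = the distance between the two centers:

    V = ⅓ π h (r₁² + r₁r₂ + r₂²)
    S = π (r₁ + r₂) √((r₁ − r₂)² + h²)

S is the lateral surface only (no end caps).  Channel totals are sums over
sections; protein totals are sums over all of its channels.  Units are Å,
Å² and Å³ throughout.

**Tracing.** For structures without external tunnel software, a built-in
tracer computes the exact clearance field, clearance(p) = minᵢ(‖p − atomᵢ‖
− vdWᵢ), on a padded grid and extracts the *widest-bottleneck* path
(maximize the minimum clearance) from a start point to the box boundary
over 26-connected voxels.  It is a toy-scale tool, not a MOLE/CAVER
replacement.

**Statistics.** Species are binned by T_opt into <50, 50–80 (endpoints
included) and >80 °C classes.  Per (enzyme, subunit, dimension) panel the
package reports each class's n, mean, sample SD and **amplitude**
(max − min, the variability statistic); compares the two warmer classes
against the <50 reference with a two-sided variance-ratio F test (larger
variance in the numerator, Bonferroni family size 2 per panel) plus a
Welch t test on the means; reports the <50/>80 amplitude fold ratio; and
fits an OLS trend of the dimension on T_opt.

## Worked example

```python
from tunnelmetrics import ChannelProfile, SphereNode, measure_channel

profile = ChannelProfile("T1", (
    SphereNode(0, 0, 0, 1.0),   # cylinder of r=1 over h=2 ...
    SphereNode(0, 0, 2, 1.0),
    SphereNode(0, 0, 5, 2.0),   # ... then a frustum tapering 1 -> 2 over h=3
))
m = measure_channel(profile)
print(f"length  = {m.length:.3f} A")    # length  = 5.000 A
print(f"surface = {m.surface:.3f} A^2") # surface = 42.370 A^2  (4π + 3π√10)
print(f"volume  = {m.volume:.3f} A^3")  # volume  = 28.274 A^3  (9π)
```

And the statistical layer on a synthetic species table (variance
contraction factor κ = 0.25, 30 species per class):

```python
from tunnelmetrics import DimensionGenSpec, generate_dimension_dataset, analyze

ds = generate_dimension_dataset(DimensionGenSpec(seed=1))
res = analyze(ds)
row = res[(res.enzyme == "Mmr") & (res.subunit == "alpha")
          & (res.dimension == "length") & (res.class_cmp == ">80")].iloc[0]
```

which for this panel prints amplitude 197.1 Å in the <50 class against
61.1 Å in the >80 class (fold ratio 3.2), F = 8.78 with Bonferroni-adjusted
p = 1.8 × 10⁻⁷ for the variance comparison (significant), adjusted p = 1.0
for the mean comparison (not significant), and a trend slope of −0.10 Å/°C
— the generated pattern: spread contracts with temperature while the
average stays put.

The same pipeline runs from the shell:

```sh
tunnelmetrics --seed 5 simulate --kind table --out-dir sim/
tunnelmetrics analyze --input sim/dimensions.tsv --out results.tsv --plots
tunnelmetrics --seed 3 simulate --kind structure --out-dir tube/
tunnelmetrics trace --pdb tube/tube.pdb --start 0,0,10 --out traced.json
tunnelmetrics measure --input traced.json --out measured.tsv
```

Measurement tables from other sources (e.g. deposited per-species tables
with different headers) can enter via
`read_dataset_table(path, column_map={...})`, mapping external column names
onto `species, enzyme, subunit, t_opt, length, surface, volume`.

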