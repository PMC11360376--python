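# Methods

This note documents the models, parameter choices and numerical
conventions behind `vinemetrics`, and what the synthetic-data tests do
and do not establish.

## The measurement chain

The package estimates five per-vine parameters from a point cloud in a
projected metric CRS: maximum canopy height H_max, percentile heights
H90 and H95, projected canopy area, and canopy volume. All heights are
above interpolated ground; all area/volume computations use only points
strictly above the lower trellis wire (default 0.30 m), which removes
undergrowth returns.

### Ground filtering (SMRF family)

1. A minimum-elevation surface is gridded at `cell_size` (default
   0.25 m). Empty cells are filled from their nearest finite neighbor,
   followed by one 3×3 smoothing pass restricted to the filled cells.
2. The surface is morphologically opened with disk windows of radius
   1 cell up to `max_window_radius` (default 2.0 m). After each opening
   a cell is flagged non-ground if it exceeds the opened surface by more
   than `slope_threshold × window_radius` (slope default 0.15).
3. A DTM is interpolated from the surviving ground cells (same
   inpainting), and a point is classified ground when its elevation is
   within `elevation_threshold + elevation_scaler × local_DTM_slope` of
   the bilinearly interpolated DTM (defaults 0.05 m and 1.25).

Defaults follow the published recommendations for this algorithm
family, scaled to survey-grade data; the maximum window is sized above a
vine canopy footprint so whole canopies cannot be absorbed into the
terrain. Two consequences worth knowing:

* the min-surface is biased low by roughly the expected minimum of the
  per-cell noise (≈ 1 cm for 5 mm noise at these densities), so
  normalized heights carry a small positive bias of the same order;
* on slopes the slope-scaled tolerance grows (≈ 0.18 m at a 10% grade
  with defaults), so low vegetation under that height is absorbed into
  the ground class there. This is inherent to slope-adaptive
  morphological filters, not an implementation artifact.

Interpolation is bilinear on the ground-cell DTM (nearest-edge beyond
the outermost cell centers); the difference against TIN interpolation
is far below the metric tolerances at 0.25 m cells. Each cloud is
normalized against its own DTM; `normalize_heights` accepts any
`GroundModel`, so a shared DTM can be supplied explicitly. Negative
normalized heights are kept (the trellis filter removes them).

### Segmentation

Footprints are flat-capped rectangles, `segment_length` (1.0 m) along
the row azimuth by 2 × `half_width` (0.8 m) across it, centered on the
surveyed vine coordinate. A buffered segment with round caps
(2.6 m × 1.6 m) would overlap neighbors at the 1.2 m planting pitch, so
flat caps are the default; round caps remain available via
`ClipSpec(cap_style="round")`. Clipping is boundary-inclusive; the
trellis filter is strictly greater-than (a point exactly at 0.30 m is
treated as undergrowth — the equality case had to be fixed by
convention and is documented here).

### Alpha shapes

The alpha shape is defined by a circumradius criterion in metres: a
Delaunay triangle (2D) or tetrahedron (3D) is retained when its
circumradius is ≤ α; α = ∞ retains everything and reproduces the convex
hull exactly. Smaller α gives a tighter, possibly disconnected shape,
which is why the dense TLS-class clouds use α = 0.05 m and the sparse
UAV-class clouds α = 0.5 m. One α per sensor class is applied to both
the 2D (area) and 3D (volume) shapes. No hole-filling or regularization
is applied: the 2D area is the summed area of retained triangles, so
interior holes reduce it. Retained-set size, area and volume are all
non-decreasing in α.

Circumradii are computed vectorized (2D: abc/4A; 3D: solving the
circumcenter system per tetrahedron); degenerate simplices get infinite
radius and are only retained at α = ∞. Degenerate inputs (collinear,
coplanar, or too few points) yield area/volume 0 with a logged reason,
not an error. Percentiles use linear interpolation at index
(n−1)·p/100 — the dominant convention in scientific computing;
alternative conventions move the result by less than one point spacing.

### Statistics

* CV is 100·SD/mean with sample SD (n−1).
* The overall significance p is the OLS F-test, which is algebraically
  identical to the two-sided Pearson t-test.
* Model-II fits: SMA slope = sign(r)·sd_y/sd_x with the closed-form CI
  b·(√(B+1) ± √B), B = t²(1−r²)/(n−2); MA slope from the leading
  covariance eigenvector with its CI obtained by rotating the axis by
  ±atan(A), A² = H/(1−H), H = t²·l1·l2/((n−2)(l1−l2)²). Intercepts pass
  through the centroid.
* RMSE against a reference is the *paired* RMSE √mean((est−ref)²); a
  regression-residual variant is provided separately (`rmse_residual`)
  because the two are often conflated in the literature.
* "Kolmogorov–Smirnov" with estimated mean/sd is implemented as the
  Lilliefors-corrected test (plain KS would be anticonservative); it
  requires n ≥ 4 and reports NaN below that.
* Welch ANOVA uses the standard heteroscedastic F with
  Satterthwaite-type df; all-constant equal groups return F = 0.
* Games–Howell: per pair, Welch SE and df, p from the studentized-range
  distribution at q = |Δ|/SE·√2 with k groups. The CI reported per pair
  is a BCa bootstrap interval of the mean difference (default 1000
  resamples, 95%, caller-seeded); degenerate resampling distributions
  collapse to the point estimate.
* The compact letter display uses an insert-and-absorb algorithm over
  the significant-pair graph at α = 0.05, assigning letters from the
  highest group mean down.

## The synthetic vineyard

The generator emulates a flat-to-gently-sloped trellised vineyard:
vines 1.20 m apart in rows 1.80 m apart, trunks to 0.55 m, an
ellipsoidal canopy from 0.55 m up to a per-vine maximum drawn around
1.57 m (SD 0.15 m), and two thin (1.5 cm) branches per vine drooping
steeply into the inter-row alley. Grass blades up to 0.30 m at
30 blades/m² cover the ground. Terrain is a plane (optional grade along
+x) plus smooth sinusoidal roughness.

Canopies are unions of simple solids rather than botanical models
because the downstream metrics are purely geometric: the only
requirement is that true height (analytic), projected area and volume
(voxel-counted at `oracle_resolution`, default 1 cm; halving the
resolution moves the values by < 2%) are computable. The canopy is
deliberately sized to sit inside the 1.0 m × 1.6 m measurement window
(along-row semi-axis 0.42 m, jitter clamped at 0.46 m): per-plant truth
and per-plant estimate must describe the same geometry for recovery
tests to be meaningful. Real vineyard rows are continuous — neighboring
canopies interpenetrate the clip window — and that regime is explicitly
not modeled.

### Sensor profiles

A profile specifies viewpoint (`terrestrial-lateral` samples uniformly
inside solids; `aerial-nadir` samples the upper surface with an
exponential penetration depth, mean 0.15 of the solid's vertical
extent, putting ≳ 85% of points in the top half), a canopy density
(points/m³), Gaussian noise sigmas, a thin-structure dropout rule
(primitives thinner than `min_feature_diameter` are dropped whole with
probability `p_miss`), ground/grass sampling, and for the LiDAR class a
multireturn model (return numbers 1/2/3 at 98.97/1.02/0.01%, later
returns displaced toward the ground).

Bundled densities are anchored to the per-canopy mean point counts of
the emulated sensors — TLS 751,780; panchromatic 2451; L1 RGB 2220;
LiDAR 1557; H20T RGB 1253; multispectral 626; TIR 328 points per canopy
— by dividing by the default canopy volume (0.224 m³). The terrestrial
profile carries a desk-scale `sample_scale` of 0.02 (≈ 15,000 points
per vine) so tests stay tractable; the per-m³ plot-wide densities
reported for such surveys are not matched simultaneously (they are
inconsistent with the per-canopy counts for canopies of this size), and
the per-canopy anchoring was chosen because every downstream metric is
per-canopy. Noise sigmas follow the sensors' reported georeferencing
RMSEs (e.g. panchromatic 0.017 m vertical, TIR 0.072 m — the worst by
far). Grass sampling emulates occlusion within the sward (points on the
upper 30% of blades), and the "smoothed" mode of photogrammetric
profiles raises the apparent ground by 3 cm to mimic the noisier
terrain reconstruction under grass.

### What the generator does not capture

* Photogrammetric *surface smoothing*: vertical error is modeled as iid
  noise, which makes noisy sparse profiles (TIR) overestimate H_max
  (max of noisy samples), whereas real photogrammetric clouds tend to
  *under*-reconstruct canopy tops. Orderings of correlation and
  variability across sensor classes are preserved; signed biases of the
  noisiest profiles are not.
* Continuous canopy rows, occlusion between neighboring vines,
  registration error between scan stations, and any radiometry.

A green test on synthetic scenes therefore establishes that the
extraction chain is correct and that density/noise orderings propagate
as expected — not that any particular real sensor will achieve a given
absolute accuracy.

## Reproducibility

Every stochastic step takes an explicit seed; scenes, clouds, bootstrap
draws and whole pipeline runs are deterministic given config + seed
(LAS files are written with fixed header dates so reruns are
byte-identical). The pipeline manifest records the version, seeds,
parameters and per-stage point counts needed to reproduce a run.
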