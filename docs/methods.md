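# Methods

## Quantity of interest

For a binary vessel segment V inside an organ mask Ω, both voxel grids with
isotropic voxel size v (µm), the pipeline reports the empirical CDF

F(d) = |{x ∈ Ω : D(x) ≤ d}| / |Ω|,

where D is the signed Euclidean distance transform of V in µm: for a
background voxel, +‖x − nearest vessel-voxel center‖·v; for a vessel voxel,
−‖x − nearest background-voxel center‖·v. Distances are exact Euclidean
(scipy's exact EDT; no chamfer approximation), measured between voxel
centers, so D never attains 0. F is evaluated at query distances d, by
default 20 µm (near-capillary contact) and 100 µm (the oxygen diffusion
limit of healthy tissue, after the Krogh supply model). F(d) is the fraction
of organ tissue a vascular bed can plausibly oxygenate at range d.

Vessel voxels have D ≤ 0 < d and therefore count as "within d" at every
query distance: perfused lumen is supplied volume. Whether lumen should be
in the population at all is genuinely ambiguous ("tissue" can be read either
way), so the population is configurable (`cdf_population: organ |
organ_minus_vessel`); including the lumen (the default) shifts fractions by
the vessel volume fraction, typically a few percent.

## Pipeline stages and parameters

| stage | parameter | default | why |
|---|---|---|---|
| smoothing | `sigma_px` | 1.0 voxel | protocol value; suppresses shot noise without erasing capillary-scale tubes |
| threshold | `threshold` | required, or `"otsu"` | the reference protocol thresholds manually per sample; Otsu (maximum between-class variance over 256 equal-width bins) is an explicit opt-in automation |
| component cleanup | `connectivity` | 26 | tubes crossing voxel corners must not fragment; 6/18 available |
| organ mask | `closing_radius_px` | 50 voxels | at the reference 4.444 µm scan voxel this is a 222.2 µm ball, large enough that the closed vascular network stands in for the whole-organ volume |
| CDF queries | `query_distances_um` | (20, 100) µm | near-capillary and diffusion-limit distances |

Conventions that tests rely on: thresholding is **inclusive** (voxel is
vessel iff intensity ≥ threshold); the Otsu threshold is returned as a bin
*edge* so the ≥ comparison matches the histogram split exactly; Gaussian
boundary handling is reflect-at-edge (no darkening at volume faces);
smoothing computes in float32. On a tie for largest component the component
containing the lexicographically smallest (z, y, x) voxel is kept, with a
warning.

## Morphological closing

The organ outer shape is the closing (dilation then erosion) of the vessel
segment with the discrete Euclidean ball {o : ‖o‖ ≤ r}. A cube element
would inflate the mask by √3·r corner-wise, so a ball it is. Closing is
computed as two exact-EDT thresholds — dilation is "distance to vessel ≤ r",
erosion is "distance to non-dilated > r" — which is mathematically identical
to the structuring-element definition (the test suite checks equality with
explicit neighborhood maxima/minima) but feasible at r = 50. Because squared
voxel-center distances are integers, the comparisons use d² ≤ r² + 0.5 and
d² > r² + 0.5, immune to square-root rounding. The volume is zero-padded by
r and cropped back, so vessels touching a face close without wrap-around.
The closed mask is applied to the distance field directly — the outer
surface is not additionally eroded, and no extra hole-filling step is added
(a 222 µm ball on a dense network closes the interior by itself).

## Group statistics

Per query distance, two groups of per-sample fractions are compared with an
unpaired two-tailed Student's t-test in its pooled (equal-variance) form —
that is what the name denotes — with df = n₁ + n₂ − 2; Welch's form is
available behind a flag. No multiple-testing correction is applied across
the two query distances, and the report says so in its footer. Degenerate
input (both groups constant and equal) yields t = 0, p = 1 by convention
with a warning.

A caution for very small samples: with n = 3 + 3 the smallest achievable
exact two-sided permutation p is 2/20 = 0.10, so t-distribution p-values
below that (e.g. 0.021 for the textbook [1,2,3] vs [4,5,6] example) are an
artifact of the normality assumption, not of the data ordering. The t-test
ranks permutations exactly like the mean difference; its p-values at such n
should be read qualitatively.

## Synthetic phantoms

The generator emulates what the pipeline actually consumes: bright tubular
networks on a dark background inside a bounded volume.

* **Geometries.** `krogh_array` — parallel capillaries (radius R_v) along z
  on a square lattice (pitch s), lines placed at integer multiples of s so
  the periodic nearest-axis field of the infinite lattice is realised
  everywhere in the box; `random_cylinders` — uniformly random chords;
  `branching_tree` — recursive dichotomous branching (configurable length
  and radius ratios, ~30° branch angle with uniform jitter), deterministic
  given its seed.
* **Rasterization.** A voxel is vessel iff its *center* lies within R_v of a
  geometry axis — the same voxel-center metric the distance transform uses,
  so oracle comparisons are consistent. Grayscale is
  background/foreground (20/200 by default) plus optional additive Gaussian
  noise; all randomness flows from the spec's integer seed through
  `numpy.random.default_rng`, so identical specs give bit-identical volumes.
* **Closed-form ground truth.** For the lattice, the tissue fraction within
  d of a vessel is the area fraction of the square unit cell covered by a
  disc of radius R = R_v + d centered on the axis: πR²/s² while the disc
  fits in the cell, 1 beyond R ≥ s·√2/2, and the exact disc–square
  intersection in between (`analytic_krogh_fraction`; verified against
  Monte-Carlo point sampling).
* **The enclosing shell.** A bare parallel lattice is a set of mutually
  disconnected tubes — no perfused network is — and the pipeline's
  largest-component cleanup would rightly discard all but one. `enclosed=True`
  adds a vessel shell of thickness w on every domain face, a feed manifold
  standing in for the supplying vasculature, making the network one
  component. The ground truth stays exact: every point within w + d of a
  face is covered via the shell, and on the interior window the lattice
  formula applies, giving f(d) = 1 − (V_int/V)(1 − f_krogh(d)). This is
  exact precisely when the lateral window lengths are integer multiples of
  the lattice pitch (the window is then phase-complete); the function
  refuses other geometries rather than return an approximation.
* **Rarefaction.** `rarefy_network` removes ⌊fraction·n⌋ removable elements
  uniformly at random (seeded): lattice lines and cylinders are all
  removable, trees only at their terminal branches; an enclosing shell never
  is. Element construction and noise use separate seeded streams, so
  rarefaction does not shift the noise field.

What the phantoms do **not** emulate: CT reconstruction artifacts (rings,
beam hardening, streaks), anisotropic point-spread, intensity
inhomogeneity, partial contrast filling, or any real renal architecture
(cortex/medulla zonation, vessel caliber statistics). Passing tests
therefore demonstrate that the measurement chain is correct on known
geometry — not that segmentation of an arbitrary real scan is correct,
which still hinges on the operator-chosen threshold.

## Study designs

Two prepackaged experiments (`vesselprox.studies`) exercise the pipeline end
to end at desk scale; the problem sizes below are the package's chosen
study conditions.

* **Krogh recovery** — noiseless enclosed lattice, s = 100 µm, R_v = 10 µm,
  2 µm voxels (a tenth of the smaller query distance, where discretization
  error in F is well below 0.01) in a 200 × 448 × 448 µm box with a 4 µm
  shell, so the 400 µm interior window is exactly four lattice cells. The
  full pipeline reproduces the exact coverage fractions within 0.02 at
  d = 20 µm, and F(100) = 1 exactly: the organ mask provably equals the
  domain box here, and no tissue point is farther than 50√2 − 10 ≈ 60.7 µm
  from a vessel surface.
* **Rarefaction contrast** — per replicate, 7 intact vs 5 rarefied (30 %
  of cylinders removed) enclosed random-chord networks (40 chords of 8 µm
  radius in 200 × 300 × 300 µm, 4 µm voxels, noise sd 10, 48 µm closing),
  echoing a control-vs-disease design with unequal group sizes. Across 20
  seed replicates the rarefied group's mean fraction-within-20 µm is lower
  and the t statistic points that way in every replicate observed.

## Degenerate inputs and resource limits

Constant volumes (no Otsu threshold), empty or all-true masks (no signed
EDT), empty organ masks and sub-2 samples per group all raise typed errors
rather than returning numbers. The closing declares its padded working set
(three float64 grids of the padded volume) and refuses, with guidance, runs
exceeding the configured memory budget instead of thrashing; the pipeline
forwards a configurable `memory_budget_gb` (default 8). TIFF I/O is
slice-wise; voxel size is caller-supplied, with a warning (never an error)
if an embedded resolution tag disagrees by more than 1 %.

## Known limitations

* The reference protocol's per-sample manual thresholds are unknown, so
  exact reproduction of any particular scan's mask is impossible in
  principle; Otsu is offered as a reproducible fallback, not as a claim
  about what the protocol did.
* The organ mask is a morphological proxy for the organ boundary; where the
  true organ extends beyond the closed vascular hull (e.g. avascular
  capsule), that tissue is invisible to the CDF denominator.
* Fractions are reported over the whole organ mask; regional analysis
  (cortex vs medulla) would require anatomical annotation the package does
  not model.
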