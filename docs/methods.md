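# Methods

## Data model and conventions

All stored coordinates are micrometres; normalized quantities are computed
on the fly and never stored as inputs. Voxel indices are 0-based and map
to physical space by the voxel-center convention
`physical = (index + 0.5) · voxel_size`, with a default voxel of
0.079 × 0.079 × 0.244 μm (x, y, z), i.e. strongly anisotropic confocal
sampling. Nuclei are spheres by default; macrophage nuclei are
near-spherical, and for a sphere the "local radius" along any ray equals
the radius. An axis-aligned ellipsoid envelope is available
(`NucleusGeometry.semiaxes`), in which case the local radius is the
envelope distance along the center→spot ray.

Radial positions divide by the local radius (range [0, 1], small
overshoots from segmentation noise are clipped within a 5% tolerance and
logged). Pairwise gene distances divide by the nucleus *diameter*,
2 × equivalent-sphere radius: a per-ray "local diameter" is ill-posed for
a two-point segment, and per-cell size correction is the purpose of the
normalization. Angle labels follow the vertex convention: `A` is the angle
at the class III vertex (numerically opposite side `a` = I–II), `B` at
class I, `C` at class II — the reverse of the usual "angle A opposite side
a" reading, so it is stated everywhere the angles surface. Degenerate
triangles with one zero side return 0° at the two touching vertices and
180° at the third.

## Allele pairing and compaction classification

The pairing algorithm is not dictated by the measurement model, so the
package uses the simplest auditable rule: among the four one-spot-per-
channel partitions of the six spots into two triplets, take the one with
minimal total within-triplet pairwise distance, and reject the nucleus as
"not clearly differentiated" when the runner-up score is within a relative
margin (default 20%) of the winner. The choice is brute-forceable and the
test suite checks it against exhaustive enumeration on every simulated
nucleus.

Compaction uses physical (μm) distances because the threshold is physical:
two loci are separated when their center distance is at least `r_i + r_j`,
the sum of the spot radii (equal radii: `2r`). An allele with all three
pairs separated is decompacted (D); with no pair separated, compacted (C);
mixed states are "ambiguous" and exclude the nucleus from pattern counts
(logged). A majority-vote rule (state of ≥2 pairs) and a global-2r̄
threshold are selectable alternatives. Under the independence null with
equiprobable states the pattern probabilities are exactly
(¼, ½, ¼) for (C-C, C-D, D-D); observed counts are tested by Pearson
goodness of fit (df = k − 1, no continuity correction) and
resting-vs-activated tables by a 3×2 contingency chi-squared (df = 2,
expected counts < 5 trigger a warning).

## Statistical comparisons

Two-sample comparisons default to the pooled-variance Student t on the raw
measurement values. Testing values rather than cumulative curves is
deliberate: pointwise tests on empirical CDFs would pseudo-replicate.
Welch and two-sample Kolmogorov–Smirnov variants are provided, as is an
optional Holm correction; raw p-values are the default since each
comparison is reported individually. The radial null is analytic: for
points uniform in a sphere, `P(X < d) = d³`.

## Survival-zone model

Each locus is confined in a sphere of radius `R_i` about a fixed center;
across cells, the observed distance for pair (i, j) ranges over
`[c_ij − R_i − R_j, c_ij + R_i + R_j]`. Population extremes of the three
diameter-normalized distances therefore determine the three pairwise sums
`R_i + R_j = (d_ij^max − d_ij^min)/2`, which solve in closed form for the
radii, and the center separations `c_ij = (d_ij^max + d_ij^min)/2`. The
identity `R_i + R_j = span/2` holds to machine precision by construction
and is the module's core regression test. Noisy data can produce a
negative closed-form radius; it is clamped to zero with a flag, the raw
value kept for diagnostics. Extremes pool both alleles of a nucleus by
default (per-allele fitting is a flag), and a quantile option
(`q`, using the (q, 1−q) empirical quantiles) is available for gross
outliers; the default `q = 0` is the strict min/max estimator.

Zone centers are laid out in a canonical 2D frame (r at the origin, g on
the positive x-axis, b in the upper half-plane by trilateration). Per-cell
reconstruction embeds each distance triple as a triangle and rigidly
aligns it to the centers by least squares (Kabsch, reflection searched);
this is this package's own reconstruction procedure, defined by the
stated objective. Densities use Gaussian KDE on a regular grid,
renormalized to integrate to 1 over the grid; an all-identical point set
(singular covariance) concentrates the unit mass in one cell.

### Finite-n bias of the extreme-value estimator

The min/max estimator converges from inside: the observed span
underestimates the true span. For loci uniform in 3D balls, the axial
projection density vanishes linearly at each pole, so the probability that
a pairwise distance comes within ε of its supremum scales as ε⁴, and the
expected deficit of the sample extreme scales as
`(R_i² R_j² / n)^(1/4)`. At n = 2000 this is roughly 8–15% of each
pairwise radius sum — a *bias*, not sampling noise, so it does not average
away over seeds, and reducing it by one order of magnitude requires ~10⁴×
more cells. Recovery experiments in the tests and the acceptance script
report exactly this: fitted radii reliably land *below* truth, within a
~n^(−1/4) band (typically 10–20% relative error at n = 2000, ~5–8% at
n = 20000). Radii fitted to real-scale populations should be read with
this downward bias in mind. Fitted spans are monotone non-decreasing on
nested subsamples, which the suite also checks.

## Synthetic populations

The generator emulates the study conditions the analysis assumes, not
chromatin physics:

- 75 nuclei per condition by default (the experimental range is ~60–88);
  nucleus radius Normal(4.0, 0.3) μm truncated below, near macrophage
  nucleus size.
- Two alleles per nucleus, anchored at ±0.5 R along a random axis, each a
  randomly rotated copy of a zone template (class II gene at the origin,
  class I at 0.9 μm, TNFα at (0.5, 0.6) μm; 0.3 μm zone radii; template
  re-centered on its centroid). Within each zone the locus is uniform —
  the within-zone motion model is not constrained by fixed-cell data, and
  uniform is the assumption made here.
- Spot radius 0.25 μm (BAC-probe FISH scale), so the compaction threshold
  is 0.5 μm. Allele states are drawn Bernoulli(`frac_decompacted`,
  default 0.5) and imposed geometrically: the triplet is rescaled about
  its centroid until all pairs are ≥1.2× (D) or ≤0.8× (C) the threshold,
  making ground-truth labels unambiguous. The 20% margins keep labels
  stable under the default 0.05 μm Gaussian measurement noise most of the
  time; noise still flips a minority of alleles to mixed/ambiguous states,
  which downstream exclusion handles — a realistic feature, not a bug.
- Activation lengthens one configured pair (default class I–III) by
  0.4 μm; the third locus is repositioned by trilateration so the other
  two distances are exactly preserved, keeping the effect attributable to
  one measure. A side effect mirrors the biology: formerly compacted
  alleles become mixed/decompacted, so activated populations have more
  D-D and more excluded nuclei.
- Randomness: one `SeedSequence` per run, spawned into one child stream
  per nucleus in index order, so growing a population never perturbs
  existing nuclei; the seed is mandatory.

What the generator does *not* model: chromatin polymer mechanics,
point-spread-function optics, chromosome territories, or correlated
motion of the three loci. Passing tests demonstrate the correctness of
the estimators on data satisfying the model's assumptions; they do not
certify the sphere-confinement model itself against real nuclei. The
compaction-state rescaling also distorts the effective zone geometry, so
radii fitted to full synthetic populations sit somewhat above the
generating zone radii — visible in `analysis/05_fit_sz.py`'s comparison.

Image rendering places an isotropic (in physical space) Gaussian blob of
σ = spot radius at each spot on the anisotropic voxel grid; detection
thresholds, labels 26-connected components, takes intensity-weighted
centroids, and estimates an equivalent-sphere radius from component
volume. The round-trip recovers centroids well within one voxel per axis
at high SNR.

## Problem sizes

Defaults throughout (75 nuclei per condition; 2000 cells for recovery
experiments; 5000 points for the radial null; 1000 replicates for type-I
error; 10⁴ random extreme sets for the algebra identity; 3 rendered nuclei
for the image round-trip) were chosen as the smallest sizes at which each
quantity is stable to well within its decision band, and run in seconds.

## Known limitations

- The extreme-value bias above is the dominant error of the survival-zone
  fit at realistic n; a debiased estimator (e.g. spacing-based tail
  extrapolation) is deliberately out of scope because the closed-form
  min/max estimator is the method under study.
- The t-test on pooled alleles treats the two alleles of a nucleus as
  independent observations, as does the distance pooling for extremes.
- Ellipsoid envelopes affect radial positions only; pair-distance
  normalization always uses the equivalent-sphere diameter.
- qPCR support is minimal by design: single reference gene, no
  multi-reference geometric mean, no downstream ANOVA.
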