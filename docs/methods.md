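# Methods

## The information dimension of a voxel set

`infodim` estimates the information (entropy-based) fractal dimension, D1,
of a binary 2D or 3D lattice — typically a subcortical gray-matter mask in
standard space at 1.5 mm isotropic voxels.  The set of foreground voxels is
covered by a grid of cubic boxes of side *r* (in cells).  With
N<sub>i</sub>(r) the number of foreground cells in box *i* and N<sub>all</sub>
the total foreground count, the occupancy probabilities are
p<sub>i</sub> = N<sub>i</sub>(r)/N<sub>all</sub> and the Shannon entropy

I(r) = −Σ<sub>i</sub> p<sub>i</sub> ln p<sub>i</sub>

is the information (in nats) needed to locate a point of the set to
accuracy *r*.  For a set of dimension D1 with a sufficiently uniform
natural measure, I(r) ≈ D1 · ln(1/r) + c over the scaling regime, so D1 is
obtained as the ordinary-least-squares slope of I(r) against ln(1/r).
Note that the entropy itself is the logarithmic ordinate of this "log–log"
plot; the slope is invariant to the common log base used for both axes.

Unlike the capacity (box-count) dimension D0, which only asks whether a box
is occupied, D1 weights boxes by how much of the structure they contain,
which makes it sensitive to inhomogeneity in the voxel distribution.  D0
and D2 (correlation dimension), surface-mesh FD and multifractal spectra
are out of scope.

## Grid placement

The counting grid is aligned to the structure, not to the image edge: the
grid origin is the first foreground voxel in C (row-major) scan order, and
boxes are half-open intervals [a + k·r, a + (k+1)·r) on each axis, with
partial boxes at the structure's edges included.  Because the anchor voxel
translates with the structure, every I(r) — and hence D1 — is invariant
under translation of the structure or empty padding of the image.  Each
foreground cell falls in exactly one box, so Σ N<sub>i</sub>(r) =
N<sub>all</sub> and Σ p<sub>i</sub> = 1 at every *r* (tested properties).

An alternative anchor, the bounding-box minimal corner, is equally
deterministic but splits large boxes very unevenly for centered symmetric
objects; in our hands it roughly tripled the spread of D1 across the
solid-sphere series (0.093 vs 0.033), so the first-voxel anchor is the
default and only convention.

## Box-size range

The default range is r = 2 … min(30, ⌊0.25 × shortest image side⌋), in
steps of 1 cell.  The minimum of 2 avoids the degenerate single-cell scale;
the 25 % cap keeps at least ~4 boxes along the shortest image axis.  For a
standard-space image of 121×145×121 cells this gives r = 2…30.  A stricter
advisory cap of 15 % of the shortest side (`cap_fraction=0.15`) is exposed
for small structures purely as an efficiency option.

Two further truncations are applied before fitting:

* **Zero-entropy points.**  When a single box covers the whole set,
  I(r) = 0; such points (a suffix of the curve) carry no scaling
  information and are dropped.
* **Extent cap.**  Boxes larger than the structure's shortest bounding-box
  extent no longer subdivide that axis: they probe the object's
  lower-dimensional silhouette (a rod-like residue of a compact solid),
  not its scaling regime.  Since D1 is a small-r limit, `compute_fd` caps
  the fitted curve at the shortest extent (keeping at least 5 points for
  very thin structures).  Without this cap, a hippocampus-sized solid
  ellipsoid in a standard-space image reads D1 ≈ 1.1 from the
  accidentally-linear large-r tail; with it, ≈ 2.5.

## Iterative fit and breakpoint selection

At large box sizes I(r) shows oscillatory behaviour and departs from the
linear regime; the box size separating the two is the breakpoint.  The fit
enumerates contiguous sub-ranges of the (truncated) curve, trimming freely
from the large-r end but at most `max_low_trim = 2` points from the
small-r end (the lower bound is revised only occasionally, while the
non-linear portion belongs to the large sizes), and returns the
least-squares fit with the largest R², subject to retaining at least
`min_points` points (default: max(5, half the usable points)).  Ties in R²
within 1e-12 break toward more retained points, then toward a smaller
largest-r.  The restriction on low-end trimming is deliberate: an
unrestricted window search preferentially selects short, accidentally
linear large-r windows whose shallow slope reflects the silhouette, not
the dimension.

Degenerate inputs: an empty mask raises an error before estimation; a
single-voxel structure returns D1 = 0 with a warning; a curve with fewer
usable points than `min_points` is an error.

## Known biases and what the phantoms show

Finite-range partition entropy is biased low for compact solids: boundary
boxes hold small occupancy fractions, depressing I(r) increasingly with
r/extent.  Measured on this implementation (all values recomputed by the
test suite and `scripts/acceptance.py`):

* solid filled cubes: D1 = 2.82 at 32³, 2.97 at 120³ (→ 3 as the lattice
  grows; non-divisor box sizes create a partial-box sawtooth);
* six solid spheres, diameters 60→45 mm at 1.5 mm cells (a ≈ 50 % volume
  reduction): D1 ≈ 2.65–2.69, spread 0.033 — the level sits ~0.28 below
  the continuum value 3 at these extents, but is nearly constant across
  the series, demonstrating the volume–complexity dissociation;
* rasterized circle outline (radius 8, 120×120): D1 = 1.096 over the
  retained range 2–16 (theory 1);
* 4th-iteration Koch curve (283×84): D1 = 1.167 (similarity dimension
  ln4/ln3 = 1.2619) — at this image size the smallest Koch segments span
  only ≈ 3.5 cells, so the smallest boxes partly see a 1-dimensional line;
* 3D random Cantor sets (128³, survival p): mean D1 over 10 seeds within
  0.15 of the theoretical 3 + ln p/ln 2 for p ∈ {0.5,…,0.9}
  (e.g. 2.35 vs 2.485 at p = 0.7; grid sizes that are not powers of two
  cut across the octree hierarchy and depress the slope slightly).

These biases are stable, systematic, and comparable between groups scanned
and processed identically, which is what the group contrast requires; the
absolute D1 level should not be read as a continuum dimension.

A further empirical finding: adding resolvable surface bumps to a smooth
solid ellipsoid *lowers* its finite-range D1 at 1–1.5 mm resolution
(rough surfaces put more mass into low-occupancy partial boxes at small
r).  The sign of the roughness→D1 relationship at these scales is
therefore estimator- and scale-dependent, and group differences in D1
should be interpreted as differences in scaling behaviour, not directly as
"more/less surface".

## Phantoms: what they emulate, what they do not

* `make_circle`, `make_koch` — midpoint/Bresenham 1-cell rasterizations of
  curves with known dimension.  They validate the 2D path of the
  estimator; they do not reproduce any particular external rasterizer
  bit-for-bit (anti-aliasing and endpoint rounding conventions differ
  between tools and shift D1 by a few hundredths).
* `make_cantor3d` — top-down octree with i.i.d. Bernoulli survival
  (probability p per subcube per level), matching the dimension formula
  3 + ln p/ln 2; cell counts follow a branching process with offspring
  Binomial(8, p), which the tests use as a moment oracle.
* `make_sphere`, `make_cube`, `make_sliced_cube` — solids for the
  volume-dissociation checks.  Sphere membership is by cell-center
  inclusion; image side = 2 × diameter in cells.  The sliced cube keeps
  the exact filled-cell count of the solid cube while spreading it into
  separated slabs (same volume, different geometry); its slab/gap layout
  is an interpretation, not a reproduction of any reference object.
* `make_bumpy_ellipsoid` — a solid ellipsoid whose radius is modulated by
  a standardized sum of Gaussian angular kernels at random directions.
  Default bump width 0.25 rad ≈ 5 mm lateral scale on a 20 mm semi-axis,
  i.e. above voxel size so the perturbation is resolvable; amplitude 0
  reproduces the smooth ellipsoid exactly.  It emulates millimeter-scale
  surface protrusions only; it has no internal texture, no partial-volume
  shell, and no segmentation noise.
* `make_cohort` — per-subject FD tables for two groups of 19 with ages
  uniform on 23–54 y, Bernoulli(½) sexes, group effect on the FD mean
  (default 0.027, about the observed hippocampal median gap), optional
  group×age interaction, Gaussian residual SD 0.015, and volumes
  positively coupled to FD.  It emulates the marginal and group structure
  of a real cohort, not its covariance across structures (structures are
  generated independently), nor non-Gaussian tails.

Passing tests on these phantoms therefore show that the estimator and the
statistical pipeline behave correctly under the stated geometric and
distributional assumptions; they do not certify accuracy on real masks
with segmentation noise, partial-volume effects, or inter-structure
correlation.

## Statistical pipeline

* **Mann-Whitney U** (two-tailed): exact p when both groups have ≤ 10
  observations and no ties; tie-corrected normal approximation otherwise.
  The function returns U for its first argument; per-structure reports use
  the min-U convention min(U, n₁n₂ − U).  Identical samples give p = 1
  with a warning.
* **Shapiro-Wilk** per group (3 ≤ n ≤ 5000) is reported as the gate
  justifying the nonparametric tests; it does not alter the pipeline.
* **FDR**: Benjamini-Hochberg step-up at α = 0.05 across all reported
  structures (fifteen in the emulated design).  Both the input level and
  the realized critical p (largest flagged p-value) are reported.
* **Cohen's U3**: fraction of the lower-scoring group strictly below the
  median of the higher-scoring group (values equal to the median do not
  count).  CIs are percentile bootstrap, default 10,000 resamples,
  seeded; resampling both groups independently.
* **Interaction models**: OLS with terms (intercept, group, covariate,
  group×covariate); simple slopes are within-group OLS fits with
  df = n_g − 2.  Centering the covariate changes neither the interaction
  coefficient nor its t.  Rank-deficient designs raise with the collinear
  term named.
* **Spearman's rho** with tie handling for the FD-volume association.

## Problem sizes used in the shipped checks

The validation battery runs the circle (120²), Koch (283×84), ten 128³
random Cantor sets, and six spheres (60³–80³) — about 15 s total.  The
calibration simulations use 1,000 null cohorts of 19+19 for the type-I
error of the Mann-Whitney test and of the interaction term, 200–500
replicates elsewhere.  Brute-force box-counting oracles run on lattices up
to 40³.
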