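# infodim

Entropy-based box-counting fractal dimension (the information dimension,
D1) for binary brain-structure masks, with a phantom validation battery and
the nonparametric group-comparison pipeline used in case-control
morphometry.

## Why

Subtle, millimeter-scale irregularities in the shape of subcortical
gray-matter structures (hippocampus, thalamus, …) are hard to capture with
volumetry alone.  The fractal dimension is a compact, scale-free shape
descriptor: it quantifies how the detail of a structure changes across
spatial scales and is dissociable from volume — shrinking an object by
half leaves its D1 nearly unchanged.  `infodim` is aimed at researchers
who have binary (or probabilistic) segmentation masks in NIfTI format —
e.g. model-based subcortical segmentations resampled to standard space at
1.5 mm — and want per-structure D1 values plus group statistics.

## The estimator

For a set of foreground voxels covered by a grid of cubic boxes of side
*r*, with p_i = N_i(r)/N_all the fraction of the structure's voxels in box
*i*, the Shannon entropy

    I(r) = − Σ_i p_i ln p_i

measures the information needed to locate a point of the set to accuracy
*r*, and the information dimension is the slope of I(r) versus ln(1/r):

    I(r) ≈ D1 · ln(1/r) + c  over the scaling regime.

The grid is aligned to the structure (anchored at its first voxel in scan
order, hence translation-invariant), box sizes run from 2 cells up to 25 %
of the shortest image side (capped at 30), and the final slope is fitted
over a sub-range selected by an iterative breakpoint search that trims the
oscillatory large-box points and maximizes R².  See `docs/methods.md` for
the full procedure and its known finite-range biases.

## Worked example

Validate the estimator on phantoms with known dimensions:

```
$ infodim validate --seeds 3
phantom                                     expected  computed  range
circle r=8 120x120                            1.0000    1.0958  2-16
Koch n=4 283x84                               1.2619    1.1667  2-11
random Cantor 128^3 p=0.7 (mean of 3)         2.4854    2.3510  -
```

`expected` is each phantom's theoretical dimension (circle: a smooth
curve, dimension 1; Koch: similarity dimension ln4/ln3; random Cantor:
3 + ln p/ln 2); `computed` is the box-counting estimate on the rasterized
object, and `range` the retained box sizes of the final fit.  Estimates on
finite rasters sit within ~0.1 of theory, with the systematic finite-range
biases discussed in the methods note.

Compute D1 and volume for a mask (here, a generated 60 mm sphere phantom):

```
$ infodim phantom --kind sphere --diameter-mm 60 --out sphere60.nii.gz
$ infodim compute --mask sphere60.nii.gz
subject_id structure       d1       r2  min_r  max_r  voxels      mm3
  sphere60  sphere60 2.683371 0.999678      4     13   33552 113238.0
```

A solid ball reads D1 ≈ 2.68 at this lattice size (R² > 0.999 over the
retained box range 4–13); its voxel-count volume, 113,238 mm³, matches the
analytic 4/3·π·30³ ≈ 113,097 mm³ to 0.13 %.  Batch runs over many masks
(`--mask 'masks/*.nii.gz' --out results/`) write a per-subject×structure
CSV plus a JSON manifest recording every fit; `infodim stats --table
cohort.csv` then produces the per-structure report (group medians and
ranges, Mann-Whitney U and p, FDR flags, Cohen's U3 with bootstrap CI).

The same functionality is available as a library:

```python
from infodim import make_sphere, compute_fd
res = compute_fd(make_sphere(60.0, cell_mm=1.5))
print(res.d1, res.retained_range, res.volume_mm3)
```

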