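"""Validation phantoms and synthetic cohorts.

Objects with known (or constructible) theoretical dimension used to validate
the information-dimension estimator:

* a rasterized circle outline (theoretical dimension 1);
* the Koch curve, similarity dimension ln 4 / ln 3 ≈ 1.2619;
* a 3D random Cantor set with per-subcube survival probability p,
  theoretical dimension 3 + ln p / ln 2 (≈ 2.485 for p = 0.7);
* voxelized solid spheres and cubes (dimension 3) for the volume-dissociation
  checks, plus a sliced-cube variant (fixed volume, different arrangement);
* solid ellipsoids with a random angular bump field, a tunable stand-in for
  millimeter-level surface protrusions on subcortical structures;
* two-group per-subject FD tables emulating a patients-vs-controls cohort,
  with a group effect and optional group-by-age interaction.

All stochastic generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter, line

from .lattice import BinaryLattice

__all__ = [
    "koch_similarity_dimension",
    "random_cantor_dimension",
    "make_circle",
    "koch_vertices",
    "make_koch",
    "make_cantor3d",
    "make_sphere",
    "make_cube",
    "make_sliced_cube",
    "make_bumpy_ellipsoid",
    "make_cohort",
    "COHORT_STRUCTURES",
]


def koch_similarity_dimension() -> float:
    """Similarity dimension of the Koch curve: 4 copies at scale 1/3."""
    return np.log(4) / np.log(3)


def random_cantor_dimension(survival_p: float, ndim: int = 3) -> float:
    """Theoretical dimension of a random Cantor set, ndim + ln p / ln 2."""
    if not 0 < survival_p <= 1:
        raise ValueError("survival_p must be in (0, 1]")
    return ndim + np.log(survival_p) / np.log(2)


def make_circle(radius: int, image_size: tuple[int, int] = (120, 120)) -> BinaryLattice:
    """1-pixel-wide midpoint-rasterized circle outline, centered in the image.

    The standard validation phantom uses radius 8 in a 120x120 image.
    """
    h, w = image_size
    if 2 * radius + 1 > min(h, w):
        raise ValueError(f"circle of radius {radius} does not fit in {image_size}")
    cells = np.zeros((h, w), dtype=np.uint8)
    rr, cc = circle_perimeter(h // 2, w // 2, radius)
    cells[rr, cc] = 1
    return BinaryLattice(cells=cells, label=f"circle_r{radius}")


def koch_vertices(iterations: int) -> np.ndarray:
    """Vertices of the Koch curve on the unit baseline, as (x, y) rows.

    Each iteration replaces every segment by 4 segments at scale 1/3 with a
    60-degree outward apex, so the vertex count is 4**n + 1.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = np.array([0.0 + 0.0j, 1.0 + 0.0j])
    rot = np.exp(-1j * np.pi / 3)  # apex above the baseline in (x, y)
    for _ in range(iterations):
        p, q = pts[:-1], pts[1:]
        d = (q - p) / 3
        a = p + d
        b = p + 2 * d
        apex = a + d * rot
        new = np.empty(4 * len(p) + 1, dtype=complex)
        new[0:-1:4] = p
        new[1::4] = a
        new[2::4] = apex
        new[3::4] = b
        new[-1] = pts[-1]
        pts = new
    return np.column_stack([pts.real, -pts.imag])


def make_koch(iterations: int, image_size: tuple[int, int] = (283, 84)) -> BinaryLattice:
    """Koch curve scaled to the image width, rasterized with 1-pixel lines.

    The image is (width, height) to match the conventional 283x84 phantom
    geometry for the fourth iteration; the returned lattice is stored as
    (rows=height, cols=width).  Iteration 0 is a straight line spanning the
    width.
    """
    w, h = image_size
    verts = koch_vertices(iterations)
    scale = (w - 1) / (verts[:, 0].max() - verts[:, 0].min())
    if iterations > 0 and scale / 3**iterations < 1.0:
        warnings.warn(
            "image too small to resolve the smallest Koch segments", stacklevel=2
        )
    cols = np.rint(verts[:, 0] * scale).astype(int)
    height_px = verts[:, 1].max() * scale
    if height_px > h - 1:
        warnings.warn("Koch curve exceeds image height; clipping", stacklevel=2)
    base_row = min(h - 1, int(np.rint(height_px)) + 1)
    rows = np.clip(base_row - np.rint(verts[:, 1] * scale).astype(int), 0, h - 1)
    cells = np.zeros((h, w), dtype=np.uint8)
    for k in range(len(cols) - 1):
        rr, cc = line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        cells[rr, cc] = 1
    return BinaryLattice(cells=cells, label=f"koch_n{iterations}")


def make_cantor3d(levels: int, survival_p: float, seed: int) -> BinaryLattice:
    """3D random Cantor set on a 2**levels cube by top-down octree survival.

    Starting from a single full cube, each level splits every surviving cube
    into 2x2x2 subcubes, keeping each independently with probability
    ``survival_p``.  The expected cell count is (8 p)**levels and the
    theoretical dimension 3 + ln p / ln 2.  ``survival_p = 1`` keeps the full
    cube.  The side is a power of two by construction.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if not 0 < survival_p <= 1:
        raise ValueError("survival_p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    alive = np.ones((1, 1, 1), dtype=bool)
    for _ in range(levels):
        alive = alive.repeat(2, 0).repeat(2, 1).repeat(2, 2)
        alive &= rng.random(alive.shape) < survival_p
    return BinaryLattice(
        cells=alive.astype(np.uint8), label=f"cantor3d_p{survival_p}"
    )


def make_sphere(diameter_mm: float, cell_mm: float = 1.5) -> BinaryLattice:
    """Solid voxelized ball: cell is 1 iff its center is within the radius.

    Image side = 2 x diameter in cells (e.g. 80 cells for a 60 mm sphere at
    1.5 mm), matching the volume-dissociation phantom series.
    """
    if diameter_mm <= cell_mm:
        raise ValueError("diameter must exceed the cell size")
    side = int(round(2 * diameter_mm / cell_mm))
    centers = (np.arange(side) + 0.5) * cell_mm - side * cell_mm / 2
    x, y, z = np.meshgrid(centers, centers, centers, indexing="ij")
    cells = (x * x + y * y + z * z) <= (diameter_mm / 2) ** 2
    return BinaryLattice(
        cells=cells.astype(np.uint8),
        cell_size=(cell_mm,) * 3,
        label=f"sphere_d{diameter_mm:g}mm",
    )


def make_cube(side_cells: int, image_size: tuple[int, int, int] | None = None,
              cell_mm: float = 1.0) -> BinaryLattice:
    """Solid filled cube, centered; by default it spans the whole image."""
    if side_cells < 1:
        raise ValueError("side_cells must be >= 1")
    if image_size is None:
        image_size = (side_cells,) * 3
    if any(s < side_cells for s in image_size):
        raise ValueError("cube does not fit in image")
    cells = np.zeros(image_size, dtype=np.uint8)
    off = [(s - side_cells) // 2 for s in image_size]
    cells[tuple(slice(o, o + side_cells) for o in off)] = 1
    return BinaryLattice(cells=cells, cell_size=(cell_mm,) * 3,
                         label=f"cube_{side_cells}")


def make_sliced_cube(side_cells: int, n_slices: int, gap: int = 2,
                     cell_mm: float = 1.0) -> BinaryLattice:
    """Cube cut into lateral slabs separated by empty gaps; volume preserved.

    The filled cell count equals ``side_cells**3`` exactly, but the slabs are
    spread along the first axis, so the object has the same volume as the
    solid cube with a different spatial arrangement (and hence a different
    estimated dimension).
    """
    if n_slices < 1 or gap < 1:
        raise ValueError("need n_slices >= 1 and gap >= 1")
    base, extra = divmod(side_cells, n_slices)
    if base == 0:
        raise ValueError("more slices than cube cells per side")
    thicknesses = [base + (1 if k < extra else 0) for k in range(n_slices)]
    total_h = sum(thicknesses) + gap * (n_slices - 1)
    cells = np.zeros((total_h, side_cells, side_cells), dtype=np.uint8)
    pos = 0
    for t in thicknesses:
        cells[pos : pos + t] = 1
        pos += t + gap
    return BinaryLattice(cells=cells, cell_size=(cell_mm,) * 3,
                         label=f"sliced_cube_{side_cells}x{n_slices}")


def make_bumpy_ellipsoid(
    semi_axes_mm: tuple[float, float, float],
    bump_amplitude_mm: float = 0.0,
    bump_count: int = 40,
    cell_mm: float = 1.5,
    seed: int = 0,
    bump_width_rad: float = 0.25,
    image_size: tuple[int, int, int] | None = (121, 145, 121),
) -> BinaryLattice:
    """Solid ellipsoid with a smooth random angular bump field on its surface.

    The radius along direction u is modulated as R(u) + A * z(u), where z is
    a standardized sum of ``bump_count`` Gaussian angular kernels (width
    ``bump_width_rad``) centered at random directions, and A is the bump
    amplitude in mm.  Amplitude 0 reproduces the smooth ellipsoid exactly.
    Hippocampus-like defaults would be semi-axes (20, 10, 8) mm with a few
    mm of amplitude.

    By default the object is centered in a 121x145x121-cell image, the
    standard-space grid of real masks at 1.5 mm, so the default box-size
    range (2..30) applies; ``image_size=None`` gives a tight image instead.
    """
    a, b, c = semi_axes_mm
    if min(a, b, c) < 3 * cell_mm:
        raise ValueError("semi-axes must be at least 3 cells long")
    if bump_amplitude_mm < 0:
        raise ValueError("bump amplitude must be >= 0")
    half = [int(np.ceil((ax + bump_amplitude_mm) / cell_mm)) + 2 for ax in (a, b, c)]
    shape = tuple(2 * hx for hx in half)
    coords = [
        (np.arange(n) + 0.5) * cell_mm - n * cell_mm / 2 for n in shape
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if bump_amplitude_mm == 0 or bump_count == 0:
        inside = rho <= 1.0
    else:
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(bump_count, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        dist = np.sqrt(x * x + y * y + z * z)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.stack([x, y, z], axis=-1) / dist[..., None]
        u = np.nan_to_num(u)  # image center: inside regardless of field
        cosang = np.clip(np.tensordot(u, centers.T, axes=1), -1.0, 1.0)
        ang = np.arccos(cosang)
        field = np.exp(-(ang**2) / (2 * bump_width_rad**2)).sum(axis=-1)
        zfield = (field - field.mean()) / field.std()
        # mm radius of the smooth ellipsoid along u (for rho normalization)
        with np.errstate(divide="ignore"):
            r_u = dist / np.where(rho > 0, rho, 1.0)
        inside = rho <= 1.0 + bump_amplitude_mm * zfield / np.where(r_u > 0, r_u, 1.0)
        inside |= rho == 0
    cells = inside.astype(np.uint8)
    if image_size is not None:
        if any(img < n for img, n in zip(image_size, cells.shape)):
            raise ValueError("ellipsoid does not fit in the requested image")
        pad = [((img - n) // 2, img - n - (img - n) // 2)
               for img, n in zip(image_size, cells.shape)]
        cells = np.pad(cells, pad)
    return BinaryLattice(
        cells=cells,
        cell_size=(cell_mm,) * 3,
        label="bumpy_ellipsoid",
    )


#: the fifteen per-subject outputs of the study design: seven bilateral
#: subcortical gray-matter structures plus the brainstem
COHORT_STRUCTURES = (
    "L_Thal", "R_Thal", "L_Caud", "R_Caud", "L_Puta", "R_Puta",
    "L_Pall", "R_Pall", "L_Hipp", "R_Hipp", "L_Amyg", "R_Amyg",
    "L_Accu", "R_Accu", "BrStem",
)


def make_cohort(
    n_per_group: int = 19,
    effect: float | dict[str, float] = 0.027,
    interaction_slope: float = 0.0,
    noise_sd: float = 0.015,
    seed: int = 0,
    structures: tuple[str, ...] = ("L_Hipp",),
    baseline: float = 2.17,
    age_range: tuple[float, float] = (23.0, 54.0),
) -> pd.DataFrame:
    """Two-group per-subject FD table with a built-in group effect.

    Per subject and structure,

        fd = baseline - effect * [group = SCZ]
                      - interaction_slope * age * [group = SCZ]
                      + Normal(0, noise_sd)

    Ages are uniform over ``age_range`` (the 23-54 y span of the emulated
    cohort), sexes Bernoulli(1/2).  Volumes are generated positively coupled
    to fd.  Defaults emulate the hippocampus contrast of a 19-vs-19
    patients/controls design: baseline FD 2.17, group effect 0.027 (the
    observed median gap), residual SD 0.015.  ``effect`` may be a mapping
    from structure name to effect size (structures absent from the mapping
    get 0).

    Returns a tidy DataFrame with columns
    (subject_id, group, age, sex, structure, fd, volume_mm3).
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 subjects per group")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    subjects = [f"S{k:03d}" for k in range(1, n + 1)]
    groups = np.array(["SCZ"] * n_per_group + ["HC"] * n_per_group)
    ages = rng.uniform(*age_range, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    rows = []
    for struct in structures:
        eff = effect.get(struct, 0.0) if isinstance(effect, dict) else effect
        is_scz = (groups == "SCZ").astype(float)
        fd = (
            baseline
            - eff * is_scz
            - interaction_slope * ages * is_scz
            + rng.normal(0.0, noise_sd, size=n)
        )
        vol = 2200.0 + 4000.0 * (fd - baseline) + rng.normal(0.0, 60.0, size=n)
        vol = np.maximum(vol, 1.0)
        for k in range(n):
            rows.append(
                (subjects[k], groups[k], ages[k], sexes[k], struct, fd[k], vol[k])
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "age", "sex", "structure", "fd", "volume_mm3"],
    )
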