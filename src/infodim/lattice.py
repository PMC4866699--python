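"""Binary voxel lattices: the sets whose fractal dimension is measured.

A :class:`BinaryLattice` is a rectangular 2D or 3D array of {0,1} cells with
physical cell dimensions.  Real inputs are binary (or probabilistic, then
thresholded) segmentation masks of subcortical structures in NIfTI format,
typically model-based segmentation outputs resampled to standard space at
1.5 mm isotropic voxels.  Masks are processed in stored voxel order; the
orientation/affine matrix is ignored except for the voxel dimensions used in
volumetry, since the dimension estimate needs no world coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "BinaryLattice",
    "EmptyStructureError",
    "MaskReadError",
    "read_mask",
    "write_mask",
    "lattice_volume",
    "bounding_box",
]


class EmptyStructureError(ValueError):
    """Raised when a mask contains no foreground cells."""


class MaskReadError(IOError):
    """Raised when a mask file cannot be read or has an unsupported layout."""


@dataclass
class BinaryLattice:
    """A 2D/3D rectangular lattice of {0,1} cells with physical cell sizes.

    Parameters
    ----------
    cells
        Array of 0/1 values over 2 or 3 axes (stored as ``uint8``).
    cell_size
        Physical edge length of a cell along each axis, in mm.  Use 1.0 on
        every axis for abstract phantoms.
    label
        Free-text structure name (e.g. ``"L_Hipp"``).
    """

    cells: np.ndarray
    cell_size: tuple[float, ...] = ()
    label: str = ""
    _count: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim not in (2, 3):
            raise ValueError(f"lattice must have 2 or 3 axes, got {cells.ndim}")
        uniq = np.unique(cells)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("lattice cells must be exactly 0 or 1")
        self.cells = cells.astype(np.uint8, copy=False)
        if not self.cell_size:
            self.cell_size = (1.0,) * cells.ndim
        self.cell_size = tuple(float(s) for s in self.cell_size)
        if len(self.cell_size) != cells.ndim:
            raise ValueError("cell_size must give one edge length per axis")
        if any(s <= 0 for s in self.cell_size):
            raise ValueError("cell sizes must be positive")
        self._count = int(self.cells.sum())

    @property
    def ndim(self) -> int:
        return self.cells.ndim

    @property
    def count(self) -> int:
        """Number of foreground (1) cells, ``N_all``."""
        return self._count

    def require_nonempty(self) -> None:
        if self._count == 0:
            raise EmptyStructureError(
                f"structure {self.label!r} has no foreground cells"
            )


def read_mask(path: str | os.PathLike, threshold: float = 0.0) -> BinaryLattice:
    """Read a mask image and binarize it at ``intensity > threshold``.

    Supports NIfTI (``.nii``, ``.nii.gz``), NumPy ``.npy`` and plain-text
    arrays (``.txt``, 2D only).  Cell sizes come from the NIfTI header's
    voxel dimensions (1.0 mm otherwise); axis order is the file's storage
    order.  The default threshold 0 treats any positive label as structure,
    matching boundary-corrected segmentation label images.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    path = os.fspath(path)
    name = os.path.basename(path)
    label = name
    for suffix in (".nii.gz", ".nii", ".npy", ".txt"):
        if name.endswith(suffix):
            label = name[: -len(suffix)]
            break
    try:
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(path)
            data = np.asanyarray(img.dataobj)
            zooms = img.header.get_zooms()[: data.ndim]
            cell_size = tuple(float(z) for z in zooms)
        elif name.endswith(".npy"):
            data = np.load(path)
            cell_size = (1.0,) * data.ndim
        else:
            data = np.loadtxt(path)
            cell_size = (1.0,) * data.ndim
    except Exception as exc:  # corrupt/unreadable file
        raise MaskReadError(f"cannot read mask {path!r}: {exc}") from exc
    if data.ndim not in (2, 3):
        raise MaskReadError(f"mask {path!r} has {data.ndim} axes; expected 2 or 3")
    cells = (data > threshold).astype(np.uint8)
    return BinaryLattice(cells=cells, cell_size=cell_size, label=label)


def write_mask(lat: BinaryLattice, path: str | os.PathLike) -> None:
    """Write a lattice as NIfTI (affine = diag(cell_size)) or ``.npy``."""
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        for i, s in enumerate(lat.cell_size):
            affine[i, i] = s
        img = nib.Nifti1Image(lat.cells.astype(np.uint8), affine)
        img.header.set_zooms(lat.cell_size)
        nib.save(img, path)
    elif path.endswith(".npy"):
        np.save(path, lat.cells)
    else:
        raise ValueError(f"unsupported mask output format: {path!r}")


def lattice_volume(lat: BinaryLattice) -> tuple[int, float]:
    """Return ``(voxel_count, volume_mm3)`` of the foreground.

    ``volume_mm3 = count * prod(cell_size)``, the voxel-count volumetry used
    for subcortical structures (equivalent to summing a binary mask).
    """
    lat.require_nonempty()
    voxels = lat.count
    mm3 = voxels * float(np.prod(lat.cell_size))
    return voxels, mm3


def bounding_box(lat: BinaryLattice) -> tuple[tuple[int, int], ...]:
    """Tight per-axis ``(min_index, max_index)`` bounds of the 1-cells."""
    lat.require_nonempty()
    nz = np.nonzero(lat.cells)
    return tuple((int(ax.min()), int(ax.max())) for ax in nz)
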