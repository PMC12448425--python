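"""Reading, writing, validation, and resampling of 3D segmentation masks.

Masks are NIfTI-1/2 volumes; any nonzero voxel is foreground.  World
coordinates are millimetres, voxel centers map through the affine
(center-of-voxel convention, 0-based indices).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ContainmentError, GeometryMismatchError, MaskFormatError

__all__ = [
    "VolumeGrid",
    "SegmentationPair",
    "read_mask",
    "write_mask",
    "validate_pair",
    "resample_isotropic",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A binary 3D label lattice with spacing and a voxel-to-world affine.

    Attributes
    ----------
    data : (i, j, k) uint8 array of {0, 1}
    spacing : per-axis voxel edge length in mm, all strictly positive
    affine : (4, 4) voxel-index -> world-mm map (voxel centers)
    label_map : semantic names for the nonzero labels
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: {1: "tumor"})

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise MaskFormatError(f"mask must be 3D, got {data.ndim}D")
        if min(data.shape) < 1:
            raise MaskFormatError(f"degenerate mask dimensions {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MaskFormatError(f"spacing must be 3 positive values, got {spacing}")
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise MaskFormatError("affine must be a non-degenerate 4x4 matrix")
        # binarize by nonzero test, then require the resulting label to be
        # declared (multi-label atlases are out of scope)
        binary = np.ascontiguousarray(data != 0, dtype=np.uint8)
        if binary.any() and 1 not in self.label_map:
            raise MaskFormatError("label_map must declare label 1 for foreground")
        object.__setattr__(self, "data", binary)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        label: str = "tumor",
    ) -> "VolumeGrid":
        """Build a grid with an axis-aligned affine from spacing and origin."""
        affine = np.diag([*spacing, 1.0]).astype(float)
        affine[:3, 3] = origin
        return cls(data, tuple(spacing), affine, {1: label})

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm through the affine."""
        idx = np.atleast_2d(indices).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass(frozen=True)
class SegmentationPair:
    """A validated tumor/brain mask pair on one common lattice."""

    tumor: VolumeGrid
    brain: VolumeGrid
    provenance: str = ""


def read_mask(path: str | os.PathLike, label: str = "tumor") -> VolumeGrid:
    """Read a NIfTI volume as a binary :class:`VolumeGrid`.

    Any nonzero voxel becomes foreground.  Raises
    :class:`~gliomashape.errors.MaskFormatError` for missing files, non-3D
    volumes, or non-positive header spacing.
    """
    if not os.path.exists(path):
        raise MaskFormatError(f"mask file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise MaskFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskFormatError(
            f"{path}: expected a 3D volume, header dim gives {data.ndim}D"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MaskFormatError(f"{path}: non-positive header pixdim {zooms}")
    return VolumeGrid(data, tuple(float(z) for z in zooms), img.affine, {1: label})


def write_mask(grid: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a grid as NIfTI; read_mask(write_mask(g)) is lossless."""
    img = nib.Nifti1Image(grid.data.astype(np.uint8), grid.affine)
    img.header.set_zooms(grid.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise MaskFormatError(f"cannot write {path}: {exc}") from exc


def validate_pair(
    tumor: VolumeGrid, brain: VolumeGrid, provenance: str = ""
) -> SegmentationPair:
    """Check tumor/brain geometry agreement and tumor ⊆ brain containment.

    Raises :class:`GeometryMismatchError` on any dimension/spacing/affine
    disagreement and :class:`ContainmentError` (with the offending voxel
    count) if tumor voxels fall outside the brain mask.
    """
    problems = []
    if tumor.shape != brain.shape:
        problems.append(f"dimensions {tumor.shape} vs {brain.shape}")
    if not np.allclose(tumor.spacing, brain.spacing, atol=1e-6):
        problems.append(f"spacing {tumor.spacing} vs {brain.spacing}")
    if tumor.shape == brain.shape and not np.allclose(
        tumor.affine, brain.affine, atol=1e-6
    ):
        problems.append("affine transforms differ")
    if problems:
        raise GeometryMismatchError("grid geometry mismatch: " + "; ".join(problems))
    outside = int(np.count_nonzero(tumor.data & ~brain.data.astype(bool)))
    if outside:
        raise ContainmentError(outside)
    return SegmentationPair(tumor=tumor, brain=brain, provenance=provenance)


def resample_isotropic(grid: VolumeGrid, target_spacing: float) -> VolumeGrid:
    """Nearest-neighbour resample onto an isotropic lattice.

    The new lattice covers the same world extent (voxel-edge bounding box)
    to within one target voxel.  Nearest-neighbour keeps labels binary.
    """
    t = float(target_spacing)
    if t <= 0:
        raise MaskFormatError(f"target_spacing must be > 0, got {target_spacing}")
    shape = np.array(grid.shape)
    spacing = np.array(grid.spacing)
    new_shape = np.maximum(np.ceil(shape * spacing / t - 1e-9).astype(int), 1)

    # direction vectors of the source lattice, renormalized to length t
    rot = grid.affine[:3, :3]
    units = rot / spacing[None, :]
    new_rot = units * t
    # keep the world position of the voxel-edge corner fixed
    corner = grid.affine[:3, 3] - rot @ np.full(3, 0.5)
    new_origin = corner + new_rot @ np.full(3, 0.5)
    new_affine = np.eye(4)
    new_affine[:3, :3] = new_rot
    new_affine[:3, 3] = new_origin

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in new_shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = idx @ new_rot.T + new_origin
    src = (world - grid.affine[:3, 3]) @ np.linalg.inv(rot).T
    coords = src.T.reshape(3, *new_shape)
    data = map_coordinates(grid.data, coords, order=0, mode="constant", cval=0)
    return VolumeGrid(data.reshape(tuple(new_shape)), (t, t, t), new_affine, dict(grid.label_map))
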