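"""Geometric scores for tumor masks: volume, surface area, dural-contact
area, contact surface area (CSA), sphericity index (SI), and the extent of
resection (EOR) outcome.

Definitions
-----------
* total area ``A``: area of the iso-surface of the tumor mask
* dural-contact area ``B``: the part of ``A`` lying on the brain-mask
  boundary (within a distance tolerance)
* ``CSA = A - B``
* ``SI = A / area(sphere of equal volume)`` — 1 for a ball, larger for
  more complex shapes

Internally everything is computed in mm/mm^2/mm^3; reports convert to
cm^2/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes

from .errors import EmptyMaskError, GliomaShapeError
from .mask_io import SegmentationPair, VolumeGrid
from .mesh import SurfaceMesh, point_mesh_distance

__all__ = [
    "ShapeReport",
    "EORRecord",
    "mask_volume",
    "extract_surface",
    "mesh_area",
    "equal_volume_sphere_area",
    "sphericity_index",
    "dural_contact_area",
    "compute_shape_report",
    "compute_eor",
    "group_eor",
    "EOR_CATEGORIES",
]

#: Gaussian pre-smoothing of the binary field before iso-surfacing, in
#: voxel units.  Plain marching cubes on a binary lattice overestimates
#: the area of smooth solids by ~8-9% regardless of resolution; one voxel
#: of smoothing brings ball-phantom area errors under 1% and restores
#: convergence as spacing decreases.  Set to 0 to disable.
DEFAULT_SMOOTHING_SIGMA = 1.0


@dataclass(frozen=True)
class ShapeReport:
    """Per-tumor shape record, reported in cm^2 / cm^3."""

    volume_cm3: float
    total_area_cm2: float
    dural_area_cm2: float
    csa_cm2: float
    sphericity_index: float
    sphere_area_cm2: float

    def __post_init__(self):
        if not 0.0 <= self.dural_area_cm2 <= self.total_area_cm2 + 1e-12:
            raise GliomaShapeError(
                "dural area must lie in [0, total area]: "
                f"B={self.dural_area_cm2}, A={self.total_area_cm2}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EORRecord:
    pre_volume_cm3: float
    post_volume_cm3: float
    eor_fraction: float
    category: str | None = None


#: cohort-level EOR groups, ordered from least to most extensive resection
EOR_CATEGORIES = ("STR-lower", "STR-middle", "STR-upper", "GTR")


def mask_volume(grid: VolumeGrid) -> float:
    """Foreground volume in mm^3 (voxel count x voxel volume)."""
    return grid.n_foreground * grid.voxel_volume


def extract_surface(
    grid: VolumeGrid, smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA
) -> SurfaceMesh:
    """Closed triangulated iso-surface of a binary mask, world mm.

    The mask is zero-padded before extraction so the mesh closes even when
    foreground touches the lattice edge.  The binary field is smoothed by
    ``smoothing_sigma`` voxels (Gaussian) and iso-surfaced at level 0.5;
    if smoothing would erase a very small structure entirely, extraction
    falls back to the unsmoothed field.
    """
    if grid.n_foreground == 0:
        raise EmptyMaskError("cannot extract a surface from an empty mask")
    pad = max(2, int(math.ceil(3 * smoothing_sigma)))
    field = np.pad(grid.data, pad).astype(np.float64)
    if smoothing_sigma > 0:
        smoothed = gaussian_filter(field, smoothing_sigma)
        if smoothed.max() <= 0.5:  # structure thinner than the kernel
            smoothed = field
    else:
        smoothed = field
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5)
    verts -= pad  # back to unpadded voxel-index coordinates
    world = verts @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return SurfaceMesh(world, faces).cleaned()


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total triangle area, mm^2."""
    return mesh.area


def equal_volume_sphere_area(volume: float) -> float:
    """Surface area of the sphere with the given volume: (36*pi)^(1/3) * V^(2/3)."""
    if volume < 0:
        raise GliomaShapeError(f"volume must be >= 0, got {volume}")
    return (36.0 * math.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)


def sphericity_index(total_area: float, volume: float) -> float:
    """SI = total surface area / equal-volume-sphere area (>= 1 for solids)."""
    if volume <= 0:
        raise GliomaShapeError(f"volume must be > 0, got {volume}")
    if total_area <= 0:
        raise GliomaShapeError(f"total_area must be > 0, got {total_area}")
    return total_area / equal_volume_sphere_area(volume)


def dural_contact_area(
    pair: SegmentationPair,
    tolerance: float | None = None,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    _meshes: tuple[SurfaceMesh, SurfaceMesh] | None = None,
) -> float:
    """Area of the tumor surface lying on the brain-mask boundary, mm^2.

    A tumor triangle counts as dural contact iff its centroid lies within
    ``tolerance`` of the brain boundary surface, measured as exact
    point-to-mesh distance.  The default tolerance is 0.9x the largest
    spacing component: the field smoothing used before iso-surfacing
    rounds shared edges over about one voxel, so a half-voxel tolerance
    systematically misses the rounded rim of a contact patch (about -6%
    on a half-ball phantom at 0.5 mm), while ~one voxel recovers it
    without picking up tangential near-contact surface.  Zero when the
    tumor is everywhere at least ``tolerance`` interior to the brain mask.
    """
    if tolerance is None:
        tolerance = 0.9 * max(pair.tumor.spacing)
    if tolerance <= 0:
        raise GliomaShapeError(f"tolerance must be > 0, got {tolerance}")
    if _meshes is not None:
        tumor_mesh, brain_mesh = _meshes
    else:
        tumor_mesh = extract_surface(pair.tumor, smoothing_sigma)
        brain_mesh = extract_surface(pair.brain, smoothing_sigma)
    d = point_mesh_distance(
        tumor_mesh.triangle_centroids, brain_mesh, max_dist=tolerance
    )
    return float(tumor_mesh.triangle_areas[d <= tolerance].sum())


def compute_shape_report(
    pair: SegmentationPair,
    tolerance: float | None = None,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
) -> ShapeReport:
    """Assemble volume, A, B, CSA = A - B, and SI for a validated pair."""
    volume_mm3 = mask_volume(pair.tumor)
    tumor_mesh = extract_surface(pair.tumor, smoothing_sigma)
    brain_mesh = extract_surface(pair.brain, smoothing_sigma)
    total_mm2 = mesh_area(tumor_mesh)
    dural_mm2 = dural_contact_area(
        pair, tolerance, smoothing_sigma, _meshes=(tumor_mesh, brain_mesh)
    )
    total_cm2 = total_mm2 / 100.0
    dural_cm2 = dural_mm2 / 100.0
    return ShapeReport(
        volume_cm3=volume_mm3 / 1000.0,
        total_area_cm2=total_cm2,
        dural_area_cm2=dural_cm2,
        csa_cm2=total_cm2 - dural_cm2,
        sphericity_index=sphericity_index(total_mm2, volume_mm3),
        sphere_area_cm2=equal_volume_sphere_area(volume_mm3) / 100.0,
    )


def compute_eor(pre_volume: float, post_volume: float) -> float:
    """Fractional decrease in tumor volume, clamped to [0, 1]."""
    if pre_volume <= 0:
        raise GliomaShapeError(f"pre_volume must be > 0, got {pre_volume}")
    if post_volume < 0:
        raise GliomaShapeError(f"post_volume must be >= 0, got {post_volume}")
    return float(min(1.0, max(0.0, 1.0 - post_volume / pre_volume)))


def group_eor(eors: list[float] | np.ndarray) -> list[str]:
    """Label each EOR value GTR (exactly 1.0) or an STR tertile.

    Subtotal resections are split by rank into three tertile groups with
    boundaries at ranks ceil(n/3) and ceil(2n/3); ties keep input order
    (stable sort).
    """
    eor = np.asarray(eors, dtype=float)
    if eor.size == 0:
        raise GliomaShapeError("group_eor needs a nonempty list")
    if np.any((eor < 0) | (eor > 1)):
        raise GliomaShapeError("EOR values must lie in [0, 1]")
    labels = np.empty(eor.size, dtype=object)
    gtr = eor == 1.0
    labels[gtr] = "GTR"
    str_idx = np.where(~gtr)[0]
    n = len(str_idx)
    if n:
        order = str_idx[np.argsort(eor[str_idx], kind="stable")]
        b1 = math.ceil(n / 3)
        b2 = math.ceil(2 * n / 3)
        labels[order[:b1]] = "STR-lower"
        labels[order[b1:b2]] = "STR-middle"
        labels[order[b2:]] = "STR-upper"
    return labels.tolist()
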