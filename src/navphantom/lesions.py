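"""Lesion-based accuracy metrics: DSC, 95th-percentile Hausdorff distance,
and the lesion characteristics (volume, depth, L2 norm).

The ground-truth lesion (GT) is a binary voxel mask in the reference image
frame (RAS, mm).  The transformed model (TM) — the lesion as the navigation
system displays it after registration — is approximated by applying the
fitted rigid transform T* to GT and resampling back onto GT's voxel grid
with nearest-neighbour interpolation (binary masks must stay binary; this
accepts a discretization error of up to one voxel, which should be kept in
mind when reading HD95 values near the voxel spacing).

Overlap metrics compare GT and TM on the shared grid:

* DSC = 2 |GT ∩ TM| / (|GT| + |TM|), volumetric overlap in [0, 1];
* HD95 — for each GT surface point, the distance to the nearest TM surface
  point; the maximum over the smallest 95% of those distances (an
  outlier-robust boundary disagreement, mm).  Surface points are the centers
  of boundary voxels (foreground voxels with at least one background
  6-neighbour), in physical mm.  The directed form is the default; a
  symmetric variant takes the max of both directions.

Lesion characteristics:

* volume — foreground voxel count times the physical volume of one voxel,
  in cm^3;
* depth — minimum radius of a sphere centered at the lesion centroid and
  tangential to the skin surface, i.e. the exact point-to-triangle distance
  from the centroid to the skin mesh, in cm;
* L2 norm — distance from the lesion centroid to the reference image
  origin, in cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .registration import RigidFit

__all__ = [
    "LesionModel",
    "LesionAccuracy",
    "transform_lesion",
    "dsc",
    "surface_points",
    "percentile_max",
    "hd95",
    "lesion_depth",
    "l2_norm",
    "evaluate_lesion",
]

MM3_PER_CM3 = 1000.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class LesionModel:
    """A binary lesion mask with its voxel-grid geometry.

    ``origin`` is the RAS position (mm) of the *center* of voxel (0, 0, 0);
    ``direction`` maps index axes to RAS axes; world coordinates of index
    ``i`` are ``origin + direction @ (spacing * i)``.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"lesion mask must be 3-D, got shape {mask.shape}")
        mask = mask.astype(bool)
        if not mask.any():
            raise ValueError("lesion mask is empty")
        direction = (
            np.eye(3) if self.direction is None else np.asarray(self.direction, float)
        )
        if direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", direction)

    @property
    def affine(self) -> np.ndarray:
        """4x4 index-to-world (RAS mm) affine, voxel-center convention."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.atleast_2d(np.asarray(world, dtype=float))
        inv = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (world - np.asarray(self.origin)) @ inv.T

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def volume_cm3(self) -> float:
        """Foreground voxel count x single-voxel volume, in cm^3."""
        return float(self.mask.sum()) * self.voxel_volume_mm3 / MM3_PER_CM3

    @property
    def centroid(self) -> np.ndarray:
        """Geometric center of the foreground voxels, RAS mm."""
        idx = np.argwhere(self.mask).astype(float)
        return self.index_to_world(idx.mean(axis=0))[0]

    def same_grid(self, other: "LesionModel") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )


@dataclass(frozen=True)
class LesionAccuracy:
    """Per-lesion accuracy metrics and characteristics (Table-style row)."""

    case_id: str
    lesion_id: int
    dsc: float
    hd95_mm: float
    volume_cm3: float
    depth_cm: float
    l2_norm_cm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"DSC out of [0, 1]: {self.dsc}")
        if self.hd95_mm < 0:
            raise ValueError("HD95 must be non-negative")

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "lesion_id": self.lesion_id,
            "volume_cm3": self.volume_cm3,
            "depth_cm": self.depth_cm,
            "l2_norm_cm": self.l2_norm_cm,
            "dsc": self.dsc,
            "hd95_mm": self.hd95_mm,
        }


def transform_lesion(gt: LesionModel, fit: RigidFit) -> LesionModel:
    """Apply the fitted rigid transform to GT, resampled onto GT's grid.

    Each output voxel center w is foreground iff the inverse-mapped point
    T*^-1(w) falls in a foreground voxel of GT (nearest-neighbour lookup).
    Content pushed outside GT's grid is clipped; generator-produced grids
    carry enough margin that this does not truncate the lesion.
    """
    shape = gt.mask.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = gt.index_to_world(idx)
    # inverse map: where did each output voxel center come from?
    src_world = (world - fit.translation) @ fit.rotation
    src_idx = np.rint(gt.world_to_index(src_world)).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(shape)), axis=1)
    out = np.zeros(shape, dtype=bool)
    vals = np.zeros(len(src_idx), dtype=bool)
    si = src_idx[inside]
    vals[inside] = gt.mask[si[:, 0], si[:, 1], si[:, 2]]
    out.ravel()[:] = vals
    if not out.any():
        raise ValueError("transformed lesion fell entirely outside the voxel grid")
    return LesionModel(out, gt.spacing, gt.origin, gt.direction)


def dsc(gt: LesionModel, tm: LesionModel) -> float:
    """Sørensen–Dice coefficient 2|GT ∩ TM| / (|GT| + |TM|) on voxel sets."""
    if not gt.same_grid(tm):
        raise ValueError("DSC requires both masks on the same voxel grid")
    inter = np.logical_and(gt.mask, tm.mask).sum()
    total = int(gt.mask.sum()) + int(tm.mask.sum())
    return 2.0 * float(inter) / float(total)


def surface_points(lesion: LesionModel) -> np.ndarray:
    """Physical (mm) centers of boundary voxels (6-connectivity).

    A boundary voxel is a foreground voxel with at least one of its six
    face-neighbours in the background (voxels on the grid edge count).
    """
    mask = lesion.mask
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    boundary = mask & ~interior
    idx = np.argwhere(boundary).astype(float)
    if len(idx) == 0:
        raise ValueError("lesion has no surface voxels")
    return lesion.index_to_world(idx)


def percentile_max(distances: np.ndarray, fraction: float = 0.95) -> float:
    """Maximum of the smallest ``fraction`` of a distance multiset.

    With n distances this is the ceil(fraction * n)-th order statistic —
    e.g. for 100 distances, the largest of the smallest 95.
    """
    d = np.sort(np.asarray(distances, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("empty distance set")
    k = max(1, int(np.ceil(fraction * d.size)))
    return float(d[k - 1])


def _directed_hd95(from_pts: np.ndarray, to_pts: np.ndarray) -> float:
    dists, _ = cKDTree(to_pts).query(from_pts, k=1)
    return percentile_max(dists, 0.95)


def hd95(gt: LesionModel, tm: LesionModel, *, symmetric: bool = False) -> float:
    """95th-percentile Hausdorff distance between lesion surfaces, mm.

    Directed by default: for each GT surface point the distance to the
    nearest TM surface point, reduced by :func:`percentile_max`.  With
    ``symmetric=True``, the maximum of both directions (the variant most
    segmentation-comparison tools report).
    """
    gt_pts = surface_points(gt)
    tm_pts = surface_points(tm)
    d = _directed_hd95(gt_pts, tm_pts)
    if symmetric:
        d = max(d, _directed_hd95(tm_pts, gt_pts))
    return d


def lesion_depth(centroid_mm: np.ndarray, skin_mesh) -> float:
    """Minimum radius (cm) of a sphere at the centroid tangent to the skin.

    Exact point-to-triangle distance from the centroid to the skin surface
    mesh (vertex-only distance would overestimate on coarse meshes).
    """
    import trimesh

    if not isinstance(skin_mesh, trimesh.Trimesh):
        skin_mesh = trimesh.Trimesh(**skin_mesh)
    if len(skin_mesh.faces) == 0 or skin_mesh.area <= 0:
        raise ValueError("degenerate skin mesh: no faces with positive area")
    point = np.asarray(centroid_mm, dtype=float).reshape(3)
    triangles = skin_mesh.triangles  # (n, 3, 3)
    # exact closest point on every face, then the global minimum
    candidates = trimesh.triangles.closest_point(
        triangles, np.tile(point, (len(triangles), 1))
    )
    dist = np.linalg.norm(candidates - point, axis=1).min()
    return float(dist) / MM_PER_CM


def l2_norm(centroid_mm: np.ndarray) -> float:
    """Distance (cm) from the lesion centroid to the reference image origin."""
    return float(np.linalg.norm(np.asarray(centroid_mm, dtype=float))) / MM_PER_CM


def evaluate_lesion(
    gt: LesionModel,
    fit: RigidFit,
    skin_mesh,
    *,
    case_id: str = "",
    lesion_id: int = 1,
    symmetric_hd95: bool = False,
) -> LesionAccuracy:
    """Run the full lesion-based evaluation for one lesion of a case."""
    tm = transform_lesion(gt, fit)
    centroid = gt.centroid
    return LesionAccuracy(
        case_id=case_id,
        lesion_id=lesion_id,
        dsc=dsc(gt, tm),
        hd95_mm=hd95(gt, tm, symmetric=symmetric_hd95),
        volume_cm3=gt.volume_cm3,
        depth_cm=lesion_depth(centroid, skin_mesh),
        l2_norm_cm=l2_norm(centroid),
    )
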