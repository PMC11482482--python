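"""Necrosis zones: isoline extraction, 360-degree revolution, registration
and overlap/distance metrics against reference segmentations.

The 2D axisymmetric necrosis mask is turned into a contour (marching
squares with sub-cell interpolation), revolved about the needle axis into a
3D voxel mask and a swept surface, and compared with a segmented reference
volume.  Agreement is quantified by the Dice coefficient, the symmetric
Hausdorff distance (max of the two directed maximum surface distances) and
the mean symmetric nearest-surface distance ("Euclidean distance"), after
an optional rigid registration (supplied transform or iterative closest
point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "ZoneContour",
    "ZoneVolume",
    "RigidTransform",
    "MetricsReport",
    "extract_contour",
    "revolve",
    "register",
    "compute_metrics",
]


@dataclass
class ZoneContour:
    """Ordered planar polylines in (r, z) meters delimiting the region."""

    loops: list[np.ndarray]  # each (n, 2) columns (r, z), closed

    @property
    def is_empty(self) -> bool:
        return len(self.loops) == 0


@dataclass
class ZoneVolume:
    """Binary voxel mask with isotropic spacing plus an optional surface."""

    mask: np.ndarray  # (nx, ny, nz) bool
    spacing: float  # m, isotropic
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))  # m, center of voxel [0,0,0]
    surface: "object | None" = None  # trimesh.Trimesh when emitted

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be > 0")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """m^3 = voxel count x spacing^3."""
        return self.voxel_count * self.spacing**3

    def voxel_centers(self, which: np.ndarray | None = None) -> np.ndarray:
        sel = self.mask if which is None else which
        ijk = np.argwhere(sel)
        return self.origin + ijk * self.spacing

    def surface_voxels(self) -> np.ndarray:
        """Mask of voxels with at least one 6-neighbour outside the zone."""
        if self.voxel_count == 0:
            return np.zeros_like(self.mask)
        eroded = ndimage.binary_erosion(self.mask)  # border voxels count as surface
        return self.mask & ~eroded

    def surface_points(self) -> np.ndarray:
        """World coordinates (m) of surface voxel centers."""
        return self.voxel_centers(self.surface_voxels())

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing * 1e3] * 3 + [1.0])
        affine[:3, 3] = self.origin * 1e3  # mm, needle z = third axis
        img = nib.Nifti1Image(self.mask.astype(np.uint8), affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "ZoneVolume":
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        sp_mm = float(abs(affine[0, 0]))
        return cls(
            mask=np.asarray(img.dataobj) > 0,
            spacing=sp_mm * 1e-3,
            origin=affine[:3, 3] * 1e-3,
        )


@dataclass
class RigidTransform:
    """Rotation + translation mapping moving-volume coordinates (m) into the
    fixed volume's frame: x_fixed = R @ x_moving + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    provenance: str = "supplied"  # or "icp"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("transform must be a 3x3 rotation and length-3 translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls, provenance: str = "supplied") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), provenance)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (points - self.translation) @ self.rotation

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, provenance: str = "supplied") -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3], provenance)


@dataclass
class MetricsReport:
    """Overlap/distance metrics of two zone volumes (distances in mm)."""

    dice: float
    hausdorff_mm: float
    mean_euclidean_mm: float
    voxel_spacing_mm: float
    transform: RigidTransform

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hausdorff_mm": self.hausdorff_mm,
            "mean_euclidean_mm": self.mean_euclidean_mm,
            "voxel_spacing_mm": self.voxel_spacing_mm,
            "transform_provenance": self.transform.provenance,
            "transform_matrix": self.transform.to_matrix().tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def extract_contour(
    field: np.ndarray,
    r_coords: np.ndarray,
    z_coords: np.ndarray,
    level: float | None = None,
) -> ZoneContour:
    """Sub-cell isoline of a 2D (r, z) scalar field or binary mask.

    For a binary mask the level is 0.5 on the indicator.  The field is padded
    below its minimum so every isoline closes (loops crossing the axis are
    clamped to r >= 0).  Coordinates may be nonuniform; fractional marching-
    squares indices are mapped through them by linear interpolation.
    """
    field = np.asarray(field, dtype=float)
    if not np.isfinite(field).all():
        raise ValueError("field contains non-finite values")
    if level is None:
        level = 0.5
    lo = min(field.min(), level) - 1.0
    padded = np.pad(field, 1, constant_values=lo)
    # ghost coordinates mirror the first/last cell pitch
    r_ext = np.concatenate([[2 * r_coords[0] - r_coords[1]], r_coords, [2 * r_coords[-1] - r_coords[-2]]])
    z_ext = np.concatenate([[2 * z_coords[0] - z_coords[1]], z_coords, [2 * z_coords[-1] - z_coords[-2]]])
    idx_r = np.arange(len(r_ext), dtype=float)
    idx_z = np.arange(len(z_ext), dtype=float)
    loops = []
    for c in measure.find_contours(padded, level):
        r = np.interp(c[:, 0], idx_r, r_ext)
        z = np.interp(c[:, 1], idx_z, z_ext)
        r = np.clip(r, 0.0, None)
        loop = np.column_stack([r, z])
        if not np.allclose(loop[0], loop[-1]):
            loop = np.vstack([loop, loop[0]])
        loops.append(loop)
    return ZoneContour(loops=loops)


def _contour_polygons(contour: ZoneContour) -> list[Polygon]:
    polys = []
    for loop in contour.loops:
        if np.any(loop[:, 0] < -1e-12):
            raise ValueError("contour has r < 0")
        pts = loop
        if not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[0]])
        poly = Polygon(pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area > 0:
            polys.append(poly)
    return polys


def revolve(contour: ZoneContour, voxel_spacing: float = 0.5e-3, sections: int = 72) -> ZoneVolume:
    """Voxelize the solid of revolution of a contour about the z axis.

    A voxel belongs to the solid when its center's (radius, z) lies inside a
    contour loop.  A swept surface (``sections`` angular steps) is attached
    when trimesh can build one.
    """
    if voxel_spacing <= 0:
        raise ValueError("voxel spacing must be > 0")
    if contour.is_empty:
        return ZoneVolume(mask=np.zeros((0, 0, 0), dtype=bool), spacing=voxel_spacing)
    polys = _contour_polygons(contour)
    if not polys:
        return ZoneVolume(mask=np.zeros((0, 0, 0), dtype=bool), spacing=voxel_spacing)

    r_max = max(p.bounds[2] for p in polys)
    z_min = min(p.bounds[1] for p in polys)
    z_max = max(p.bounds[3] for p in polys)
    sp = voxel_spacing
    nxy = int(np.ceil((r_max + sp) / sp)) * 2 + 1
    nz = int(np.ceil((z_max - z_min) / sp)) + 3
    half = (nxy - 1) // 2
    # half-voxel lattice offset: centers never sit exactly on axis-aligned
    # region boundaries, which would bias voxel counts systematically
    origin = np.array([-half * sp + sp / 2, -half * sp + sp / 2, z_min - sp / 2])

    x = origin[0] + np.arange(nxy) * sp
    z = origin[2] + np.arange(nz) * sp
    X, Y = np.meshgrid(x, x, indexing="ij")
    R = np.hypot(X, Y)

    mask = np.zeros((nxy, nxy, nz), dtype=bool)
    rr = np.repeat(R.ravel(), nz)
    zz = np.tile(z, R.size)
    inside = np.zeros(rr.shape, dtype=bool)
    for poly in polys:
        inside |= contains_xy(poly, rr, zz)
    mask = inside.reshape(nxy, nxy, nz)

    surface = None
    try:
        import trimesh

        loop = max(contour.loops, key=lambda l: Polygon(l).area if len(l) > 3 else 0.0)
        surface = trimesh.creation.revolve(loop[:, :2], sections=sections)
    except Exception:
        surface = None
    return ZoneVolume(mask=mask, spacing=sp, origin=origin, surface=surface)


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    Hm = (moving - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(Hm)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return R, t


def register(
    moving: ZoneVolume,
    fixed: ZoneVolume,
    transform: RigidTransform | None = None,
    max_iterations: int = 60,
    tolerance: float = 1e-9,
) -> RigidTransform:
    """Return the rigid transform aligning ``moving`` onto ``fixed``.

    A supplied transform is validated (orthonormal, det +1) and returned
    unchanged — mirroring a manually derived registration matrix that must
    not be silently refined.  Without one, iterative closest point runs on
    the surface voxel centers from a centroid-aligned start.
    """
    if moving.voxel_count == 0 or fixed.voxel_count == 0:
        raise ValueError("cannot register empty volumes")
    if transform is not None:
        return RigidTransform(transform.rotation, transform.translation, "supplied")

    src = moving.surface_points()
    dst = fixed.surface_points()
    tree = cKDTree(dst)
    R = np.eye(3)
    t = dst.mean(axis=0) - src.mean(axis=0)
    prev = np.inf
    for _ in range(max_iterations):
        cur = src @ R.T + t
        dist, j = tree.query(cur)
        R, t = _kabsch(src, dst[j])
        err = float(np.mean(dist**2))
        if abs(prev - err) < tolerance:
            break
        prev = err
    return RigidTransform(R, t, "icp")


def _resample_onto(moving: ZoneVolume, fixed: ZoneVolume, transform: RigidTransform) -> np.ndarray:
    """Nearest-neighbour resampling of the moving mask onto the fixed grid."""
    ijk = np.indices(fixed.mask.shape).reshape(3, -1).T
    x_fixed = fixed.origin + ijk * fixed.spacing
    x_moving = transform.inverse_apply(x_fixed)
    mi = np.rint((x_moving - moving.origin) / moving.spacing).astype(int)
    ok = np.all((mi >= 0) & (mi < np.array(moving.mask.shape)), axis=1)
    out = np.zeros(len(ijk), dtype=bool)
    out[ok] = moving.mask[mi[ok, 0], mi[ok, 1], mi[ok, 2]]
    return out.reshape(fixed.mask.shape)


def compute_metrics(
    a: ZoneVolume,
    b: ZoneVolume,
    transform: RigidTransform | None = None,
) -> MetricsReport:
    """Dice, symmetric Hausdorff and mean symmetric surface distance (mm).

    ``a`` is resampled through the transform onto ``b``'s voxel grid
    (nearest neighbour, preserving the binary mask) before the overlap is
    counted; surface distances use surface voxel centers in ``b``'s frame.
    """
    transform = transform or RigidTransform.identity()
    if a.voxel_count == 0 and b.voxel_count == 0:
        raise ValueError("metrics undefined: both volumes are empty")

    same_frame = (
        a.mask.shape == b.mask.shape
        and np.isclose(a.spacing, b.spacing)
        and np.allclose(a.origin, b.origin)
        and np.allclose(transform.to_matrix(), np.eye(4))
    )
    a_on_b = a.mask if same_frame else _resample_onto(a, b, transform)

    inter = np.logical_and(a_on_b, b.mask).sum()
    denom = a_on_b.sum() + b.mask.sum()
    dice = 2.0 * inter / denom if denom > 0 else 0.0

    av = ZoneVolume(mask=a_on_b, spacing=b.spacing, origin=b.origin)
    pa = av.surface_points()
    pb = b.surface_points()
    if len(pa) == 0 or len(pb) == 0:
        hausdorff = mean_d = float("inf")
    else:
        da = cKDTree(pb).query(pa)[0]
        db = cKDTree(pa).query(pb)[0]
        hausdorff = max(da.max(), db.max())
        mean_d = (da.sum() + db.sum()) / (len(da) + len(db))
    return MetricsReport(
        dice=float(dice),
        hausdorff_mm=float(hausdorff * 1e3),
        mean_euclidean_mm=float(mean_d * 1e3),
        voxel_spacing_mm=float(b.spacing * 1e3),
        transform=transform,
    )
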