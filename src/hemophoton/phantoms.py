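"""Voxel tissue phantoms: slabs, fingertip- and wrist-like geometries.

Grids are axis-aligned with cubic voxels (default pitch 0.5 mm).  Voxel
``(i, j, k)`` spans the half-open box ``[origin + i*pitch, origin +
(i+1)*pitch)`` and indices are 0-based.  Ambient (label 0) is an explicit
material so photon exit detection is a label test; builders always pad the
tissue with an ambient margin.

The skin is a single *composite* label: its six sublayers are not voxelized.
Instead a :class:`CompositeRegion` stores the centroids of the outer-surface
skin voxels as reference points, and the sublayer at any continuous position
is resolved at run time from the Euclidean distance to the nearest reference
point, bucketed by the cumulative sublayer depth edges (0.02 / 0.27 / 0.37 /
0.45 / 0.65 / 0.95 mm).  Depths beyond the last edge clamp to the deepest
sublayer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .tissue_optics import MATERIAL_NAMES, SKIN_SUBLAYER_EDGES_MM

#: Integer label per material, stable across the package.
MATERIAL_LABELS = {name: i for i, name in enumerate(MATERIAL_NAMES)}
AMBIENT, SKIN, NAIL, FAT, MUSCLE, BONE, ARTERY, VEIN = range(8)


@dataclass
class VoxelGrid:
    """Axis-aligned 3-D grid of material labels with cubic voxels."""

    labels: np.ndarray  # int16 array (nx, ny, nz)
    pitch: float = 0.5  # mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm, corner of voxel 0

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        bad = set(np.unique(self.labels)) - set(MATERIAL_LABELS.values())
        if bad:
            raise ValueError(f"unregistered material labels in volume: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_to_index(self, position) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(position, float) - self.origin) / self.pitch).astype(int)
        return tuple(idx)

    def index_to_world(self, index) -> np.ndarray:
        """Centroid of voxel ``index``, mm."""
        return self.origin + (np.asarray(index, float) + 0.5) * self.pitch

    def contains_index(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.shape))

    def label_at(self, position) -> int:
        idx = self.world_to_index(position)
        if not self.contains_index(idx):
            raise IndexError(f"position {position} outside the grid")
        return int(self.labels[idx])

    def centroids(self, mask: np.ndarray) -> np.ndarray:
        """Centroids (n, 3) of the voxels selected by boolean ``mask``."""
        ijk = np.argwhere(mask)
        return self.origin + (ijk + 0.5) * self.pitch

    def extent(self) -> np.ndarray:
        """(2, 3) world-space bounding box [min; max] of the grid, mm."""
        return np.stack([self.origin, self.origin + np.array(self.shape) * self.pitch])


@dataclass
class CompositeRegion:
    """Runtime sublayer resolution for a composite (skin) label."""

    label: int
    reference_points: np.ndarray  # (n, 3) outer-surface voxel centroids, mm
    depth_edges_mm: np.ndarray = field(
        default_factory=lambda: np.asarray(SKIN_SUBLAYER_EDGES_MM)
    )

    def __post_init__(self):
        self.reference_points = np.atleast_2d(np.asarray(self.reference_points, float))
        self.depth_edges_mm = np.asarray(self.depth_edges_mm, float)
        if self.reference_points.size == 0:
            raise ValueError("composite region has an empty reference point set")
        if np.any(np.diff(self.depth_edges_mm) <= 0):
            raise ValueError("depth bin edges must be strictly increasing")
        self._tree = cKDTree(self.reference_points)

    @property
    def n_sublayers(self) -> int:
        return len(self.depth_edges_mm)

    def depth(self, position) -> float:
        """Distance from ``position`` to the nearest reference point, mm."""
        d, _ = self._tree.query(np.asarray(position, float))
        return float(d)

    def resolve(self, position) -> int:
        """Sublayer index (0 = outermost) at a continuous position."""
        return bucket_depth(self.depth(position), self.depth_edges_mm)


def bucket_depth(depth_mm: float, edges: np.ndarray) -> int:
    """Bucket a depth by cumulative edges; clamps beyond the last edge."""
    i = int(np.searchsorted(edges, depth_mm, side="left"))
    return min(i, len(edges) - 1)


def resolve_sublayer(position, region: CompositeRegion) -> int:
    """Sublayer index at ``position`` (functional form of ``region.resolve``)."""
    return region.resolve(position)


def surface_reference_points(grid: VoxelGrid, label: int = SKIN) -> np.ndarray:
    """Centroids of ``label`` voxels with an ambient 6-neighbor (outer surface)."""
    lab = grid.labels
    ambient = lab == AMBIENT
    near_ambient = ndimage.binary_dilation(
        ambient, structure=ndimage.generate_binary_structure(3, 1)
    )
    surface = (lab == label) & near_ambient
    return grid.centroids(surface)


def make_composite_region(grid: VoxelGrid, label: int = SKIN) -> CompositeRegion:
    pts = surface_reference_points(grid, label)
    if pts.size == 0:
        raise ValueError("grid has no outer-surface voxels of the composite label")
    return CompositeRegion(label=label, reference_points=pts)


# --- builders --------------------------------------------------------------


def _voxels(thickness_mm: float, pitch: float) -> int:
    """Thickness in voxels, rounding half away from zero."""
    return int(np.floor(thickness_mm / pitch + 0.5))


def build_slab(
    layers: list[tuple[str | int, float]],
    lateral_mm: float = 10.0,
    pitch: float = 0.5,
    margin_voxels: int = 2,
) -> VoxelGrid:
    """Z-stacked homogeneous layers with ambient above and below.

    ``layers`` lists (material name or label, thickness mm) from the top (low
    z) downward.  Thicknesses are rounded to whole voxels, half away from
    zero; a layer that rounds to zero voxels is an error.
    """
    if not layers:
        raise ValueError("layer list is empty")
    counts = []
    for mat, th in layers:
        c = _voxels(th, pitch)
        if c <= 0:
            raise ValueError(f"layer {mat!r} has zero thickness after voxel rounding")
        counts.append(c)
    n_lat = max(1, _voxels(lateral_mm, pitch))
    nz = sum(counts) + 2 * margin_voxels
    labels = np.zeros((n_lat, n_lat, nz), dtype=np.int16)
    z = margin_voxels
    for (mat, _), c in zip(layers, counts):
        lab = MATERIAL_LABELS[mat] if isinstance(mat, str) else int(mat)
        labels[:, :, z : z + c] = lab
        z += c
    return VoxelGrid(labels=labels, pitch=pitch)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric parameters of the synthetic digit / wrist phantoms.

    Defaults size the digit near the reference scale of 57 x 76 x 48 voxels
    at 0.5 mm pitch.  Radii are in mm; the digit is a concentric half-capped
    cylinder along y (bone core, muscle, fat, composite-skin shell) with an
    optional nail patch on the dorsal (+z) face near the tip.
    """

    kind: str = "digit"
    pitch: float = 0.5
    margin_voxels: int = 2
    # digit parameters
    outer_radius: float = 7.0
    skin_thickness: float = 0.95
    fat_thickness: float = 1.5
    muscle_thickness: float = 2.0
    length: float = 34.0
    nail: bool = True
    nail_thickness: float = 0.5
    nail_length: float = 8.0
    nail_halfwidth: float = 3.0
    # wrist parameters (elliptical cross-section along y)
    wrist_semiaxis_x: float = 12.0
    wrist_semiaxis_z: float = 9.0
    wrist_length: float = 12.0
    wrist_fat_thickness: float = 2.0
    bone_radius: float = 3.0
    bone_offset_x: float = 4.5
    bone_depth: float = 5.0
    artery_radius: float = 1.0
    vein_radius: float = 1.0
    vessel_depth: float = 2.5
    vessel_offset_x: float = 2.0

    def __post_init__(self):
        if self.kind not in ("slab", "digit", "wrist"):
            raise ValueError("phantom kind must be slab, digit or wrist")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        inner = self.outer_radius - self.skin_thickness - self.fat_thickness
        if inner <= 0:
            raise ValueError("digit shells invert: outer radius too small")
        if self.skin_thickness < self.pitch:
            raise ValueError("skin shell thinner than one voxel")


def build_digit_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[VoxelGrid, CompositeRegion]:
    """Fingertip-like phantom: bone, muscle, fat and a composite-skin shell.

    The digit is a cylinder along +y, hemispherically capped at the tip
    (y max), with an optional nail patch replacing the outer shell on the
    dorsal face near the tip.  Returns the grid and the skin composite region.
    """
    p, m = spec.pitch, spec.margin_voxels
    R = spec.outer_radius
    r_fat = R - spec.skin_thickness
    r_muscle = r_fat - spec.fat_thickness
    r_bone = max(r_muscle - spec.muscle_thickness, 0.0)
    if r_muscle <= 0:
        raise ValueError("digit shells invert")

    nx = 2 * (_voxels(R, p) + m)
    nz = nx
    ny = _voxels(spec.length, p) + 2 * m
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # voxel centroid coordinates
    cx = nx * p / 2.0
    cz = nz * p / 2.0
    y_tip = (ny - m) * p  # world y of the distal tissue end
    y_base = 0.0  # digit extends to the proximal grid face region
    cap_center_y = y_tip - R

    xs = (np.arange(nx) + 0.5) * p
    ys = (np.arange(ny) + 0.5) * p
    zs = (np.arange(nz) + 0.5) * p
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    # radial distance from the digit axis, with a spherical cap at the tip
    r_ax = np.sqrt((X - cx) ** 2 + (Z - cz) ** 2)
    r_cap = np.sqrt((X - cx) ** 2 + (Y - cap_center_y) ** 2 + (Z - cz) ** 2)
    r_eff = np.where(Y <= cap_center_y, r_ax, r_cap)
    inside = (Y >= y_base) & (r_eff <= R)

    labels[inside & (r_eff <= r_bone)] = BONE
    labels[inside & (r_eff > r_bone) & (r_eff <= r_muscle)] = MUSCLE
    labels[inside & (r_eff > r_muscle) & (r_eff <= r_fat)] = FAT
    labels[inside & (r_eff > r_fat)] = SKIN

    if spec.nail and spec.nail_thickness > 0:
        nail_zone = (
            (labels == SKIN)
            & (Z > cz)
            & (r_eff > R - spec.nail_thickness)
            & (Y > y_tip - R - spec.nail_length)
            & (np.abs(X - cx) <= spec.nail_halfwidth)
        )
        labels[nail_zone] = NAIL

    grid = VoxelGrid(labels=labels, pitch=p)
    return grid, make_composite_region(grid)


def build_wrist_phantom(spec: PhantomSpec | None = None) -> tuple[VoxelGrid, CompositeRegion]:
    """Wrist-like phantom: elliptical limb with two bones and vessel cylinders.

    An elliptical cylinder along +y carries a composite-skin shell over fat
    over muscle; two bone cylinders sit deep, and artery/vein cylinders run
    at ``vessel_depth`` below the dorsal (+z) surface, offset laterally by
    ``+-vessel_offset_x``.  A zero vessel radius omits that vessel.
    """
    spec = spec or PhantomSpec(kind="wrist")
    p, m = spec.pitch, spec.margin_voxels
    ax, az = spec.wrist_semiaxis_x, spec.wrist_semiaxis_z

    nx = 2 * (_voxels(ax, p) + m)
    nz = 2 * (_voxels(az, p) + m)
    ny = _voxels(spec.wrist_length, p) + 2 * m
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    cx, cz = nx * p / 2.0, nz * p / 2.0
    xs = (np.arange(nx) + 0.5) * p
    zs = (np.arange(nz) + 0.5) * p
    X, Z = np.meshgrid(xs, zs, indexing="ij")

    def ellipse(sa_x, sa_z):
        if sa_x <= 0 or sa_z <= 0:
            return np.zeros_like(X, dtype=bool)
        return ((X - cx) / sa_x) ** 2 + ((Z - cz) / sa_z) ** 2 <= 1.0

    outer = ellipse(ax, az)
    fat_in = ellipse(ax - spec.skin_thickness, az - spec.skin_thickness)
    muscle_in = ellipse(
        ax - spec.skin_thickness - spec.wrist_fat_thickness,
        az - spec.skin_thickness - spec.wrist_fat_thickness,
    )
    cross = np.zeros((nx, nz), dtype=np.int16)
    cross[outer] = SKIN
    cross[fat_in] = FAT
    cross[muscle_in] = MUSCLE

    for sgn in (-1, 1):
        bx, bz = cx + sgn * spec.bone_offset_x, cz + az - spec.bone_depth - spec.bone_radius
        bone = (X - bx) ** 2 + (Z - bz) ** 2 <= spec.bone_radius**2
        cross[bone & muscle_in] = BONE

    # dorsal surface height above a lateral offset x0
    def surface_z(x0):
        t = 1.0 - ((x0 - cx) / ax) ** 2
        return cz + az * np.sqrt(max(t, 0.0))

    for label, sgn, radius in ((ARTERY, 1, spec.artery_radius), (VEIN, -1, spec.vein_radius)):
        if radius <= 0:
            continue
        vx = cx + sgn * spec.vessel_offset_x
        vz = surface_z(vx) - spec.vessel_depth
        vessel = (X - vx) ** 2 + (Z - vz) ** 2 <= radius**2
        cross[vessel & fat_in] = label  # anywhere beneath the skin shell

    labels[:, m : ny - m, :] = cross[:, None, :]
    grid = VoxelGrid(labels=labels, pitch=p)
    return grid, make_composite_region(grid)


def build_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, CompositeRegion | None]:
    if spec.kind == "digit":
        return build_digit_phantom(spec)
    if spec.kind == "wrist":
        return build_wrist_phantom(spec)
    raise ValueError("build_phantom handles digit and wrist kinds; use build_slab for slabs")


# --- serialization ---------------------------------------------------------


def save_volume(path, grid: VoxelGrid) -> None:
    """Write a NIfTI-1 label volume with a JSON label/pitch sidecar."""
    path = Path(path)
    affine = np.diag([grid.pitch] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.labels.astype(np.int16), affine), str(path))
    sidecar = {
        "pitch_mm": grid.pitch,
        "origin_mm": list(grid.origin),
        "labels": {str(v): k for k, v in MATERIAL_LABELS.items()},
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_volume(path) -> VoxelGrid:
    """Load a NIfTI-1 label volume; requires the JSON sidecar written alongside."""
    path = Path(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing label sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], float)
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"anisotropic voxels {zooms} unsupported: engine assumes cubic voxels")
    if not np.isclose(zooms[0], sidecar["pitch_mm"]):
        raise ValueError(
            f"pitch mismatch: header {zooms[0]} mm vs sidecar {sidecar['pitch_mm']} mm"
        )
    data = np.asarray(img.dataobj).astype(np.int16)
    known = {int(k) for k in sidecar["labels"]}
    present = set(np.unique(data).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"volume contains labels absent from the sidecar map: {sorted(unknown)}")
    origin = np.asarray(sidecar.get("origin_mm", img.affine[:3, 3]), float)
    return VoxelGrid(labels=data, pitch=float(sidecar["pitch_mm"]), origin=origin)
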