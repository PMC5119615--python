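"""Voxel volumes, tetrahedral meshes, camera model and optode placement.

A measured (or synthetic) surface height map is converted to a binary voxel
volume and then to a conforming tetrahedral mesh by splitting every occupied
voxel into the six Kuhn tetrahedra sharing the min->max body diagonal.  The
decomposition is deterministic and volume conserving: the mesh volume equals
the number of occupied voxels times voxel^3 exactly.

Sources and virtual detectors (blocks of camera pixels) are placed on the
mesh surface on regular grids; detector pixel coordinates are mapped to mm
through a pinhole camera model.  Coordinates are mm, with the z axis along
the optical axis: z = 0 is the resting stage (source side) and the camera
looks down from +z.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VoxelVolume",
    "TetMesh",
    "CameraModel",
    "OptodeSet",
    "OptodeGridSpec",
    "height_map_to_volume",
    "volume_to_mesh",
    "box_volume",
    "pixel_to_physical",
    "physical_to_pixel",
    "build_optode_set",
    "grid_on_face",
]


class EmptyVolumeError(ValueError):
    """Thresholding produced no occupied voxels."""


class PlacementError(ValueError):
    """An optode does not project onto the mesh surface."""


@dataclass
class VoxelVolume:
    """Binary occupancy grid with physical voxel size and origin (mm)."""

    occupancy: np.ndarray  # (nx, ny, nz) bool
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        return self.n_occupied * self.voxel_size**3


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with per-element region labels.

    ``nodes`` are mm coordinates, ``elements`` 0-based node indices (1-based
    in files), ``regions`` integer labels (0 = background).  Boundary faces
    and node flags are derived on first access and cached.
    """

    nodes: np.ndarray
    elements: np.ndarray
    regions: np.ndarray = None
    provenance: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.regions is None:
            self.regions = np.zeros(len(self.elements), dtype=np.int64)
        self.regions = np.asarray(self.regions, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (E, 4)")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element indices out of range")

    # -- geometry ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def element_volumes(self) -> np.ndarray:
        if "volumes" not in self._cache:
            self._cache["volumes"] = self.signed_volumes()
        return self._cache["volumes"]

    def element_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.nodes[self.elements].mean(axis=1)
        return self._cache["centroids"]

    def orient(self) -> None:
        """Swap nodes of negatively oriented tets so all volumes are > 0."""
        v = self.signed_volumes()
        bad = v < 0
        if bad.any():
            self.elements[bad, 2], self.elements[bad, 3] = (
                self.elements[bad, 3].copy(), self.elements[bad, 2].copy())
        self._cache.clear()

    def boundary_faces(self) -> np.ndarray:
        """Faces belonging to exactly one element, shape (F, 3), outward order."""
        if "bfaces" in self._cache:
            return self._cache["bfaces"]
        # local faces opposite each node, ordered so the outward normal is
        # consistent for positively oriented tets
        local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        faces = self.elements[:, local].reshape(-1, 3)
        owner = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T[::-1])
        key_s, faces_s, owner_s = key[order], faces[order], owner[order]
        dup = np.ones(len(key_s), dtype=bool)
        same_next = np.all(key_s[1:] == key_s[:-1], axis=1)
        dup[1:] &= ~same_next
        dup[:-1] &= ~same_next
        self._cache["bfaces"] = faces_s[dup]
        self._cache["bface_owner"] = owner_s[dup]
        return self._cache["bfaces"]

    def boundary_face_owners(self) -> np.ndarray:
        self.boundary_faces()
        return self._cache["bface_owner"]

    def boundary_nodes(self) -> np.ndarray:
        """Boolean flag per node: lies on the boundary surface."""
        if "bnodes" not in self._cache:
            flags = np.zeros(self.n_nodes, dtype=bool)
            flags[np.unique(self.boundary_faces())] = True
            self._cache["bnodes"] = flags
        return self._cache["bnodes"]

    def boundary_face_normals(self) -> np.ndarray:
        """Unit outward normals of boundary faces."""
        if "bnormals" not in self._cache:
            f = self.boundary_faces()
            p = self.nodes[f]
            n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            self._cache["bnormals"] = n
        return self._cache["bnormals"]

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    # -- point location ---------------------------------------------------

    def _centroid_tree(self) -> cKDTree:
        if "ctree" not in self._cache:
            self._cache["ctree"] = cKDTree(self.element_centroids())
        return self._cache["ctree"]

    def barycentric(self, elem: int, point: np.ndarray) -> np.ndarray:
        x = self.nodes[self.elements[elem]]
        T = (x[1:] - x[0]).T
        lam = np.linalg.solve(T, np.asarray(point, float) - x[0])
        return np.concatenate([[1.0 - lam.sum()], lam])

    def locate(self, point, tol: float = 1e-9) -> tuple:
        """Containing element and barycentric weights for a point."""
        point = np.asarray(point, dtype=float)
        k = min(64, self.n_elements)
        _, cand = self._centroid_tree().query(point, k=k)
        for e in np.atleast_1d(cand):
            w = self.barycentric(int(e), point)
            if w.min() >= -tol:
                return int(e), np.clip(w, 0.0, None) / max(w.sum(), 1e-300)
        for e in range(self.n_elements):  # rare fallback
            w = self.barycentric(e, point)
            if w.min() >= -tol:
                return e, np.clip(w, 0.0, None) / max(w.sum(), 1e-300)
        raise PlacementError(f"point {point} lies outside the mesh")


# ---------------------------------------------------------------------------
# height map -> voxel volume -> mesh
# ---------------------------------------------------------------------------

def height_map_to_volume(height, voxel_size: float, threshold: float,
                         pitch: float | None = None,
                         origin_xy=(0.0, 0.0)) -> VoxelVolume:
    """Threshold a height map into a binary voxel volume.

    Voxel (i, j, k) is occupied iff the local height (sampled at the voxel's
    xy centre) is >= ``threshold`` and ``k * voxel_size`` < height.

    ``height`` is either a 2-D array (mm) with pixel ``pitch`` (mm/pixel) or a
    :class:`~specdot.profilometry.HeightMap`.
    """
    from .profilometry import HeightMap  # local import to avoid cycle

    if isinstance(height, HeightMap):
        pitch = height.pitch
        z = np.where(height.mask, height.values, 0.0)
    else:
        z = np.asarray(height, dtype=float)
        if pitch is None:
            raise ValueError("pitch (mm/pixel) required for a raw height array")
    if voxel_size <= 0:
        raise ValueError("voxel size must be > 0")
    ny_px, nx_px = z.shape  # rows = I (y), cols = J (x)
    extent_x, extent_y = nx_px * pitch, ny_px * pitch
    nx = max(int(round(extent_x / voxel_size)), 1)
    ny = max(int(round(extent_y / voxel_size)), 1)
    # sample height at voxel centres (nearest pixel)
    cx = (np.arange(nx) + 0.5) * voxel_size
    cy = (np.arange(ny) + 0.5) * voxel_size
    jx = np.clip((cx / pitch).astype(int), 0, nx_px - 1)
    iy = np.clip((cy / pitch).astype(int), 0, ny_px - 1)
    h = z[np.ix_(iy, jx)].T  # (nx, ny)
    h = np.where(h >= threshold, h, 0.0)
    nz = max(int(np.ceil(h.max() / voxel_size)), 1)
    kz = np.arange(nz) * voxel_size
    occ = h[:, :, None] > kz[None, None, :]
    if not occ.any():
        raise EmptyVolumeError("no voxel exceeds the height threshold")
    return VoxelVolume(occ, voxel_size, origin=np.array([origin_xy[0], origin_xy[1], 0.0]))


def box_volume(extent, voxel_size: float, origin=(0.0, 0.0, 0.0)) -> VoxelVolume:
    """Fully occupied box of given extent (mm), for slab/block phantoms."""
    n = [max(int(round(e / voxel_size)), 1) for e in extent]
    return VoxelVolume(np.ones(n, dtype=bool), voxel_size, origin=np.asarray(origin, float))


# six Kuhn tetrahedra of the unit cube around the (0,0,0)->(1,1,1) diagonal;
# corners indexed by bit pattern (x + 2y + 4z)
_KUHN = []
for perm in itertools.permutations((1, 2, 4)):
    path = [0]
    for step in perm:
        path.append(path[-1] + step)
    _KUHN.append(path)
_KUHN = np.array(_KUHN)
_CUBE_CORNERS = np.array([[i & 1, (i >> 1) & 1, (i >> 2) & 1] for i in range(8)])


def volume_to_mesh(volume: VoxelVolume) -> TetMesh:
    """Split every occupied voxel into 6 Kuhn tetrahedra.

    The split is face-conformal across neighbouring voxels (shared-face
    diagonals agree because every cube uses the min->max corner diagonal)
    and conserves volume exactly.
    """
    if volume.n_occupied == 0:
        raise EmptyVolumeError("cannot mesh an empty volume")
    ii, jj, kk = np.nonzero(volume.occupancy)
    vox = np.column_stack([ii, jj, kk])  # (V, 3)
    # grid node ids for the 8 corners of each voxel
    corners = vox[:, None, :] + _CUBE_CORNERS[None, :, :]  # (V, 8, 3)
    flat = corners.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    corner_ids = inv.reshape(-1, 8)  # (V, 8)
    elements = corner_ids[:, _KUHN].reshape(-1, 4)  # (V*6, 4)
    nodes = volume.origin + uniq * volume.voxel_size
    mesh = TetMesh(nodes, elements,
                   provenance={"voxel_size": volume.voxel_size,
                               "n_voxels": volume.n_occupied})
    mesh.orient()
    if np.any(mesh.element_volumes() <= 0):
        raise ValueError("degenerate tetrahedra in voxel decomposition")
    return mesh


# ---------------------------------------------------------------------------
# pinhole camera
# ---------------------------------------------------------------------------

@dataclass
class CameraModel:
    """Pinhole camera looking down the -z axis from ``standoff`` mm.

    The pixel pitch on the reference plane is standoff / focal_length.
    """

    focal_length: float  # pixels
    principal_point: tuple = (0.0, 0.0)  # (u0, v0) pixels
    standoff: float = 500.0  # mm

    def __post_init__(self):
        if self.focal_length <= 0 or self.standoff <= 0:
            raise ValueError("focal length and stand-off must be > 0")

    @property
    def pitch(self) -> float:
        """mm per pixel on the reference plane."""
        return self.standoff / self.focal_length


def pixel_to_physical(camera: CameraModel, pixel) -> np.ndarray:
    """Map pixel (u, v) to (x, y) mm on the reference plane."""
    u, v = pixel
    u0, v0 = camera.principal_point
    return np.array([(u - u0) * camera.pitch, (v - v0) * camera.pitch])


def physical_to_pixel(camera: CameraModel, xy) -> np.ndarray:
    x, y = xy
    u0, v0 = camera.principal_point
    return np.array([x / camera.pitch + u0, y / camera.pitch + v0])


# ---------------------------------------------------------------------------
# optodes
# ---------------------------------------------------------------------------

@dataclass
class OptodeSet:
    """Sources and detectors with an active-link table.

    ``links`` holds (source index, detector index) pairs; only active sources
    appear.  Positions are on the mesh surface (mm).
    """

    sources: np.ndarray
    detectors: np.ndarray
    source_active: np.ndarray = None
    links: np.ndarray = None

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, float))
        self.detectors = np.atleast_2d(np.asarray(self.detectors, float))
        if self.source_active is None:
            self.source_active = np.ones(len(self.sources), dtype=bool)
        self.source_active = np.asarray(self.source_active, dtype=bool)
        if self.links is None:
            act = np.nonzero(self.source_active)[0]
            self.links = np.array([(s, d) for s in act
                                   for d in range(len(self.detectors))], dtype=np.int64)
        self.links = np.asarray(self.links, dtype=np.int64).reshape(-1, 2)
        if len(self.links):
            if self.links[:, 0].max() >= len(self.sources) or \
               self.links[:, 1].max() >= len(self.detectors):
                raise ValueError("link table references invalid optodes")
            if not self.source_active[self.links[:, 0]].all():
                raise ValueError("link table references inactive sources")

    @property
    def n_active_sources(self) -> int:
        return int(self.source_active.sum())

    @property
    def n_links(self) -> int:
        return len(self.links)

    def without_source(self, index: int) -> "OptodeSet":
        active = self.source_active.copy()
        active[index] = False
        links = self.links[self.links[:, 0] != index]
        return OptodeSet(self.sources, self.detectors, active, links)


@dataclass
class OptodeGridSpec:
    """Regular source/detector grid layout for a transmission measurement."""

    n_sources: tuple = (4, 4)
    source_spacing: float = 5.0
    n_detectors: tuple = (6, 6)
    detector_spacing: float = 2.5
    n_omitted_sources: int = 2
    active_sources: Sequence[int] | None = None  # explicit override
    source_face: tuple = ("z", -1)
    detector_face: tuple = ("z", +1)
    center: tuple | None = None  # (x, y) or None for mesh centroid


_AXIS = {"x": 0, "y": 1, "z": 2}


def _surface_project(mesh: TetMesh, uv, face: tuple, name: str) -> np.ndarray:
    """Project in-plane coordinates onto the boundary faces of one mesh side."""
    ax, side = _AXIS[face[0]], face[1]
    normals = mesh.boundary_face_normals()
    sel = np.nonzero(normals[:, ax] * side > 0.5)[0]
    if len(sel) == 0:
        raise PlacementError(f"{name}: mesh has no boundary faces on side {face}")
    other = [i for i in range(3) if i != ax]
    faces = mesh.boundary_faces()[sel]
    p = mesh.nodes[faces]  # (F, 3, 3)
    uv = np.asarray(uv, dtype=float)
    # 2-D barycentric test in the projected plane
    a, b, c = p[:, 0][:, other], p[:, 1][:, other], p[:, 2][:, other]
    v0, v1 = b - a, c - a
    v2 = uv[None, :] - a
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(den) > 1e-12
    w1 = np.where(ok, (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / np.where(ok, den, 1), -1)
    w2 = np.where(ok, (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / np.where(ok, den, 1), -1)
    w0 = 1.0 - w1 - w2
    inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9) & ok
    if not inside.any():
        raise PlacementError(f"{name} at {uv} falls outside the mesh footprint on side {face}")
    idx = np.nonzero(inside)[0][0]
    w = np.clip(np.array([w0[idx], w1[idx], w2[idx]]), 0, None)
    w /= w.sum()
    return w @ p[idx]


def grid_on_face(mesh: TetMesh, n: tuple, spacing: float, face: tuple,
                 center=None, name: str = "optode") -> np.ndarray:
    """Centred regular grid of positions projected onto one mesh face."""
    ax = _AXIS[face[0]]
    other = [i for i in range(3) if i != ax]
    if center is None:
        lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
        center = [(lo[i] + hi[i]) / 2 for i in other]
    g0 = (np.arange(n[0]) - (n[0] - 1) / 2) * spacing + center[0]
    g1 = (np.arange(n[1]) - (n[1] - 1) / 2) * spacing + center[1]
    pts = []
    for a_ in g0:
        for b_ in g1:
            pts.append(_surface_project(mesh, (a_, b_), face, name=f"{name} ({a_:g},{b_:g})"))
    return np.array(pts)


def build_optode_set(spec: OptodeGridSpec, mesh: TetMesh,
                     camera: CameraModel | None = None) -> OptodeSet:
    """Place source and detector grids on opposite mesh faces.

    Detector grids emulate blocks of camera pixels grouped into virtual
    detectors; when a ``camera`` is given the spacing is interpreted as a
    pixel-group pitch mapped through the pinhole model, otherwise directly
    as mm.  By default the two corner sources farthest from the detector
    grid centroid are switched off (low transmitted signal), mirroring the
    system's 14-of-16 source usage.
    """
    d_spacing = spec.detector_spacing * (camera.pitch if camera is not None else 1.0)
    s_spacing = spec.source_spacing
    sources = grid_on_face(mesh, spec.n_sources, s_spacing, spec.source_face,
                           center=spec.center, name="source")
    detectors = grid_on_face(mesh, spec.n_detectors, d_spacing, spec.detector_face,
                             center=spec.center, name="detector")
    active = np.ones(len(sources), dtype=bool)
    if spec.active_sources is not None:
        active[:] = False
        active[list(spec.active_sources)] = True
    elif spec.n_omitted_sources > 0:
        centroid = detectors.mean(axis=0)
        d = np.linalg.norm(sources - centroid, axis=1)
        order = sorted(range(len(sources)),
                       key=lambda i: (-d[i],) + tuple(sources[i]))
        active[order[:spec.n_omitted_sources]] = False
    return OptodeSet(sources, detectors, source_active=active)
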