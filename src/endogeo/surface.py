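"""World-space point-cloud fusion and incremental surface meshing.

Each keyframe's dense point cloud lives in that keyframe's camera frame;
the SLAM pose provides the rigid frame-to-world transform ``T_f2w`` that
stitches the clouds into one world-frame cloud.  Overlapping keyframes
re-observe the same tissue, so the fused cloud is deduplicated on a voxel
grid (one representative — the centroid — per voxel).  The fused cloud is
then triangulated into the global surface mesh that all AR operations
anchor to.

Meshing uses a projection-based greedy triangulation: the cloud is
projected onto its dominant (PCA) plane, Delaunay-triangulated there, and
lifted back to 3D, dropping triangles whose projected edges are much
longer than the local sampling distance (holes and range discontinuities
stay holes rather than being bridged).  Endoscopic reconstructions are
camera-facing sheets — single-valued over their dominant plane — which is
exactly the regime where this construction is well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .tracking import RigidTransform

__all__ = [
    "SurfaceMesh",
    "FrameToWorld",
    "to_world",
    "fuse",
    "voxel_downsample",
    "remove_statistical_outliers",
    "estimate_normals",
    "triangulate_surface",
    "save_mesh",
    "load_mesh",
]

FrameToWorld = RigidTransform  # alias: the SLAM pose read as a point map


@dataclass
class SurfaceMesh:
    """Triangle mesh in world coordinates (mm)."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int
    normals: np.ndarray | None = None  # (n, 3) unit, per vertex

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        self.triangles = np.atleast_2d(np.asarray(self.triangles, dtype=int)).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle references a missing vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-12)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


def to_world(points_cam: np.ndarray, t_f2w: FrameToWorld) -> np.ndarray:
    """Rigidly map a camera-frame cloud into the world frame."""
    return t_f2w.apply(points_cam)


def voxel_downsample(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """One centroid per occupied voxel of an axis-aligned grid."""
    points = np.atleast_2d(points)
    if len(points) == 0:
        return points.reshape(0, 3)
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    keys = np.floor(points / voxel_size).astype(np.int64)
    # lexicographic voxel id
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inv, points)
    return sums / counts[:, None]


def fuse(global_cloud: np.ndarray, new_cloud: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Merge a new world-frame cloud into the global one.

    The union is voxel-downsampled, so duplicated surface regions collapse
    to one representative per voxel and the fused count never exceeds the
    union count.  ``fuse(X, X)`` returns X's voxel representatives.
    """
    global_cloud = np.atleast_2d(global_cloud).reshape(-1, 3)
    new_cloud = np.atleast_2d(new_cloud).reshape(-1, 3)
    union = np.vstack([global_cloud, new_cloud]) if len(global_cloud) else new_cloud
    return voxel_downsample(union, voxel_size)


def remove_statistical_outliers(
    points: np.ndarray, k: int = 16, std_ratio: float = 2.0
) -> np.ndarray:
    """Drop points whose mean k-NN distance is anomalously large.

    Stereo mismatches produce sparse floating points off the tissue sheet;
    their neighbourhoods are much looser than on the densely sampled
    surface, so thresholding the mean k-neighbour distance at
    ``mean + std_ratio * std`` removes them without eroding the surface.
    """
    points = np.atleast_2d(points)
    if len(points) <= k:
        return points
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k + 1)
    mean_d = d[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + std_ratio * mean_d.std()
    return points[mean_d <= cutoff]


def estimate_normals(
    points: np.ndarray, k: int = 20, orient_toward: np.ndarray | None = None
) -> np.ndarray:
    """Per-point unit normals by local PCA plane fit over k neighbours.

    With ``orient_toward`` (a camera position) normals are flipped to face
    it, giving a consistent outward orientation for camera-facing sheets.
    """
    points = np.atleast_2d(points)
    n = len(points)
    k = min(k, n)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    normals = np.empty((n, 3))
    for i in range(n):
        nb = points[idx[i]]
        nb = nb - nb.mean(axis=0)
        # smallest principal axis of the neighbourhood
        _, _, Vt = np.linalg.svd(nb, full_matrices=False)
        normals[i] = Vt[-1]
    if orient_toward is not None:
        flip = np.einsum("ij,ij->i", normals, orient_toward - points) < 0
        normals[flip] *= -1
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.maximum(norms, 1e-12)


def triangulate_surface(
    cloud: np.ndarray,
    max_edge_factor: float = 3.0,
    camera_position: np.ndarray | None = None,
    normal_k: int = 20,
) -> SurfaceMesh:
    """Greedy projection triangulation of a (locally single-valued) cloud.

    The cloud is projected onto its dominant PCA plane and Delaunay-
    triangulated there; triangles with a projected edge longer than
    ``max_edge_factor`` times the median nearest-neighbour spacing are
    discarded (they bridge holes or depth discontinuities), as are
    zero-area slivers.  Vertex normals come from a local plane fit,
    oriented toward ``camera_position`` when given.

    Raises ``ValueError`` for clouds that are too small or collinear to
    support a surface.
    """
    cloud = np.atleast_2d(cloud)
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to triangulate")
    centred = cloud - cloud.mean(axis=0)
    _, s, Vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-12):
        raise ValueError("cloud is collinear; no surface to triangulate")
    # project onto the two dominant axes
    uv = centred @ Vt[:2].T
    try:
        tri = Delaunay(uv)
    except Exception as exc:  # qhull degeneracies
        raise ValueError(f"triangulation failed: {exc}") from None
    faces = tri.simplices

    # Edge filter: drop triangles whose 3D edges are much longer than the
    # local sampling distance — they bridge holes or range discontinuities.
    # The allowance is slope-aware: where the surface tilts away from the
    # projection plane, Delaunay-in-projection edges legitimately stretch
    # by ~1/cos(slope), so the threshold grows with the local tilt.
    normals = estimate_normals(cloud, k=normal_k, orient_toward=camera_position)
    tree = cKDTree(cloud)
    d_nn, _ = tree.query(cloud, k=2)
    nn = d_nn[:, 1]
    axis = Vt[2]
    cos_tilt = np.abs(normals @ axis)
    stretch = 1.0 / np.clip(cos_tilt, 0.1, 1.0)  # clamp: never above 10x
    allowance = max_edge_factor * np.maximum(nn * stretch, 1e-12)

    def edge_ok(i, j):
        length = np.linalg.norm(cloud[i] - cloud[j], axis=1)
        return length <= np.maximum(allowance[i], allowance[j])

    keep = (
        edge_ok(faces[:, 0], faces[:, 1])
        & edge_ok(faces[:, 1], faces[:, 2])
        & edge_ok(faces[:, 2], faces[:, 0])
    )
    faces = faces[keep]

    # drop zero-area slivers in 3D
    v = cloud
    areas = 0.5 * np.linalg.norm(
        np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]]), axis=1
    )
    faces = faces[areas > 1e-12]
    if len(faces) == 0:
        raise ValueError("no valid triangles after filtering (cloud too sparse)")

    # orient faces consistently with the vertex normals
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    vn = normals[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", fn, vn) < 0
    faces[flip] = faces[flip][:, ::-1]

    return SurfaceMesh(vertices=cloud.copy(), triangles=faces, normals=normals)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write PLY or OBJ (by extension) via trimesh."""
    mesh.to_trimesh().export(str(path))


def load_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))
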