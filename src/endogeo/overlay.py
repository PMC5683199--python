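"""Geometry-aware AR operations on the global surface mesh.

Once the world-frame mesh exists, AR content can be anchored *to the
anatomy* instead of to the image: a clicked pixel is resolved to a point
on the mesh (ray casting), labels are oriented by the local surface
normal, measurements run along the curved surface rather than through
space, and highlighted regions are geodesic patches with a physical area
in mm^2.  Re-projecting the mesh into the current camera view gives the
per-pixel depth / face-id layer that makes the overlay occlusion-aware.

"Clicks" are pixel coordinates supplied programmatically; no GUI is
involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .geometry import CameraRig, Pose
from .surface import SurfaceMesh

__all__ = [
    "SurfaceAnchor",
    "SurfacePath",
    "LabelPose",
    "RayMiss",
    "pick",
    "cast_ray",
    "pixel_ray",
    "closest_point_on_mesh",
    "reproject_mesh",
    "render_overlay_png",
    "measure_on_surface",
    "highlight_area",
    "place_label",
    "save_anchors_json",
]


class RayMiss(RuntimeError):
    """The viewing ray does not intersect the mesh."""


class Unreachable(RuntimeError):
    """Anchors lie in disconnected mesh components."""


@dataclass
class SurfaceAnchor:
    """A point fixed to the mesh surface."""

    triangle_id: int
    barycentric: np.ndarray  # (3,), non-negative, sums to 1
    position: np.ndarray  # world, mm
    normal: np.ndarray  # unit surface normal at the anchor

    def __post_init__(self) -> None:
        self.barycentric = np.asarray(self.barycentric, dtype=float).reshape(3)
        b = self.barycentric
        if np.any(b < -1e-9) or abs(b.sum() - 1.0) > 1e-6:
            raise ValueError("barycentric coordinates must be non-negative and sum to 1")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if n > 0:
            self.normal = self.normal / n


@dataclass
class SurfacePath:
    """Polyline constrained to the mesh surface; lengths in mm."""

    points: np.ndarray  # (n, 3) world

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class LabelPose:
    """An oriented label plane stuck to the surface."""

    position: np.ndarray
    normal: np.ndarray  # label plane normal = surface normal at the anchor
    up: np.ndarray  # in-plane up direction
    payload: object = None


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def pixel_ray(pixel: np.ndarray, pose: Pose, rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    """World-frame ray (origin, unit direction) through a pixel center."""
    x, y = float(pixel[0]), float(pixel[1])
    d_cam = np.array([(x - rig.cx) / rig.fx, (y - rig.cy) / rig.fy, 1.0])
    d_world = pose.rotation_matrix() @ d_cam
    return pose.position.copy(), d_world / np.linalg.norm(d_world)


def cast_ray(
    origin: np.ndarray, direction: np.ndarray, mesh: SurfaceMesh
) -> tuple[int, float, np.ndarray]:
    """First ray-mesh intersection by vectorised Moller-Trumbore.

    Returns ``(triangle id, ray parameter t, barycentric (3,))`` of the
    nearest hit with t > 0; raises :class:`RayMiss` otherwise.
    """
    v = mesh.vertices
    t = mesh.triangles
    if len(t) == 0:
        raise RayMiss("empty mesh")
    v0 = v[t[:, 0]]
    e1 = v[t[:, 1]] - v0
    e2 = v[t[:, 2]] - v0
    d = np.asarray(direction, dtype=float)
    o = np.asarray(origin, dtype=float)
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = o - v0
    u = np.einsum("ij,ij->i", s, p) * inv_det
    q = np.cross(s, e1)
    w = (q @ d) * inv_det
    tt = np.einsum("ij,ij->i", e2, q) * inv_det
    eps = 1e-9
    hit = ok & (u >= -eps) & (w >= -eps) & (u + w <= 1 + eps) & (tt > eps)
    if not hit.any():
        raise RayMiss("ray misses the mesh")
    idx = np.flatnonzero(hit)
    best = idx[np.argmin(tt[idx])]
    bary = np.array([1.0 - u[best] - w[best], u[best], w[best]])
    bary = np.clip(bary, 0.0, None)
    bary = bary / bary.sum()
    return int(best), float(tt[best]), bary


def _anchor_from_hit(mesh: SurfaceMesh, tri_id: int, bary: np.ndarray) -> SurfaceAnchor:
    tri = mesh.triangles[tri_id]
    pos = bary @ mesh.vertices[tri]
    if mesh.normals is not None:
        n = bary @ mesh.normals[tri]
    else:
        n = mesh.face_normals()[tri_id]
    n = n / max(np.linalg.norm(n), 1e-12)
    return SurfaceAnchor(tri_id, bary, pos, n)


def pick(pixel: np.ndarray, pose: Pose, rig: CameraRig, mesh: SurfaceMesh) -> SurfaceAnchor:
    """Resolve a clicked pixel to the nearest surface point along its ray.

    The anchor normal interpolates the vertex normals of the hit face
    (falling back to the face normal when the mesh carries none).
    """
    x, y = float(pixel[0]), float(pixel[1])
    if not (0 <= x < rig.width and 0 <= y < rig.height):
        raise ValueError("pixel outside the image")
    origin, direction = pixel_ray(pixel, pose, rig)
    tri_id, _, bary = cast_ray(origin, direction, mesh)
    return _anchor_from_hit(mesh, tri_id, bary)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------


def reproject_mesh(
    mesh: SurfaceMesh, pose: Pose, rig: CameraRig
) -> tuple[np.ndarray, np.ndarray]:
    """Software z-buffer rasterisation of the mesh into the camera view.

    Returns ``(depth, face_id)`` buffers of the rig's image size: depth in
    mm (inf where nothing projects) and the visible triangle id (-1 where
    none).  Depth interpolation is perspective-correct (1/z linear in
    screen space).
    """
    h, w = rig.height, rig.width
    depth = np.full((h, w), np.inf)
    face_id = np.full((h, w), -1, dtype=int)

    pc = pose.to_camera(mesh.vertices)
    z = pc[:, 2]
    u = rig.fx * pc[:, 0] / np.where(z > 1e-9, z, 1.0) + rig.cx
    v = rig.fy * pc[:, 1] / np.where(z > 1e-9, z, 1.0) + rig.cy

    for fi, tri in enumerate(mesh.triangles):
        tz = z[tri]
        if np.any(tz <= 1e-9):  # clip triangles touching the camera plane
            continue
        tu, tv = u[tri], v[tri]
        x0 = max(int(np.floor(tu.min())), 0)
        x1 = min(int(np.ceil(tu.max())), w - 1)
        y0 = max(int(np.floor(tv.min())), 0)
        y1 = min(int(np.ceil(tv.max())), h - 1)
        if x0 > x1 or y0 > y1:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        # barycentric via the 2x2 edge system
        d = np.array([tu[1] - tu[0], tu[2] - tu[0], tv[1] - tv[0], tv[2] - tv[0]])
        det = d[0] * d[3] - d[1] * d[2]
        if abs(det) < 1e-12:
            continue
        px = xs - tu[0]
        py = ys - tv[0]
        b1 = (px * d[3] - py * d[1]) / det
        b2 = (py * d[0] - px * d[2]) / det
        b0 = 1.0 - b1 - b2
        eps = -1e-9
        inside = (b0 >= eps) & (b1 >= eps) & (b2 >= eps)
        if not inside.any():
            continue
        inv_z = b0 / tz[0] + b1 / tz[1] + b2 / tz[2]
        zpix = 1.0 / np.maximum(inv_z, 1e-12)
        closer = inside & (zpix < depth[y0 : y1 + 1, x0 : x1 + 1])
        sub_d = depth[y0 : y1 + 1, x0 : x1 + 1]
        sub_f = face_id[y0 : y1 + 1, x0 : x1 + 1]
        sub_d[closer] = zpix[closer]
        sub_f[closer] = fi
    return depth, face_id


# ---------------------------------------------------------------------------
# geodesics on the mesh
# ---------------------------------------------------------------------------


def _surface_graph(mesh: SurfaceMesh) -> tuple[np.ndarray, sp.csr_matrix, np.ndarray]:
    """Graph over vertices + edge midpoints; all 6 nodes of a face interlink.

    Edge midpoints act as Steiner points: paths may cross faces instead of
    hugging edges, which cuts the metric overestimate of a pure edge graph
    roughly in half.  Returns ``(node positions, adjacency, midpoint index
    per (face, local edge))``.
    """
    v = mesh.vertices
    t = mesh.triangles
    edges = np.sort(
        np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
    )
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    midpoints = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    nodes = np.vstack([v, midpoints])
    n_v = len(v)
    mid_idx = inv.reshape(3, -1).T + n_v  # (n_faces, 3) node ids of edge mids

    rows, cols = [], []
    face_nodes = np.concatenate([t, mid_idx], axis=1)  # (n_faces, 6)
    for a in range(6):
        for b in range(a + 1, 6):
            rows.append(face_nodes[:, a])
            cols.append(face_nodes[:, b])

    # across-edge shortcuts: for each pair of faces sharing an edge, link
    # every node of one to every node of the other.  On a (nearly) planar
    # face pair these chords are valid surface paths; they cut the graph
    # metric's overestimate of geodesic lengths from ~3% to ~1%.
    edge_faces: dict[int, list[int]] = {}
    for fi in range(len(t)):
        for le in range(3):
            edge_faces.setdefault(int(mid_idx[fi, le]), []).append(fi)
    pair_a, pair_b = [], []
    for eid, incident in edge_faces.items():
        if len(incident) == 2:
            pair_a.append(incident[0])
            pair_b.append(incident[1])
    if pair_a:
        fa = face_nodes[np.asarray(pair_a)]
        fb = face_nodes[np.asarray(pair_b)]
        for a in range(6):
            for b in range(6):
                rows.append(fa[:, a])
                cols.append(fb[:, b])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = len(nodes)
    # deduplicate pairs (duplicate COO entries would SUM their weights) and
    # drop self-loops from nodes shared between adjacent faces
    distinct = rows != cols
    rows, cols = rows[distinct], cols[distinct]
    key = rows.astype(np.int64) * n + cols
    key, first = np.unique(key, return_index=True)
    rows, cols = rows[first], cols[first]
    w = np.linalg.norm(nodes[rows] - nodes[cols], axis=1)
    adj = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)
    return nodes, adj, mid_idx


def _closest_point_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); vectorised.

    Standard region classification on the barycentric plane (Ericson).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    t = np.where(np.abs(d1 - d3) > 1e-30, d1 / np.maximum(d1 - d3, 1e-30), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    t = np.where(np.abs(d2 - d6) > 1e-30, d2 / np.maximum(d2 - d6, 1e-30), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = np.maximum((d4 - d3) + (d5 - d6), 1e-30)
    t = (d4 - d3) / denom
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = np.maximum(va + vb + vc, 1e-30)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_point_on_mesh(
    mesh: SurfaceMesh, points: np.ndarray, n_candidates: int = 12
) -> np.ndarray:
    """Nearest mesh-surface point for each query point.

    Broad phase by k nearest triangle centroids, exact narrow phase on the
    candidate triangles.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(points)
    v = mesh.vertices
    t = mesh.triangles
    centroids = v[t].mean(axis=1)
    k = min(n_candidates, len(t))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty_like(points)
    for i, p in enumerate(points):
        tri = t[cand[i]]
        cp = _closest_point_on_triangles(
            np.repeat(p[None], len(tri), axis=0), v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
        )
        out[i] = cp[np.argmin(np.linalg.norm(cp - p, axis=1))]
    return out


def _augment_graph(
    adj: sp.csr_matrix, size: int, rows, cols, weights
) -> sp.csr_matrix:
    """Embed ``adj`` in a larger sparse graph with extra weighted edges."""
    coo = adj.tocoo()
    data = np.concatenate([coo.data, np.asarray(weights, dtype=float)])
    r = np.concatenate([coo.row, np.asarray(rows, dtype=int)])
    c = np.concatenate([coo.col, np.asarray(cols, dtype=int)])
    return sp.csr_matrix((data, (r, c)), shape=(size, size))


def _straighten_on_mesh(points: np.ndarray, mesh: SurfaceMesh, n_iter: int = 25) -> np.ndarray:
    """Shrink a surface polyline by midpoint pulls re-projected to the mesh."""
    pts = points.copy()
    for _ in range(n_iter):
        if len(pts) < 3:
            break
        mids = 0.5 * (pts[:-2] + pts[2:])
        proj = closest_point_on_mesh(mesh, mids)
        new = pts.copy()
        new[1:-1] = proj
        # accept only if it shortens the path
        if np.linalg.norm(np.diff(new, axis=0), axis=1).sum() < np.linalg.norm(
            np.diff(pts, axis=0), axis=1
        ).sum():
            pts = new
        else:
            break
    return pts


def measure_on_surface(
    a: SurfaceAnchor, b: SurfaceAnchor, mesh: SurfaceMesh, refine: bool = True
) -> SurfacePath:
    """Shortest on-surface path between two anchors.

    Dijkstra over the vertex + edge-midpoint graph (anchors linked to their
    face's six nodes), optionally followed by midpoint straightening that
    keeps every vertex on the mesh.  The result's length always bounds the
    straight-line chord from below-never-above: a surface path cannot beat
    the chord.
    """
    nodes, adj, mid_idx = _surface_graph(mesh)
    n = adj.shape[0]
    face_nodes = np.concatenate([mesh.triangles, mid_idx], axis=1)

    extra_rows, extra_cols, extra_w = [], [], []
    for k, anchor in enumerate((a, b)):
        node_id = n + k
        targets = face_nodes[anchor.triangle_id]
        for tgt in targets:
            extra_rows += [node_id, tgt]
            extra_cols += [tgt, node_id]
            d = np.linalg.norm(nodes[tgt] - anchor.position)
            extra_w += [d, d]
    big = _augment_graph(adj, n + 2, extra_rows, extra_cols, extra_w)

    dist, pred = dijkstra(big, indices=n, return_predecessors=True)
    if not np.isfinite(dist[n + 1]):
        raise Unreachable("anchors lie in disconnected mesh components")
    path_ids = []
    cur = n + 1
    while cur != n and cur >= 0:
        path_ids.append(cur)
        cur = pred[cur]
    path_ids.append(n)
    path_ids.reverse()

    all_nodes = np.vstack([nodes, a.position[None], b.position[None]])
    pts = all_nodes[path_ids]
    if refine and len(pts) >= 3:
        pts = _straighten_on_mesh(pts, mesh)
    return SurfacePath(points=pts)


def highlight_area(
    seed: SurfaceAnchor, radius_mm: float, mesh: SurfaceMesh
) -> tuple[np.ndarray, float]:
    """Geodesic flood fill: faces within surface distance ``radius_mm``.

    A face is included when the geodesic distance of its centroid proxy
    (mean of its node distances) stays within the radius.  Returns
    ``(face ids, total area mm^2)``.
    """
    nodes, adj, mid_idx = _surface_graph(mesh)
    n = adj.shape[0]
    face_nodes = np.concatenate([mesh.triangles, mid_idx], axis=1)
    extra_rows, extra_cols, extra_w = [], [], []
    for tgt in face_nodes[seed.triangle_id]:
        d = np.linalg.norm(nodes[tgt] - seed.position)
        extra_rows += [n, tgt]
        extra_cols += [tgt, n]
        extra_w += [d, d]
    big = _augment_graph(adj, n + 1, extra_rows, extra_cols, extra_w)
    dist = dijkstra(big, indices=n)
    face_dist = dist[face_nodes].mean(axis=1)
    selected = np.flatnonzero(face_dist <= radius_mm)
    area = float(mesh.face_areas()[selected].sum())
    return selected, area


def place_label(
    anchor: SurfaceAnchor, payload: object = None, camera_up: np.ndarray | None = None
) -> LabelPose:
    """Orient a label plane at the anchor using the surface normal.

    The in-plane "up" direction is the camera up-vector (default world -y,
    i.e. image-up) projected into the label plane at placement time.
    """
    n = anchor.normal
    up_hint = np.array([0.0, -1.0, 0.0]) if camera_up is None else np.asarray(camera_up, float)
    up = up_hint - (up_hint @ n) * n
    if np.linalg.norm(up) < 1e-9:  # normal parallel to the up hint
        alt = np.array([1.0, 0.0, 0.0])
        up = alt - (alt @ n) * n
    up = up / np.linalg.norm(up)
    return LabelPose(position=anchor.position.copy(), normal=n.copy(), up=up, payload=payload)


def render_overlay_png(
    path: str | Path,
    image: np.ndarray,
    mesh: SurfaceMesh,
    pose: Pose,
    rig: CameraRig,
    tint=(0.1, 0.9, 0.2),
    alpha: float = 0.35,
) -> None:
    """Blend the re-projected mesh over a camera frame and write a PNG.

    The geometric layer is tinted wherever the mesh covers the view — the
    visual check that reconstruction and tracking agree with the video.
    """
    import imageio.v3 as iio

    _, face_id = reproject_mesh(mesh, pose, rig)
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    if img.max() > 1.5:
        img = img / 255.0
    covered = face_id >= 0
    out = img.copy()
    out[covered] = (1 - alpha) * img[covered] + alpha * np.asarray(tint)
    iio.imwrite(str(path), (np.clip(out, 0, 1) * 255).astype(np.uint8))


def save_anchors_json(path: str | Path, anchors: list[SurfaceAnchor]) -> None:
    data = [
        {
            "triangle_id": int(a.triangle_id),
            "barycentric": a.barycentric.tolist(),
            "position": a.position.tolist(),
            "normal": a.normal.tolist(),
        }
        for a in anchors
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
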