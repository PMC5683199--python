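"""Geometry-aware AR: picking, rasterisation, measurement, highlighting."""

import numpy as np
import pytest

from endogeo.geometry import CameraRig, Pose
from endogeo.overlay import (
    RayMiss,
    SurfaceAnchor,
    cast_ray,
    highlight_area,
    measure_on_surface,
    pick,
    pixel_ray,
    place_label,
    reproject_mesh,
)
from endogeo.surface import SurfaceMesh

from conftest import make_hemisphere_mesh


@pytest.fixture()
def rig():
    return CameraRig(200.0, (100.0, 80.0), 5.0, (200, 160))


def single_triangle_mesh(depth=50.0, size=20.0):
    v = np.array(
        [[-size, -size, depth], [size, -size, depth], [0.0, size, depth]]
    )
    return SurfaceMesh(vertices=v, triangles=np.array([[0, 1, 2]]))


def anchor_at(mesh, tri_id, bary=(1 / 3, 1 / 3, 1 / 3)):
    bary = np.asarray(bary, dtype=float)
    pos = bary @ mesh.vertices[mesh.triangles[tri_id]]
    if mesh.normals is not None:
        n = bary @ mesh.normals[mesh.triangles[tri_id]]
    else:
        n = mesh.face_normals()[tri_id]
    return SurfaceAnchor(tri_id, bary, pos, n)


class TestPick:
    def test_centroid_click_gives_uniform_barycentric(self, rig):
        mesh = single_triangle_mesh()
        centroid = mesh.vertices.mean(axis=0)
        pix = np.array(
            [
                rig.fx * centroid[0] / centroid[2] + rig.cx,
                rig.fy * centroid[1] / centroid[2] + rig.cy,
            ]
        )
        anchor = pick(pix, Pose(), rig, mesh)
        assert anchor.triangle_id == 0
        np.testing.assert_allclose(anchor.barycentric, [1 / 3] * 3, atol=1e-9)

    def test_nearer_of_stacked_triangles_returned(self, rig):
        near = single_triangle_mesh(depth=40.0)
        far = single_triangle_mesh(depth=90.0)
        mesh = SurfaceMesh(
            vertices=np.vstack([near.vertices, far.vertices]),
            triangles=np.array([[0, 1, 2], [3, 4, 5]]),
        )
        anchor = pick(np.array([rig.cx, rig.cy]), Pose(), rig, mesh)
        assert anchor.triangle_id == 0
        assert anchor.position[2] == pytest.approx(40.0, abs=1e-9)

    def test_miss_raises(self, rig):
        mesh = single_triangle_mesh()
        with pytest.raises(RayMiss):
            pick(np.array([2.0, 2.0]), Pose(), rig, mesh)  # corner ray misses

    def test_pixel_outside_image_rejected(self, rig):
        with pytest.raises(ValueError):
            pick(np.array([-5.0, 10.0]), Pose(), rig, single_triangle_mesh())

    @staticmethod
    def _scalar_ray_oracle(origin, direction, mesh):
        """Independent route: plane intersection + barycentric sign test,
        one triangle at a time."""
        best = None
        for fi, tri in enumerate(mesh.triangles):
            a, b, c = mesh.vertices[tri]
            n = np.cross(b - a, c - a)
            denom = n @ direction
            if abs(denom) < 1e-14:
                continue
            t = (n @ (a - origin)) / denom
            if t <= 1e-9:
                continue
            p = origin + t * direction
            # barycentric via projected areas
            area2 = np.linalg.norm(n)
            w0 = np.cross(b - p, c - p) @ n / area2**2 * area2
            w1 = np.cross(c - p, a - p) @ n / area2**2 * area2
            w2 = np.cross(a - p, b - p) @ n / area2**2 * area2
            if w0 >= -1e-9 and w1 >= -1e-9 and w2 >= -1e-9:
                if best is None or t < best[1]:
                    best = (fi, t)
        return best

    def test_matches_scalar_ray_oracle(self, rig, hemisphere_mesh):
        """First hits agree with a per-triangle plane/barycentric oracle."""
        mesh = SurfaceMesh(
            vertices=hemisphere_mesh.vertices + np.array([0, 0, 60.0]),
            triangles=hemisphere_mesh.triangles,
            normals=hemisphere_mesh.normals,
        )
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(100):
            pix = rng.uniform([0, 0], [rig.width, rig.height])
            origin, direction = pixel_ray(pix, Pose(), rig)
            try:
                tri_id, t, bary = cast_ray(origin, direction, mesh)
            except RayMiss:
                tri_id = None
            oracle = self._scalar_ray_oracle(origin, direction, mesh)
            if tri_id is None:
                assert oracle is None
                continue
            assert oracle is not None
            assert t == pytest.approx(oracle[1], abs=1e-9)
            if bary.min() > 1e-6:  # interior hits have a unique face
                assert tri_id == oracle[0]
            checked += 1
        assert checked > 60


class TestReprojectMesh:
    def test_mesh_behind_camera_gives_empty_buffer(self, rig):
        mesh = single_triangle_mesh(depth=-50.0)
        depth, face_id = reproject_mesh(mesh, Pose(), rig)
        assert np.all(np.isinf(depth))
        assert np.all(face_id == -1)

    def test_fronto_parallel_triangle_depth_exact(self, rig):
        mesh = single_triangle_mesh(depth=70.0)
        depth, face_id = reproject_mesh(mesh, Pose(), rig)
        covered = face_id == 0
        assert covered.sum() > 100
        np.testing.assert_allclose(depth[covered], 70.0, atol=1e-9)

    def test_pick_and_rasterise_agree(self, rig, hemisphere_mesh):
        """Picking a rasterised pixel returns the face that covered it."""
        mesh = SurfaceMesh(
            vertices=hemisphere_mesh.vertices + np.array([0, 0, 60.0]),
            triangles=hemisphere_mesh.triangles,
            normals=hemisphere_mesh.normals,
        )
        depth, face_id = reproject_mesh(mesh, Pose(), rig)
        rng = np.random.default_rng(1)
        ys, xs = np.nonzero(face_id >= 0)
        idx = rng.choice(len(ys), size=100, replace=False)
        agree = 0
        for i in idx:
            pix = np.array([float(xs[i]), float(ys[i])])
            anchor = pick(pix, Pose(), rig, mesh)
            agree += anchor.triangle_id == face_id[ys[i], xs[i]]
        # pixel-centre rounding can land on a neighbouring face at edges
        assert agree >= 95

    def test_depth_buffer_vs_ground_truth(self, scene, small_rig):
        """Rasterised mesh depth tracks the true depth map (median <=2 mm)."""
        from endogeo import synth
        from endogeo.surface import triangulate_surface

        pose = synth.hover_trajectory(3)[0]
        fr = synth.render_frame(scene, pose, small_rig)
        gx, gy = np.meshgrid(np.linspace(-45, 45, 80), np.linspace(-40, 40, 75))
        cloud = np.column_stack([gx.ravel(), gy.ravel(), scene.height(gx, gy).ravel()])
        mesh = triangulate_surface(cloud)
        depth, face_id = reproject_mesh(mesh, pose, small_rig)
        covered = face_id >= 0
        err = np.abs(depth[covered] - fr.depth[covered])
        assert np.median(err) <= 2.0


class TestMeasurement:
    def test_flat_mesh_path_equals_chord(self):
        gx, gy = np.meshgrid(np.linspace(0, 40, 30), np.linspace(0, 40, 30))
        cloud = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        from endogeo.surface import triangulate_surface

        mesh = triangulate_surface(cloud)
        a = anchor_at(mesh, 0)
        b = anchor_at(mesh, mesh.n_triangles - 1)
        path = measure_on_surface(a, b, mesh)
        chord = np.linalg.norm(a.position - b.position)
        assert path.length == pytest.approx(chord, rel=0.01)
        assert path.length >= chord - 1e-9

    def test_hemisphere_quarter_great_circle(self, hemisphere_mesh):
        """Geodesic between equator and pole: pi R / 2, strictly > chord."""
        R = 30.0
        mesh = hemisphere_mesh
        # anchors nearest to (R,0,0) and (0,0,R)
        ia = np.argmin(np.linalg.norm(mesh.vertices - [R, 0, 0], axis=1))
        ib = np.argmin(np.linalg.norm(mesh.vertices - [0, 0, R], axis=1))

        def vertex_anchor(vid):
            tri_id = int(np.argwhere((mesh.triangles == vid).any(axis=1))[0, 0])
            tri = mesh.triangles[tri_id]
            bary = (tri == vid).astype(float)
            return SurfaceAnchor(tri_id, bary, mesh.vertices[vid], mesh.normals[vid])

        a, b = vertex_anchor(ia), vertex_anchor(ib)
        path = measure_on_surface(a, b, mesh)
        analytic = np.pi * R / 2
        chord = np.linalg.norm(a.position - b.position)
        assert path.length == pytest.approx(analytic, rel=0.03)
        assert path.length > chord

    def test_finer_mesh_converges_to_analytic(self, hemisphere_mesh, hemisphere_mesh_coarse):
        R = 30.0
        analytic = np.pi * R / 2

        def quarter_length(mesh):
            ia = np.argmin(np.linalg.norm(mesh.vertices - [R, 0, 0], axis=1))
            ib = np.argmin(np.linalg.norm(mesh.vertices - [0, 0, R], axis=1))

            def vertex_anchor(vid):
                tri_id = int(np.argwhere((mesh.triangles == vid).any(axis=1))[0, 0])
                tri = mesh.triangles[tri_id]
                bary = (tri == vid).astype(float)
                return SurfaceAnchor(tri_id, bary, mesh.vertices[vid], mesh.normals[vid])

            return measure_on_surface(
                vertex_anchor(ia), vertex_anchor(ib), mesh
            ).length

        err_coarse = abs(quarter_length(hemisphere_mesh_coarse) - analytic)
        err_fine = abs(quarter_length(hemisphere_mesh) - analytic)
        assert err_fine < err_coarse

    def test_path_length_bounds_chord_always(self, hemisphere_mesh):
        rng = np.random.default_rng(2)
        mesh = hemisphere_mesh
        for _ in range(10):
            ta, tb = rng.integers(0, mesh.n_triangles, size=2)
            a, b = anchor_at(mesh, ta), anchor_at(mesh, tb)
            path = measure_on_surface(a, b, mesh)
            assert path.length >= np.linalg.norm(a.position - b.position) - 1e-9

    def test_disconnected_components_unreachable(self):
        from endogeo.overlay import Unreachable

        v = np.array(
            [
                [0, 0, 0], [1, 0, 0], [0, 1, 0],
                [100, 100, 0], [101, 100, 0], [100, 101, 0],
            ],
            dtype=float,
        )
        mesh = SurfaceMesh(vertices=v, triangles=np.array([[0, 1, 2], [3, 4, 5]]))
        with pytest.raises(Unreachable):
            measure_on_surface(anchor_at(mesh, 0), anchor_at(mesh, 1), mesh)


class TestHighlight:
    def test_whole_mesh_highlight_equals_total_area(self, hemisphere_mesh):
        seed = anchor_at(hemisphere_mesh, 0)
        faces, area = highlight_area(seed, radius_mm=1e6, mesh=hemisphere_mesh)
        assert len(faces) == hemisphere_mesh.n_triangles
        assert area == pytest.approx(hemisphere_mesh.area(), rel=1e-9)

    def test_planar_disc_area(self):
        from endogeo.surface import triangulate_surface

        gx, gy = np.meshgrid(np.linspace(-40, 40, 90), np.linspace(-40, 40, 90))
        cloud = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        mesh = triangulate_surface(cloud)
        centre = np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1))
        tri_id = int(np.argwhere((mesh.triangles == centre).any(axis=1))[0, 0])
        tri = mesh.triangles[tri_id]
        bary = (tri == centre).astype(float)
        seed = SurfaceAnchor(tri_id, bary, mesh.vertices[centre], np.array([0, 0, 1.0]))
        r = 20.0
        _, area = highlight_area(seed, r, mesh)
        assert area == pytest.approx(np.pi * r**2, rel=0.05)

    def test_spherical_cap_area(self, hemisphere_mesh):
        """Cap of angular radius theta: 2 pi R^2 (1 - cos theta) within 5%."""
        R = 30.0
        mesh = hemisphere_mesh
        pole = np.argmin(np.linalg.norm(mesh.vertices - [0, 0, R], axis=1))
        tri_id = int(np.argwhere((mesh.triangles == pole).any(axis=1))[0, 0])
        tri = mesh.triangles[tri_id]
        bary = (tri == pole).astype(float)
        seed = SurfaceAnchor(tri_id, bary, mesh.vertices[pole], np.array([0, 0, 1.0]))
        theta = np.deg2rad(40)
        _, area = highlight_area(seed, R * theta, mesh)
        assert area == pytest.approx(2 * np.pi * R**2 * (1 - np.cos(theta)), rel=0.05)


class TestLabels:
    def test_fronto_parallel_label_faces_camera(self, rig):
        mesh = single_triangle_mesh(depth=60.0)
        anchor = pick(np.array([rig.cx, rig.cy]), Pose(), rig, mesh)
        label = place_label(anchor, payload="tumour")
        # surface normal of a fronto-parallel plane is the viewing direction
        assert abs(abs(label.normal[2]) - 1.0) < 1e-9
        assert label.payload == "tumour"
        assert abs(label.normal @ label.up) < 1e-9

    def test_sphere_labels_radial(self, hemisphere_mesh):
        rng = np.random.default_rng(3)
        mesh = hemisphere_mesh
        for _ in range(20):
            tri = rng.integers(0, mesh.n_triangles)
            anchor = anchor_at(mesh, tri)
            label = place_label(anchor)
            radial = anchor.position / np.linalg.norm(anchor.position)
            ang = np.degrees(
                np.arccos(np.clip(abs(label.normal @ radial), -1, 1))
            )
            assert ang <= 5.0

    def test_label_stays_anchored_over_trajectory(self, scene, small_rig):
        """Re-projected label tracks its anchor within 3 px over 50 frames."""
        from endogeo import synth
        from endogeo.geometry import project_many
        from endogeo.surface import triangulate_surface

        gx, gy = np.meshgrid(np.linspace(-35, 35, 70), np.linspace(-35, 35, 70))
        cloud = np.column_stack([gx.ravel(), gy.ravel(), scene.height(gx, gy).ravel()])
        mesh = triangulate_surface(cloud)
        pose0 = synth.hover_trajectory(3)[0]
        anchor = pick(np.array([small_rig.cx + 20, small_rig.cy - 10]), pose0, small_rig, mesh)
        label = place_label(anchor)
        # the anchor's true surface point: same (x, y), height from the scene
        true_pt = np.array(
            [anchor.position[0], anchor.position[1],
             float(scene.height(anchor.position[0], anchor.position[1]))]
        )
        for pose in synth.hover_trajectory(50):
            pix_label, _ = project_many(label.position[None], pose, small_rig)
            pix_true, _ = project_many(true_pt[None], pose, small_rig)
            assert np.linalg.norm(pix_label - pix_true) <= 3.0


class TestOverlayRender:
    def test_overlay_png_written_and_tinted(self, rig, tmp_path):
        import imageio.v3 as iio

        mesh = single_triangle_mesh(depth=70.0)
        image = np.full((rig.height, rig.width), 100, dtype=np.uint8)
        from endogeo.overlay import render_overlay_png

        path = tmp_path / "overlay.png"
        render_overlay_png(path, image, mesh, Pose(), rig)
        out = iio.imread(path)
        assert out.shape == (rig.height, rig.width, 3)
        # covered pixels shifted toward the green tint, others untouched
        _, face_id = reproject_mesh(mesh, Pose(), rig)
        covered = face_id >= 0
        assert (out[covered][:, 1] > out[covered][:, 0]).all()
        assert np.array_equal(out[~covered][:, 0], np.full((~covered).sum(), 100))
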