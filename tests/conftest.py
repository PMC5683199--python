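"""Shared fixtures: small synthetic rigs, scenes and meshes.

Module tests run on a reduced rig (420x320) so each rendered frame costs
a fraction of a second; the end-to-end benchmark in
``test_acceptance.py`` uses the full-size study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from endogeo.geometry import CameraRig
from endogeo import synth


@pytest.fixture(scope="session")
def small_rig() -> CameraRig:
    return CameraRig(
        focal_length_px=300.0,
        principal_point=(210.0, 160.0),
        baseline_mm=5.0,
        image_size=(420, 320),
    )


@pytest.fixture(scope="session")
def full_rig() -> CameraRig:
    return synth.default_rig()


@pytest.fixture(scope="session")
def scene():
    return synth.generate_scene(11)


@pytest.fixture(scope="session")
def frame_pair(scene, small_rig):
    """One rendered ground-truth stereo frame at the reduced resolution."""
    pose = synth.hover_trajectory(3)[0]
    return synth.render_frame(scene, pose, small_rig)


@pytest.fixture(scope="session")
def frame_pair_full(scene, full_rig):
    """One rendered frame at the full 840x640 study resolution."""
    pose = synth.hover_trajectory(3)[0]
    return synth.render_frame(scene, pose, full_rig)


@pytest.fixture(scope="session")
def small_sequence(scene, small_rig):
    """A short rendered trajectory with ground truth, reduced resolution."""
    traj = synth.hover_trajectory(30)
    return synth.render_sequence(scene, traj, small_rig)


def make_hemisphere_mesh(radius: float = 30.0, subdivisions: int = 4):
    """Upper-hemisphere triangle mesh with exact radial normals."""
    import trimesh

    from endogeo.surface import SurfaceMesh

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(sphere.vertices)
    f = np.asarray(sphere.faces)
    keep_v = v[:, 2] >= -1e-9
    idx_map = -np.ones(len(v), dtype=int)
    idx_map[keep_v] = np.arange(keep_v.sum())
    keep_f = keep_v[f].all(axis=1)
    faces = idx_map[f[keep_f]]
    verts = v[keep_v]
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(vertices=verts, triangles=faces, normals=normals)


@pytest.fixture(scope="session")
def hemisphere_mesh():
    return make_hemisphere_mesh(radius=30.0, subdivisions=4)


@pytest.fixture(scope="session")
def hemisphere_mesh_coarse():
    return make_hemisphere_mesh(radius=30.0, subdivisions=2)
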