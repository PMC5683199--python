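"""Camera model, pose algebra and stereo triangulation.

Conventions (fixed once, used everywhere):

* Right-handed coordinates; the camera looks down its +z axis, x to the
  right, y down.  Image origin is the top-left corner and pixel centers sit
  at integer coordinates.
* The world frame coincides with the first camera frame of a run.
* Quaternions are scalar-first ``(w, x, y, z)`` and encode the
  camera-to-world rotation: ``x_world = R(q) @ x_cam + r``.
  Composition ``quat_multiply(a, b)`` applies ``b`` first, then ``a``
  (matrix convention ``R(a @ b) = R(a) R(b)``).
* The stereo rig is rectified: the right camera is displaced by the
  baseline ``B`` along the left camera's +x axis, with identical
  intrinsics, so corresponding points share an image row and the
  disparity ``d = x_left - x_right`` is positive for points at finite
  positive depth, giving the depth relation ``Z = f * B / d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CameraRig",
    "Pose",
    "StereoObservation",
    "triangulate",
    "triangulate_many",
    "project",
    "project_many",
    "quat_multiply",
    "quat_conjugate",
    "quat_normalize",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_from_rotvec",
    "quat_to_rotvec",
    "load_calibration",
    "save_calibration",
    "MIN_DISPARITY_PX",
]

#: Disparities below this are treated as non-matching / at-infinity points:
#: the depth Z = f*B/d diverges as d -> 0 and its error explodes with it.
MIN_DISPARITY_PX = 0.5


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first)
# ---------------------------------------------------------------------------

def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("zero quaternion cannot be normalised")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` (apply ``b`` first, then ``a``)."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Rotation matrix to scalar-first unit quaternion (Shepperd's method)."""
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        if i == 0:
            s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2.0
            q = np.array(
                [(R[2, 1] - R[1, 2]) / s, 0.25 * s, (R[0, 1] + R[1, 0]) / s, (R[0, 2] + R[2, 0]) / s]
            )
        elif i == 1:
            s = np.sqrt(1.0 - R[0, 0] + R[1, 1] - R[2, 2]) * 2.0
            q = np.array(
                [(R[0, 2] - R[2, 0]) / s, (R[0, 1] + R[1, 0]) / s, 0.25 * s, (R[1, 2] + R[2, 1]) / s]
            )
        else:
            s = np.sqrt(1.0 - R[0, 0] - R[1, 1] + R[2, 2]) * 2.0
            q = np.array(
                [(R[1, 0] - R[0, 1]) / s, (R[0, 2] + R[2, 0]) / s, (R[1, 2] + R[2, 1]) / s, 0.25 * s]
            )
    if q[0] < 0:
        q = -q
    return quat_normalize(q)


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, radians) to unit quaternion."""
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        # first-order expansion keeps the map smooth through zero
        return quat_normalize(np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]))
    axis = v / theta
    return np.concatenate([[np.cos(theta / 2.0)], np.sin(theta / 2.0) * axis])


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(q)
    if w < 0:
        w, x, y, z = -w, -x, -y, -z
    s = np.linalg.norm([x, y, z])
    if s < 1e-12:
        return 2.0 * np.array([x, y, z])
    theta = 2.0 * np.arctan2(s, w)
    return theta * np.array([x, y, z]) / s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CameraRig:
    """Rectified stereo rig: shared intrinsics, baseline along +x.

    Parameters
    ----------
    focal_length_px:
        Focal length *f* in pixels.  ``fy`` may differ from ``fx`` (set
        ``focal_length_y_px``); by default the rig is isotropic.
    principal_point:
        ``(cx, cy)`` in pixels.
    baseline_mm:
        Stereo baseline *B* in millimetres (>0).
    image_size:
        ``(width, height)`` in pixels.
    """

    focal_length_px: float
    principal_point: tuple[float, float]
    baseline_mm: float
    image_size: tuple[int, int]
    focal_length_y_px: float | None = None
    min_disparity_px: float = MIN_DISPARITY_PX

    def __post_init__(self) -> None:
        if self.focal_length_px <= 0:
            raise ValueError("focal_length_px must be > 0")
        if self.baseline_mm <= 0:
            raise ValueError("baseline_mm must be > 0")
        if self.focal_length_y_px is None:
            self.focal_length_y_px = float(self.focal_length_px)

    @property
    def fx(self) -> float:
        return float(self.focal_length_px)

    @property
    def fy(self) -> float:
        return float(self.focal_length_y_px)

    @property
    def cx(self) -> float:
        return float(self.principal_point[0])

    @property
    def cy(self) -> float:
        return float(self.principal_point[1])

    @property
    def width(self) -> int:
        return int(self.image_size[0])

    @property
    def height(self) -> int:
        return int(self.image_size[1])

    def depth_from_disparity(self, disparity: np.ndarray | float):
        """Depth Z = f*B/d for positive disparities (mm)."""
        return self.fx * self.baseline_mm / np.asarray(disparity, dtype=float)

    def disparity_from_depth(self, depth: np.ndarray | float):
        return self.fx * self.baseline_mm / np.asarray(depth, dtype=float)


@dataclass
class Pose:
    """Camera pose: position ``r`` (mm, world) + camera-to-world quaternion ``q``."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = quat_normalize(np.asarray(self.orientation, dtype=float).reshape(4))

    def rotation_matrix(self) -> np.ndarray:
        """Camera-to-world rotation."""
        return quat_to_matrix(self.orientation)

    def to_world(self, points_cam: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_cam, dtype=float))
        return pts @ self.rotation_matrix().T + self.position

    def to_camera(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        return (pts - self.position) @ self.rotation_matrix()

    def compose(self, other: "Pose") -> "Pose":
        """This pose applied after ``other`` (both camera-to-world maps)."""
        return Pose(
            position=self.to_world(other.position)[0],
            orientation=quat_multiply(self.orientation, other.orientation),
        )

    def inverse(self) -> "Pose":
        qinv = quat_conjugate(self.orientation)
        return Pose(position=-(quat_to_matrix(qinv) @ self.position), orientation=qinv)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous camera-to-world matrix."""
        T = np.eye(4)
        T[:3, :3] = self.rotation_matrix()
        T[:3, 3] = self.position
        return T

    def copy(self) -> "Pose":
        return Pose(self.position.copy(), self.orientation.copy())


@dataclass
class StereoObservation:
    """One matched keypoint pair on a rectified stereo frame."""

    x_left: float
    x_right: float
    y: float

    @property
    def disparity(self) -> float:
        return self.x_left - self.x_right


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def triangulate(obs: StereoObservation, rig: CameraRig) -> np.ndarray:
    """Back-project one stereo observation to a camera-frame 3D point (mm).

    Depth is the similar-triangles relation ``Z = f * B / d``; x and y follow
    from the pinhole model at that depth.  Raises ``ValueError`` for
    disparities at or below the rig's minimum cutoff.
    """
    d = obs.disparity
    if d <= 0 or d < rig.min_disparity_px:
        raise ValueError(f"disparity {d:.3f} px below minimum {rig.min_disparity_px} px")
    Z = rig.fx * rig.baseline_mm / d
    X = (obs.x_left - rig.cx) * Z / rig.fx
    Y = (obs.y - rig.cy) * Z / rig.fy
    return np.array([X, Y, Z])


def triangulate_many(
    x_left: np.ndarray, x_right: np.ndarray, y: np.ndarray, rig: CameraRig
) -> np.ndarray:
    """Vectorised :func:`triangulate` for arrays of matched coordinates."""
    x_left = np.asarray(x_left, dtype=float)
    d = x_left - np.asarray(x_right, dtype=float)
    if np.any(d < rig.min_disparity_px):
        raise ValueError("disparities below the minimum cutoff; filter first")
    Z = rig.fx * rig.baseline_mm / d
    X = (x_left - rig.cx) * Z / rig.fx
    Y = (np.asarray(y, dtype=float) - rig.cy) * Z / rig.fy
    return np.column_stack([X, Y, Z])


def project(
    point_world: np.ndarray,
    pose: Pose,
    rig: CameraRig,
    camera: str = "left",
) -> tuple[np.ndarray, bool]:
    """Pinhole projection of one world point into the chosen camera.

    Returns ``(pixel, visible)``; ``visible`` is False for points at or
    behind the camera plane (depth <= 0), whose pixel is meaningless.
    """
    pix, vis = project_many(np.asarray(point_world, dtype=float)[None, :], pose, rig, camera)
    return pix[0], bool(vis[0])


def project_many(
    points_world: np.ndarray, pose: Pose, rig: CameraRig, camera: str = "left"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised projection; returns ``(pixels (n,2), visible (n,) bool)``."""
    pc = pose.to_camera(points_world)
    if camera == "right":
        # rectified rig: right camera sits baseline further along +x
        pc = pc - np.array([rig.baseline_mm, 0.0, 0.0])
    elif camera != "left":
        raise ValueError("camera must be 'left' or 'right'")
    z = pc[:, 2]
    visible = z > 1e-9
    zs = np.where(visible, z, 1.0)
    u = rig.fx * pc[:, 0] / zs + rig.cx
    v = rig.fy * pc[:, 1] / zs + rig.cy
    return np.column_stack([u, v]), visible


# ---------------------------------------------------------------------------
# calibration I/O
# ---------------------------------------------------------------------------


def load_calibration(path: str | Path) -> CameraRig:
    """Read a YAML calibration file.

    Accepts either a single ``f`` or separate ``fx``/``fy``, plus
    ``cx, cy, baseline_mm, width, height``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "f" in data:
        fx = float(data["f"])
        fy = float(data.get("fy", fx))
    else:
        fx = float(data["fx"])
        fy = float(data.get("fy", fx))
    return CameraRig(
        focal_length_px=fx,
        focal_length_y_px=fy,
        principal_point=(float(data["cx"]), float(data["cy"])),
        baseline_mm=float(data["baseline_mm"]),
        image_size=(int(data["width"]), int(data["height"])),
        min_disparity_px=float(data.get("min_disparity_px", MIN_DISPARITY_PX)),
    )


def save_calibration(rig: CameraRig, path: str | Path) -> None:
    data = {
        "fx": rig.fx,
        "fy": rig.fy,
        "cx": rig.cx,
        "cy": rig.cy,
        "baseline_mm": rig.baseline_mm,
        "width": rig.width,
        "height": rig.height,
        "min_disparity_px": rig.min_disparity_px,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
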