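"""Frame-to-frame camera pose estimation.

The tracker predicts each new pose with the constant-velocity motion model
(position advanced by the linear velocity, orientation composed with the
quaternion of the angular-velocity rotation vector), re-projects the map to
obtain per-landmark search windows, forms 3D-3D correspondences by
descriptor matching inside those windows, and estimates the rigid motion
with a 3-point RANSAC whose minimal solver is the closed-form
orthogonal-Procrustes (Kabsch) alignment.  RANSAC is what makes tracking
survive the non-rigid part of an endoscopic scene: mismatched features,
moving specular highlights and locally deforming tissue all land in the
outlier set.

Residual convention
-------------------
The estimated :class:`RigidTransform` ``(R, T)`` maps points of the *later*
frame into the *earlier* frame: ``p_t ≈ R @ p_{t+1} + T`` (sum of norms of
those residuals is the objective).  The camera motion between the frames is
the same map read as a pose update: if ``p_t`` are world-frame (or
earlier-camera-frame) points and ``p_{t+1}`` are current-camera points,
then ``(R, T)`` is directly the current camera-to-world (camera-to-earlier)
pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    CameraRig,
    Pose,
    project_many,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
)

__all__ = [
    "MotionState",
    "RigidTransform",
    "CorrespondenceSet",
    "RansacParams",
    "TrackingLost",
    "predict_pose",
    "advance_motion_state",
    "guided_search_regions",
    "solve_rigid_minimal",
    "solve_rigid_lsq",
    "estimate_rigid_ransac",
    "refine_pose_reprojection",
    "ransac_num_iterations",
]


class TrackingLost(RuntimeError):
    """Raised when no RANSAC hypothesis reaches the minimum inlier count."""


@dataclass
class MotionState:
    """Camera kinematic state for constant-velocity prediction.

    Accelerations are carried for completeness but default to zero (the
    plain constant-velocity model); set ``estimate_acceleration`` in the
    pipeline config to finite-difference them from successive velocities.
    """

    pose: Pose = field(default_factory=Pose)
    linear_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm/frame
    angular_velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/frame
    linear_acceleration: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angular_acceleration: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dt: float = 1.0


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + T`` (R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class CorrespondenceSet:
    """Paired 3D points: ``points_t`` (earlier/world) vs ``points_t1`` (later)."""

    points_t: np.ndarray
    points_t1: np.ndarray

    def __post_init__(self) -> None:
        self.points_t = np.atleast_2d(np.asarray(self.points_t, dtype=float))
        self.points_t1 = np.atleast_2d(np.asarray(self.points_t1, dtype=float))
        if self.points_t.shape != self.points_t1.shape:
            raise ValueError("correspondence arrays must have equal shape")

    def __len__(self) -> int:
        return len(self.points_t)


@dataclass
class RansacParams:
    inlier_threshold_mm: float = 1.0
    max_iterations: int = 500
    confidence: float = 0.99
    min_inliers: int = 10
    seed: int | None = None


# ---------------------------------------------------------------------------
# motion model
# ---------------------------------------------------------------------------


def predict_pose(state: MotionState) -> Pose:
    """One step of the constant-velocity motion model.

    ``r_{t+1} = r_t + v_t dt``; ``q_{t+1} = q_t * q(w_t dt)``, the angular
    velocity being expressed in the camera frame (so the increment composes
    on the right).  The quaternion is renormalised after the update.
    """
    r = state.pose.position + state.linear_velocity * state.dt
    dq = quat_from_rotvec(state.angular_velocity * state.dt)
    q = quat_normalize(quat_multiply(state.pose.orientation, dq))
    return Pose(position=r, orientation=q)


def advance_motion_state(state: MotionState, new_pose: Pose, estimate_acceleration: bool = False) -> MotionState:
    """Update velocities from the newly estimated pose (finite differences).

    With ``estimate_acceleration`` the accelerations are the differences of
    the last two velocity estimates; otherwise they stay zero and the model
    is purely constant-velocity.
    """
    dt = state.dt
    v_new = (new_pose.position - state.pose.position) / dt
    dq = quat_multiply(
        np.array([state.pose.orientation[0], *(-state.pose.orientation[1:])]), new_pose.orientation
    )
    from .geometry import quat_to_rotvec

    w_new = quat_to_rotvec(dq) / dt
    if estimate_acceleration:
        a = (v_new - state.linear_velocity) / dt
        alpha = (w_new - state.angular_velocity) / dt
    else:
        a = np.zeros(3)
        alpha = np.zeros(3)
    return MotionState(
        pose=new_pose.copy(),
        linear_velocity=v_new + a * dt if estimate_acceleration else v_new,
        angular_velocity=w_new + alpha * dt if estimate_acceleration else w_new,
        linear_acceleration=a,
        angular_acceleration=alpha,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# guided search
# ---------------------------------------------------------------------------


def guided_search_regions(
    predicted: Pose,
    landmark_positions: np.ndarray,
    rig: CameraRig,
    radius_px: float = 15.0,
) -> dict[int, tuple[float, float, float, float]]:
    """Square pixel windows where each landmark is expected to appear.

    Returns ``{landmark index: (x_min, y_min, x_max, y_max)}`` for every
    landmark that projects in front of the camera and inside the (window-
    expanded) image; landmarks behind the camera or far outside the frame
    yield no window.
    """
    pixels, visible = project_many(landmark_positions, predicted, rig)
    regions: dict[int, tuple[float, float, float, float]] = {}
    for i, (pix, vis) in enumerate(zip(pixels, visible)):
        if not vis:
            continue
        x, y = pix
        if x < -radius_px or y < -radius_px or x >= rig.width + radius_px or y >= rig.height + radius_px:
            continue
        regions[i] = (x - radius_px, y - radius_px, x + radius_px, y + radius_px)
    return regions


# ---------------------------------------------------------------------------
# rigid estimation
# ---------------------------------------------------------------------------


def solve_rigid_lsq(points_t: np.ndarray, points_t1: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment (Kabsch / SVD).

    Finds ``(R, T)`` minimising ``sum ||p_t - (R p_{t+1} + T)||^2``.
    """
    a = np.atleast_2d(points_t1)  # source
    b = np.atleast_2d(points_t)  # target
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return RigidTransform(R, cb - R @ ca)


def solve_rigid_minimal(points_t: np.ndarray, points_t1: np.ndarray) -> RigidTransform:
    """Minimal 3-point rigid alignment; raises on (near-)collinear triples."""
    a = np.atleast_2d(points_t1)
    if len(a) != 3:
        raise ValueError("minimal solver needs exactly 3 pairs")
    # collinearity check on the source triple: degenerate triangles give an
    # ill-conditioned rotation and must be resampled by the caller
    v1, v2 = a[1] - a[0], a[2] - a[0]
    cross = np.cross(v1, v2)
    scale = max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12)
    if np.linalg.norm(cross) < 1e-6 * scale:
        raise ValueError("collinear triple")
    return solve_rigid_lsq(points_t, points_t1)


def ransac_num_iterations(
    inlier_fraction: float, confidence: float = 0.99, sample_size: int = 3
) -> int:
    """Standard RANSAC iteration count for a target confidence level."""
    inlier_fraction = min(max(inlier_fraction, 1e-6), 1.0 - 1e-12)
    p_good = inlier_fraction**sample_size
    return int(np.ceil(np.log(1.0 - confidence) / np.log(1.0 - p_good)))


def estimate_rigid_ransac(
    corr: CorrespondenceSet,
    params: RansacParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Robust rigid motion from 3D-3D correspondences.

    Repeatedly samples 3 pairs, solves the minimal alignment, and scores
    hypotheses by the per-point residual ``||p_t - (R p_{t+1} + T)||``
    against the inlier threshold.  The best hypothesis's inliers are then
    refined with the full least-squares solver; the refinement cannot
    increase the residual of the consensus set.  The iteration budget
    adapts from the best inlier ratio seen so far (0.99-confidence rule)
    and is capped at ``params.max_iterations``.

    Returns ``(transform, inlier_mask)``.  Raises :class:`TrackingLost`
    when no hypothesis gathers ``params.min_inliers`` inliers.
    """
    params = params or RansacParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(corr)
    if n < 3:
        raise TrackingLost(f"need >= 3 correspondences, got {n}")

    pt, pt1 = corr.points_t, corr.points_t1
    best_hyp: RigidTransform | None = None
    best_mask: np.ndarray | None = None
    best_count = 0
    best_err = np.inf
    max_iter = params.max_iterations
    it = 0
    while it < max_iter:
        it += 1
        idx = rng.choice(n, size=3, replace=False)
        try:
            hyp = solve_rigid_minimal(pt[idx], pt1[idx])
        except ValueError:
            continue
        resid = np.linalg.norm(pt - hyp.apply(pt1), axis=1)
        mask = resid < params.inlier_threshold_mm
        count = int(mask.sum())
        err = float(resid[mask].sum()) if count else np.inf
        if count > best_count or (count == best_count and err < best_err):
            best_count, best_mask, best_err, best_hyp = count, mask, err, hyp
            # adaptive budget: enough iterations for 0.99 confidence at the
            # observed inlier ratio, never above the configured cap
            needed = ransac_num_iterations(count / n, params.confidence)
            max_iter = min(params.max_iterations, max(it, needed))

    if best_mask is None or best_count < params.min_inliers:
        raise TrackingLost(
            f"best hypothesis has {best_count} inliers (< {params.min_inliers})"
        )

    refined = solve_rigid_lsq(pt[best_mask], pt1[best_mask])
    # refinement is monotone in the sum-of-norms objective on the consensus
    # set: fall back to the minimal hypothesis in the rare case it scores
    # better (the closed form minimises squared norms, not norms)
    err_ref = float(np.linalg.norm(pt[best_mask] - refined.apply(pt1[best_mask]), axis=1).sum())
    if err_ref > best_err:
        refined = best_hyp
    resid_ref = np.linalg.norm(pt - refined.apply(pt1), axis=1)
    mask_ref = resid_ref < params.inlier_threshold_mm
    if mask_ref.sum() >= best_count:
        return refined, mask_ref
    return refined, best_mask


def refine_pose_reprojection(
    pose: Pose,
    points_world: np.ndarray,
    pixels: np.ndarray,
    rig: CameraRig,
    huber_delta_px: float = 2.0,
    n_iter: int = 8,
) -> Pose:
    """Motion-only refinement: minimise robust reprojection error over the pose.

    The 3D-3D RANSAC estimate inherits the depth noise of stereo
    triangulation; re-projecting the map into the image and minimising the
    pixel error instead uses the far more precise keypoint positions.
    Damped Gauss-Newton on 6 parameters with Huber-weighted residuals;
    steps are only accepted while the robust cost decreases.
    """
    points_world = np.atleast_2d(points_world)
    pixels = np.atleast_2d(pixels)
    position = pose.position.copy()
    orientation = pose.orientation.copy()

    def _residuals(position, orientation):
        R = Pose(position, orientation).rotation_matrix()
        pc = (points_world - position) @ R
        z = np.maximum(pc[:, 2], 1e-6)
        u = rig.fx * pc[:, 0] / z + rig.cx
        v = rig.fy * pc[:, 1] / z + rig.cy
        return pixels - np.column_stack([u, v]), pc, R

    def _cost(res):
        s = np.linalg.norm(res, axis=1)
        return float(
            np.where(
                s <= huber_delta_px, 0.5 * s * s, huber_delta_px * (s - 0.5 * huber_delta_px)
            ).sum()
        )

    res, pc, R = _residuals(position, orientation)
    cost = _cost(res)
    damping = 1e-4
    for _ in range(n_iter):
        s = np.linalg.norm(res, axis=1)
        w = np.where(s <= huber_delta_px, 1.0, huber_delta_px / np.maximum(s, 1e-12))
        z = np.maximum(pc[:, 2], 1e-6)
        n = len(res)
        J = np.empty((n, 2, 6))
        fx, fy = rig.fx, rig.fy
        inv_z = 1.0 / z
        Jproj = np.zeros((n, 2, 3))
        Jproj[:, 0, 0] = fx * inv_z
        Jproj[:, 0, 2] = -fx * pc[:, 0] * inv_z**2
        Jproj[:, 1, 1] = fy * inv_z
        Jproj[:, 1, 2] = -fy * pc[:, 1] * inv_z**2
        # d pc/d r = -R^T ; d pc/d theta = [pc]_x ; residual = obs - proj
        J[:, :, :3] = -np.einsum("nij,jk->nik", Jproj, -R.T)
        skew = np.zeros((n, 3, 3))
        skew[:, 0, 1] = -pc[:, 2]
        skew[:, 0, 2] = pc[:, 1]
        skew[:, 1, 0] = pc[:, 2]
        skew[:, 1, 2] = -pc[:, 0]
        skew[:, 2, 0] = -pc[:, 1]
        skew[:, 2, 1] = pc[:, 0]
        J[:, :, 3:] = -np.einsum("nij,njk->nik", Jproj, skew)
        Jw = J * np.sqrt(w)[:, None, None]
        rw = res * np.sqrt(w)[:, None]
        A = np.einsum("nij,nik->jk", Jw, Jw)
        b = np.einsum("nij,ni->j", Jw, rw)
        accepted = False
        while damping <= 1e8:
            try:
                step = -np.linalg.solve(A + damping * np.eye(6), b)  # GN descent
            except np.linalg.LinAlgError:
                damping *= 10
                continue
            new_pos = position + step[:3]
            new_q = quat_normalize(quat_multiply(orientation, quat_from_rotvec(step[3:])))
            new_res, new_pc, new_R = _residuals(new_pos, new_q)
            new_cost = _cost(new_res)
            if new_cost < cost:
                position, orientation = new_pos, new_q
                res, pc, R = new_res, new_pc, new_R
                improved = (cost - new_cost) / max(cost, 1e-30)
                cost = new_cost
                damping = max(damping / 10, 1e-10)
                accepted = True
                if improved < 1e-10:
                    return Pose(position, orientation)
                break
            damping *= 10
        if not accepted:
            break
    return Pose(position, orientation)
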