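"""Keyframe management and Huber-robust bundle adjustment.

Frame-to-frame tracking accumulates drift; keyframe-based bundle adjustment
(BA) corrects it by jointly refining the stored keyframe poses ``KF_i`` and
landmark positions ``P_j`` so that the total robust reprojection cost

    sum_{i,j} rho_h( || p_ij - CamProj(KF_i, P_j) || )

is minimised, where ``p_ij`` is the observed pixel of landmark ``j`` in
keyframe ``i`` and ``rho_h`` is the Huber loss (quadratic below ``delta``,
linear above — gross outliers get bounded influence).

The optimiser is an iteratively-reweighted Gauss-Newton with Levenberg
damping on sparse normal equations: a step is accepted only when the robust
cost decreases, so the cost trace is monotone non-increasing by
construction.  The gauge is fixed by anchoring the first keyframe of the
problem, whose pose is left bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import CameraRig, Pose, quat_from_rotvec, quat_multiply, quat_normalize

__all__ = [
    "Keyframe",
    "Landmark",
    "HuberCost",
    "SlamMap",
    "BAParams",
    "BAResult",
    "keyframe_criterion",
    "should_insert_keyframe",
    "bundle_adjust",
    "reprojection_residuals",
    "write_tum_trajectory",
    "read_tum_trajectory",
    "write_ply_points",
]

#: Keyframe insertion thresholds: a new keyframe is taken when the shared-
#: keypoint fraction with the last keyframe drops below the overlap
#: threshold while the frame still tracks more than the minimum count.
KEYFRAME_OVERLAP_THRESHOLD = 0.80
KEYFRAME_MIN_KEYPOINTS = 50


@dataclass
class Keyframe:
    id: int
    pose: Pose
    frame_index: int
    #: list of (landmark id, observed pixel, descriptor); the pixel is
    #: ``(u_left, v)`` or ``(u_left, v, u_right)`` — including the right-
    #: camera column makes the adjustment stereo-constrained, which fixes
    #: the scale that left-only reprojection leaves free
    observations: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def landmark_ids(self) -> set[int]:
        return {lm_id for lm_id, _, _ in self.observations}


@dataclass
class Landmark:
    id: int
    position: np.ndarray  # world frame, mm
    descriptor: np.ndarray
    observation_count: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class HuberCost:
    """Huber transition point in pixels; rho is quadratic below, linear above."""

    delta: float = 2.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("Huber delta must be > 0")

    def rho(self, s: np.ndarray) -> np.ndarray:
        """rho_h applied to non-negative residual norms ``s``."""
        s = np.asarray(s, dtype=float)
        return np.where(s <= self.delta, 0.5 * s * s, self.delta * (s - 0.5 * self.delta))

    def weight(self, s: np.ndarray) -> np.ndarray:
        """IRLS weight rho'(s)/s for the weighted Gauss-Newton step."""
        s = np.asarray(s, dtype=float)
        safe = np.maximum(s, 1e-12)
        return np.where(s <= self.delta, 1.0, self.delta / safe)


@dataclass
class SlamMap:
    """The landmark map plus keyframe history of one run."""

    landmarks: dict[int, Landmark] = field(default_factory=dict)
    keyframes: list[Keyframe] = field(default_factory=list)
    _next_landmark_id: int = 0

    def add_landmark(self, position: np.ndarray, descriptor: np.ndarray) -> int:
        lm_id = self._next_landmark_id
        self._next_landmark_id += 1
        self.landmarks[lm_id] = Landmark(lm_id, position, descriptor)
        return lm_id

    def landmark_positions(self, ids: list[int] | None = None) -> np.ndarray:
        if ids is None:
            ids = list(self.landmarks)
        return np.array([self.landmarks[i].position for i in ids]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# keyframe criterion
# ---------------------------------------------------------------------------


def keyframe_criterion(
    overlap_fraction: float,
    total_keypoints: int,
    overlap_threshold: float = KEYFRAME_OVERLAP_THRESHOLD,
    min_keypoints: int = KEYFRAME_MIN_KEYPOINTS,
) -> bool:
    """True iff shared-keypoint fraction < 0.80 AND keypoint count > 50."""
    return overlap_fraction < overlap_threshold and total_keypoints > min_keypoints


def should_insert_keyframe(
    current_landmark_ids: set[int],
    last_keyframe: Keyframe,
    total_keypoints: int | None = None,
    recall_baseline: float = 1.0,
    overlap_threshold: float = KEYFRAME_OVERLAP_THRESHOLD,
    min_keypoints: int = KEYFRAME_MIN_KEYPOINTS,
) -> bool:
    """Apply the keyframe criterion to a tracked frame vs the last keyframe.

    ``current_landmark_ids`` are the map landmarks the frame tracked;
    ``total_keypoints`` is the frame's full keypoint count (defaults to the
    tracked count).  The shared fraction is the tracked landmarks common
    with the last keyframe over the smaller of the two keypoint counts, so
    a frame that sees a small subset of a rich keyframe still counts as
    overlapping.

    ``recall_baseline`` rescales the measured fraction by the matcher's
    same-view recall: binary-descriptor matching re-finds only a fraction
    of keypoints even with no view change, so the raw fraction
    underestimates how much the views truly share.  The pipeline estimates
    the baseline from the first frame after each keyframe; 1.0 applies the
    raw rule.
    """
    kf_ids = last_keyframe.landmark_ids
    total = len(current_landmark_ids) if total_keypoints is None else total_keypoints
    denom = min(total, len(kf_ids))
    if denom == 0:
        return total > min_keypoints
    overlap = len(current_landmark_ids & kf_ids) / denom
    overlap = min(overlap / max(recall_baseline, 1e-6), 1.0)
    return keyframe_criterion(overlap, total, overlap_threshold, min_keypoints)


# ---------------------------------------------------------------------------
# bundle adjustment
# ---------------------------------------------------------------------------


@dataclass
class BAParams:
    max_iterations: int = 25
    #: stop when the relative cost decrease of an accepted step is below this
    ftol: float = 1e-8
    initial_damping: float = 1e-4
    max_damping: float = 1e8


@dataclass
class BAResult:
    cost_initial: float
    cost_final: float
    iterations: int
    converged: bool
    cost_trace: list[float] = field(default_factory=list)


def _collect_problem(
    keyframes: list[Keyframe], landmarks: dict[int, Landmark]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Flatten observations of landmarks seen >= 2 times in the window."""
    counts: dict[int, int] = {}
    for kf in keyframes:
        for lm_id, _, _ in kf.observations:
            counts[lm_id] = counts.get(lm_id, 0) + 1
    active = sorted(i for i, c in counts.items() if c >= 2 and i in landmarks)
    lm_index = {lm_id: k for k, lm_id in enumerate(active)}
    obs_kf, obs_lm, obs_px = [], [], []
    for ki, kf in enumerate(keyframes):
        for lm_id, pixel, _ in kf.observations:
            if lm_id in lm_index:
                obs_kf.append(ki)
                obs_lm.append(lm_index[lm_id])
                px = np.asarray(pixel, dtype=float).ravel()
                if px.size == 2:  # mono observation: right column unknown
                    px = np.array([px[0], px[1], np.nan])
                obs_px.append(px)
    return (
        np.asarray(obs_kf, dtype=int),
        np.asarray(obs_lm, dtype=int),
        np.asarray(obs_px, dtype=float).reshape(-1, 3),
        active,
    )


def reprojection_residuals(
    poses: list[Pose], points: np.ndarray, obs_kf: np.ndarray, obs_lm: np.ndarray,
    obs_px: np.ndarray, rig: CameraRig,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals (n,3) ``p_ij - proj(...)`` and camera-frame points (n,3).

    Components are (left u, left v, right u); the third is zero for mono
    observations (NaN right column).
    """
    n = len(obs_kf)
    res = np.zeros((n, 3))
    pcams = np.empty((n, 3))
    Rs = [p.rotation_matrix() for p in poses]
    rs = [p.position for p in poses]
    for ki in range(len(poses)):
        sel = obs_kf == ki
        if not sel.any():
            continue
        pc = (points[obs_lm[sel]] - rs[ki]) @ Rs[ki]
        pcams[sel] = pc
        z = np.maximum(pc[:, 2], 1e-6)
        u = rig.fx * pc[:, 0] / z + rig.cx
        v = rig.fy * pc[:, 1] / z + rig.cy
        ur = rig.fx * (pc[:, 0] - rig.baseline_mm) / z + rig.cx
        pred = np.column_stack([u, v, ur])
        r = obs_px[sel] - pred
        r[np.isnan(obs_px[sel, 2]), 2] = 0.0
        res[sel] = r
    return res, pcams


def _robust_cost(res: np.ndarray, huber: HuberCost) -> float:
    return float(huber.rho(np.linalg.norm(res, axis=1)).sum())


def bundle_adjust(
    keyframes: list[Keyframe],
    landmarks: dict[int, Landmark],
    rig: CameraRig,
    huber: HuberCost | None = None,
    params: BAParams | None = None,
) -> BAResult:
    """Minimise the Huber-robust reprojection cost over poses and points.

    Updates ``keyframes`` poses (except the first, the gauge anchor) and
    the positions of every landmark observed at least twice, in place.
    Landmarks observed once are left untouched.  Steps that do not lower
    the robust cost are rejected and the damping raised, so the final cost
    never exceeds the initial one.
    """
    huber = huber or HuberCost()
    params = params or BAParams()
    if len(keyframes) < 2:
        return BAResult(0.0, 0.0, 0, True)

    obs_kf, obs_lm, obs_px, active = _collect_problem(keyframes, landmarks)
    if len(obs_px) == 0:
        return BAResult(0.0, 0.0, 0, True)

    poses = [kf.pose.copy() for kf in keyframes]
    points = np.array([landmarks[i].position for i in active])

    n_kf = len(keyframes)
    n_lm = len(active)
    # parameter layout: 6 per non-anchor keyframe, then 3 per landmark
    n_pose_params = 6 * (n_kf - 1)
    n_params = n_pose_params + 3 * n_lm

    res, _ = reprojection_residuals(poses, points, obs_kf, obs_lm, obs_px, rig)
    cost = _robust_cost(res, huber)
    trace = [cost]
    damping = params.initial_damping
    converged = False
    it = 0

    for it in range(1, params.max_iterations + 1):
        res, pcams = reprojection_residuals(poses, points, obs_kf, obs_lm, obs_px, rig)
        norms = np.linalg.norm(res, axis=1)
        w = huber.weight(norms)

        # build the weighted sparse Jacobian of the residuals
        rows, cols, vals = [], [], []
        n_obs = len(res)
        sw = np.sqrt(w)
        Rmats = [p.rotation_matrix() for p in poses]
        b = (res * sw[:, None]).reshape(-1)

        has_right = ~np.isnan(obs_px[:, 2])
        for k in range(n_obs):
            ki = obs_kf[k]
            li = obs_lm[k]
            X, Y, Z = pcams[k]
            Z = max(Z, 1e-6)
            Jproj = np.array(
                [[rig.fx / Z, 0.0, -rig.fx * X / (Z * Z)],
                 [0.0, rig.fy / Z, -rig.fy * Y / (Z * Z)],
                 [rig.fx / Z, 0.0, -rig.fx * (X - rig.baseline_mm) / (Z * Z)]]
            )
            n_rows = 3 if has_right[k] else 2
            # residual = obs - proj  =>  d res/d x = -Jproj * d pc/d x
            # landmark block: d pc/d P = R^T
            Jlm = -sw[k] * (Jproj @ Rmats[ki].T)
            c0 = n_pose_params + 3 * li
            for rr in range(n_rows):
                for cc in range(3):
                    rows.append(3 * k + rr)
                    cols.append(c0 + cc)
                    vals.append(Jlm[rr, cc])
            if ki > 0:
                pc = pcams[k]
                # pose blocks: d pc/d r = -R^T ; d pc/d dtheta = [pc]_x
                # (local rotation increment composed on the camera side)
                Jr = -sw[k] * (Jproj @ (-Rmats[ki].T))
                skew = np.array(
                    [[0, -pc[2], pc[1]], [pc[2], 0, -pc[0]], [-pc[1], pc[0], 0]]
                )
                Jth = -sw[k] * (Jproj @ skew)
                c0 = 6 * (ki - 1)
                for rr in range(n_rows):
                    for cc in range(3):
                        rows.append(3 * k + rr)
                        cols.append(c0 + cc)
                        vals.append(Jr[rr, cc])
                        rows.append(3 * k + rr)
                        cols.append(c0 + 3 + cc)
                        vals.append(Jth[rr, cc])

        J = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n_obs, n_params))
        JtJ = (J.T @ J).tocsc()
        Jtb = J.T @ b

        accepted = False
        while damping <= params.max_damping:
            A = JtJ + damping * sp.eye(n_params, format="csc")
            try:
                step = -spsolve(A, Jtb)  # Gauss-Newton: delta = -(J'J)^-1 J'r
            except Exception:
                damping *= 10.0
                continue
            new_poses = [poses[0].copy()]
            for ki in range(1, n_kf):
                dp = step[6 * (ki - 1) : 6 * (ki - 1) + 3]
                dth = step[6 * (ki - 1) + 3 : 6 * (ki - 1) + 6]
                q = quat_normalize(
                    quat_multiply(poses[ki].orientation, quat_from_rotvec(dth))
                )
                new_poses.append(Pose(poses[ki].position + dp, q))
            new_points = points + step[n_pose_params:].reshape(-1, 3)
            new_res, _ = reprojection_residuals(
                new_poses, new_points, obs_kf, obs_lm, obs_px, rig
            )
            new_cost = _robust_cost(new_res, huber)
            if new_cost < cost:
                poses, points = new_poses, new_points
                decrease = (cost - new_cost) / max(cost, 1e-30)
                cost = new_cost
                trace.append(cost)
                damping = max(damping / 10.0, 1e-10)
                accepted = True
                if decrease < params.ftol:
                    converged = True
                break
            damping *= 10.0
        if not accepted:
            converged = cost <= trace[0]
            break
        if converged:
            break

    # write back: anchor untouched (bit-exact), others updated
    for ki in range(1, n_kf):
        keyframes[ki].pose = poses[ki]
    for k, lm_id in enumerate(active):
        landmarks[lm_id].position = points[k]

    return BAResult(trace[0], cost, it, converged, trace)


# ---------------------------------------------------------------------------
# map export
# ---------------------------------------------------------------------------


def write_tum_trajectory(path: str | Path, poses: list[Pose], timestamps=None) -> None:
    """Trajectory as TUM lines: ``timestamp tx ty tz qx qy qz qw``."""
    if timestamps is None:
        timestamps = np.arange(len(poses), dtype=float)
    with open(path, "w") as fh:
        for t, p in zip(timestamps, poses):
            w, x, y, z = p.orientation
            tx, ty, tz = p.position
            fh.write(f"{t:.6f} {tx:.6f} {ty:.6f} {tz:.6f} {x:.6f} {y:.6f} {z:.6f} {w:.6f}\n")


def read_tum_trajectory(path: str | Path) -> tuple[np.ndarray, list[Pose]]:
    ts, poses = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = [float(v) for v in line.split()]
            ts.append(vals[0])
            poses.append(Pose(np.array(vals[1:4]), np.array([vals[7], vals[4], vals[5], vals[6]])))
    return np.asarray(ts), poses


def write_ply_points(path: str | Path, points: np.ndarray) -> None:
    """ASCII PLY point cloud."""
    points = np.atleast_2d(points)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\nend_header\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
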