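"""The offline pipeline driver: track, map, densify, fuse, mesh.

Per frame: ORB stereo matching and specular filtering; constant-velocity
pose prediction; guided matching of the local landmark map inside
re-projected search windows; 3-point RANSAC rigid alignment of the
matched world/camera point pairs (which directly yields the camera-to-
world pose); keyframe insertion by the overlap criterion.  Per keyframe:
windowed Huber-robust bundle adjustment, ZNCC dense stereo, Huber-L1
smoothing, back-projection, world-space fusion on a voxel grid, and mesh
re-triangulation.  Everything is seeded and deterministic for a fixed
configuration.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import dense_stereo, features, mapping, surface, tracking
from .features import FeatureParams, StereoMatchSet, detect_and_match, filter_specular
from .geometry import CameraRig, Pose, load_calibration, matrix_to_quat
from .mapping import (
    BAParams,
    HuberCost,
    Keyframe,
    SlamMap,
    bundle_adjust,
    should_insert_keyframe,
    write_ply_points,
    write_tum_trajectory,
)
from .tracking import (
    CorrespondenceSet,
    MotionState,
    RansacParams,
    TrackingLost,
    advance_motion_state,
    estimate_rigid_ransac,
    guided_search_regions,
    predict_pose,
)

logger = logging.getLogger("endogeo")

__all__ = ["PipelineConfig", "RunReport", "StereoSlamPipeline", "run_pipeline", "load_frames_dir"]


@dataclass
class PipelineConfig:
    calib_path: str | None = None
    frames_dir: str | None = None
    out_dir: str | None = None
    feature: FeatureParams = field(default_factory=FeatureParams)
    ransac: RansacParams = field(default_factory=lambda: RansacParams(inlier_threshold_mm=1.5))
    ba: BAParams = field(default_factory=lambda: BAParams(max_iterations=12))
    huber_delta_px: float = 2.0
    ba_window: int = 5
    global_ba: bool = False
    keyframe_overlap: float = mapping.KEYFRAME_OVERLAP_THRESHOLD
    keyframe_min_count: int = mapping.KEYFRAME_MIN_KEYPOINTS
    d_range: tuple[int, int] = (1, 64)
    patch_radius: int = 3
    smoothing: dense_stereo.SmoothingParams = field(default_factory=dense_stereo.SmoothingParams)
    smooth: bool = True
    voxel_size_mm: float = 1.0
    points_stride: int = 2
    guided_radius_px: float = 15.0
    match_hamming_max: int = 80
    #: landmarks from this many recent keyframes form the active local map
    local_map_keyframes: int = 3
    estimate_acceleration: bool = False
    incremental_mesh: bool = False
    save_disparity: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.keyframe_overlap <= 1):
            raise ValueError("keyframe_overlap must lie in (0, 1]")
        if self.d_range[0] < 1 or self.d_range[1] <= self.d_range[0]:
            raise ValueError("invalid disparity range")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be > 0")

    def save(self, path) -> None:
        """Write the full configuration as YAML (lossless round trip)."""
        import yaml

        data = asdict(self)
        data["d_range"] = list(self.d_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["feature"] = FeatureParams(**data.get("feature", {}))
        data["ransac"] = RansacParams(**data.get("ransac", {}))
        data["ba"] = BAParams(**data.get("ba", {}))
        data["smoothing"] = dense_stereo.SmoothingParams(**data.get("smoothing", {}))
        data["d_range"] = tuple(data.get("d_range", (1, 64)))
        return cls(**data)


@dataclass
class RunReport:
    n_frames: int = 0
    n_tracked: int = 0
    n_keyframes: int = 0
    n_landmarks: int = 0
    tracking_lost_frames: list[int] = field(default_factory=list)
    mean_reprojection_error_px: float = float("nan")
    mean_ransac_inliers: float = float("nan")
    stage_seconds: dict = field(default_factory=dict)

    @property
    def tracked_fraction(self) -> float:
        return self.n_tracked / self.n_frames if self.n_frames else 0.0

    def to_json(self) -> dict:
        d = asdict(self)
        d["tracked_fraction"] = self.tracked_fraction
        return d


_pack = features.pack_descriptors
_hamming_matrix = features.hamming_matrix


class StereoSlamPipeline:
    """Stateful frame-by-frame pipeline; feed frames, then finalise."""

    def __init__(self, rig: CameraRig, config: PipelineConfig | None = None):
        self.rig = rig
        self.config = config or PipelineConfig()
        self.config.validate()
        self.map = SlamMap()
        self.motion: MotionState | None = None
        self.trajectory: list[Pose] = []
        self.trajectory_frames: list[int] = []
        self.fused_cloud = np.zeros((0, 3))
        self.mesh: surface.SurfaceMesh | None = None
        self.report = RunReport()
        self.disparity_maps: dict[int, dense_stereo.DisparityMap] = {}
        self._rng = np.random.default_rng(self.config.seed)
        self._recall_baseline: float | None = None
        self._frames_since_kf = 0
        self._frame_index = 0
        self._reproj_errors: list[float] = []
        self._inlier_counts: list[int] = []
        self._timers: dict[str, float] = {}

    # -- helpers ----------------------------------------------------------

    def _time(self, key: str, t0: float) -> None:
        self._timers[key] = self._timers.get(key, 0.0) + (time.perf_counter() - t0)

    def _active_landmarks(self) -> list[int]:
        """Local map: landmarks observed by the most recent keyframes."""
        kfs = self.map.keyframes[-self.config.local_map_keyframes :]
        ids: set[int] = set()
        for kf in kfs:
            ids |= kf.landmark_ids
        return sorted(ids)

    def _match_to_map(
        self, matches: StereoMatchSet, predicted: Pose, radius_px: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Guided matching: (landmark ids, feature indices) pairs."""
        cfg = self.config
        radius = cfg.guided_radius_px if radius_px is None else radius_px
        active = self._active_landmarks()
        if not active:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        positions = self.map.landmark_positions(active)
        windows = guided_search_regions(predicted, positions, self.rig, radius)
        if not windows:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        widx = np.fromiter(windows.keys(), dtype=int)
        centers = np.array(
            [[0.5 * (w[0] + w[2]), 0.5 * (w[1] + w[3])] for w in windows.values()]
        )
        fpix = matches.left_pixels
        fdesc_packed = _pack(matches.descriptors)
        ldesc_packed = _pack(
            np.array([self.map.landmarks[active[i]].descriptor for i in widx])
        )
        best_feat = np.full(len(widx), -1, dtype=int)
        best_ham = np.full(len(widx), 10**9, dtype=int)
        chunk = 512
        for s in range(0, len(widx), chunk):
            e = min(s + chunk, len(widx))
            dx = np.abs(centers[s:e, 0:1] - fpix[None, :, 0][0][None, :])
            dy = np.abs(centers[s:e, 1:2] - fpix[None, :, 1][0][None, :])
            inwin = (dx <= radius) & (dy <= radius)
            if not inwin.any():
                continue
            ham = _hamming_matrix(ldesc_packed[s:e], fdesc_packed)
            ham = np.where(inwin, ham, 10**9)
            bi = np.argmin(ham, axis=1)
            bh = ham[np.arange(e - s), bi]
            best_feat[s:e] = np.where(bh <= cfg.match_hamming_max, bi, -1)
            best_ham[s:e] = bh
        # resolve conflicts: each feature keeps its best landmark
        ok = best_feat >= 0
        lm_ids = np.array([active[i] for i in widx], dtype=int)
        order = np.argsort(best_ham[ok])
        sel_lm, sel_ft = [], []
        used = set()
        lm_ok = lm_ids[ok][order]
        ft_ok = best_feat[ok][order]
        for lm, ft in zip(lm_ok, ft_ok):
            if ft in used:
                continue
            used.add(ft)
            sel_lm.append(lm)
            sel_ft.append(ft)
        return np.asarray(sel_lm, dtype=int), np.asarray(sel_ft, dtype=int)

    # -- frame processing --------------------------------------------------

    def process_frame(self, left: np.ndarray, right: np.ndarray) -> bool:
        """Ingest one stereo pair; returns True if the frame was tracked."""
        cfg = self.config
        idx = self._frame_index
        self._frame_index += 1
        self.report.n_frames += 1

        t0 = time.perf_counter()
        matches = detect_and_match(left, right, cfg.feature, self.rig)
        matches = filter_specular(matches, cfg.feature.specular_threshold)
        self._time("features", t0)
        if matches.untrackable or len(matches) < cfg.feature.min_matches:
            logger.warning("frame %d untrackable (%d matches)", idx, len(matches))
            self.report.tracking_lost_frames.append(idx)
            return False

        if not self.map.keyframes:
            pose = Pose()  # world frame := first camera frame
            self.motion = MotionState(pose=pose)
            self._insert_keyframe(idx, pose, matches, np.zeros(0, int), np.zeros(0, int))
            self.trajectory.append(pose.copy())
            self.trajectory_frames.append(idx)
            self.report.n_tracked += 1
            return True

        t0 = time.perf_counter()
        predicted = predict_pose(self.motion)
        # bootstrap: with no velocity estimate yet (right after start or a
        # tracking loss) the prediction may be far off; widen the windows
        radius = None
        if not np.any(self.motion.linear_velocity) and not np.any(self.motion.angular_velocity):
            radius = 3.0 * cfg.guided_radius_px
        lm_ids, feat_idx = self._match_to_map(matches, predicted, radius)
        self._time("matching", t0)
        if len(lm_ids) < 3:
            self.report.tracking_lost_frames.append(idx)
            logger.warning("frame %d: %d map matches, tracking lost", idx, len(lm_ids))
            return False

        pts_world = self.map.landmark_positions(list(lm_ids))
        pts_cam = matches.subset(feat_idx).points_camera(self.rig)
        t0 = time.perf_counter()
        try:
            tf, inliers = estimate_rigid_ransac(
                CorrespondenceSet(pts_world, pts_cam), cfg.ransac, self._rng
            )
        except TrackingLost:
            self.report.tracking_lost_frames.append(idx)
            logger.warning("frame %d: RANSAC failed, tracking lost", idx)
            return False
        self._time("ransac", t0)

        pose = Pose(position=tf.translation, orientation=matrix_to_quat(tf.rotation))
        # motion-only refinement: swap the depth-noisy 3D-3D estimate for the
        # pixel-accurate reprojection optimum over the same inliers
        pose = tracking.refine_pose_reprojection(
            pose,
            pts_world[inliers],
            matches.left_pixels[feat_idx[inliers]],
            self.rig,
            cfg.huber_delta_px,
        )
        self.motion = advance_motion_state(self.motion, pose, cfg.estimate_acceleration)
        self.trajectory.append(pose.copy())
        self.trajectory_frames.append(idx)
        self.report.n_tracked += 1
        self._inlier_counts.append(int(inliers.sum()))

        # keyframe decision uses the descriptor-matched set (RANSAC inlier
        # classification is noisy at the mm threshold and would jitter it)
        tracked_ids = set(int(i) for i in lm_ids)
        self._frames_since_kf += 1
        if self._frames_since_kf == 1:
            # first frame after a keyframe: the view has barely changed, so
            # the raw shared fraction measures the matcher's recall
            kf_ids = self.map.keyframes[-1].landmark_ids
            denom = min(len(matches), len(kf_ids))
            raw = len(tracked_ids & kf_ids) / max(denom, 1)
            raw = min(max(raw, 0.3), 1.0)
            self._recall_baseline = (
                raw if self._recall_baseline is None else 0.7 * self._recall_baseline + 0.3 * raw
            )
        if should_insert_keyframe(
            tracked_ids,
            self.map.keyframes[-1],
            len(matches),
            self._recall_baseline or 1.0,
            cfg.keyframe_overlap,
            cfg.keyframe_min_count,
        ):
            self._insert_keyframe(idx, pose, matches, lm_ids[inliers], feat_idx[inliers])
        return True

    def _insert_keyframe(
        self,
        frame_idx: int,
        pose: Pose,
        matches: StereoMatchSet,
        matched_lm: np.ndarray,
        matched_ft: np.ndarray,
    ) -> None:
        cfg = self.config
        kf = Keyframe(id=len(self.map.keyframes), pose=pose.copy(), frame_index=frame_idx)

        def stereo_pixel(ft: int) -> np.ndarray:
            return np.array(
                [
                    matches.left_pixels[ft, 0],
                    matches.left_pixels[ft, 1],
                    matches.right_pixels[ft, 0],
                ]
            )

        # observations of existing landmarks
        for lm_id, ft in zip(matched_lm, matched_ft):
            kf.observations.append((int(lm_id), stereo_pixel(ft), matches.descriptors[ft]))
            self.map.landmarks[int(lm_id)].observation_count += 1

        # unmatched features become new landmarks
        new_mask = np.ones(len(matches), dtype=bool)
        new_mask[matched_ft] = False
        new_idx = np.flatnonzero(new_mask)
        if len(new_idx):
            pts_cam = matches.subset(new_idx).points_camera(self.rig)
            pts_world = pose.to_world(pts_cam)
            for k, fi in enumerate(new_idx):
                lm_id = self.map.add_landmark(pts_world[k], matches.descriptors[fi])
                kf.observations.append((lm_id, stereo_pixel(fi), matches.descriptors[fi]))
        self.map.keyframes.append(kf)
        self._frames_since_kf = 0
        logger.info(
            "keyframe %d at frame %d: %d obs (%d new landmarks)",
            kf.id, frame_idx, len(kf.observations), len(new_idx),
        )

        # windowed (or global) bundle adjustment
        if len(self.map.keyframes) >= 2:
            window = (
                self.map.keyframes
                if cfg.global_ba
                else self.map.keyframes[-cfg.ba_window :]
            )
            t0 = time.perf_counter()
            bundle_adjust(
                window, self.map.landmarks, self.rig, HuberCost(cfg.huber_delta_px), cfg.ba
            )
            self._time("ba", t0)
            self.trajectory[-1] = kf.pose.copy()
            if self.motion is not None:
                self.motion.pose = kf.pose.copy()
            self._reproj_errors.append(self._window_rms_reproj(window))

        # dense reconstruction at the keyframe
        t0 = time.perf_counter()
        self._densify(kf, matches.disparities)
        self._time("dense", t0)

    def _window_rms_reproj(self, window: list[Keyframe]) -> float:
        from .mapping import _collect_problem, reprojection_residuals

        obs_kf, obs_lm, obs_px, active = _collect_problem(window, self.map.landmarks)
        if not len(obs_px):
            return float("nan")
        pts = np.array([self.map.landmarks[i].position for i in active])
        res, _ = reprojection_residuals(
            [k.pose for k in window], pts, obs_kf, obs_lm, obs_px, self.rig
        )
        return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))

    _pending_images: tuple[np.ndarray, np.ndarray] | None = None

    def _densify(self, kf: Keyframe, feature_disparities: np.ndarray | None = None) -> None:
        cfg = self.config
        if self._pending_images is None:
            return
        left, right = self._pending_images
        d_range = cfg.d_range
        if feature_disparities is not None and len(feature_disparities) >= 10:
            # sparse SLAM features bracket the scene's true disparity range;
            # restricting the dense search to it suppresses gross mismatches
            lo = max(cfg.d_range[0], int(np.floor(feature_disparities.min())) - 5)
            hi = min(cfg.d_range[1], int(np.ceil(feature_disparities.max())) + 5)
            if hi - lo >= 8:
                d_range = (lo, hi)
        vol = dense_stereo.build_cost_volume(left, right, d_range, cfg.patch_radius)
        wta = dense_stereo.winner_takes_all(vol)
        wta = dense_stereo.filter_disparity(vol, wta)
        disp = (
            dense_stereo.smooth_disparity(vol, wta, cfg.smoothing) if cfg.smooth else wta
        )
        self.disparity_maps[kf.id] = disp
        pts_cam = dense_stereo.disparity_to_points(disp, self.rig, cfg.points_stride)
        pts_cam = surface.remove_statistical_outliers(pts_cam)
        t_f2w = surface.FrameToWorld(kf.pose.rotation_matrix(), kf.pose.position)
        pts_world = surface.to_world(pts_cam, t_f2w)
        self.fused_cloud = surface.fuse(self.fused_cloud, pts_world, cfg.voxel_size_mm)
        if cfg.incremental_mesh:
            self._remesh()

    def _remesh(self) -> None:
        if len(self.fused_cloud) < 10:
            return
        cam = self.map.keyframes[-1].pose.position if self.map.keyframes else None
        t0 = time.perf_counter()
        self.mesh = surface.triangulate_surface(self.fused_cloud, camera_position=cam)
        self._time("mesh", t0)

    # public wrapper so callers can hand images to the keyframe densifier
    def feed(self, left: np.ndarray, right: np.ndarray) -> bool:
        self._pending_images = (features.to_grayscale(left), features.to_grayscale(right))
        ok = self.process_frame(left, right)
        self._pending_images = None
        return ok

    def finalise(self) -> RunReport:
        if self.mesh is None:
            self._remesh()
        rep = self.report
        rep.n_keyframes = len(self.map.keyframes)
        rep.n_landmarks = len(self.map.landmarks)
        if self._reproj_errors:
            rep.mean_reprojection_error_px = float(np.mean(self._reproj_errors))
        if self._inlier_counts:
            rep.mean_ransac_inliers = float(np.mean(self._inlier_counts))
        rep.stage_seconds = {k: round(v, 2) for k, v in self._timers.items()}
        return rep


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------


def load_frames_dir(frames_dir: str | Path):
    """Yield (left, right) uint8 arrays from left/%06d.png, right/%06d.png."""
    import imageio.v3 as iio

    frames_dir = Path(frames_dir)
    lefts = sorted((frames_dir / "left").glob("*.png")) + sorted(
        (frames_dir / "left").glob("*.tif*")
    )
    if not lefts:
        raise FileNotFoundError(f"no frames found under {frames_dir}/left")
    for lp in lefts:
        rp = frames_dir / "right" / lp.name
        if not rp.exists():
            raise FileNotFoundError(f"missing right frame for {lp.name}")
        yield iio.imread(lp), iio.imread(rp)


def run_pipeline(
    config: PipelineConfig,
    frames=None,
    rig: CameraRig | None = None,
) -> tuple[StereoSlamPipeline, RunReport]:
    """Execute the full pipeline and write the outputs.

    ``frames`` may be an iterable of (left, right) arrays (e.g. from the
    synthetic generator); otherwise they are read from
    ``config.frames_dir`` and the rig from ``config.calib_path``.
    """
    config.validate()
    if rig is None:
        if config.calib_path is None:
            raise ValueError("need a calibration file or an explicit rig")
        rig = load_calibration(config.calib_path)
    if frames is None:
        if config.frames_dir is None:
            raise ValueError("need frames_dir or an explicit frame iterable")
        frames = load_frames_dir(config.frames_dir)

    pipe = StereoSlamPipeline(rig, config)
    for left, right in frames:
        pipe.feed(left, right)
    report = pipe.finalise()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tum_trajectory(
            out / "trajectory.txt", pipe.trajectory, np.asarray(pipe.trajectory_frames, float)
        )
        if len(pipe.fused_cloud):
            write_ply_points(out / "fused_cloud.ply", pipe.fused_cloud)
        if pipe.map.landmarks:
            write_ply_points(out / "landmarks.ply", pipe.map.landmark_positions())
        if pipe.map.keyframes:
            write_tum_trajectory(
                out / "keyframes.txt",
                [kf.pose for kf in pipe.map.keyframes],
                np.array([kf.frame_index for kf in pipe.map.keyframes], dtype=float),
            )
        if pipe.mesh is not None:
            surface.save_mesh(pipe.mesh, out / "mesh.ply")
        if config.save_disparity:
            for kf_id, disp in pipe.disparity_maps.items():
                dense_stereo.save_disparity_png16(out / f"disparity_{kf_id:04d}.png", disp)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json(), fh, indent=1)
    return pipe, report
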