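"""Keypoint detection, left-right stereo matching and specular filtering.

ORB (oriented FAST + rotated BRIEF) binary features are detected in both
rectified images and matched by mutual-best Hamming distance.  Matches are
then filtered by the rectification constraint (same image row within a
tolerance), a positive-disparity requirement, and optionally by intensity to
drop saturated specular highlights — wet-tissue reflections move with the
camera and would otherwise corrupt both stereo and temporal matching.

Detection is delegated to :class:`skimage.feature.ORB`; the pipeline's
contribution is how the features are matched, filtered and used, not the
descriptor itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB

from .geometry import CameraRig, triangulate_many

__all__ = [
    "Feature",
    "StereoMatchSet",
    "FeatureParams",
    "to_grayscale",
    "detect_features",
    "detect_and_match",
    "filter_specular",
    "refine_disparity_subpixel",
    "pack_descriptors",
    "hamming_matrix",
    "mutual_hamming_matches",
]

#: Rec. 601 luminance weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default saturation threshold (on a 0-255 scale) above which a keypoint is
#: treated as lying on a specular highlight.
SPECULAR_INTENSITY_THRESHOLD = 240.0


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Return a float image in [0, 1]; RGB collapses via Rec. 601 luminance."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    img = img.astype(float)
    if img.max() > 1.5:  # 8-bit input
        img = img / 255.0
    return img


@dataclass
class FeatureParams:
    n_features: int = 1000
    scale_factor: float = 1.2
    n_levels: int = 4
    fast_threshold: float = 0.05
    #: maximum Hamming distance (bits) for an acceptable stereo match
    max_hamming: int = 80
    #: rectified rows must agree within this many pixels
    row_tolerance_px: float = 2.0
    #: frames with fewer surviving matches than this are flagged untrackable
    min_matches: int = 20
    specular_threshold: float = SPECULAR_INTENSITY_THRESHOLD
    #: half-width of the 1D ZNCC search used for sub-pixel disparity
    subpixel_patch_radius: int = 4
    subpixel: bool = True


@dataclass
class Feature:
    """A single keypoint: pixel position, binary descriptor, local intensity."""

    pixel: np.ndarray  # (x, y) in pixels
    descriptor: np.ndarray  # bool array, fixed length per run
    intensity: float  # 0-255 scale at the keypoint
    scale: float = 1.0


@dataclass
class StereoMatchSet:
    """Matched keypoints of one rectified frame pair.

    Column arrays are aligned: row ``i`` of each describes match ``i``.
    """

    left_pixels: np.ndarray  # (n, 2) x,y
    right_pixels: np.ndarray  # (n, 2)
    descriptors: np.ndarray  # (n, k) bool, from the left image
    intensities: np.ndarray  # (n,) 0-255 at the left keypoint
    untrackable: bool = False

    def __len__(self) -> int:
        return len(self.left_pixels)

    @property
    def disparities(self) -> np.ndarray:
        return self.left_pixels[:, 0] - self.right_pixels[:, 0]

    def points_camera(self, rig: CameraRig) -> np.ndarray:
        """Stereo-triangulated camera-frame 3D points (mm) for all matches."""
        return triangulate_many(
            self.left_pixels[:, 0], self.right_pixels[:, 0], self.left_pixels[:, 1], rig
        )

    def subset(self, idx: np.ndarray) -> "StereoMatchSet":
        return StereoMatchSet(
            left_pixels=self.left_pixels[idx],
            right_pixels=self.right_pixels[idx],
            descriptors=self.descriptors[idx],
            intensities=self.intensities[idx],
            untrackable=self.untrackable,
        )

    @staticmethod
    def empty(descriptor_len: int = 256) -> "StereoMatchSet":
        return StereoMatchSet(
            left_pixels=np.zeros((0, 2)),
            right_pixels=np.zeros((0, 2)),
            descriptors=np.zeros((0, descriptor_len), dtype=bool),
            intensities=np.zeros(0),
            untrackable=True,
        )


def detect_features(image: np.ndarray, params: FeatureParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run ORB on one image.

    Returns ``(pixels (n,2) xy, descriptors (n,256) bool, scales (n,))``.
    """
    gray = to_grayscale(image)
    orb = ORB(
        n_keypoints=params.n_features,
        downscale=params.scale_factor,
        n_scales=params.n_levels,
        fast_threshold=params.fast_threshold,
    )
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return np.zeros((0, 2)), np.zeros((0, 256), dtype=bool), np.zeros(0)
    # skimage keypoints are (row, col); convert to (x, y)
    pixels = orb.keypoints[:, ::-1].astype(float)
    return pixels, orb.descriptors, orb.scales


def pack_descriptors(desc: np.ndarray) -> np.ndarray:
    """Pack boolean descriptors into uint8 rows for fast Hamming distances."""
    return np.packbits(desc.astype(np.uint8), axis=1)


def hamming_matrix(a_packed: np.ndarray, b_packed: np.ndarray) -> np.ndarray:
    """(n_a, n_b) pairwise Hamming distances between packed descriptors."""
    x = np.bitwise_xor(a_packed[:, None, :], b_packed[None, :, :])
    return np.bitwise_count(x).sum(axis=2, dtype=np.int32)


def mutual_hamming_matches(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Mutual-best (cross-checked) Hamming matches between descriptor sets.

    Returns an (m, 2) array of (index_a, index_b) pairs where each is the
    other's nearest neighbour.
    """
    if len(desc_a) == 0 or len(desc_b) == 0:
        return np.zeros((0, 2), dtype=int)
    ham = hamming_matrix(pack_descriptors(desc_a), pack_descriptors(desc_b))
    best_b = np.argmin(ham, axis=1)
    best_a = np.argmin(ham, axis=0)
    ia = np.arange(len(desc_a))
    mutual = best_a[best_b] == ia
    return np.column_stack([ia[mutual], best_b[mutual]])


def _intensity_at(gray: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Image intensity (0-255 scale) at integer-rounded pixel positions."""
    h, w = gray.shape
    xi = np.clip(np.round(pixels[:, 0]).astype(int), 0, w - 1)
    yi = np.clip(np.round(pixels[:, 1]).astype(int), 0, h - 1)
    return gray[yi, xi] * 255.0


def detect_and_match(
    left_image: np.ndarray,
    right_image: np.ndarray,
    params: FeatureParams | None = None,
    rig: CameraRig | None = None,
) -> StereoMatchSet:
    """Detect ORB keypoints in a rectified pair and match them left-right.

    Matches are mutual-best under Hamming distance, then filtered by

    1. Hamming distance threshold,
    2. the epipolar row tolerance (rectified images: same row),
    3. positive disparity above the rig's minimum cutoff.

    Sub-pixel disparity is recovered by a 1D ZNCC parabola fit along the
    epipolar row (see :func:`refine_disparity_subpixel`) when enabled.
    Frames with fewer than ``params.min_matches`` survivors are flagged
    ``untrackable`` (blur, occlusion, texture loss).
    """
    params = params or FeatureParams()
    if left_image.shape[:2] != right_image.shape[:2]:
        raise ValueError("stereo pair must share an image size")
    gray_l = to_grayscale(left_image)
    gray_r = to_grayscale(right_image)

    pix_l, desc_l, _ = detect_features(gray_l, params)
    pix_r, desc_r, _ = detect_features(gray_r, params)
    if len(pix_l) == 0 or len(pix_r) == 0:
        return StereoMatchSet.empty()

    matches = mutual_hamming_matches(desc_l, desc_r)
    if len(matches) == 0:
        return StereoMatchSet.empty(desc_l.shape[1])

    ml, mr = matches[:, 0], matches[:, 1]
    hamming_bits = np.count_nonzero(desc_l[ml] != desc_r[mr], axis=1)
    row_ok = np.abs(pix_l[ml, 1] - pix_r[mr, 1]) <= params.row_tolerance_px
    disparity = pix_l[ml, 0] - pix_r[mr, 0]
    min_disp = rig.min_disparity_px if rig is not None else 0.5
    keep = (hamming_bits <= params.max_hamming) & row_ok & (disparity >= min_disp)

    ml, mr = ml[keep], mr[keep]
    out = StereoMatchSet(
        left_pixels=pix_l[ml].copy(),
        right_pixels=pix_r[mr].copy(),
        descriptors=desc_l[ml].copy(),
        intensities=_intensity_at(gray_l, pix_l[ml]),
        untrackable=keep.sum() < params.min_matches,
    )
    if params.subpixel and len(out) > 0:
        refine_disparity_subpixel(out, gray_l, gray_r, params.subpixel_patch_radius)
    return out


def filter_specular(
    matches: StereoMatchSet, intensity_threshold: float = SPECULAR_INTENSITY_THRESHOLD
) -> StereoMatchSet:
    """Drop matches whose left-image intensity exceeds the threshold.

    Saturated pixels sit on specular highlights, which are view-dependent
    and violate the static-scene assumption.  Idempotent; preserves order.
    """
    if not 0 < intensity_threshold <= 255:
        raise ValueError("intensity threshold must lie in (0, 255]")
    keep = matches.intensities <= intensity_threshold
    out = matches.subset(keep)
    out.untrackable = matches.untrackable
    return out


def refine_disparity_subpixel(
    matches: StereoMatchSet,
    gray_left: np.ndarray,
    gray_right: np.ndarray,
    patch_radius: int = 4,
) -> None:
    """Refine each match's right-image x to sub-pixel precision, in place.

    For every match a small horizontal patch around the left keypoint is
    ZNCC-correlated against the right image at integer offsets -1, 0, +1
    around the matched position; a parabola through the three scores gives
    the sub-pixel peak.  Depth resolution scales with disparity resolution
    (dZ/dd = Z^2 / (f B)), so this step directly sharpens triangulation.
    """
    h, w = gray_left.shape
    r = patch_radius
    for i in range(len(matches)):
        xl, yl = matches.left_pixels[i]
        xr = matches.right_pixels[i, 0]
        yi = int(round(yl))
        xli = int(round(xl))
        xri = int(round(xr))
        if not (r <= yi < h - r and r <= xli < w - r and r + 1 <= xri < w - r - 1):
            continue
        patch_l = gray_left[yi - r : yi + r + 1, xli - r : xli + r + 1]
        pl = patch_l - patch_l.mean()
        nl = np.sqrt((pl * pl).sum())
        if nl < 1e-12:
            continue
        scores = np.empty(3)
        for k, off in enumerate((-1, 0, 1)):
            patch_r = gray_right[yi - r : yi + r + 1, xri + off - r : xri + off + r + 1]
            pr = patch_r - patch_r.mean()
            nr = np.sqrt((pr * pr).sum())
            scores[k] = (pl * pr).sum() / (nl * nr) if nr >= 1e-12 else -1.0
        denom = scores[0] - 2 * scores[1] + scores[2]
        if abs(denom) < 1e-12 or not (scores[1] >= scores[0] and scores[1] >= scores[2]):
            continue
        delta = 0.5 * (scores[0] - scores[2]) / denom
        if abs(delta) <= 1.0:
            # keep the left x fixed; shift the right x (and therefore disparity)
            matches.right_pixels[i, 0] = xri + delta + (xl - xli)
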