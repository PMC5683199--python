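"""Dense disparity estimation: ZNCC cost volume, WTA, Huber-L1 smoothing.

For each keyframe a dense disparity map is computed from the rectified
pair.  The matching score for pixel ``p`` at disparity ``d`` is the
zero-mean normalised cross-correlation (ZNCC) between the patch ``N_p``
around ``p`` in the left image and the patch around ``p - d`` in the right
image.  ZNCC is invariant to affine intensity changes of either patch,
which is what makes it usable on wet, specular tissue where lighting moves
with the endoscope.

Sign convention (asserted in tests): ZNCC is a *similarity* in [-1, 1];
the cost volume stores ``cost = -ZNCC`` so that lower is better and the
winner-takes-all step is an argmin.  Invalid entries (window out of the
image, zero-variance patch) are masked, never NaN-propagated.

The WTA map is then smoothed by minimising the Huber-L1 variational energy

    E(u) = sum_p  H_eps(grad u(p)) + lam * C(p, u(p))

with a quadratic-relaxation (theta-coupling) scheme: alternate a Huber-
regularised proximal smoothing of ``u`` with a point-wise search over the
cost volume.  Iterates are kept only while the true energy decreases, so
the returned map never has higher energy than its WTA initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter

from .geometry import CameraRig

__all__ = [
    "CostVolume",
    "DisparityMap",
    "SmoothingParams",
    "zncc_cost",
    "build_cost_volume",
    "winner_takes_all",
    "filter_disparity",
    "huber_l1_energy",
    "smooth_disparity",
    "disparity_to_points",
    "save_disparity_png16",
    "load_disparity_png16",
]

#: Value stored at masked cost-volume entries (worse than any valid cost).
INVALID_COST = 2.0


@dataclass
class CostVolume:
    """Per-pixel, per-disparity matching cost ``C[y, x, k]`` (lower = better).

    ``disparities[k]`` gives the disparity of slice ``k``; ``valid`` masks
    entries whose patch left the image or had zero variance.
    """

    costs: np.ndarray  # (h, w, n_disp) float, -ZNCC
    disparities: np.ndarray  # (n_disp,)
    valid: np.ndarray  # (h, w, n_disp) bool
    patch_radius: int

    @property
    def d_min(self) -> int:
        return int(self.disparities[0])

    @property
    def d_max(self) -> int:
        return int(self.disparities[-1])


@dataclass
class DisparityMap:
    disparity: np.ndarray  # (h, w) float
    valid: np.ndarray  # (h, w) bool

    def masked(self) -> np.ndarray:
        out = self.disparity.copy()
        out[~self.valid] = np.nan
        return out


@dataclass
class SmoothingParams:
    #: data-term weight lambda; larger pulls the solution toward the WTA costs
    lam: float = 2.0
    #: Huber transition of the gradient penalty (disparity units)
    huber_eps: float = 0.5
    #: quadratic-coupling parameter theta (annealed downward)
    theta: float = 2.0
    n_outer: int = 12
    n_inner: int = 10


def zncc_cost(left_patch: np.ndarray, right_patch: np.ndarray) -> float:
    """ZNCC similarity of two equal-sized patches, in [-1, 1].

    Raises ``ValueError`` on a zero-variance patch — the correlation is
    undefined there and callers must mask the pixel instead.
    """
    a = np.asarray(left_patch, dtype=float).ravel()
    b = np.asarray(right_patch, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("patches must have equal size")
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-variance patch: ZNCC undefined")
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0))


def build_cost_volume(
    left_image: np.ndarray,
    right_image: np.ndarray,
    d_range: tuple[int, int] = (1, 64),
    patch_radius: int = 3,
) -> CostVolume:
    """ZNCC cost volume over integer disparities ``d_min..d_max``.

    Patch sums are evaluated with box filters, so the whole volume costs
    O(width * height * n_disparities) independent of the patch size.  The
    stored cost is ``-ZNCC`` (lower = better).  Borders where the patch
    leaves either image, and zero-variance patches, are masked.
    """
    L = np.asarray(left_image, dtype=np.float64)
    R = np.asarray(right_image, dtype=np.float64)
    if L.ndim == 3:
        from .features import to_grayscale

        L = to_grayscale(L)
        R = to_grayscale(R)
    if L.shape != R.shape:
        raise ValueError("rectified pair must share shape")
    h, w = L.shape
    d_min, d_max = int(d_range[0]), int(d_range[1])
    disparities = np.arange(d_min, d_max + 1)
    n_d = len(disparities)
    r = patch_radius
    size = 2 * r + 1

    def _box(img):
        return uniform_filter(img, size=size, mode="constant")

    # per-pixel patch statistics of the left image
    mu_l = _box(L)
    mu_l2 = _box(L * L)
    var_l = np.maximum(mu_l2 - mu_l * mu_l, 0.0)

    mu_r = _box(R)
    mu_r2 = _box(R * R)
    var_r = np.maximum(mu_r2 - mu_r * mu_r, 0.0)

    costs = np.full((h, w, n_d), INVALID_COST, dtype=np.float64)
    valid = np.zeros((h, w, n_d), dtype=bool)

    # interior where the left patch fits
    ys, ye = r, h - r
    eps = 1e-10
    for k, d in enumerate(disparities):
        xs = r + d  # left x range where the shifted right patch also fits
        xe = w - r
        if xs >= xe or ys >= ye:
            continue
        # full-width shifted right image so box windows never leave the data
        Rs = np.zeros_like(R)
        Rs[:, d:] = R[:, : w - d]
        cross = uniform_filter(L * Rs, size=size, mode="constant")
        mrs = np.zeros_like(mu_r)
        mrs[:, d:] = mu_r[:, : w - d]
        vrs = np.zeros_like(var_r)
        vrs[:, d:] = var_r[:, : w - d]
        cov = cross - mu_l * mrs
        denom = np.sqrt(var_l * vrs)
        ok = denom > eps
        z = np.zeros_like(cov)
        z[ok] = cov[ok] / denom[ok]
        np.clip(z, -1.0, 1.0, out=z)
        block = np.where(ok, -z, INVALID_COST)[ys:ye, xs:xe]
        costs[ys:ye, xs:xe, k] = block
        valid[ys:ye, xs:xe, k] = ok[ys:ye, xs:xe]

    return CostVolume(costs=costs, disparities=disparities, valid=valid, patch_radius=r)


def winner_takes_all(volume: CostVolume, subpixel: bool = True) -> DisparityMap:
    """Per-pixel argmin of the cost volume.

    Ties break toward the smaller disparity (argmin returns the first
    minimum and slices are ordered by increasing d).  With ``subpixel`` a
    parabola through the three costs around the winner refines the
    disparity to a continuous value; refinement is skipped at range ends
    and next to masked entries.  Pixels with no valid entry are invalid.
    """
    c = volume.costs
    k_best = np.argmin(c, axis=2)
    h, w, n_d = c.shape
    iy, ix = np.indices((h, w))
    best_cost = c[iy, ix, k_best]
    valid = volume.valid[iy, ix, k_best] & (best_cost < INVALID_COST)
    disp = volume.disparities[k_best].astype(float)

    if subpixel and n_d >= 3:
        km = np.clip(k_best - 1, 0, n_d - 1)
        kp = np.clip(k_best + 1, 0, n_d - 1)
        cm = c[iy, ix, km]
        cp = c[iy, ix, kp]
        interior = (k_best > 0) & (k_best < n_d - 1)
        ok = (
            interior
            & valid
            & volume.valid[iy, ix, km]
            & volume.valid[iy, ix, kp]
        )
        denom = cm - 2 * best_cost + cp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(np.abs(denom) > 1e-12, 0.5 * (cm - cp) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        disp = np.where(ok, disp + delta, disp)

    disp[~valid] = np.nan
    return DisparityMap(disparity=disp, valid=valid)


def filter_disparity(
    volume: CostVolume,
    disp: DisparityMap,
    min_zncc: float = 0.3,
    lr_max_diff_px: float = 1.5,
) -> DisparityMap:
    """Invalidate unreliable disparities: weak matches and LR failures.

    Two standard checks, both free given the cost volume:

    * confidence — pixels whose best ZNCC similarity falls below
      ``min_zncc`` (texture-poor or saturated regions match anything);
    * left-right consistency — the right image's WTA disparity at
      ``p - d`` is read from the same volume (``C_R(x, d) = C_L(x+d, d)``);
      pixels whose two estimates disagree by more than ``lr_max_diff_px``
      are occluded or mismatched.
    """
    c = volume.costs
    h, w, n_d = c.shape
    iy, ix = np.indices((h, w))
    k_best = np.argmin(c, axis=2)
    best_cost = c[iy, ix, k_best]
    conf_ok = best_cost <= -min_zncc

    # right-image cost volume slices are shifted views of the left's
    right_costs = np.full_like(c, INVALID_COST)
    for k, d in enumerate(volume.disparities):
        right_costs[:, : w - d, k] = c[:, d:, k]
    kr = np.argmin(right_costs, axis=2)
    d_right = volume.disparities[kr].astype(float)
    d_right[right_costs[iy, ix, kr] >= INVALID_COST] = np.nan

    d_left = disp.disparity
    xr = ix - np.round(np.nan_to_num(d_left)).astype(int)
    inb = (xr >= 0) & disp.valid
    xr = np.clip(xr, 0, w - 1)
    lr_ok = inb & (np.abs(d_left - d_right[iy, xr]) <= lr_max_diff_px)

    valid = disp.valid & conf_ok & lr_ok

    # speckle rejection: isolated spikes far from their neighbourhood median
    from scipy.ndimage import median_filter

    med = median_filter(np.where(valid, disp.disparity, np.nan), size=3)
    spike = np.abs(disp.disparity - med) > 2.0
    valid &= ~(spike & np.isfinite(med))

    out = disp.disparity.copy()
    out[~valid] = np.nan
    return DisparityMap(disparity=out, valid=valid)


def _sample_cost(volume: CostVolume, u: np.ndarray) -> np.ndarray:
    """Linearly interpolate C(p, u(p)) along the disparity axis."""
    c = volume.costs
    h, w, n_d = c.shape
    d0 = volume.disparities[0]
    k = np.clip(u - d0, 0.0, n_d - 1.0)
    k0 = np.floor(k).astype(int)
    k1 = np.minimum(k0 + 1, n_d - 1)
    t = k - k0
    iy, ix = np.indices((h, w))
    return (1 - t) * c[iy, ix, k0] + t * c[iy, ix, k1]


def huber_l1_energy(
    volume: CostVolume, disp: np.ndarray, valid: np.ndarray, params: SmoothingParams
) -> float:
    """Total Huber-L1 energy: Huber(grad u) + lam * C(p, u)."""
    u = np.where(valid, disp, 0.0)
    gx = np.diff(u, axis=1, append=u[:, -1:])
    gy = np.diff(u, axis=0, append=u[-1:, :])
    # gradient terms only where both pixels are valid
    vx = valid & np.roll(valid, -1, axis=1)
    vx[:, -1] = False
    vy = valid & np.roll(valid, -1, axis=0)
    vy[-1, :] = False
    g = np.sqrt(gx * gx + gy * gy)
    eps = params.huber_eps
    hub = np.where(g <= eps, 0.5 * g * g / eps, g - 0.5 * eps)
    reg = float(hub[vx | vy].sum())
    data = float(_sample_cost(volume, np.where(valid, disp, volume.d_min))[valid].sum())
    return reg + params.lam * data


def smooth_disparity(
    volume: CostVolume,
    wta: DisparityMap,
    params: SmoothingParams | None = None,
) -> DisparityMap:
    """Huber-L1 variational smoothing of a WTA disparity map.

    Quadratic relaxation: introduce an auxiliary map ``a`` coupled to
    ``u`` by ``(u - a)^2 / (2 theta)``; alternate (i) a few weighted-
    diffusion steps that decrease the Huber-gradient + coupling energy in
    ``u``, and (ii) an exact point-wise minimisation of
    ``(u - a)^2/(2 theta) + lam C(p, a)`` over the disparity samples.
    ``theta`` is annealed downward to tighten the coupling.  The candidate
    with the lowest true Huber-L1 energy seen across iterations is
    returned, so the energy never exceeds the initialisation's.
    """
    params = params or SmoothingParams()
    valid = wta.valid.copy()
    if not valid.any():
        return DisparityMap(wta.disparity.copy(), valid)
    u = np.where(valid, wta.disparity, float(volume.d_min)).astype(float)

    best_u = u.copy()
    best_E = huber_l1_energy(volume, u, valid, params)
    init_E = best_E

    theta = params.theta
    d_grid = volume.disparities.astype(float)
    c = volume.costs
    h, w, n_d = c.shape

    a = u.copy()
    for _ in range(params.n_outer):
        # (i) smooth u toward a under the Huber gradient penalty:
        # lagged-diffusivity / weighted Jacobi iterations on the reflected grid
        for _ in range(params.n_inner):
            up = np.pad(u, 1, mode="edge")
            gx = up[1:-1, 2:] - u
            gy = up[2:, 1:-1] - u
            g = np.sqrt(gx * gx + gy * gy)
            wgt = 1.0 / np.maximum(g, params.huber_eps)  # Huber weight 1/max(|g|,eps)
            wp = np.pad(wgt, 1, mode="edge")
            # edge weight between a pixel and its left/up neighbour is the
            # neighbour's gradient weight (lagged diffusivity)
            w_right, w_left = wgt, wp[1:-1, :-2]
            w_down, w_up = wgt, wp[:-2, 1:-1]
            nbr = (
                w_right * up[1:-1, 2:]
                + w_left * up[1:-1, :-2]
                + w_down * up[2:, 1:-1]
                + w_up * up[:-2, 1:-1]
            )
            wsum = w_right + w_left + w_down + w_up
            u_new = (nbr + a / theta) / (wsum + 1.0 / theta)
            u = np.where(valid, u_new, u)

        # (ii) point-wise exact search: a = argmin (u-d)^2/(2 theta) + lam C(p,d),
        # seeded with the off-grid candidate d = u so a flat data term
        # exerts no pull on the regulariser
        best = params.lam * _sample_cost(volume, u)
        a_new = u.copy()
        for k in range(n_d):
            cand = (u - d_grid[k]) ** 2 / (2.0 * theta) + params.lam * c[:, :, k]
            cand = np.where(volume.valid[:, :, k], cand, np.inf)
            better = cand < best
            best = np.where(better, cand, best)
            a_new = np.where(better, d_grid[k], a_new)
        a = np.where(valid & np.isfinite(best), a_new, a)

        E = huber_l1_energy(volume, np.where(valid, a, u), valid, params)
        if E < best_E:
            best_E = E
            best_u = np.where(valid, a, u)
        Eu = huber_l1_energy(volume, u, valid, params)
        if Eu < best_E:
            best_E = Eu
            best_u = u.copy()
        theta = max(theta * 0.5, 0.05)

    assert best_E <= init_E + 1e-9
    out = best_u.copy()
    out[~valid] = np.nan
    return DisparityMap(disparity=out, valid=valid)


def disparity_to_points(
    disp: DisparityMap, rig: CameraRig, stride: int = 1
) -> np.ndarray:
    """Back-project every valid pixel to a camera-frame point cloud (mm).

    ``stride`` subsamples the pixel grid (a stride of 2 keeps a quarter of
    the points) — dense maps at full resolution are usually denser than
    the fusion voxel grid needs.
    """
    h, w = disp.disparity.shape
    ys, xs = np.mgrid[0:h:stride, 0:w:stride]
    d = disp.disparity[ys, xs]
    ok = disp.valid[ys, xs] & (d > rig.min_disparity_px)
    d = d[ok]
    x = xs[ok].astype(float)
    y = ys[ok].astype(float)
    Z = rig.fx * rig.baseline_mm / d
    X = (x - rig.cx) * Z / rig.fx
    Y = (y - rig.cy) * Z / rig.fy
    return np.column_stack([X, Y, Z])


def save_disparity_png16(path: str | Path, disp: DisparityMap, scale: float = 256.0) -> None:
    """16-bit PNG with a YAML sidecar holding the scale factor."""
    import imageio.v3 as iio
    import yaml

    arr = np.where(disp.valid, disp.disparity, 0.0)
    png = np.clip(arr * scale, 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), png)
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump({"scale": float(scale), "invalid_value": 0}, fh)


def load_disparity_png16(path: str | Path) -> DisparityMap:
    import imageio.v3 as iio
    import yaml

    with open(str(path) + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    png = iio.imread(str(path)).astype(float)
    disp = png / float(meta["scale"])
    valid = png > 0
    disp[~valid] = np.nan
    return DisparityMap(disparity=disp, valid=valid)
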