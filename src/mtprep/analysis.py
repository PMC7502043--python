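"""MTR maps and quantitative image metrics.

Covers the full analysis chain: voxel-wise MTR with a validity floor,
per-slice Gaussian smoothing, remote-referenced mean-2*sigma scar
thresholding with overlap / false-positive scoring against a labelled
reference, short-axis reformatting, AHA 16-segment statistics, blood/myo
contrast ratio, vessel sharpness along a centerline, and lung-noise CNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, map_coordinates

__all__ = [
    "MTRMap",
    "AHALabels",
    "SegmentStats",
    "mtr_map",
    "smooth_map",
    "scar_threshold_segmentation",
    "overlap_percent",
    "false_positive_percent",
    "dice",
    "reformat_short_axis",
    "aha16_labels",
    "segment_stats",
    "contrast_ratio",
    "vessel_sharpness",
    "cnr",
]


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


@dataclass
class MTRMap:
    """Voxel-wise MTR (percent) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    n_clipped: int = 0
    floor: float = 0.05

    def masked(self) -> np.ndarray:
        out = np.full_like(self.values, np.nan)
        out[self.valid] = self.values[self.valid]
        return out


def mtr_map(
    vol_mt: np.ndarray,
    vol_ref: np.ndarray,
    floor: float = 0.05,
    voxel_size=(1.0, 1.0, 1.0),
) -> MTRMap:
    """Voxel-wise MTR = 100 (1 - I_MT / I_REF), percent.

    Voxels whose reference intensity falls below ``floor`` times the robust
    (99th percentile) reference maximum are marked invalid rather than
    divided; values are clipped to [-100, 100] and the clip count recorded.
    """
    vol_mt = np.asarray(vol_mt, dtype=float)
    vol_ref = np.asarray(vol_ref, dtype=float)
    if vol_mt.shape != vol_ref.shape:
        raise ValueError("MT and REF volumes must share a grid")
    robust_max = np.percentile(vol_ref, 99.0)
    valid = vol_ref > floor * robust_max
    values = np.zeros_like(vol_mt)
    raw = 100.0 * (1.0 - vol_mt[valid] / vol_ref[valid])
    n_clipped = int(np.sum((raw < -100) | (raw > 100)))
    values[valid] = np.clip(raw, -100.0, 100.0)
    return MTRMap(values, valid, tuple(voxel_size), n_clipped, floor)


def _gauss_kernel2d(kernel: int, sigma: float) -> np.ndarray:
    half = kernel // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def smooth_map(mtr: MTRMap, kernel: int = 5, sigma: float = 3.0) -> MTRMap:
    """Per-slice 2D Gaussian smoothing (default 5 px kernel, sigma 3 px).

    The heavily truncated kernel is renormalized, and normalized convolution
    restricts the averaging to valid voxels so invalid regions neither leak
    zeros in nor get filled.
    """
    if kernel % 2 == 0:
        raise ValueError("kernel size must be odd")
    g = _gauss_kernel2d(kernel, sigma)
    vals = np.where(mtr.valid, mtr.values, 0.0)
    out = np.zeros_like(mtr.values)
    for z in range(mtr.values.shape[2]):
        num = convolve(vals[:, :, z], g, mode="constant")
        den = convolve(mtr.valid[:, :, z].astype(float), g, mode="constant")
        sl = mtr.valid[:, :, z]
        out[:, :, z][sl] = num[sl] / den[sl]
    return MTRMap(out, mtr.valid.copy(), mtr.voxel_size, mtr.n_clipped, mtr.floor)


def scar_threshold_segmentation(
    mtr: MTRMap, myo: np.ndarray, remote: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scar = valid myocardial voxels with MTR below remote mean - 2 sigma."""
    myo = np.asarray(myo, dtype=bool)
    remote = np.asarray(remote, dtype=bool)
    if not np.any(remote):
        raise MetricError("empty remote ROI")
    if np.any(remote & ~myo):
        raise MetricError("remote ROI must lie within the myocardium mask")
    sel = remote & mtr.valid
    if not np.any(sel):
        raise MetricError("remote ROI has no valid MTR voxels")
    vals = mtr.values[sel]
    threshold = float(vals.mean() - 2.0 * vals.std())
    scar = myo & mtr.valid & (mtr.values < threshold)
    return scar, threshold


def overlap_percent(scar_mtr: np.ndarray, scar_lge: np.ndarray) -> float:
    """100 * |LGE_scar intersect MTR_scar| / |LGE_scar|."""
    scar_mtr = np.asarray(scar_mtr, dtype=bool)
    scar_lge = np.asarray(scar_lge, dtype=bool)
    if scar_mtr.shape != scar_lge.shape:
        raise ValueError("masks must share a grid")
    n_lge = scar_lge.sum()
    if n_lge == 0:
        raise MetricError("empty reference scar mask")
    return 100.0 * float((scar_lge & scar_mtr).sum()) / float(n_lge)


def false_positive_percent(
    scar_mtr: np.ndarray, remote_lge: np.ndarray, literal: bool = False
) -> float:
    """Fraction of reference remote tissue wrongly labelled scar, percent.

    Default: 100 * |remote intersect scar| / |remote| (the evident intent).
    ``literal=True`` gives the complementary printed form
    100 * (1 - |remote intersect scar| / |remote|).
    """
    scar_mtr = np.asarray(scar_mtr, dtype=bool)
    remote_lge = np.asarray(remote_lge, dtype=bool)
    if scar_mtr.shape != remote_lge.shape:
        raise ValueError("masks must share a grid")
    n_rem = remote_lge.sum()
    if n_rem == 0:
        raise MetricError("empty remote mask")
    frac = float((remote_lge & scar_mtr).sum()) / float(n_rem)
    return 100.0 * (1.0 - frac) if literal else 100.0 * frac


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise MetricError("both masks empty")
    return 2.0 * float((a & b).sum()) / float(denom)


def reformat_short_axis(
    vol: np.ndarray,
    axes: np.ndarray,
    origin,
    out_shape,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear resampling onto a new (short-axis) grid.

    ``axes`` is a 3x3 matrix whose columns are the output grid axes expressed
    in input voxel coordinates (orthonormal up to scale); output voxel j maps
    to input coordinate ``origin + axes @ j``.  Returns (volume, valid mask);
    out-of-field voxels are invalid and zero.
    """
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3) or abs(np.linalg.det(axes)) < 1e-12:
        raise ValueError("axes must be a non-singular 3x3 matrix")
    jj = np.indices(out_shape, dtype=float).reshape(3, -1)
    coords = np.asarray(origin, dtype=float).reshape(3, 1) + axes @ jj
    inside = np.ones(coords.shape[1], dtype=bool)
    for ax, dim in enumerate(vol.shape):
        inside &= (coords[ax] >= -0.5) & (coords[ax] <= dim - 0.5)
    out = map_coordinates(
        np.asarray(vol, dtype=float), coords, order=1, mode="nearest"
    )
    out[~inside] = 0.0
    return out.reshape(out_shape), inside.reshape(out_shape)


@dataclass
class AHALabels:
    """Per-voxel AHA 16-segment ids (0 = unlabelled)."""

    labels: np.ndarray
    rv_angle_deg: float


_SLAB_LAYOUT = (("basal", 1, 6), ("mid", 7, 6), ("apical", 13, 4))


def aha16_labels(
    slabs: dict,
    centre,
    rv_insertion,
) -> AHALabels:
    """Divide the LV myocardium into the AHA 16-segment model.

    ``slabs`` maps "basal"/"mid"/"apical" to boolean 3D masks of the LV
    myocardium in each slab.  Angular sectors are measured counterclockwise
    (in the index plane, viewed from apex) from the ray centre->rv_insertion:
    6 x 60 deg basal (ids 1-6), 6 x 60 deg mid (7-12), 4 x 90 deg apical
    (13-16); sector boundaries belong to the lower id.
    """
    missing = [k for k, _, _ in _SLAB_LAYOUT if k not in slabs]
    if missing:
        raise ValueError(f"missing slabs: {missing}")
    any_mask = next(iter(slabs.values()))
    cx, cy = float(centre[0]), float(centre[1])
    bbox = np.nonzero(np.any(sum(np.asarray(m, bool) for m in slabs.values()), axis=2))
    if bbox[0].size and not (
        bbox[0].min() - 0.5 <= cx <= bbox[0].max() + 0.5
        and bbox[1].min() - 0.5 <= cy <= bbox[1].max() + 0.5
    ):
        raise ValueError("centre outside the myocardium bounding box")
    rv_angle = np.degrees(
        np.arctan2(rv_insertion[1] - cy, rv_insertion[0] - cx)
    )
    labels = np.zeros(any_mask.shape, dtype=np.int8)
    for name, base, n_sect in _SLAB_LAYOUT:
        mask = np.asarray(slabs[name], dtype=bool)
        if not np.any(mask):
            continue
        ix, iy, iz = np.nonzero(mask)
        theta = np.degrees(np.arctan2(iy - cy, ix - cx)) - rv_angle
        theta = np.mod(theta, 360.0)
        width = 360.0 / n_sect
        # boundaries belong to the lower id: sectors are (k*w, (k+1)*w]
        sect = (np.ceil(theta / width).astype(int) - 1) % n_sect
        labels[ix, iy, iz] = base + sect
    return AHALabels(labels, float(np.mod(rv_angle, 360.0)))


@dataclass
class SegmentStats:
    per_segment: pd.DataFrame  # index: segment id; mean, sd, spatial_variation
    global_mean: float
    intersegment_variation: float
    empty_segments: list = field(default_factory=list)


def segment_stats(mtr: MTRMap, labels: AHALabels) -> SegmentStats:
    """Per-segment mean/SD MTR, spatial variation 100*SD/mean, global mean and
    intersegment variation 100*SD(segment means)/mean(segment means)."""
    if labels.labels.shape != mtr.values.shape:
        raise ValueError("labels must be on the map grid")
    rows, empty = {}, []
    for seg in range(1, 17):
        sel = (labels.labels == seg) & mtr.valid
        if not np.any(sel):
            empty.append(seg)
            continue
        vals = mtr.values[sel]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows[seg] = {
            "mean": mean,
            "sd": sd,
            "spatial_variation": 100.0 * sd / mean if mean != 0 else np.nan,
            "n_voxels": int(vals.size),
        }
    per_segment = pd.DataFrame.from_dict(rows, orient="index")
    all_sel = (labels.labels > 0) & mtr.valid
    global_mean = float(mtr.values[all_sel].mean()) if np.any(all_sel) else np.nan
    means = per_segment["mean"].to_numpy()
    inter = (
        100.0 * means.std(ddof=1) / means.mean() if means.size > 1 else np.nan
    )
    return SegmentStats(per_segment, global_mean, float(inter), empty)


def contrast_ratio(mtr: MTRMap, myo: np.ndarray, blood: np.ndarray) -> float:
    """Contrast ratio mean(MTR | myocardium) / mean(MTR | blood)."""
    myo = np.asarray(myo, bool) & mtr.valid
    blood = np.asarray(blood, bool) & mtr.valid
    if not np.any(myo) or not np.any(blood):
        raise MetricError("empty ROI")
    blood_mean = mtr.values[blood].mean()
    if blood_mean == 0:
        raise MetricError("zero blood MTR mean")
    return float(mtr.values[myo].mean() / blood_mean)


def vessel_sharpness(
    image: np.ndarray,
    centerline: np.ndarray,
    vessel_diameter: float = 3.0,
    step: float = 0.5,
) -> float:
    """Vessel sharpness in percent.

    At each centerline point two intensity profiles are cast from the centre,
    one to each side, perpendicular to the local tangent in the slice plane
    (length 3x the nominal vessel diameter, ``step``-voxel sampling, linear
    interpolation).  Each side's edge gradient is the maximum absolute
    finite difference per voxel-step; VS = 100 * mean(edge gradients) /
    centre intensity, averaged along the centerline.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 5:
        raise ValueError("centerline needs >= 5 points of (x, y, z)")
    image = np.asarray(image, dtype=float)
    n_steps = int(round(3.0 * vessel_diameter / step))
    offsets = np.arange(n_steps + 1) * step
    vs_points = []
    for i, p in enumerate(pts):
        lo = pts[max(i - 1, 0)]
        hi = pts[min(i + 1, len(pts) - 1)]
        tangent = hi - lo
        # perpendicular within the slice plane
        perp = np.array([-tangent[1], tangent[0], 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        centre_val = float(
            map_coordinates(image, p.reshape(3, 1), order=1, mode="nearest")[0]
        )
        if centre_val <= 0:
            raise MetricError("non-positive vessel centre intensity")
        grads = []
        for sign in (+1.0, -1.0):
            coords = (p[:, None] + sign * perp[:, None] * offsets[None, :])
            prof = map_coordinates(image, coords, order=1, mode="nearest")
            grads.append(np.max(np.abs(np.diff(prof))) / step)
        vs_points.append(100.0 * np.mean(grads) / centre_val)
    return float(np.mean(vs_points))


def cnr(
    image: np.ndarray,
    blood: np.ndarray,
    myo: np.ndarray,
    lungs: np.ndarray,
) -> float:
    """Blood-myocardium contrast-to-noise ratio using lung-ROI noise:
    (mean blood - mean myo) / SD(lungs), SD with n-1 normalization."""
    image = np.asarray(image, dtype=float)
    blood = np.asarray(blood, bool)
    myo = np.asarray(myo, bool)
    lungs = np.asarray(lungs, bool)
    if lungs.sum() < 2:
        raise MetricError("lung ROI needs more than one voxel")
    sd = image[lungs].std(ddof=1)
    if sd == 0:
        raise MetricError("zero lung noise SD")
    return float((image[blood].mean() - image[myo].mean()) / sd)
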