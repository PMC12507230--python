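"""Geometry-based arm location from silhouette video.

Markerless pose models track the eyes well but not the eight arm tips, so
arm directions are recovered directly from the images: each frame is
background-subtracted, cropped to a body-centered 600 x 600 px window, and
rotated so the body axis points straight down.  An average body image per
individual yields a bounding rectangle (symmetric about the body axis,
enclosing a set fraction of total intensity) and a bounding circle whose
radius reaches the rectangle's most distant vertices — large enough that a
ring at that radius crosses the arms but never the mantle.  Five concentric
one-pixel rings at that radius are unwrapped into 100 angular bins (3.6
degrees each) and averaged; arms appear as circular-array peaks, and the
angle between each detected arm and the animal's heading is the
heading-arm offset (the smallest in magnitude identifies the leading arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .angles import signed_offset_deg, wrap_deg

logger = logging.getLogger(__name__)

N_BINS = 100
BIN_WIDTH_DEG = 360.0 / N_BINS  # 3.6 degrees
#: circular-boundary rescue: rerun peak finding on a copy rolled this far
EDGE_SHIFT_BINS = 5
CROP_SIZE = 600


def bin_center_deg(bins) -> np.ndarray:
    """Angle of bin center(s) relative to the body axis (CCW positive)."""
    b = np.asarray(bins, dtype=float)
    return wrap_deg(BIN_WIDTH_DEG * (b + 0.5))


def angle_to_bin(angle_deg) -> np.ndarray:
    """Bin index containing angle(s) measured from the body axis."""
    a = np.asarray(angle_deg, dtype=float) % 360.0
    return (np.floor(a / BIN_WIDTH_DEG).astype(int)) % N_BINS


@dataclass
class BodyGeometry:
    """Per-individual bounding rectangle and circle on the average image.

    The rectangle is symmetric about the (vertical) body axis of the
    standardized image; half_width/top/bottom are offsets in px from the
    body center.  The circle is centered on the body center with radius
    equal to the distance to the rectangle's most distant vertices.
    """

    half_width_px: float
    top_px: float  # extent toward the head (up the standardized image)
    bottom_px: float  # extent toward the mantle
    radius_px: float
    intensity_fraction: float = 0.95

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")

    def to_dict(self) -> dict:
        return {
            "half_width_px": self.half_width_px,
            "top_px": self.top_px,
            "bottom_px": self.bottom_px,
            "radius_px": self.radius_px,
            "intensity_fraction": self.intensity_fraction,
        }


@dataclass
class ArmProfile:
    """100-bin ring intensity profile and detected arms for one frame."""

    bin_means: np.ndarray
    peaks: np.ndarray | None = None  # bin indices
    heading_arm_offsets_deg: np.ndarray | None = None
    nearest_arm_offset_deg: float = np.nan

    def __post_init__(self):
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        if self.bin_means.shape != (N_BINS,):
            raise ValueError(f"profile must have exactly {N_BINS} bins")

    @property
    def bin_angle_deg(self) -> np.ndarray:
        return bin_center_deg(np.arange(N_BINS))

    def peak_angles_deg(self) -> np.ndarray:
        """Detected arm angles relative to the body axis."""
        if self.peaks is None:
            return np.empty(0)
        return bin_center_deg(self.peaks)


# ---------------------------------------------------------------------------
# background subtraction


def dynamic_background(
    frames: np.ndarray,
    centers_px: np.ndarray,
    min_dist_px: float = 600.0,
    k: int = 10,
) -> np.ndarray:
    """Per-frame background: mean of the k temporally nearest far-away frames.

    A frame qualifies as background material for frame *i* when the animal
    is more than ``min_dist_px`` away from its position at *i*; this tracks
    slow background change (e.g. sediment deposition) without ever
    averaging the animal into its own background.
    """
    frames = np.asarray(frames)
    centers = np.asarray(centers_px, dtype=float)
    n = len(frames)
    if centers.shape != (n, 2):
        raise ValueError("need one (x, y) center per frame")
    out = np.empty(frames.shape, dtype=np.float32)
    dmat_warned = False
    for i in range(n):
        dist = np.linalg.norm(centers - centers[i], axis=1)
        qual = np.flatnonzero(dist > min_dist_px)
        if qual.size == 0:
            raise ValueError(f"frame {i}: no frames with the animal > {min_dist_px} px away")
        if qual.size < k:
            if not dmat_warned:
                logger.warning(
                    "fewer than k=%d qualifying background frames; using all %d",
                    k,
                    qual.size,
                )
                dmat_warned = True
            chosen = qual
        else:
            order = np.argsort(np.abs(qual - i), kind="stable")
            chosen = qual[order[:k]]
        out[i] = frames[chosen].mean(axis=0)
    return out


def subtract_background(frames: np.ndarray, backgrounds: np.ndarray) -> np.ndarray:
    """Background subtraction, clamped at zero."""
    diff = np.asarray(frames, dtype=np.float32) - np.asarray(backgrounds, dtype=np.float32)
    return np.clip(diff, 0.0, None)


class BackgroundSubtractedStack:
    """Frame stack with dynamic background subtraction applied on access.

    Avoids materializing a float copy of the whole video: each ``stack[i]``
    computes the mean of the k temporally nearest frames in which the
    animal is at least ``min_dist_px`` away, subtracts it and clamps at
    zero.  Raises on construction if any frame has no qualifying
    background material.
    """

    def __init__(self, frames, centers_px, min_dist_px: float = 600.0, k: int = 10):
        self.frames = frames
        self.centers = np.asarray(centers_px, dtype=float)
        self.min_dist_px = float(min_dist_px)
        self.k = int(k)
        if len(self.centers) != len(frames):
            raise ValueError("need one center per frame")
        dists = np.linalg.norm(
            self.centers[:, None, :] - self.centers[None, :, :], axis=-1
        )
        self._qualifying = dists > self.min_dist_px
        bad = np.flatnonzero(~self._qualifying.any(axis=1))
        if bad.size:
            raise ValueError(
                f"frame {bad[0]}: no frames with the animal > {self.min_dist_px} px away"
            )
        if (self._qualifying.sum(axis=1) < self.k).any():
            logger.warning(
                "some frames have fewer than k=%d qualifying background frames", self.k
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        qual = np.flatnonzero(self._qualifying[i])
        order = np.argsort(np.abs(qual - i), kind="stable")
        chosen = np.sort(qual[order[: self.k]])
        bg = np.mean([np.asarray(self.frames[j], dtype=np.float32) for j in chosen], axis=0)
        diff = np.asarray(self.frames[i], dtype=np.float32) - bg
        return np.clip(diff, 0.0, None)


# ---------------------------------------------------------------------------
# standardization


def crop_and_rotate(
    frame: np.ndarray,
    center_px: tuple[float, float],
    body_axis_deg: float,
    size: int = CROP_SIZE,
) -> np.ndarray:
    """Body-centered, axis-aligned crop.

    The output has the body center at its midpoint and the body axis
    pointing down the image (toward -y in image algebra, i.e. -90 deg).
    Bilinear interpolation; out-of-frame regions are zero.
    """
    img = np.asarray(frame, dtype=float)
    cx, cy = center_px
    half = size / 2.0
    # output direction -90 deg must correspond to the input body axis:
    # input = center + R(axis + 90) @ (out - half)
    delta = np.deg2rad(body_axis_deg + 90.0)
    cosd, sind = np.cos(delta), np.sin(delta)
    xo = np.arange(size) - half
    yo = np.arange(size) - half
    xx, yy = np.meshgrid(xo, yo)  # yy: row offset, xx: col offset
    xi = cx + cosd * xx - sind * yy
    yi = cy + sind * xx + cosd * yy
    return map_coordinates(img, [yi, xi], order=1, mode="constant", cval=0.0)


def standardized_direction(angle_from_axis_deg) -> np.ndarray:
    """Unit vector(s) in the standardized image for an angle from the axis.

    Angle 0 is the body-axis direction (down the image, -90 deg in image
    algebra); positive angles rotate counter-clockwise in the arena sense.
    """
    a = np.deg2rad(np.asarray(angle_from_axis_deg, dtype=float) - 90.0)
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


def average_body_image(standardized: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of standardized images, scaled to unit maximum."""
    stack = np.asarray(standardized)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1:
        raise ValueError("need at least one image")
    avg = stack.mean(axis=0, dtype=np.float64)
    peak = avg.max()
    if peak <= 0:
        raise ValueError("all-zero image stack")
    return avg / peak


def fit_bounding_geometry(
    avg_image: np.ndarray,
    intensity_fraction: float = 0.95,
    mask_threshold: str = "otsu",
) -> BodyGeometry:
    """Bounding rectangle and circle from the normalized average image.

    The image is thresholded (Otsu by default) to mask residual background,
    then a rectangle symmetric about the vertical body axis is grown
    greedily — expanding whichever of its three free extents (half-width,
    toward head, toward mantle) captures the most masked intensity per px —
    until it encloses ``intensity_fraction`` of the total.  The bounding
    circle is centered on the body center with radius to the most distant
    rectangle vertices.
    """
    img = np.asarray(avg_image, dtype=float)
    H, W = img.shape
    r0, c0 = H // 2, W // 2
    if mask_threshold == "otsu":
        masked = np.where(img > threshold_otsu(img), img, 0.0)
    elif mask_threshold == "none":
        masked = img
    else:
        raise ValueError(f"unknown mask_threshold: {mask_threshold!r}")
    total = masked.sum()
    if total <= 0 or (masked > 0).sum() < 2:
        raise ValueError("degenerate average image")
    target = intensity_fraction * total

    col_dist = np.abs(np.arange(W) - c0)
    rows_up = r0  # toward the head (smaller row index)
    rows_down = H - 1 - r0

    hw, top, bot = 0, 0, 0

    def enclosed(hw, top, bot):
        return masked[r0 - top : r0 + bot + 1, c0 - hw : c0 + hw + 1].sum()

    cur = enclosed(hw, top, bot)
    while cur < target:
        gains = []
        if hw < min(c0, W - 1 - c0):
            g = masked[r0 - top : r0 + bot + 1, [c0 - hw - 1, c0 + hw + 1]].sum()
            gains.append((g / 2.0, "hw"))
        if top < rows_up:
            g = masked[r0 - top - 1, c0 - hw : c0 + hw + 1].sum()
            gains.append((g, "top"))
        if bot < rows_down:
            g = masked[r0 + bot + 1, c0 - hw : c0 + hw + 1].sum()
            gains.append((g, "bot"))
        if not gains:
            break
        _, which = max(gains, key=lambda t: t[0])
        if which == "hw":
            hw += 1
        elif which == "top":
            top += 1
        else:
            bot += 1
        cur = enclosed(hw, top, bot)

    radius = float(np.sqrt(hw**2 + max(top, bot) ** 2))
    if radius <= 0:
        raise ValueError("degenerate bounding geometry")
    return BodyGeometry(
        half_width_px=float(hw),
        top_px=float(top),
        bottom_px=float(bot),
        radius_px=radius,
        intensity_fraction=intensity_fraction,
    )


# ---------------------------------------------------------------------------
# ring profile and peaks


def ring_profile(
    standardized: np.ndarray,
    geometry: BodyGeometry,
    n_rings: int = 5,
    samples_per_ring: int = 1000,
) -> ArmProfile:
    """Mean angular intensity profile on the bounding ring.

    ``n_rings`` concentric one-pixel circles at radii r, r-1, ..., r-n+1
    (the ring extends inward from the bounding radius so it never leaves
    the crop) are sampled bilinearly, unwrapped, binned into 100 angular
    bins, and averaged bin-wise.
    """
    img = np.asarray(standardized, dtype=float)
    H, W = img.shape
    cx, cy = W / 2.0, H / 2.0
    r = geometry.radius_px
    if r < n_rings:
        raise ValueError(f"radius {r:.1f} px too small for {n_rings} rings")
    angles = (np.arange(samples_per_ring) + 0.5) * (360.0 / samples_per_ring)
    dirs = standardized_direction(angles)  # (m, 2) unit vectors
    bins = angle_to_bin(angles)
    ring_means = np.empty((n_rings, N_BINS))
    for j in range(n_rings):
        rho = r - j
        x = cx + rho * dirs[:, 0]
        y = cy + rho * dirs[:, 1]
        vals = map_coordinates(img, [y, x], order=1, mode="constant", cval=0.0)
        sums = np.bincount(bins, weights=vals, minlength=N_BINS)
        counts = np.bincount(bins, minlength=N_BINS)
        ring_means[j] = sums / counts
    return ArmProfile(bin_means=ring_means.mean(axis=0))


def detect_arm_peaks(
    profile: ArmProfile,
    prominence_frac: float = 0.1,
    min_separation_bins: int = 2,
) -> np.ndarray:
    """Circular peak detection on the 100-bin profile.

    Peaks split across the array ends are invisible to a linear peak
    finder, so detection runs on the original and on a copy rolled by
    ``EDGE_SHIFT_BINS``; the union is de-duplicated within one bin.
    A flat profile yields no peaks.
    """
    y = profile.bin_means
    span = y.max() - y.min()
    if span <= 0:
        profile.peaks = np.empty(0, dtype=int)
        return profile.peaks
    prominence = prominence_frac * span
    candidates = set()
    p1, _ = find_peaks(y, prominence=prominence, distance=min_separation_bins)
    candidates.update(int(i) for i in p1)
    rolled = np.roll(y, EDGE_SHIFT_BINS)
    p2, _ = find_peaks(rolled, prominence=prominence, distance=min_separation_bins)
    candidates.update((int(i) - EDGE_SHIFT_BINS) % N_BINS for i in p2)
    if not candidates:
        profile.peaks = np.empty(0, dtype=int)
        return profile.peaks
    # de-duplicate circularly within one bin, keeping the higher bin value
    ordered = sorted(candidates, key=lambda b: -y[b])
    kept: list[int] = []
    for b in ordered:
        if all(min((b - kb) % N_BINS, (kb - b) % N_BINS) > 1 for kb in kept):
            kept.append(b)
    profile.peaks = np.array(sorted(kept), dtype=int)
    return profile.peaks


def heading_arm_offsets(
    peaks: np.ndarray,
    body_axis_deg: float,
    heading_deg: float,
) -> tuple[np.ndarray, float]:
    """Signed offsets of detected arms from the heading; nearest-arm offset.

    Offsets are in (-180, 180], positive when the arm lies counter-clockwise
    of the heading.  The nearest arm minimizes |offset|; an exact +/- tie is
    broken toward the positive offset.  Returns ``(offsets, nan)`` when no
    arms were detected or the heading is undefined.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0 or not np.isfinite(heading_deg):
        return np.empty(0), np.nan
    arm_angles = body_axis_deg + bin_center_deg(peaks)
    offsets = signed_offset_deg(heading_deg, arm_angles)
    offsets = np.atleast_1d(offsets)
    best = np.min(np.abs(offsets))
    tied = offsets[np.isclose(np.abs(offsets), best)]
    nearest = float(np.max(tied))  # tie toward positive
    return offsets, nearest


# ---------------------------------------------------------------------------
# per-track driver


def arm_profiles_for_track(
    frames: np.ndarray,
    kin,
    px_per_cm: float,
    geometry: BodyGeometry | None = None,
    crop_size: int = CROP_SIZE,
    prominence_frac: float = 0.1,
    min_separation_bins: int = 2,
):
    """Run standardization, geometry fitting, ring profiling and peak
    detection for every frame of a track.

    ``kin`` is the kinematics table (``center_*_px``, ``body_axis_deg``,
    ``heading_deg``).  When ``geometry`` is None it is fitted from the
    average of all standardized frames with a defined body axis.  Returns
    ``(profiles, geometry, table)`` where ``table`` is a DataFrame with
    per-frame nearest-arm offsets and peak counts.
    """
    import pandas as pd

    centers = kin[["center_x_px", "center_y_px"]].to_numpy(dtype=float)
    axes = kin["body_axis_deg"].to_numpy(dtype=float)
    headings = kin["heading_deg"].to_numpy(dtype=float)
    n = len(frames)  # any indexable stack works, including lazy ones
    std = np.empty((n, crop_size, crop_size), dtype=np.float32)
    ok = np.isfinite(axes)
    for i in range(n):
        if ok[i]:
            std[i] = crop_and_rotate(frames[i], centers[i], axes[i], size=crop_size)
        else:
            std[i] = 0.0
    if geometry is None:
        avg = average_body_image(std[ok])
        geometry = fit_bounding_geometry(avg)
    profiles: list[ArmProfile] = []
    rows = []
    for i in range(n):
        if not ok[i]:
            prof = ArmProfile(bin_means=np.zeros(N_BINS))
            prof.peaks = np.empty(0, dtype=int)
            nearest = np.nan
            n_peaks = 0
        else:
            prof = ring_profile(std[i], geometry)
            peaks = detect_arm_peaks(
                prof, prominence_frac=prominence_frac, min_separation_bins=min_separation_bins
            )
            offsets, nearest = heading_arm_offsets(peaks, axes[i], headings[i])
            prof.heading_arm_offsets_deg = offsets
            prof.nearest_arm_offset_deg = nearest
            n_peaks = peaks.size
        profiles.append(prof)
        rows.append(
            {
                "frame": int(kin["frame"].iloc[i]),
                "n_arms": n_peaks,
                "nearest_arm_offset_deg": prof.nearest_arm_offset_deg,
            }
        )
    return profiles, geometry, pd.DataFrame(rows)
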