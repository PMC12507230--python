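"""Pose-track cleaning and per-frame kinematics.

Raw input is a markerless pose track: per-frame pixel coordinates of the two
eyes and the mantle tip, plus a tracker confidence.  The cleaning chain is
outlier rejection (displacement spikes), linear gap interpolation, and
Savitzky-Golay smoothing of the coordinates.  From the cleaned track we
derive the quantities the downstream analysis runs on:

* body center — midpoint of the two eyes;
* body axis — unit normal of the inter-eye line pointing away from the
  mantle tip (the direction the animal faces);
* heading — direction of body-center displacement between successive frames;
* heading offset — signed angle from body axis to heading, in (-180, 180]
  (0 means moving face-first, negative means heading clockwise of facing);
* speed and per-individual speed z-score (animals of different sizes have
  different speed scales, so speeds are standardized before pooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .angles import signed_offset_deg, vector_angle_deg

BODY_PARTS = ("eyeL", "eyeR", "mantle")
POSE_COLUMNS = (
    "frame",
    "eyeL_x",
    "eyeL_y",
    "eyeR_x",
    "eyeR_y",
    "mantle_x",
    "mantle_y",
    "confidence",
)

#: displacement (px/frame) below which the heading direction is undefined
HEADING_EPSILON_PX = 0.05


@dataclass
class CleaningReport:
    """Bookkeeping for the cleaning chain applied to one pose track."""

    n_outliers_dropped: int = 0
    n_interpolated: int = 0
    n_trimmed_leading: int = 0
    n_trimmed_trailing: int = 0
    filter_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_outliers_dropped": self.n_outliers_dropped,
            "n_interpolated": self.n_interpolated,
            "n_trimmed_leading": self.n_trimmed_leading,
            "n_trimmed_trailing": self.n_trimmed_trailing,
            "filter_params": dict(self.filter_params),
        }


def _validate_track(track: pd.DataFrame) -> None:
    missing = [c for c in POSE_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"pose track missing columns: {missing}")
    frames = track["frame"].to_numpy()
    if len(frames) > 1 and not np.all(np.diff(frames) > 0):
        raise ValueError("frame indices must be strictly increasing")


def detect_and_drop_outliers(
    track: pd.DataFrame, mad_k: float = 5.0
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop displacement-spike coordinates, leaving NaN gaps.

    For each body part, per-frame displacements are computed and a frame's
    coordinate is flagged when both the displacement into and out of the
    frame exceed ``median + mad_k * MAD`` of that part's displacements
    (a spike: the tracker jumped away and back).  Edge frames are judged on
    their single available displacement.  Flagged coordinates become NaN.
    """
    _validate_track(track)
    if len(track) < 3:
        raise ValueError("need at least 3 frames for outlier detection")
    cleaned = track.copy()
    n_dropped = 0
    for part in BODY_PARTS:
        xy = cleaned[[f"{part}_x", f"{part}_y"]].to_numpy(dtype=float)
        disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)  # disp[i]: i -> i+1
        med = np.nanmedian(disp)
        mad = np.nanmedian(np.abs(disp - med))
        thresh = med + mad_k * mad
        n = len(xy)
        disp_in = np.full(n, np.nan)
        disp_out = np.full(n, np.nan)
        disp_in[1:] = disp
        disp_out[:-1] = disp
        # interior: both neighbors exceed; edges: the single defined one
        both = np.fmin(disp_in, disp_out)
        both[0] = disp_out[0]
        both[-1] = disp_in[-1]
        bad = both > thresh
        n_dropped += int(bad.sum())
        cleaned.loc[bad, [f"{part}_x", f"{part}_y"]] = np.nan
    coord_cols = [f"{p}_{c}" for p in BODY_PARTS for c in "xy"]
    if cleaned[coord_cols].isna().all(axis=1).all():
        raise ValueError("all frames dropped as outliers; check mad_k")
    report = CleaningReport(n_outliers_dropped=n_dropped)
    return cleaned, report


def interpolate_gaps(
    track: pd.DataFrame, report: CleaningReport | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Fill interior NaN gaps by per-coordinate linear interpolation.

    No extrapolation: leading/trailing frames in which any coordinate is
    missing are trimmed and noted in the report.
    """
    _validate_track(track)
    report = report or CleaningReport()
    coord_cols = [f"{p}_{c}" for p in BODY_PARTS for c in "xy"]
    any_missing = track[coord_cols].isna().any(axis=1).to_numpy()
    present = ~any_missing
    if not present.any():
        raise ValueError("no complete frames to anchor interpolation")
    first, last = np.argmax(present), len(present) - 1 - np.argmax(present[::-1])
    report.n_trimmed_leading = int(first)
    report.n_trimmed_trailing = int(len(present) - 1 - last)
    out = track.iloc[first : last + 1].copy()
    n_gap = int(out[coord_cols].isna().to_numpy().any(axis=1).sum())
    out[coord_cols] = out[coord_cols].interpolate(method="linear", limit_area="inside")
    report.n_interpolated = n_gap
    return out.reset_index(drop=True), report


def savgol_smooth(series, order: int = 5, window: int = 29):
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Applied per coordinate column when given a pose-track DataFrame,
    otherwise along the first axis of an array.  The filter reproduces
    polynomials up to ``order`` exactly, so genuine smooth motion passes
    through while frame-to-frame tracker jitter is attenuated.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if isinstance(series, pd.DataFrame):
        n = len(series)
        if n < window:
            raise ValueError(
                f"series length {n} < window {window}; shorten the window"
            )
        out = series.copy()
        cols = [f"{p}_{c}" for p in BODY_PARTS for c in "xy" if f"{p}_{c}" in series]
        for col in cols:
            out[col] = savgol_filter(series[col].to_numpy(dtype=float), window, order)
        return out
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] < window:
        raise ValueError(
            f"series length {arr.shape[0]} < window {window}; shorten the window"
        )
    return savgol_filter(arr, window, order, axis=0)


def derive_kinematics(
    track: pd.DataFrame, frame_rate_hz: float, px_per_cm: float
) -> pd.DataFrame:
    """Per-frame body center, body axis, heading, heading offset, speed.

    Expects a cleaned, smoothed track.  The mantle point enters only to pick
    the sign of the body-axis normal (``axis . (center - mantle) > 0``).
    The heading at frame *t* is the direction of the center displacement
    from frame *t-1* to *t*; it is NaN on the first frame and whenever the
    displacement is below ``HEADING_EPSILON_PX``.
    """
    _validate_track(track)
    eyeL = track[["eyeL_x", "eyeL_y"]].to_numpy(dtype=float)
    eyeR = track[["eyeR_x", "eyeR_y"]].to_numpy(dtype=float)
    mantle = track[["mantle_x", "mantle_y"]].to_numpy(dtype=float)
    center = 0.5 * (eyeL + eyeR)

    eye_vec = eyeR - eyeL
    eye_len = np.linalg.norm(eye_vec, axis=1)
    # two candidate normals of the inter-eye line; pick the one facing away
    # from the mantle tip
    normal = np.stack([-eye_vec[:, 1], eye_vec[:, 0]], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = normal / eye_len[:, None]
    flip = np.einsum("ij,ij->i", normal, center - mantle) < 0
    normal[flip] *= -1.0
    body_axis_deg = vector_angle_deg(normal)
    body_axis_deg[eye_len == 0] = np.nan  # coincident eyes: axis undefined

    disp = np.diff(center, axis=0)
    disp_norm = np.linalg.norm(disp, axis=1)
    heading_deg = np.full(len(center), np.nan)
    defined = disp_norm >= HEADING_EPSILON_PX
    heading_deg[1:][defined] = vector_angle_deg(disp[defined])
    speed = np.concatenate([[np.nan], disp_norm]) / px_per_cm * frame_rate_hz

    heading_offset_deg = signed_offset_deg(body_axis_deg, heading_deg)
    heading_offset_deg[np.isnan(body_axis_deg) | np.isnan(heading_deg)] = np.nan

    return pd.DataFrame(
        {
            "frame": track["frame"].to_numpy(),
            "time_s": track["frame"].to_numpy(dtype=float) / frame_rate_hz,
            "center_x_px": center[:, 0],
            "center_y_px": center[:, 1],
            "center_x_cm": center[:, 0] / px_per_cm,
            "center_y_cm": center[:, 1] / px_per_cm,
            "body_axis_deg": body_axis_deg,
            "heading_deg": heading_deg,
            "heading_offset_deg": heading_offset_deg,
            "speed_cm_s": speed,
        }
    )


def speed_zscore(speeds) -> np.ndarray:
    """Standardize one individual's speeds: (v - mean) / sd, population sd.

    NaN frames (undefined speed) are excluded from the mean/sd and stay NaN
    in the output.
    """
    v = np.asarray(speeds, dtype=float)
    defined = ~np.isnan(v)
    if defined.sum() < 2:
        raise ValueError("need >= 2 frames with defined speed")
    mu = v[defined].mean()
    sd = v[defined].std(ddof=0)
    if sd == 0:
        raise ValueError("zero speed standard deviation; z-score undefined")
    return (v - mu) / sd


def clean_pose_track(
    track: pd.DataFrame,
    mad_k: float = 5.0,
    savgol_order: int = 5,
    savgol_window: int = 29,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Full cleaning chain: outlier drop -> interpolate -> Savgol smooth."""
    dropped, report = detect_and_drop_outliers(track, mad_k=mad_k)
    filled, report = interpolate_gaps(dropped, report)
    smoothed = savgol_smooth(filled, order=savgol_order, window=savgol_window)
    report.filter_params = {"order": savgol_order, "window": savgol_window}
    return smoothed, report
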