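"""Condition labeling, FAAM segmentation and behavioral-window embedding.

Trajectory spans in the plume are assigned to one of three conditions:
*chemosensory tracking* (bait present, approach ends in feeding), *food not
eaten* (bait present, plume entered, and that bait placement never eaten on
any approach), and *no food* (no bait in the flume, hence no odor plume to
track).  Fast arm-aligned motions (FAAM) — lunges in which one extended arm
lines up with the velocity vector — are segmented by per-frame kinematic
criteria: speed z-score between 1.5 and 4.0, nearest-arm heading offset
within +/-5 degrees, sustained for at least 0.5 s.  One-second windows of
the two criterion signals can be embedded to 2-D for visualization of
behavioral structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import unit_vector_deg

FAAM_Z_LO = 1.5
FAAM_Z_HI = 4.0
FAAM_ANGLE_ABS_MAX_DEG = 5.0
FAAM_MIN_DURATION_S = 0.5

CONDITIONS = ("chemosensory_tracking", "food_not_eaten", "no_food")


@dataclass
class ConditionSegment:
    """One plume-visit span labeled with its behavioral condition."""

    condition: str
    start_frame: int
    end_frame: int  # exclusive
    individual: str = "octo0"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.end_frame <= self.start_frame:
            raise ValueError("empty segment")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class FaamEvent:
    """One fast arm-aligned motion bout."""

    start_frame: int
    end_frame: int  # exclusive
    duration_s: float
    mean_direction: tuple[float, float] | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def segment_conditions(
    plume_intervals: list[tuple[int, int]],
    bait_placements: list[tuple[int, int]],
    feeding_frames: list[int],
    individual: str = "octo0",
) -> list[ConditionSegment]:
    """Assign in-plume intervals to the three behavioral conditions.

    ``plume_intervals`` are [start, end) frame spans with the animal inside
    the plume polygon; ``bait_placements`` are [start, end) spans with bait
    in the flume (must not overlap); ``feeding_frames`` are annotated eating
    frames.

    Rules: a plume visit containing a feeding frame is *chemosensory
    tracking* (span truncated at the feeding frame); a visit during a bait
    placement whose bait was eventually eaten on some later approach is
    excluded (it is neither a successful track nor evidence of no
    appetite); a visit during a never-eaten placement is *food not eaten*;
    a visit with no bait present is *no food*.
    """
    placements = sorted(bait_placements)
    for (s1, e1), (s2, e2) in zip(placements, placements[1:]):
        if s2 < e1:
            raise ValueError("bait placements overlap")
    feeding = np.asarray(sorted(feeding_frames), dtype=int)
    segments: list[ConditionSegment] = []
    for start, end in plume_intervals:
        placement = next((p for p in placements if p[0] < end and start < p[1]), None)
        if placement is None:
            segments.append(ConditionSegment("no_food", start, end, individual))
            continue
        ps, pe = placement
        fed_here = feeding[(feeding >= start) & (feeding < end)]
        if fed_here.size:
            segments.append(
                ConditionSegment(
                    "chemosensory_tracking",
                    start,
                    int(fed_here[0]) + 1,
                    individual,
                    extras={"feeding_frame": int(fed_here[0])},
                )
            )
            continue
        placement_fed = feeding[(feeding >= ps) & (feeding < pe)]
        if placement_fed.size:
            # bait eventually eaten on another approach: excluded from
            # "food not eaten" by definition
            continue
        segments.append(ConditionSegment("food_not_eaten", start, end, individual))
    return segments


def detect_faam(
    speed_z: np.ndarray,
    nearest_arm_offset_deg: np.ndarray,
    frame_rate_hz: float = 10.0,
    z_lo: float = FAAM_Z_LO,
    z_hi: float = FAAM_Z_HI,
    angle_abs_max_deg: float = FAAM_ANGLE_ABS_MAX_DEG,
    min_duration_s: float = FAAM_MIN_DURATION_S,
    heading_deg: np.ndarray | None = None,
    frame_offset: int = 0,
) -> list[FaamEvent]:
    """Segment FAAM bouts from the two criterion series.

    A frame qualifies when ``z_lo <= speed_z <= z_hi`` and
    ``|nearest_arm_offset| <= angle_abs_max_deg``; frames with an undefined
    heading or no detected arm (NaN in either series) never qualify.
    Events are maximal contiguous runs of qualifying frames lasting at
    least ``min_duration_s`` — no gap tolerance, one disqualifying frame
    splits a bout.  If ``heading_deg`` is given, each event carries the
    normalized mean of its per-frame unit heading vectors.
    """
    z = np.asarray(speed_z, dtype=float)
    a = np.asarray(nearest_arm_offset_deg, dtype=float)
    if z.shape != a.shape:
        raise ValueError("speed_z and nearest_arm_offset must be aligned")
    ok = np.isfinite(z) & np.isfinite(a) & (z >= z_lo) & (z <= z_hi) & (np.abs(a) <= angle_abs_max_deg)
    min_frames = int(np.ceil(min_duration_s * frame_rate_hz))
    events: list[FaamEvent] = []
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        if j - i >= min_frames:
            mean_dir = None
            if heading_deg is not None:
                h = np.asarray(heading_deg, dtype=float)[i:j]
                vecs = unit_vector_deg(h[np.isfinite(h)])
                if len(vecs):
                    m = vecs.mean(axis=0)
                    norm = np.linalg.norm(m)
                    if norm > 0:
                        mean_dir = tuple(m / norm)
            events.append(
                FaamEvent(
                    start_frame=frame_offset + i,
                    end_frame=frame_offset + j,
                    duration_s=(j - i) / frame_rate_hz,
                    mean_direction=mean_dir,
                )
            )
        i = j
    return events


def faam_statistics(
    events: list[FaamEvent],
    segments: list[ConditionSegment],
) -> pd.DataFrame:
    """Per-condition FAAM counts, percent time, and mean direction.

    An event belongs to a condition segment when its start frame falls in
    the segment span.  Percent time is FAAM frames inside the condition's
    spans divided by total condition frames, x100.  The condition mean
    direction is the normalized mean of the events' mean direction
    vectors; conditions with no frames are reported with NaN statistics.
    """
    rows = []
    for cond in CONDITIONS:
        spans = [(s.start_frame, s.end_frame) for s in segments if s.condition == cond]
        total_frames = sum(e - s for s, e in spans)
        cond_events = [
            ev for ev in events if any(s <= ev.start_frame < e for s, e in spans)
        ]
        faam_frames = 0
        for ev in cond_events:
            faam_frames += sum(
                max(0, min(ev.end_frame, e) - max(ev.start_frame, s)) for s, e in spans
            )
        if total_frames == 0:
            pct = np.nan
        else:
            pct = 100.0 * faam_frames / total_frames
        dirs = np.array([ev.mean_direction for ev in cond_events if ev.mean_direction is not None])
        if len(dirs):
            m = dirs.mean(axis=0)
            norm = np.linalg.norm(m)
            mean_dir = tuple(m / norm) if norm > 0 else (np.nan, np.nan)
        else:
            mean_dir = (np.nan, np.nan)
        rows.append(
            {
                "condition": cond,
                "n_events": len(cond_events),
                "n_condition_frames": total_frames,
                "faam_percent_time": pct,
                "mean_direction_x": mean_dir[0],
                "mean_direction_y": mean_dir[1],
            }
        )
    return pd.DataFrame(rows)


def embed_windows(
    speed_z: np.ndarray,
    nearest_arm_offset_deg: np.ndarray,
    frame_rate_hz: float = 10.0,
    window_s: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D embedding of one-second kinematic windows.

    The two criterion series are chopped into non-overlapping complete
    windows; each window's concatenated samples are z-normalized feature-
    wise across all windows and embedded with UMAP (fixed ``random_state``
    for determinism).  Windows containing NaN frames are dropped.  Returns
    a DataFrame with window start frames and embedding coordinates.
    """
    z = np.asarray(speed_z, dtype=float)
    a = np.asarray(nearest_arm_offset_deg, dtype=float)
    if z.shape != a.shape:
        raise ValueError("series must be aligned")
    w = int(round(window_s * frame_rate_hz))
    n_win = len(z) // w
    feats = []
    starts = []
    for k in range(n_win):
        zz = z[k * w : (k + 1) * w]
        aa = a[k * w : (k + 1) * w]
        if np.isfinite(zz).all() and np.isfinite(aa).all():
            feats.append(np.concatenate([zz, aa]))
            starts.append(k * w)
    feats = np.asarray(feats)
    if len(feats) < n_neighbors + 2:
        raise ValueError(
            f"need at least {n_neighbors + 2} complete windows, got {len(feats)}"
        )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - mu) / sd
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(feats)
    return pd.DataFrame(
        {
            "window_start_frame": starts,
            "umap_x": coords[:, 0],
            "umap_y": coords[:, 1],
        }
    )
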