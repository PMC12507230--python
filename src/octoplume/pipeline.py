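"""End-to-end orchestration: config, demo data, and the full analysis run.

A run consumes a pose-track CSV, a rendered video stack, a plume video (or
a plume-polygon vertex file), bait-schedule and feeding annotations, and
produces kinematics, arm tables, crossing events, condition segments, FAAM
statistics and null-model test results, bundled into a machine-readable
summary keyed by a hash of the exact configuration used.

`make_demo_dataset` builds a complete synthetic experiment — a
plume-tracking feeding session with lunges, a plume-visualization video,
and a set of three-station approach trajectories — so the pipeline can be
exercised with no external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arms as arms_mod
from . import behavior, io, kinematics, regions, stats
from .angles import vector_angle_deg, wrap_deg
from .synthetic import (
    DEFAULT_ARM_ANGLES,
    GroundTruth,
    SyntheticScene,
    render_octopus_frames,
    simulate_motion,
    simulate_plume_video,
    simulate_pose_track,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, scene parameters and algorithm parameters for one run."""

    out_dir: str
    paths: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def to_yaml(self, path) -> None:
        # round-trip through JSON to coerce numpy scalars to plain types
        plain = json.loads(json.dumps(self.as_dict(), default=float))
        Path(path).write_text(yaml.safe_dump(plain, sort_keys=True))

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "paths": self.paths,
            "scene": self.scene,
            "params": self.params,
            "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# demo dataset


def _session_truth(
    scene: SyntheticScene,
    station_cm: tuple[float, float],
    seed: int,
    n_lunges: int = 3,
    wander_s: float = 12.0,
    start_offset_cm: float = 95.0,
) -> tuple[GroundTruth, dict]:
    """A scripted feeding session with known structure.

    Phase A: upstream plume-tracking approach toward the baited station
    with ``n_lunges`` fast arm-aligned lunges aimed along the travel
    direction, ending inside the target circle, followed by a feeding
    pause.  Phase B: the animal leaves downstream and makes one bait-free
    plume visit.  Returns the ground truth plus annotation dict (bait
    placements, feeding frames).
    """
    rng = np.random.default_rng(seed)
    rate = scene.frame_rate_hz
    dt = 1.0 / rate
    station = np.asarray(station_cm, float)
    pos = station + np.array([-start_offset_cm, 6.0])  # downstream, near plume axis
    centers = [pos.copy()]
    intervals: list[tuple[int, int]] = []
    base_speed, lunge_speed = 2.0, 8.0
    lunge_len = int(round(1.2 * rate))
    next_lunge_gap = int((2.5 + rng.uniform(0, 1.5)) * rate)
    since_lunge = 0
    in_lunge = 0
    i = 0
    # phase A: approach until inside a 12 cm standoff of the station
    while np.linalg.norm(pos - station) > 12.0 and i < 5000:
        to_station = station - pos
        d = to_station / np.linalg.norm(to_station)
        if in_lunge > 0:
            v = lunge_speed * d
            in_lunge -= 1
        elif since_lunge >= next_lunge_gap and len(intervals) < n_lunges:
            intervals.append((i + 1, i + 1 + lunge_len))
            in_lunge = lunge_len - 1
            since_lunge = 0
            next_lunge_gap = int((2.5 + rng.uniform(0, 1.5)) * rate)
            v = lunge_speed * d
        else:
            zig = np.sin(2 * np.pi * i / (3.0 * rate))
            cross = np.array([-d[1], d[0]])
            v = base_speed * d + 2.0 * zig * cross + 0.3 * rng.standard_normal(2)
            since_lunge += 1
        pos = pos + v * dt
        centers.append(pos.copy())
        i += 1
    # feeding pause at the station
    feeding_frame = i + int(0.5 * rate)
    pause = int(2.0 * rate)
    for _ in range(pause):
        centers.append(pos.copy())
        i += 1
    # phase B: leave downstream, wander outside, one bait-free plume visit
    bait_end = i + int(0.5 * rate)
    leave_dir = np.array([-1.0, 0.6])
    leave_dir /= np.linalg.norm(leave_dir)
    for _ in range(int(6.0 * rate)):
        pos = pos + 3.0 * leave_dir * dt + 0.1 * rng.standard_normal(2)
        centers.append(pos.copy())
        i += 1
    # re-approach the plume axis slowly, without bait
    target = station + np.array([-25.0, -2.0])
    for _ in range(int(wander_s * rate)):
        to_t = target - pos
        n = np.linalg.norm(to_t)
        d = to_t / n if n > 1.0 else np.zeros(2)
        pos = pos + 2.5 * d * dt + 0.3 * rng.standard_normal(2)
        centers.append(pos.copy())
        i += 1
    centers = np.asarray(centers)
    L, W = scene.arena_size_cm
    centers[:, 0] = np.clip(centers[:, 0], 20.0, L - 20.0)
    centers[:, 1] = np.clip(centers[:, 1], 20.0, W - 20.0)

    n = len(centers)
    disp = np.diff(centers, axis=0)
    heading = np.zeros(n)
    heading[1:] = vector_angle_deg(disp)
    moving = np.concatenate([[False], np.linalg.norm(disp, axis=1) > 1e-6])
    for j in range(1, n):
        if not moving[j]:
            heading[j] = heading[j - 1]
    heading[0] = heading[1] if n > 1 else 0.0
    axis = np.empty(n)
    axis[0] = heading[0]
    for j in range(1, n):
        axis[j] = axis[j - 1] + 0.35 * wrap_deg(heading[j] - axis[j - 1]) + rng.normal(0, 0.5)
    axis = wrap_deg(axis)
    arm_angles = wrap_deg(
        DEFAULT_ARM_ANGLES[None, :] + rng.normal(0, 1.5, size=(n, DEFAULT_ARM_ANGLES.size))
    )
    intervals = [iv for iv in intervals if iv[1] <= n]
    for s0, e0 in intervals:
        arm_angles[s0:e0, 0] = wrap_deg(
            heading[s0:e0] - axis[s0:e0] + rng.normal(0, 0.5, size=e0 - s0).clip(-1.5, 1.5)
        )
    truth = GroundTruth(
        true_center_cm=centers,
        true_body_axis_deg=axis,
        true_arm_angles_deg=arm_angles,
        true_faam_intervals=intervals,
        motion_model_label="scripted_session",
        frame_rate_hz=rate,
    )
    annotations = {
        "bait_placements": [[0, int(bait_end)]],
        "feeding_frames": [int(feeding_frame)],
    }
    return truth, annotations


def _three_station_tracks(
    rect: regions.StationRectangle,
    scene: SyntheticScene,
    n_tracks: int,
    seed: int,
) -> pd.DataFrame:
    """Approach trajectories toward the station rectangle (cm, pose-free).

    Most start downstream (upstream surge-cast approaches, odor-gated);
    a minority start upstream and drift down with the flow.
    """
    rng = np.random.default_rng(seed)
    cx, cy = rect.center
    rows = []
    for t in range(n_tracks):
        downstream = rng.random() < 0.75
        y0 = cy + rng.uniform(-1.6, 1.6) * rect.square_size
        if downstream:
            start = (cx - rng.uniform(45, 60), y0)
            model = "surge_cast"
        else:
            start = (cx + rng.uniform(45, 60), y0)
            model = "random_walk"
        truth = simulate_motion(
            model,
            duration_s=60.0,
            seed=int(rng.integers(2**31 - 1)),
            scene=scene,
            params={"start_cm": start, "wall_margin_cm": 10.0},
        )
        c = truth.true_center_cm
        if not downstream:
            # push a drifting track downstream through the rectangle
            drift = np.linspace(0, 1, len(c))[:, None] * np.array([-70.0, 0.0])
            c = c + drift
            L, W = scene.arena_size_cm
            c[:, 0] = np.clip(c[:, 0], 5.0, L - 5.0)
            c[:, 1] = np.clip(c[:, 1], 5.0, W - 5.0)
        for f, (x, y) in enumerate(c):
            rows.append({"track_id": t, "frame": f, "center_x_cm": x, "center_y_cm": y})
    return pd.DataFrame(rows)


def make_demo_dataset(seed: int, scale: str, out_dir) -> RunConfig:
    """Generate a complete synthetic experiment on disk.

    ``tiny`` keeps the total frame count under 500 for smoke tests;
    ``desk`` is a few minutes of video, sized for a desktop CPU.
    """
    if scale not in ("tiny", "desk"):
        raise ValueError("scale must be 'tiny' or 'desk'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiny = scale == "tiny"
    # half-resolution render for the session video; coarse for plume video
    scene = SyntheticScene(rng_seed=seed)
    plume_scene = SyntheticScene(px_per_cm=2.0, rng_seed=seed + 1)
    station = (150.0, 58.0)
    n_lunges = 3 if tiny else 6
    truth, annotations = _session_truth(
        scene,
        station,
        seed,
        n_lunges=n_lunges,
        wander_s=8.0 if tiny else 40.0,
        start_offset_cm=55.0 if tiny else 95.0,
    )
    frames = render_octopus_frames(scene, truth)
    pose = simulate_pose_track(
        truth, scene.px_per_cm, jitter_sd_px=1.0, outlier_rate=0.02, seed=seed + 2
    )
    n_plume = 150 if tiny else 600
    plume = simulate_plume_video(plume_scene, station, n_frames=n_plume, seed=seed + 3)
    rect = regions.StationRectangle(center=(140.0, 58.0), square_size=24.0, bait_index=1)
    tracks3 = _three_station_tracks(rect, scene, n_tracks=8 if tiny else 24, seed=seed + 4)

    io.write_tiff_stack(out / "frames.tif", frames)
    io.write_tiff_stack(out / "plume.tif", plume)
    io.write_pose_csv(out / "pose.csv", pose)
    io.write_json(out / "annotations.json", annotations)
    io.write_json(out / "truth.json", truth.to_dict())
    tracks3.to_csv(out / "three_station_tracks.csv", index=False)

    config = RunConfig(
        out_dir=str(out / "results"),
        paths={
            "pose_csv": str(out / "pose.csv"),
            "frames_tiff": str(out / "frames.tif"),
            "plume_tiff": str(out / "plume.tif"),
            "annotations_json": str(out / "annotations.json"),
            "three_station_csv": str(out / "three_station_tracks.csv"),
        },
        scene={
            "frame_rate_hz": scene.frame_rate_hz,
            "px_per_cm": scene.px_per_cm,
            "plume_px_per_cm": plume_scene.px_per_cm,
            "flow_direction": list(scene.flow_direction),
            "arena_size_cm": list(scene.arena_size_cm),
            "station_cm": list(station),
            "target_radius_cm": regions.TARGET_RADIUS_CM,
            "station_rect": {
                "center": list(rect.center),
                "square_size": rect.square_size,
                "bait_index": rect.bait_index,
            },
        },
        params={
            "mad_k": 5.0,
            "savgol_order": 5,
            "savgol_window": 29,
            "crop_size": 300,
            "background": "none" if tiny else "dynamic",
            # 600 px at the camera's full 1920 px width = 300 px at this
            # half-scale render; the tiny session covers less ground, so a
            # shorter exclusion distance still guarantees clean backgrounds
            "min_dist_px": 150.0 if tiny else 300.0,
            "plume_percentile": 98.0,
            "reset_s": 5.0,
            "embed": not tiny,
        },
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config


# ---------------------------------------------------------------------------
# full pipeline


def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True."""
    out = []
    m = np.asarray(mask, dtype=bool)
    i = 0
    n = len(m)
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute kinematics -> arms -> regions -> behavior -> stats.

    Writes kinematics, arm, event and segment tables plus a summary JSON
    into ``config.out_dir`` and returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.scene
    p = config.params
    rate = float(sc["frame_rate_hz"])
    ppc = float(sc["px_per_cm"])
    flow = tuple(sc.get("flow_direction", (-1.0, 0.0)))
    import time as _time

    summary: dict = {"config_hash": config.hash(), "stages": []}
    _t = {"last": _time.time(), "name": None}

    def stage(name):
        # stage timings go to the log, not the summary, so reruns with the
        # same config produce byte-identical summaries
        now = _time.time()
        if _t["name"] is not None:
            logger.info("stage %s took %.2f s", _t["name"], now - _t["last"])
        _t["last"], _t["name"] = now, name
        summary["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    # --- kinematics ---
    stage("kinematics")
    pose = io.read_pose_csv(config.paths["pose_csv"])
    cleaned, report = kinematics.clean_pose_track(
        pose,
        mad_k=float(p.get("mad_k", 5.0)),
        savgol_order=int(p.get("savgol_order", 5)),
        savgol_window=int(p.get("savgol_window", 29)),
    )
    kin = kinematics.derive_kinematics(cleaned, rate, ppc)
    kin["speed_z"] = kinematics.speed_zscore(kin["speed_cm_s"].to_numpy())
    summary["cleaning"] = report.to_dict()

    # --- arm detection ---
    stage("arm_detection")
    frames = io.read_tiff_stack(config.paths["frames_tiff"])
    frames = frames[kin["frame"].to_numpy()]  # align to surviving frames
    centers = kin[["center_x_px", "center_y_px"]].to_numpy()
    if p.get("background", "dynamic") == "dynamic":
        try:
            frames_sub = arms_mod.BackgroundSubtractedStack(
                frames, centers, min_dist_px=float(p.get("min_dist_px", 600.0))
            )
        except ValueError as err:
            logger.warning("dynamic background unavailable (%s); using raw frames", err)
            frames_sub = frames
    else:
        frames_sub = frames
    profiles, geometry, arm_table = arms_mod.arm_profiles_for_track(
        frames_sub, kin, ppc, crop_size=int(p.get("crop_size", 600))
    )
    kin = kin.merge(arm_table, on="frame", how="left")
    io.write_json(out / "body_geometry.json", geometry.to_dict())

    # --- regions ---
    stage("regions")
    station = tuple(sc["station_cm"])
    circle = regions.TargetCircle(center=station, radius=float(sc.get("target_radius_cm", 14.0)))
    if "plume_polygon_json" in config.paths:
        plume_poly = io.read_polygon(config.paths["plume_polygon_json"])
    else:
        plume_stack = io.read_tiff_stack(config.paths["plume_tiff"])
        var_img = regions.variance_projection(plume_stack)
        plume_poly = regions.threshold_to_polygon(
            var_img,
            px_per_cm=float(sc.get("plume_px_per_cm", ppc)),
            source_cm=station,
            percentile=float(p.get("plume_percentile", 99.0)),
        )
    region_set = regions.RegionSet(
        target_circle=circle,
        plume=plume_poly,
        flow_direction=flow,
        arena_size_cm=tuple(sc.get("arena_size_cm", (185.0, 116.0))),
    )
    io.write_polygon(out / "plume_polygon.json", plume_poly)
    reset_s = float(p.get("reset_s", 30.0))
    circle_events = regions.first_crossing(kin, circle, "target_circle", rate, reset_s=reset_s)
    for ev in circle_events:
        regions.classify_approach(ev, region_set)
    n_inside = sum(ev.label == "inside_plume" for ev in circle_events)
    n_outside = sum(ev.label == "outside_plume" for ev in circle_events)
    arc = regions.expected_ratios(region_set, "plume_arc")
    summary["approaches"] = {
        "inside_plume": n_inside,
        "outside_plume": n_outside,
        "expected_inside_ratio": arc["inside_plume"],
    }
    if n_inside + n_outside > 0:
        summary["plume_binomial"] = stats.binomial_test_result(
            n_inside, n_inside + n_outside, arc["inside_plume"]
        ).to_dict()

    # --- behavior ---
    stage("behavior")
    pts = kin[["center_x_cm", "center_y_cm"]].to_numpy()
    from shapely.geometry import Point

    poly = plume_poly.shapely
    in_plume = np.array([poly.covers(Point(q)) for q in pts])
    plume_intervals = _intervals_from_mask(in_plume)
    ann = io.read_json(config.paths["annotations_json"])
    segments = behavior.segment_conditions(
        plume_intervals,
        [tuple(b) for b in ann["bait_placements"]],
        list(ann["feeding_frames"]),
    )
    faam_events = behavior.detect_faam(
        kin["speed_z"].to_numpy(),
        kin["nearest_arm_offset_deg"].to_numpy(),
        rate,
        heading_deg=kin["heading_deg"].to_numpy(),
    )
    faam_stats = behavior.faam_statistics(faam_events, segments)
    summary["faam"] = {
        "n_events": len(faam_events),
        "per_condition": faam_stats.to_dict(orient="records"),
    }
    if p.get("embed", False):
        try:
            emb = behavior.embed_windows(
                kin["speed_z"].to_numpy(),
                kin["nearest_arm_offset_deg"].to_numpy(),
                rate,
                seed=config.seed,
            )
            emb.to_csv(out / "embedding.csv", index=False)
            summary["embedding"] = {"n_windows": len(emb)}
        except ValueError as err:
            summary["embedding"] = {"skipped": str(err)}

    # --- three-station statistics ---
    if "three_station_csv" in config.paths:
        stage("three_station")
        rect_cfg = sc["station_rect"]
        rect = regions.StationRectangle(
            center=tuple(rect_cfg["center"]),
            square_size=float(rect_cfg["square_size"]),
            bait_index=int(rect_cfg["bait_index"]),
            flow_direction=flow,
        )
        region_set.station_rect = rect
        tracks3 = pd.read_csv(config.paths["three_station_csv"])
        labels = []
        for _, g in tracks3.groupby("track_id"):
            evs = regions.first_crossing(g, rect, "station_rect", rate, reset_s=reset_s)
            for ev in evs:
                labels.append(regions.classify_approach(ev, region_set))
        counts = pd.Series(labels).value_counts().to_dict() if labels else {}
        against = sum(v for k, v in counts.items() if k.startswith("against_flow"))
        with_flow = sum(v for k, v in counts.items() if k.startswith("with_flow"))
        side = counts.get("side", 0)
        total = against + with_flow + side
        ratios = regions.expected_ratios(region_set, "side_partition")
        summary["three_station"] = {
            "counts": counts,
            "against_flow": against,
            "with_flow": with_flow,
            "side": side,
            "expected_against_flow_ratio": ratios["against_flow"],
            "expected_bait_given_against_flow": regions.expected_ratios(
                region_set, "stations_given_against_flow"
            )["bait"],
        }
        if total:
            summary["three_station"]["against_flow_binomial"] = stats.binomial_test_result(
                against, total, ratios["against_flow"]
            ).to_dict()
            s = rect.square_size
            summary["three_station"]["chisq_sides"] = stats.chisq_uniform(
                [against, with_flow, side], [3 * s, 3 * s, 2 * s]
            ).to_dict()
        bait_against = counts.get("against_flow:bait", 0)
        if against:
            summary["three_station"]["bait_given_against_binomial"] = (
                stats.binomial_test_result(bait_against, against, 1.0 / 3.0).to_dict()
            )

    # --- outputs ---
    stage("write_outputs")
    kin.to_csv(out / "kinematics.csv", index=False)
    pd.DataFrame(
        [
            {
                "frame": ev.frame,
                "x_cm": ev.point[0],
                "y_cm": ev.point[1],
                "region": ev.region_id,
                "label": ev.label,
                "started_inside": ev.started_inside,
            }
            for ev in circle_events
        ]
    ).to_csv(out / "crossing_events.csv", index=False)
    pd.DataFrame(
        [
            {
                "condition": s.condition,
                "start_frame": s.start_frame,
                "end_frame": s.end_frame,
            }
            for s in segments
        ]
    ).to_csv(out / "condition_segments.csv", index=False)
    pd.DataFrame(
        [
            {
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "duration_s": ev.duration_s,
            }
            for ev in faam_events
        ]
    ).to_csv(out / "faam_events.csv", index=False)
    logger.info("stage %s took %.2f s", _t["name"], _time.time() - _t["last"])
    io.write_json(out / "summary.json", summary)
    return summary
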