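"""Synthetic flume recordings with known ground truth.

Emulates the statistical structure of the study recordings — 10 Hz
near-infrared monochrome video of a benthic octopus in a 185 x 116 cm
recirculating flume — so the whole analysis chain can be exercised and
validated without raw footage.  Everything is a pure function of its seed
and parameters.

The generators produce:

* rendered frames: a bright body blob with mantle, two eye maxima, and
  eight tapering arms at known angles on a textured background;
* pose tracks: the true eye/mantle geometry plus isotropic Gaussian jitter
  and sparse teleport outliers, mimicking markerless pose-estimation error;
* motion models: stationary, smooth random walk, surge/cast (odor-gated
  rheotaxis: upstream surges alternating with cross-stream casts), and
  lunges in which one arm aligns with the velocity (fast arm-aligned
  motion, FAAM);
* a particle-advection plume video: filaments released at the source are
  advected by mean flow plus a shared meander and per-particle diffusion,
  producing downstream widening and intermittent pixel time series.

Coordinates are arena-frame cm (x upstream, y across-stream, flow toward
-x); rendered images are indexed ``[row, col]`` with ``col = x * px_per_cm``
and ``row = y * px_per_cm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import unit_vector_deg, wrap_deg

ARENA_SIZE_CM = (185.0, 116.0)
DEFAULT_RENDER_WIDTH_PX = 960  # half the 1920 px camera width


@dataclass
class SyntheticScene:
    """Arena, optics and timing for one synthetic recording."""

    arena_size_cm: tuple[float, float] = ARENA_SIZE_CM
    px_per_cm: float = DEFAULT_RENDER_WIDTH_PX / ARENA_SIZE_CM[0]
    frame_rate_hz: float = 10.0
    flow_direction: tuple[float, float] = (-1.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        f = np.asarray(self.flow_direction, dtype=float)
        n = np.linalg.norm(f)
        if n == 0:
            raise ValueError("flow_direction must be a nonzero vector")
        self.flow_direction = tuple(f / n)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of rendered frames."""
        L, W = self.arena_size_cm
        return (int(round(W * self.px_per_cm)), int(round(L * self.px_per_cm)))


@dataclass(frozen=True)
class BodyPlan:
    """Rendered octopus geometry (cm).  Shared by renderer and pose model."""

    eye_separation_cm: float = 3.0
    mantle_length_cm: float = 4.0  # eye midpoint -> mantle tip
    body_offset_cm: float = 0.0  # body disc centered on the eye midpoint
    body_sigma_along_cm: float = 3.2
    body_sigma_across_cm: float = 3.2
    arm_root_cm: float = 4.0
    arm_length_cm: float = 18.0
    arm_sigma_root_cm: float = 0.6
    arm_sigma_tip_cm: float = 0.2
    arm_amp_root: float = 90.0
    arm_amp_tip: float = 30.0
    body_amp: float = 230.0
    eye_amp: float = 90.0
    eye_sigma_cm: float = 0.3


DEFAULT_ARM_ANGLES = wrap_deg(22.5 + 45.0 * np.arange(8))


@dataclass
class GroundTruth:
    """Per-frame ground truth for one synthetic trajectory."""

    true_center_cm: np.ndarray  # (n, 2)
    true_body_axis_deg: np.ndarray  # (n,)
    true_arm_angles_deg: np.ndarray  # (n, n_arms), relative to body axis
    true_faam_intervals: list = field(default_factory=list)  # [(start, end)) frames
    motion_model_label: str = "unspecified"
    frame_rate_hz: float = 10.0

    def __post_init__(self):
        self.true_center_cm = np.asarray(self.true_center_cm, dtype=float)
        self.true_body_axis_deg = np.asarray(self.true_body_axis_deg, dtype=float)
        self.true_arm_angles_deg = np.atleast_2d(
            np.asarray(self.true_arm_angles_deg, dtype=float)
        )
        prev_end = -1
        for s, e in self.true_faam_intervals:
            if s <= prev_end or e <= s:
                raise ValueError("FAAM intervals must be ordered and non-overlapping")
            prev_end = e

    @property
    def n_frames(self) -> int:
        return len(self.true_center_cm)

    def true_speed_cm_s(self) -> np.ndarray:
        disp = np.linalg.norm(np.diff(self.true_center_cm, axis=0), axis=1)
        return np.concatenate([[np.nan], disp]) * self.frame_rate_hz

    def eye_mantle_geometry(self, plan: BodyPlan = BodyPlan()):
        """True (eyeL, eyeR, mantle) positions in cm, per frame."""
        axis = unit_vector_deg(self.true_body_axis_deg)
        left = np.stack([-axis[:, 1], axis[:, 0]], axis=1)  # +90 deg of axis
        c = self.true_center_cm
        eyeL = c + 0.5 * plan.eye_separation_cm * left
        eyeR = c - 0.5 * plan.eye_separation_cm * left
        mantle = c - plan.mantle_length_cm * axis
        return eyeL, eyeR, mantle

    def nearest_arm_offset_deg(self, heading_deg: np.ndarray) -> np.ndarray:
        """Per-frame signed offset of the true arm nearest to a heading.

        Arm directions in the arena frame are the true body axis plus the
        true arm angles; the offset convention matches the detector
        (positive CCW of the heading, exact ties broken positive).
        """
        h = np.asarray(heading_deg, dtype=float)
        arm_arena = self.true_body_axis_deg[:, None] + self.true_arm_angles_deg
        # wrap into (-180, 180]
        off = -(((-(arm_arena - h[:, None]) + 180.0) % 360.0) - 180.0)
        out = np.full(len(h), np.nan)
        finite = np.isfinite(h)
        if finite.any():
            a = np.abs(off[finite])
            best = a.min(axis=1)
            # tie toward positive: take max of offsets attaining min |.|
            masked = np.where(np.isclose(a, best[:, None]), off[finite], -np.inf)
            out[finite] = masked.max(axis=1)
        return out

    def to_dict(self) -> dict:
        return {
            "true_center_cm": self.true_center_cm.tolist(),
            "true_body_axis_deg": self.true_body_axis_deg.tolist(),
            "true_arm_angles_deg": self.true_arm_angles_deg.tolist(),
            "true_faam_intervals": [list(iv) for iv in self.true_faam_intervals],
            "motion_model_label": self.motion_model_label,
            "frame_rate_hz": self.frame_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_center_cm=np.asarray(d["true_center_cm"], dtype=float),
            true_body_axis_deg=np.asarray(d["true_body_axis_deg"], dtype=float),
            true_arm_angles_deg=np.asarray(d["true_arm_angles_deg"], dtype=float),
            true_faam_intervals=[tuple(iv) for iv in d["true_faam_intervals"]],
            motion_model_label=d["motion_model_label"],
            frame_rate_hz=d["frame_rate_hz"],
        )


# ---------------------------------------------------------------------------
# rendering


def _render_octopus_patch(
    patch_shape: tuple[int, int],
    origin_px: tuple[float, float],
    center_px: np.ndarray,
    axis_deg: float,
    arm_angles_deg: np.ndarray,
    px_per_cm: float,
    plan: BodyPlan,
) -> np.ndarray:
    """Additive intensity of the animal on a local pixel patch."""
    rows = np.arange(patch_shape[0]) + origin_px[0]
    cols = np.arange(patch_shape[1]) + origin_px[1]
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    s = px_per_cm
    axis = unit_vector_deg(axis_deg)
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    # body blob: anisotropic Gaussian behind the eyes
    bc = center_px - plan.body_offset_cm * s * axis
    u = (xx - bc[0]) * axis[0] + (yy - bc[1]) * axis[1]  # along-axis
    v = -(xx - bc[0]) * axis[1] + (yy - bc[1]) * axis[0]  # across-axis
    # flat silhouette with a sharp logistic edge, like saturated backlit video
    q = np.sqrt(
        (u / (plan.body_sigma_along_cm * s)) ** 2 + (v / (plan.body_sigma_across_cm * s)) ** 2
    )
    out = plan.body_amp / (1.0 + np.exp((q - 1.3) / 0.04))
    # eyes: two sharp maxima symmetric about the axis
    left = np.array([-axis[1], axis[0]])
    for sign in (+1.0, -1.0):
        e = center_px + sign * 0.5 * plan.eye_separation_cm * s * left
        out += plan.eye_amp * np.exp(
            -0.5 * (((xx - e[0]) ** 2 + (yy - e[1]) ** 2) / (plan.eye_sigma_cm * s) ** 2)
        )
    # arms: tapering strokes radiating from near the body at known angles
    r0, r1 = plan.arm_root_cm * s, plan.arm_length_cm * s
    for a in np.atleast_1d(arm_angles_deg):
        d = unit_vector_deg(axis_deg + a)
        t = dx * d[0] + dy * d[1]  # along-arm distance from center
        p = -dx * d[1] + dy * d[0]  # perpendicular distance
        frac = np.clip((t - r0) / (r1 - r0), 0.0, 1.0)
        sigma = (plan.arm_sigma_root_cm + frac * (plan.arm_sigma_tip_cm - plan.arm_sigma_root_cm)) * s
        amp = plan.arm_amp_root + frac * (plan.arm_amp_tip - plan.arm_amp_root)
        on = (t >= r0) & (t <= r1)
        out += np.where(on, amp * np.exp(-0.5 * (p / sigma) ** 2), 0.0)
    return out


def render_octopus_frames(
    scene: SyntheticScene,
    truth: GroundTruth,
    plan: BodyPlan = BodyPlan(),
    background_level: float = 10.0,
    texture_amplitude: float = 3.0,
    noise_amplitude: float = 2.0,
    invert_contrast: bool = False,
) -> np.ndarray:
    """Render monochrome uint8 frames of the animal on a textured background.

    The body is a bright anisotropic Gaussian blob behind the eye midpoint,
    the eyes two sharp local maxima symmetric about the body axis, and the
    eight arms tapering bright strokes at the true arm angles.  A static
    background texture (fixed per video) and per-frame sensor noise are
    added; ``invert_contrast`` flips polarity for footage with a bright
    floor.
    """
    L, W = scene.arena_size_cm
    c = truth.true_center_cm
    if np.any(c[:, 0] < 0) or np.any(c[:, 0] > L) or np.any(c[:, 1] < 0) or np.any(c[:, 1] > W):
        raise ValueError("trajectory leaves the arena; cannot render")
    rng = np.random.default_rng(scene.rng_seed)
    H, Wpx = scene.frame_shape
    from scipy.ndimage import gaussian_filter

    texture = np.zeros((H, Wpx))
    if texture_amplitude > 0:
        texture = gaussian_filter(rng.standard_normal((H, Wpx)), 8.0)
        texture *= texture_amplitude / max(texture.std(), 1e-12)

    s = scene.px_per_cm
    reach_px = int(np.ceil((plan.arm_length_cm + 2.0) * s))
    frames = np.empty((truth.n_frames, H, Wpx), dtype=np.uint8)
    for i in range(truth.n_frames):
        img = background_level + texture
        if noise_amplitude > 0:
            img = img + noise_amplitude * rng.standard_normal((H, Wpx))
        cp = c[i] * s  # (x, y) px
        r_lo = max(0, int(np.floor(cp[1])) - reach_px)
        r_hi = min(H, int(np.ceil(cp[1])) + reach_px)
        c_lo = max(0, int(np.floor(cp[0])) - reach_px)
        c_hi = min(Wpx, int(np.ceil(cp[0])) + reach_px)
        patch = _render_octopus_patch(
            (r_hi - r_lo, c_hi - c_lo),
            (r_lo, c_lo),
            cp,
            truth.true_body_axis_deg[i],
            truth.true_arm_angles_deg[i],
            s,
            plan,
        )
        img[r_lo:r_hi, c_lo:c_hi] += patch
        if invert_contrast:
            img = 255.0 - img
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------------
# pose tracks


def simulate_pose_track(
    truth: GroundTruth,
    px_per_cm: float,
    jitter_sd_px: float = 1.0,
    outlier_rate: float = 0.0,
    outlier_scale_px: float = 300.0,
    seed: int = 0,
    plan: BodyPlan = BodyPlan(),
) -> pd.DataFrame:
    """Pose-estimation output for a ground-truth trajectory.

    True eye/mantle geometry in pixels plus isotropic Gaussian jitter; a
    Bernoulli(``outlier_rate``) subset of frames is teleported by a random
    vector of length ~``outlier_scale_px`` (all parts jointly, mimicking an
    identity swap / detection failure), with depressed confidence.
    """
    if jitter_sd_px < 0:
        raise ValueError("jitter_sd_px must be non-negative")
    if not 0.0 <= outlier_rate < 1.0:
        raise ValueError("outlier_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    eyeL, eyeR, mantle = truth.eye_mantle_geometry(plan)
    n = truth.n_frames
    parts = {"eyeL": eyeL * px_per_cm, "eyeR": eyeR * px_per_cm, "mantle": mantle * px_per_cm}
    confidence = np.full(n, 0.95)
    out = {"frame": np.arange(n)}
    jitter = {p: rng.normal(0.0, 1.0, size=(n, 2)) * jitter_sd_px for p in parts}
    is_outlier = rng.random(n) < outlier_rate
    theta = rng.uniform(0, 2 * np.pi, size=n)
    displacement = (
        np.stack([np.cos(theta), np.sin(theta)], axis=1)
        * outlier_scale_px
        * (0.75 + 0.5 * rng.random((n, 1)))
    )
    for p, xy in parts.items():
        noisy = xy + jitter[p]
        noisy[is_outlier] += displacement[is_outlier]
        out[f"{p}_x"] = noisy[:, 0]
        out[f"{p}_y"] = noisy[:, 1]
    confidence = confidence + rng.normal(0, 0.02, size=n)
    confidence[is_outlier] = 0.3
    out["confidence"] = np.clip(confidence, 0.0, 1.0)
    df = pd.DataFrame(out)
    df.attrs["outlier_frames"] = np.flatnonzero(is_outlier).tolist()
    return df


# ---------------------------------------------------------------------------
# motion models


def _axis_follow(heading_deg: np.ndarray, rng, lag: float = 0.2, noise_deg: float = 2.0):
    """Body axis that smoothly follows the heading with noise."""
    n = len(heading_deg)
    axis = np.empty(n)
    axis[0] = heading_deg[0]
    for i in range(1, n):
        delta = wrap_deg(heading_deg[i] - axis[i - 1])
        axis[i] = axis[i - 1] + lag * delta + rng.normal(0, noise_deg)
    return wrap_deg(axis)


def simulate_motion(
    model: str,
    duration_s: float,
    seed: int = 0,
    scene: SyntheticScene | None = None,
    params: dict | None = None,
) -> GroundTruth:
    """Ground-truth trajectory for one of the four motion models.

    ``stationary``
        fixed center and axis.
    ``random_walk``
        Ornstein-Uhlenbeck velocity, reflected off a wall margin.
    ``surge_cast``
        odor-gated-rheotaxis-like alternation of upstream surges and
        cross-stream casts relative to the scene's flow direction.
    ``faam_lunge``
        slow meander with inserted lunges: constant-direction bouts of
        elevated speed during which one arm is held within a few degrees
        of the velocity direction; lunge spans are recorded in
        ``true_faam_intervals``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    scene = scene or SyntheticScene()
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    rate = scene.frame_rate_hz
    n = int(round(duration_s * rate))
    dt = 1.0 / rate
    L, W = scene.arena_size_cm
    margin = params.pop("wall_margin_cm", 25.0)
    start = np.asarray(params.pop("start_cm", (L / 2, W / 2)), dtype=float)
    arm_jitter = params.pop("arm_jitter_deg", 1.5)
    arms0 = np.asarray(params.pop("arm_angles_deg", DEFAULT_ARM_ANGLES), dtype=float)

    def arm_matrix():
        base = np.tile(arms0, (n, 1))
        if arm_jitter > 0:
            base = base + rng.normal(0, arm_jitter, size=(n, arms0.size))
        return wrap_deg(base)

    if model == "stationary":
        axis0 = params.pop("body_axis_deg", 90.0)
        center = np.tile(start, (n, 1))
        axis = np.full(n, float(axis0))
        return GroundTruth(center, axis, arm_matrix(), [], "stationary", rate)

    if model == "random_walk":
        sigma = params.pop("speed_sigma_cm_s", 2.0)
        beta = params.pop("relaxation", 0.1)
        vel = np.zeros((n, 2))
        center = np.empty((n, 2))
        center[0] = start
        v = np.zeros(2)
        for i in range(1, n):
            v = (1 - beta) * v + sigma * np.sqrt(2 * beta * dt) * rng.standard_normal(2)
            p = center[i - 1] + v * dt
            for d, hi in ((0, L), (1, W)):
                if p[d] < margin or p[d] > hi - margin:
                    v[d] = -v[d]
                    p[d] = np.clip(p[d], margin, hi - margin)
            vel[i] = v
            center[i] = p
        heading = np.rad2deg(np.arctan2(vel[:, 1], vel[:, 0]))
        heading[0] = heading[1] if n > 1 else 0.0
        axis = _axis_follow(heading, rng)
        return GroundTruth(center, axis, arm_matrix(), [], "random_walk", rate)

    if model == "surge_cast":
        surge_speed = params.pop("surge_speed_cm_s", 5.0)
        cast_speed = params.pop("cast_speed_cm_s", 3.0)
        surge_s = params.pop("surge_duration_s", 3.0)
        cast_s = params.pop("cast_duration_s", 4.0)
        upstream = -np.asarray(scene.flow_direction)
        cross = np.array([-upstream[1], upstream[0]])
        center = np.empty((n, 2))
        center[0] = start
        vel = np.zeros((n, 2))
        i = 1
        surging = True
        cast_sign = 1.0
        phase_left = int(surge_s * rate)
        while i < n:
            if phase_left == 0:
                surging = not surging
                if surging:
                    phase_left = int(surge_s * rate * (0.7 + 0.6 * rng.random()))
                else:
                    cast_sign = -cast_sign
                    phase_left = int(cast_s * rate * (0.7 + 0.6 * rng.random()))
            if surging:
                v = surge_speed * upstream
            else:
                v = cast_speed * cast_sign * cross + 0.3 * surge_speed * upstream
            v = v + 0.3 * rng.standard_normal(2)
            p = center[i - 1] + v * dt
            for d, hi in ((0, L), (1, W)):
                if p[d] < margin or p[d] > hi - margin:
                    p[d] = np.clip(p[d], margin, hi - margin)
                    if d == 1:
                        cast_sign = -cast_sign
            vel[i] = v
            center[i] = p
            phase_left -= 1
            i += 1
        heading = np.rad2deg(np.arctan2(vel[:, 1], vel[:, 0]))
        heading[0] = heading[1] if n > 1 else 0.0
        axis = _axis_follow(heading, rng)
        return GroundTruth(center, axis, arm_matrix(), [], "surge_cast", rate)

    if model == "faam_lunge":
        n_lunges = int(params.pop("n_lunges", 3))
        lunge_speed = params.pop("lunge_speed_cm_s", 12.0)
        base_speed = params.pop("base_speed_cm_s", 1.0)
        lunge_s = params.pop("lunge_duration_s", 1.0)
        align_sd = params.pop("align_sd_deg", 0.5)
        lunge_len = max(int(round(lunge_s * rate)), int(np.ceil(0.5 * rate)))
        gap = (n - n_lunges * lunge_len) // (n_lunges + 1)
        if gap < int(2 * rate):
            raise ValueError("duration too short for the requested number of lunges")
        intervals = []
        pos = gap
        for _ in range(n_lunges):
            intervals.append((pos, pos + lunge_len))
            pos += lunge_len + gap
        in_lunge = np.zeros(n, dtype=bool)
        for s0, e0 in intervals:
            in_lunge[s0:e0] = True
        # meander baseline + constant-direction fast bouts; a lunge's
        # direction is chosen at launch so its whole path clears the walls
        # (a real lunge is a committed ballistic motion, not a wall strike)
        base_dir = rng.uniform(-180, 180)
        lunge_dirs: dict = {}
        lunge_reach = lunge_speed * lunge_len * dt
        center = np.empty((n, 2))
        center[0] = start
        heading = np.empty(n)
        heading[0] = base_dir
        for i in range(1, n):
            iv = next((iv for iv in intervals if iv[0] <= i < iv[1]), None)
            if iv is not None:
                if iv not in lunge_dirs:
                    p0 = center[i - 1]
                    d_try = rng.uniform(-180, 180)
                    for _ in range(50):
                        end = p0 + 1.2 * lunge_reach * unit_vector_deg(d_try)
                        if margin <= end[0] <= L - margin and margin <= end[1] <= W - margin:
                            break
                        d_try = rng.uniform(-180, 180)
                    lunge_dirs[iv] = d_try
                d = lunge_dirs[iv]
                speed = lunge_speed
            else:
                base_dir += rng.normal(0, 8.0)
                d = base_dir
                speed = max(base_speed + rng.normal(0, 0.2), 0.1)
            v = speed * unit_vector_deg(d)
            p = center[i - 1] + v * dt
            for dd, hi in ((0, L), (1, W)):
                if p[dd] < margin or p[dd] > hi - margin:
                    p[dd] = np.clip(p[dd], margin, hi - margin)
                    base_dir = rng.uniform(-180, 180)
            center[i] = p
            heading[i] = np.rad2deg(
                np.arctan2(center[i, 1] - center[i - 1, 1], center[i, 0] - center[i - 1, 0])
            )
        axis = _axis_follow(heading, rng, lag=0.15, noise_deg=1.5)
        arms = arm_matrix()
        # hold arm 0 aligned with the velocity during each lunge
        for s0, e0 in intervals:
            aligned = wrap_deg(
                heading[s0:e0] - axis[s0:e0] + rng.normal(0, align_sd, size=e0 - s0).clip(-1.5, 1.5)
            )
            arms[s0:e0, 0] = aligned
        return GroundTruth(center, axis, arms, intervals, "faam_lunge", rate)

    raise ValueError(f"unknown motion model: {model!r}")


# ---------------------------------------------------------------------------
# plume video


def simulate_plume_video(
    scene: SyntheticScene,
    source_cm: tuple[float, float],
    n_frames: int,
    particle_params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Particle-advection plume video (uint8 stack).

    Each frame injects filament particles at the source; particles drift
    with the mean flow, a shared slowly-meandering cross-stream velocity,
    and per-particle diffusion, and are rendered as scattered-light
    Gaussian splats.  The result widens downstream and individual pixels
    see intermittent intensity, like a bead-seeded laser-sheet plume.
    Not a turbulence simulation.
    """
    p = dict(particle_params or {})
    flow_speed = p.pop("flow_speed_cm_s", 2.0)
    inject = int(p.pop("particles_per_frame", 40))
    diffusion = p.pop("diffusion_cm", 0.35)
    meander_sd = p.pop("meander_cm_s", 1.2)
    meander_tau_s = p.pop("meander_tau_s", 3.0)
    splat_sigma_cm = p.pop("splat_sigma_cm", 0.8)
    amp = p.pop("particle_intensity", 25.0)
    background = p.pop("background_level", 5.0)
    L, W = scene.arena_size_cm
    src = np.asarray(source_cm, dtype=float)
    if not (0 <= src[0] <= L and 0 <= src[1] <= W):
        raise ValueError("plume source must lie inside the arena")
    if flow_speed == 0 and diffusion == 0:
        warnings.warn("zero flow and zero diffusion: degenerate plume", stacklevel=2)
    rng = np.random.default_rng(seed)
    dt = 1.0 / scene.frame_rate_hz
    flow = np.asarray(scene.flow_direction)
    cross = np.array([-flow[1], flow[0]])
    H, Wpx = scene.frame_shape
    s = scene.px_per_cm
    from scipy.ndimage import gaussian_filter

    frames = np.empty((n_frames, H, Wpx), dtype=np.uint8)
    particles = np.empty((0, 2))
    meander = 0.0
    alpha = dt / meander_tau_s
    for i in range(n_frames):
        meander = (1 - alpha) * meander + meander_sd * np.sqrt(2 * alpha * dt) * rng.standard_normal()
        if len(particles):
            particles = (
                particles
                + (flow * flow_speed + cross * meander) * dt
                + diffusion * np.sqrt(dt) * rng.standard_normal(particles.shape)
            )
            keep = (
                (particles[:, 0] > 0)
                & (particles[:, 0] < L)
                & (particles[:, 1] > 0)
                & (particles[:, 1] < W)
            )
            particles = particles[keep]
        if inject > 0:
            new = src[None, :] + 0.3 * rng.standard_normal((inject, 2))
            particles = np.vstack([particles, new])
        img = np.zeros((H, Wpx))
        if len(particles):
            px = particles * s  # (x, y) -> col, row
            cols = np.clip(np.round(px[:, 0]).astype(int), 0, Wpx - 1)
            rows = np.clip(np.round(px[:, 1]).astype(int), 0, H - 1)
            np.add.at(img, (rows, cols), 1.0)
            sigma_px = splat_sigma_cm * s
            # scale so one isolated particle contributes ~amp at its center
            img = gaussian_filter(img, sigma_px) * (amp * 2.0 * np.pi * sigma_px**2)
        frames[i] = np.clip(background + img, 0, 255).astype(np.uint8)
    return frames
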