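import numpy as np
import pytest

from octoplume import arms, synthetic as syn


@pytest.fixture(scope="session")
def scene():
    return syn.SyntheticScene(rng_seed=1)


@pytest.fixture(scope="session")
def stationary_truth(scene):
    """One noise-free stationary posture with the default 8 arms."""
    return syn.simulate_motion(
        "stationary",
        duration_s=0.2,
        seed=3,
        scene=scene,
        params={"arm_jitter_deg": 0.0, "body_axis_deg": 37.0},
    )


@pytest.fixture(scope="session")
def rendered_frame(scene, stationary_truth):
    """Clean rendered frame + standardized crop + fitted geometry."""
    frames = syn.render_octopus_frames(
        scene, stationary_truth, noise_amplitude=0.0, texture_amplitude=0.0
    )
    center_px = stationary_truth.true_center_cm[0] * scene.px_per_cm
    std = arms.crop_and_rotate(
        frames[0].astype(float), center_px, stationary_truth.true_body_axis_deg[0], size=300
    )
    geom = arms.fit_bounding_geometry(arms.average_body_image(std))
    return {"frames": frames, "std": std, "geom": geom, "center_px": center_px}


@pytest.fixture(scope="session")
def faam_pipeline_run(scene):
    """Full pose-level run of the FAAM recovery chain on lunge data."""
    from octoplume import behavior, kinematics as K

    truth = syn.simulate_motion(
        "faam_lunge", duration_s=60.0, seed=11, scene=scene, params={"n_lunges": 6}
    )
    pose = syn.simulate_pose_track(
        truth, scene.px_per_cm, jitter_sd_px=1.0, outlier_rate=0.02, seed=7
    )
    cleaned, report = K.clean_pose_track(pose)
    kin = K.derive_kinematics(cleaned, scene.frame_rate_hz, scene.px_per_cm)
    frames = kin["frame"].to_numpy()
    z = np.full(truth.n_frames, np.nan)
    h = np.full(truth.n_frames, np.nan)
    z[frames] = K.speed_zscore(kin["speed_cm_s"].to_numpy())
    h[frames] = kin["heading_deg"].to_numpy()
    nao = truth.nearest_arm_offset_deg(h)
    events = behavior.detect_faam(z, nao, scene.frame_rate_hz, heading_deg=h)
    return {
        "truth": truth,
        "pose": pose,
        "kin": kin,
        "speed_z": z,
        "heading": h,
        "nao": nao,
        "events": events,
        "report": report,
    }
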