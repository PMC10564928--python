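import numpy as np
import pytest

from onhpulse.phantom import (
    PulsationGroundTruth,
    Scene,
    VesselSpec,
    demo_scene,
    render_pulsation_video,
)


@pytest.fixture(scope="session")
def scene():
    return demo_scene()


@pytest.fixture(scope="session")
def small_scene():
    """Compact single-artery/single-vein scene for fast unit tests."""
    vessels = [
        VesselSpec(control_points=((10.0, 30.0), (85.0, 40.0)),
                   width=8.0, contrast=40.0, label="vein", name="v"),
        VesselSpec(control_points=((12.0, 60.0), (88.0, 62.0)),
                   width=6.0, contrast=28.0, label="artery", name="a"),
    ]
    return Scene(vessels=vessels, canvas_size=(96, 96), background=100.0,
                 onh_center=(48.0, 48.0), onh_radius=26.0)


@pytest.fixture(scope="session")
def noiseless_video(scene):
    gt = PulsationGroundTruth(
        A_true=2.0, f_true=72.0, phase_true=0.4, offset_true=100.0,
        drift_slope=0.5, jitter_sd=0.0, noise_sd=0.0,
    )
    return render_pulsation_video(scene, gt, n_frames=72, fps=24.0, seed=0)


@pytest.fixture(scope="session")
def jittered_video(scene):
    gt = PulsationGroundTruth(
        A_true=2.0, f_true=72.0, phase_true=0.4, offset_true=100.0,
        drift_slope=0.5, jitter_sd=1.5, noise_sd=0.1,
    )
    return render_pulsation_video(scene, gt, n_frames=72, fps=24.0, seed=3)


@pytest.fixture(scope="session")
def registered(jittered_video):
    from onhpulse.imgproc import register_sequence

    return register_sequence(jittered_video.seq, max_shift=8)


@pytest.fixture(scope="session")
def waveform_7224():
    """Timestamps of a 24 Hz x 3 s acquisition."""
    return np.arange(72) / 24.0
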