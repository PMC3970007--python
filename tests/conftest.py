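import numpy as np
import pytest

from wormloop.synthetic import make_behavior_scene, make_posture
from wormloop.vision import segment_stack


def ventral_hint_point(posture, s=0.3, depth=0.6):
    """A pixel point on the ventral half of the body at arclength s."""
    sg = posture.arclength_fractions()
    i = int(np.searchsorted(sg, s))
    return (posture.centerline[i]
            + depth * posture.half_width[i] * posture.ventral_side
            * posture.normals()[i])


@pytest.fixture(scope="session")
def forward_scene():
    """200-frame forward crawl: the shared behaviour fixture."""
    return make_behavior_scene(
        length_px=200.0, width_px=20.0, n_frames=200, frame_rate=30.0,
        locomotion_schedule=[(0.3, 10.0)], seed=11)


@pytest.fixture(scope="session")
def forward_segmentation(forward_scene):
    truth0 = forward_scene.truth_postures[0]
    return segment_stack(forward_scene.frames,
                         head_hint=truth0.centerline[0],
                         ventral_hint=ventral_hint_point(truth0))


@pytest.fixture(scope="session")
def straight_posture():
    """Straight worm, 200 px long, 20 px max width, centred in 256x256."""
    return make_posture(200.0, 10.0, amplitude_rad=0.0, center=(128.0, 128.0))
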