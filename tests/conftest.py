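import numpy as np
import pytest

from gaitkit import SkeletonFrame, Tracklet, TrackletDataset
from gaitkit.coco import (JOINT_INDEX, LEFT_ANKLE, LEFT_HIP, LEFT_KNEE,
                          LEFT_SHOULDER, N_JOINTS, RIGHT_ANKLE, RIGHT_HIP,
                          RIGHT_KNEE, RIGHT_SHOULDER)


def make_frame(hips=((90.0, 300.0), (110.0, 300.0)),
               shoulders=((90.0, 150.0), (110.0, 150.0)),
               confidence=0.9, fill=(100.0, 200.0)):
    """A valid frame with hips/shoulders placed explicitly and every other
    joint at ``fill``. Left joint first in each pair."""
    joints = np.zeros((N_JOINTS, 3))
    joints[:, 0], joints[:, 1] = fill
    joints[:, 2] = confidence
    joints[LEFT_HIP, :2], joints[RIGHT_HIP, :2] = hips
    joints[LEFT_SHOULDER, :2], joints[RIGHT_SHOULDER, :2] = shoulders
    return SkeletonFrame(joints)


def make_tracklet(n_frames=60, track_id="t0", confidence=0.9, fps=24.0,
                  ankle_step=0.0, rng=None):
    """A tracklet of translated copies of the canonical frame; optionally the
    left ankle advances ``ankle_step`` per frame so leg velocity is known."""
    base = make_frame(confidence=confidence).joints
    data = np.repeat(base[None], n_frames, axis=0).astype(float)
    if ankle_step:
        data[:, LEFT_ANKLE, 0] += ankle_step * np.arange(n_frames)
    if rng is not None:
        data[:, :, :2] += rng.normal(0, 0.1, size=(n_frames, N_JOINTS, 2))
    return Tracklet(track_id, data, fps=fps)


@pytest.fixture
def frame():
    return make_frame()


@pytest.fixture
def walking_dataset():
    """A small clean synthetic benchmark: 6 identities x 4 runs x 2 angles."""
    import gaitkit as gk
    rng = np.random.default_rng(7)
    ds, truth = gk.make_benchmark(6, 4, angles=(0.0, 90.0), rng=rng)
    return ds, truth
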