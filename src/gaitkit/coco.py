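"""COCO-17 keypoint conventions.

All skeleton data in this package uses the 17-joint COCO ordering with
image (y-down) pixel coordinates until normalization. Each joint carries an
(x, y, confidence) triple.
"""

from __future__ import annotations

import numpy as np

#: Joint names in the canonical COCO-17 order.
JOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_JOINTS = 17

JOINT_INDEX: dict[str, int] = {n: i for i, n in enumerate(JOINT_NAMES)}

NOSE = JOINT_INDEX["nose"]
LEFT_SHOULDER = JOINT_INDEX["left_shoulder"]
RIGHT_SHOULDER = JOINT_INDEX["right_shoulder"]
LEFT_HIP = JOINT_INDEX["left_hip"]
RIGHT_HIP = JOINT_INDEX["right_hip"]
LEFT_KNEE = JOINT_INDEX["left_knee"]
RIGHT_KNEE = JOINT_INDEX["right_knee"]
LEFT_ANKLE = JOINT_INDEX["left_ankle"]
RIGHT_ANKLE = JOINT_INDEX["right_ankle"]

#: Indices of ankles (the "feet" of the visibility / velocity heuristics).
FEET = (LEFT_ANKLE, RIGHT_ANKLE)

#: Leg joints used by the walking-velocity heuristic: both ankles and knees.
LEG_JOINTS = (LEFT_ANKLE, RIGHT_ANKLE, LEFT_KNEE, RIGHT_KNEE)

#: Undirected skeleton edges of the COCO person graph (joint-index pairs).
SKELETON_EDGES: tuple[tuple[int, int], ...] = (
    (15, 13), (13, 11), (16, 14), (14, 12),  # legs
    (11, 12),                                # hip line
    (5, 11), (6, 12),                        # torso sides
    (5, 6),                                  # shoulder line
    (5, 7), (7, 9), (6, 8), (8, 10),         # arms
    (0, 1), (0, 2), (1, 3), (2, 4),          # head
    (3, 5), (4, 6),                          # ears to shoulders
)

#: (left, right) joint index pairs, used by the mirror augmentation.
LR_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16),
)


def adjacency_matrix() -> np.ndarray:
    """Symmetric 17x17 {0,1} adjacency of the COCO skeleton, zero diagonal."""
    A = np.zeros((N_JOINTS, N_JOINTS), dtype=float)
    for i, j in SKELETON_EDGES:
        A[i, j] = 1.0
        A[j, i] = 1.0
    return A
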