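"""Height-invariant, anonymizing skeleton normalization.

Each skeleton is zero-centered at the pelvis (midpoint of the hips) and
scaled per axis: x by the shoulder width ``|x_Rshoulder - x_Lshoulder|`` and
y by the torso length ``|y_neck - y_pelvis|`` (neck = shoulder midpoint).
For every joint::

    x' = (x - x_pelvis) / |x_Rshoulder - x_Lshoulder|
    y' = (y - y_pelvis) / |y_neck - y_pelvis|

After normalization the pelvis sits at the origin, shoulder width and torso
length are exactly 1, and no absolute position or stature information
remains — similar poses land on similar coordinates regardless of where or
how large the person appeared in the image. The transform is idempotent and
invariant to translation and uniform scaling of the input.

COCO-17 contains neither a pelvis nor a neck joint; both are derived as
hip/shoulder midpoints. Denominators are per frame. The y-down pixel
convention is preserved (no axis flip), so a standing person's neck has
negative normalized y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coco import LEFT_HIP, LEFT_SHOULDER, RIGHT_HIP, RIGHT_SHOULDER
from .io import SkeletonFrame, Tracklet, TrackletDataset

#: Degeneracy guard on the denominators, in source units.
EPS = 1e-6


class DegenerateFrameError(ValueError):
    """Shoulder width or torso length below the degeneracy threshold."""


@dataclass(frozen=True)
class VirtualJoints:
    """Pelvis and neck, derived as hip and shoulder midpoints."""

    pelvis: np.ndarray  # (2,)
    neck: np.ndarray    # (2,)


def derive_virtual_joints(frame: SkeletonFrame) -> VirtualJoints:
    xy = frame.xy
    parents = xy[[LEFT_HIP, RIGHT_HIP, LEFT_SHOULDER, RIGHT_SHOULDER]]
    if not np.all(np.isfinite(parents)):
        raise ValueError("non-finite hip/shoulder joints")
    pelvis = 0.5 * (xy[LEFT_HIP] + xy[RIGHT_HIP])
    neck = 0.5 * (xy[LEFT_SHOULDER] + xy[RIGHT_SHOULDER])
    return VirtualJoints(pelvis=pelvis, neck=neck)


def _normalize_block(xy: np.ndarray) -> np.ndarray:
    """Vectorized normalization of a (T, 17, 2) coordinate block."""
    pelvis = 0.5 * (xy[:, LEFT_HIP] + xy[:, RIGHT_HIP])          # (T, 2)
    neck = 0.5 * (xy[:, LEFT_SHOULDER] + xy[:, RIGHT_SHOULDER])  # (T, 2)
    shoulder_w = np.abs(xy[:, RIGHT_SHOULDER, 0] - xy[:, LEFT_SHOULDER, 0])
    torso_l = np.abs(neck[:, 1] - pelvis[:, 1])
    bad = (shoulder_w <= EPS) | (torso_l <= EPS)
    if np.any(bad):
        raise DegenerateFrameError(
            f"{int(bad.sum())} frame(s) with degenerate shoulder width or torso length"
        )
    out = np.empty_like(xy)
    out[:, :, 0] = (xy[:, :, 0] - pelvis[:, None, 0]) / shoulder_w[:, None]
    out[:, :, 1] = (xy[:, :, 1] - pelvis[:, None, 1]) / torso_l[:, None]
    return out


def normalize_frame(frame: SkeletonFrame) -> SkeletonFrame:
    """Normalize a single skeleton; confidences are unchanged."""
    data = frame.joints.copy()
    data[:, :2] = _normalize_block(frame.xy[None])[0]
    return SkeletonFrame(data)


def normalize_tracklet(t: Tracklet) -> Tracklet:
    """Per-frame normalization of a whole tracklet.

    Any degenerate frame rejects the entire tracklet (default policy):
    a skeleton whose shoulders or torso collapse to a point is a pose
    failure, and per-frame scale factors from such frames would corrupt
    the sequence.
    """
    data = t.data.copy()
    try:
        data[:, :, :2] = _normalize_block(t.xy)
    except DegenerateFrameError as exc:
        raise DegenerateFrameError(f"track {t.track_id!r}: {exc}") from exc
    return t.with_data(data)


def normalize_dataset(ds: TrackletDataset, on_error: str = "drop") -> TrackletDataset:
    """Normalize every tracklet; degenerate tracklets are dropped or raise.

    ``on_error``: ``"drop"`` silently removes tracklets with degenerate
    frames (they would be rejected downstream anyway), ``"raise"``
    propagates the error.
    """
    if on_error not in ("drop", "raise"):
        raise ValueError("on_error must be 'drop' or 'raise'")
    kept = []
    for t in ds:
        try:
            kept.append(normalize_tracklet(t))
        except DegenerateFrameError:
            if on_error == "raise":
                raise
    return TrackletDataset(kept, dict(ds.provenance))
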