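"""Tracklet quality filters for curating walking sequences.

Raw tracked skeletons from unconstrained footage mix genuine walkers with
poorly detected poses, occluded feet, tracking fragments and standing
people. Four heuristics curate the walking set, applied in a fixed order
(length -> mean confidence -> feet visibility -> velocity); a rejection is
attributed to the first failing filter.

* **length** — at least 54 frames (about two full gait cycles at 24 fps),
  at most ``max_length`` frames (very long tracks are usually loiterers).
* **mean confidence** — the mean detection confidence over all frames and
  all 17 joints must exceed 0.60 (strict).
* **feet visibility** — per frame the feet confidence is the minimum of the
  two ankle confidences; no more than 3 consecutive frames may fall below
  0.50, ensuring both feet stay visible throughout.
* **velocity** — mean frame-to-frame displacement of the leg joints (both
  ankles and both knees) on *normalized* coordinates must reach 0.01
  units/frame; static people fail. Expects normalization to have been
  applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coco import FEET, LEG_JOINTS
from .io import Tracklet, TrackletDataset

#: Filter stages in application order.
FILTER_ORDER = ("length", "mean_confidence", "feet_visibility", "velocity")


@dataclass
class FilterConfig:
    min_mean_confidence: float = 0.60
    feet_conf_threshold: float = 0.50
    max_consecutive_low_feet: int = 3
    min_length: int = 54
    min_mean_velocity: float = 0.01
    max_length: int = 1000
    #: include knees (with the ankles) in the velocity average
    velocity_use_knees: bool = True

    def __post_init__(self) -> None:
        if min(self.min_mean_confidence, self.feet_conf_threshold,
               self.max_consecutive_low_feet, self.min_length,
               self.min_mean_velocity, self.max_length) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterReport:
    """Per-filter rejection counts plus a per-tracklet verdict table."""

    n_input: int = 0
    n_survivors: int = 0
    rejections: dict = field(default_factory=lambda: {k: 0 for k in FILTER_ORDER})
    verdicts: list = field(default_factory=list)  # (track_id, first_failing_filter | "pass")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.verdicts, columns=["track_id", "verdict"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def length_filters(t: Tracklet, cfg: FilterConfig) -> bool:
    """Pass iff min_length <= len(t) <= max_length."""
    return cfg.min_length <= len(t) <= cfg.max_length


def mean_confidence_filter(t: Tracklet, cfg: FilterConfig) -> bool:
    """Pass iff mean confidence over all frames and joints is strictly above
    the threshold (the rule is "over 60%", hence strict)."""
    return float(np.mean(t.confidence)) > cfg.min_mean_confidence


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    # run-length encode: boundaries where the mask value changes
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


def feet_visibility_filter(t: Tracklet, cfg: FilterConfig) -> bool:
    """Pass iff the longest run of frames whose feet confidence (minimum of
    the two ankle confidences) is below threshold does not exceed
    ``max_consecutive_low_feet``."""
    feet_conf = t.confidence[:, list(FEET)].min(axis=1)
    low = feet_conf < cfg.feet_conf_threshold
    return _longest_true_run(low) <= cfg.max_consecutive_low_feet


def leg_velocity(t: Tracklet, cfg: FilterConfig | None = None) -> float:
    """Mean frame-to-frame Euclidean displacement of the leg joints.

    Averaged over both ankles and both knees (ankles only when
    ``velocity_use_knees`` is off) and over all frame transitions, in the
    tracklet's coordinate units per frame.
    """
    if len(t) < 2:
        raise ValueError(f"track {t.track_id!r}: velocity undefined for length < 2")
    joints = list(LEG_JOINTS) if (cfg is None or cfg.velocity_use_knees) else list(FEET)
    legs = t.xy[:, joints, :]                      # (T, J, 2)
    disp = np.linalg.norm(np.diff(legs, axis=0), axis=2)  # (T-1, J)
    return float(disp.mean())


def velocity_filter(t: Tracklet, cfg: FilterConfig) -> bool:
    """Pass iff the mean leg velocity reaches ``min_mean_velocity``.

    Coordinates are expected to be normalized (the 0.01 default is in
    normalized units per frame)."""
    return leg_velocity(t, cfg) >= cfg.min_mean_velocity


_FILTER_FNS = {
    "length": length_filters,
    "mean_confidence": mean_confidence_filter,
    "feet_visibility": feet_visibility_filter,
    "velocity": velocity_filter,
}


def first_failing_filter(t: Tracklet, cfg: FilterConfig) -> str | None:
    """Name of the first filter (in canonical order) that rejects ``t``,
    or None if all pass."""
    for name in FILTER_ORDER:
        if not _FILTER_FNS[name](t, cfg):
            return name
    return None


def apply_filters(ds: TrackletDataset, cfg: FilterConfig | None = None) -> tuple[TrackletDataset, FilterReport]:
    """Apply the full filter cascade to a (normalized) dataset.

    Returns the surviving dataset and a report in which every rejection is
    attributed to the first failing filter; survivors + rejections always
    equal the input count. Deterministic.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(ds))
    survivors = []
    for t in ds:
        verdict = first_failing_filter(t, cfg)
        if verdict is None:
            survivors.append(t)
            report.verdicts.append((t.track_id, "pass"))
        else:
            report.rejections[verdict] += 1
            report.verdicts.append((t.track_id, verdict))
    report.n_survivors = len(survivors)
    return TrackletDataset(survivors, dict(ds.provenance)), report
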