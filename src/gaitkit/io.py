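"""Tracklet data model and keypoint I/O.

A *tracklet* is a contiguous, uniformly sampled sequence of 2D skeletons of
one tracked person. Internally a tracklet stores a single float64 array of
shape ``(T, 17, 3)`` — frames x joints x (x, y, confidence) — which is the
natural unit for every downstream stage (filtering, normalization,
augmentation, encoding).

Two interchange dialects are read:

* ``coco-json`` — a COCO-keypoints-style JSON document whose
  ``annotations`` list holds one detection per person per frame, each with
  ``track_id``, ``frame_index`` and a flat 51-element ``keypoints`` list.
* ``jsonl`` — one detection object per line with the same fields
  (AlphaPose-style streaming output).

Datasets are written to a single HDF5 archive (one dataset per tracklet)
plus a CSV sidecar of per-tracklet metadata; the round trip is bit-exact.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

from .coco import N_JOINTS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A record violates the keypoint schema (e.g. wrong joint count)."""


class IntegrityError(ValueError):
    """Frame indices within a track are not contiguous."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One person in one frame: 17 joints with (x, y, confidence).

    Coordinates are in image pixels (y-down) until normalization;
    confidences are unitless in [0, 1].
    """

    joints: np.ndarray  # (17, 3)

    def __post_init__(self) -> None:
        j = np.asarray(self.joints, dtype=float)
        if j.shape != (N_JOINTS, 3):
            raise SchemaError(f"expected ({N_JOINTS}, 3) joints, got {j.shape}")
        if not np.all(np.isfinite(j[:, :2])):
            raise ValueError("non-finite joint coordinates")
        if np.any(j[:, 2] < 0) or np.any(j[:, 2] > 1):
            raise ValueError("confidence outside [0, 1]")
        object.__setattr__(self, "joints", j)

    @property
    def xy(self) -> np.ndarray:
        return self.joints[:, :2]

    @property
    def confidence(self) -> np.ndarray:
        return self.joints[:, 2]


@dataclass
class Tracklet:
    """An ordered skeleton sequence sharing one track identifier.

    ``data`` has shape (T, 17, 3); frame k occurs at time k / fps seconds
    (frame indices are 0-based).
    """

    track_id: str
    data: np.ndarray
    fps: float = 24.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[1:] != (N_JOINTS, 3):
            raise SchemaError(f"tracklet data must be (T, {N_JOINTS}, 3), got {d.shape}")
        if d.shape[0] == 0:
            raise ValueError("tracklet has no frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.data = d

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def xy(self) -> np.ndarray:
        """(T, 17, 2) coordinate block."""
        return self.data[:, :, :2]

    @property
    def confidence(self) -> np.ndarray:
        """(T, 17) confidence block."""
        return self.data[:, :, 2]

    def frame(self, k: int) -> SkeletonFrame:
        return SkeletonFrame(self.data[k])

    def with_data(self, data: np.ndarray, fps: float | None = None) -> "Tracklet":
        return Tracklet(self.track_id, data, self.fps if fps is None else fps, dict(self.meta))


@dataclass
class TrackletDataset:
    """A collection of tracklets with pairwise-distinct track ids."""

    tracklets: list[Tracklet] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracklets]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate track ids in dataset")

    def __len__(self) -> int:
        return len(self.tracklets)

    def __iter__(self) -> Iterator[Tracklet]:
        return iter(self.tracklets)

    def __getitem__(self, i: int) -> Tracklet:
        return self.tracklets[i]

    def map(self, fn) -> "TrackletDataset":
        return TrackletDataset([fn(t) for t in self.tracklets], dict(self.provenance))


def _keypoints_to_array(kp: Sequence[float], where: str) -> np.ndarray:
    arr = np.asarray(kp, dtype=float)
    if arr.size != N_JOINTS * 3:
        raise SchemaError(f"{where}: expected {N_JOINTS * 3} keypoint values, got {arr.size}")
    return arr.reshape(N_JOINTS, 3)


def _records_to_dataset(records: list[dict], fps: float, provenance: dict) -> TrackletDataset:
    by_track: dict[str, list[tuple[int, np.ndarray]]] = {}
    for n, rec in enumerate(records):
        where = f"record {n}"
        try:
            tid = str(rec["track_id"])
            fidx = int(rec["frame_index"])
            kp = rec["keypoints"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{where}: malformed record ({exc})") from exc
        by_track.setdefault(tid, []).append((fidx, _keypoints_to_array(kp, where)))

    tracklets = []
    for tid, frames in by_track.items():
        frames.sort(key=lambda p: p[0])
        idx = np.array([f for f, _ in frames])
        if np.any(np.diff(idx) != 1):
            raise IntegrityError(f"track {tid!r}: frame indices not contiguous")
        data = np.stack([a for _, a in frames])
        tracklets.append(Tracklet(tid, data, fps=fps))
    return TrackletDataset(tracklets, provenance)


def read_keypoint_tracklets(path: str | Path, dialect: str = "jsonl", fps: float = 24.0) -> TrackletDataset:
    """Read tracked keypoint detections and group them into tracklets.

    Parameters
    ----------
    path : file path of the detections file.
    dialect : ``"coco-json"`` (single JSON document with an ``annotations``
        list) or ``"jsonl"`` (one detection object per line).
    fps : nominal frame rate of the source video (frames are assumed
        uniformly sampled).

    Frames are grouped by ``track_id`` and sorted by ``frame_index``;
    non-contiguous frame indices within a track raise :class:`IntegrityError`
    because tracking is contiguous by construction.
    """
    path = Path(path)
    if dialect == "coco-json":
        with open(path) as fh:
            doc = json.load(fh)
        records = doc.get("annotations", []) if isinstance(doc, dict) else doc
    elif dialect == "jsonl":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not records:
        warnings.warn(f"{path}: no detections found; returning empty dataset", stacklevel=2)
        return TrackletDataset([], {"source": str(path)})
    return _records_to_dataset(records, fps, {"source": str(path), "dialect": dialect})


def write_tracklets(ds: TrackletDataset, path: str | Path) -> Path:
    """Write a dataset to an HDF5 archive with a CSV metadata sidecar.

    One ``(T, 17, 3)`` float64 dataset per tracklet; fps and JSON-encoded
    meta stored as attributes. The sidecar ``<path>.meta.csv`` tabulates
    track id, length, fps and meta for quick inspection. Round trip through
    :func:`read_tracklets` is bit-exact.
    """
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["provenance"] = json.dumps(ds.provenance)
        fh.attrs["track_ids"] = json.dumps([t.track_id for t in ds.tracklets])
        grp = fh.create_group("tracklets")
        for i, t in enumerate(ds.tracklets):
            d = grp.create_dataset(str(i), data=t.data)
            d.attrs["track_id"] = t.track_id
            d.attrs["fps"] = t.fps
            d.attrs["meta"] = json.dumps(t.meta)
    rows = [
        {"track_id": t.track_id, "n_frames": len(t), "fps": t.fps, "meta": json.dumps(t.meta)}
        for t in ds.tracklets
    ]
    pd.DataFrame(rows, columns=["track_id", "n_frames", "fps", "meta"]).to_csv(
        path.with_suffix(path.suffix + ".meta.csv"), index=False
    )
    return path


def read_tracklets(path: str | Path) -> TrackletDataset:
    """Read an archive written by :func:`write_tracklets`."""
    with h5py.File(path, "r") as fh:
        provenance = json.loads(fh.attrs.get("provenance", "{}"))
        order = json.loads(fh.attrs["track_ids"])
        grp = fh["tracklets"]
        by_id = {}
        for key in grp:
            d = grp[key]
            t = Tracklet(
                track_id=str(d.attrs["track_id"]),
                data=d[()],
                fps=float(d.attrs["fps"]),
                meta=json.loads(d.attrs["meta"]),
            )
            by_id[t.track_id] = t
    return TrackletDataset([by_id[tid] for tid in order], provenance)


def resample_tracklet(t: Tracklet, target_fps: float) -> Tracklet:
    """Linearly resample a tracklet in time to ``target_fps``.

    The new length is ``round(len * target_fps / fps)``; joint trajectories
    and confidences are linearly interpolated at the resampled instants
    (confidences clamped back to [0, 1]). Resampling to the original fps
    returns the tracklet unchanged.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if target_fps == t.fps:
        return t
    T = len(t)
    new_T = max(2, int(round(T * target_fps / t.fps)))
    # Original knots at k/fps; new frames at k/target_fps, clamped to the
    # original span so the tail repeats the last frame rather than
    # extrapolating. Instants that land on original knots reproduce them
    # exactly, which makes a double resample (2f then f) an identity.
    old_t = np.arange(T) / t.fps
    new_t = np.minimum(np.arange(new_T) / target_fps, old_t[-1])
    flat = t.data.reshape(T, -1)
    out = np.empty((new_T, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new_t, old_t, flat[:, c])
    data = out.reshape(new_T, N_JOINTS, 3)
    data[:, :, 2] = np.clip(data[:, :, 2], 0.0, 1.0)
    return t.with_data(data, fps=target_fps)
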