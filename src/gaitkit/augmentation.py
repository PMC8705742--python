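"""Stochastic view generation for contrastive training.

A single tracked walk is turned into multiple "views" of the same person:
a pace change (temporal dilation/contraction), a random fixed-length crop
(with repeat-padding of short sequences), and independent draws of spatial
squeeze, horizontal mirroring, temporal flip and joint/frame dropout.
Two such views of one tracklet form the positive pair of a multiviewed
contrastive batch.

Operations act on plain ``(T, 17, 3)`` arrays; :func:`make_views` packages
the result as fixed-shape :class:`GaitSample` tensors of shape
``(3, 17, crop_length)`` (channels x joints x frames).

Order of application: pace -> crop -> squeeze/mirror/flip -> dropout, so
the emitted length is exactly ``crop_length`` regardless of pace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .coco import LR_PAIRS, N_JOINTS
from .io import Tracklet

#: Discrete pace (time-modification) factors sampled uniformly.
DEFAULT_PACE_FACTORS = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class GaitSample:
    """Fixed-shape network input: (3, 17, T) tensor plus labels.

    Channels are (x, y, confidence); ``label`` is the contrastive class
    (tracklet id during pretraining, identity during fine-tuning).
    """

    tensor: np.ndarray
    label: str
    viewpoint: float | None = None
    run: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.ndim != 3 or t.shape[0] != 3 or t.shape[1] != N_JOINTS:
            raise ValueError(f"GaitSample tensor must be (3, {N_JOINTS}, T), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite values in GaitSample")
        object.__setattr__(self, "tensor", t)


@dataclass
class AugmentConfig:
    crop_length: int = 54
    pace_factors: tuple = DEFAULT_PACE_FACTORS
    squeeze_range: tuple = (0.8, 1.2)
    p_mirror: float = 0.5
    p_timeflip: float = 0.5
    p_joint_dropout: float = 0.1
    p_frame_dropout: float = 0.1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_mirror, self.p_timeflip, self.p_joint_dropout, self.p_frame_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(f <= 0 for f in self.pace_factors):
            raise ValueError("pace factors must be positive")
        if self.crop_length <= 0:
            raise ValueError("crop_length must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        d = dict(d)
        for k in ("pace_factors", "squeeze_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def identity(cls, crop_length: int = 54) -> "AugmentConfig":
        """A degenerate config under which every view equals the input crop."""
        return cls(crop_length=crop_length, pace_factors=(1.0,),
                   squeeze_range=(1.0, 1.0), p_mirror=0.0, p_timeflip=0.0,
                   p_joint_dropout=0.0, p_frame_dropout=0.0)


def random_crop(seq: np.ndarray, crop_length: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous random window of ``crop_length`` frames.

    Sequences shorter than the crop are repeat-padded by tiling from the
    start until the crop is filled.
    """
    if crop_length <= 0:
        raise ValueError("crop_length must be positive")
    T = seq.shape[0]
    if T >= crop_length:
        start = int(rng.integers(0, T - crop_length + 1))
        return seq[start:start + crop_length].copy()
    reps = int(np.ceil(crop_length / T))
    return np.concatenate([seq] * reps, axis=0)[:crop_length].copy()


def change_pace(seq: np.ndarray, factor: float) -> np.ndarray:
    """Dilate (factor < 1) or contract (factor > 1) the sequence in time.

    New length is ``max(2, round(T / factor))``; trajectories are linearly
    interpolated at the resampled instants, so a factor > 1 simulates faster
    walking with fewer frames.
    """
    if factor <= 0:
        raise ValueError("pace factor must be positive")
    T = seq.shape[0]
    if T < 2:
        raise ValueError("pace change needs at least 2 frames")
    if factor == 1.0:
        return seq.copy()
    new_T = max(2, int(round(T / factor)))
    old_i = np.arange(T, dtype=float)
    # Resample at stride `factor` so original frames are hit exactly whenever
    # k*factor is integral; the tail clamps to the last frame if overshooting.
    new_i = np.minimum(np.arange(new_T, dtype=float) * factor, T - 1.0)
    flat = seq.reshape(T, -1)
    out = np.empty((new_T, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new_i, old_i, flat[:, c])
    return out.reshape((new_T,) + seq.shape[1:])


def mirror(seq: np.ndarray) -> np.ndarray:
    """Horizontal reflection: x -> -x and left/right joints swapped."""
    out = seq.copy()
    out[:, :, 0] = -out[:, :, 0]
    for left, right in LR_PAIRS:
        out[:, [left, right]] = out[:, [right, left]]
    return out


def time_flip(seq: np.ndarray) -> np.ndarray:
    """Temporal reversal (walking the sequence backwards)."""
    return seq[::-1].copy()


def squeeze(seq: np.ndarray, sx: float) -> np.ndarray:
    """Scale x by ``sx``, leaving y and confidence untouched."""
    if sx <= 0:
        raise ValueError("squeeze factor must be positive")
    out = seq.copy()
    out[:, :, 0] *= sx
    return out


def dropout_joints(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Zero whole joint trajectories (coordinates and confidence), each joint
    independently with probability ``p``; the shape is unchanged."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    out = seq.copy()
    mask = rng.random(seq.shape[1]) < p
    out[:, mask, :] = 0.0
    return out


def dropout_frames(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Zero whole frames independently with probability ``p``; frames are
    zeroed, not deleted, keeping the tensor shape static."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < p
    out[mask] = 0.0
    return out


def augment_once(seq: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """One independent augmentation draw: pace, crop, squeeze, mirror,
    temporal flip, joint/frame dropout."""
    factor = cfg.pace_factors[int(rng.integers(len(cfg.pace_factors)))]
    view = change_pace(seq, factor)
    view = random_crop(view, cfg.crop_length, rng)
    lo, hi = cfg.squeeze_range
    view = squeeze(view, float(rng.uniform(lo, hi)))
    if rng.random() < cfg.p_mirror:
        view = mirror(view)
    if rng.random() < cfg.p_timeflip:
        view = time_flip(view)
    view = dropout_joints(view, cfg.p_joint_dropout, rng)
    view = dropout_frames(view, cfg.p_frame_dropout, rng)
    return view


def to_sample(seq: np.ndarray, t: Tracklet, label: str | None = None) -> GaitSample:
    """Package a (T, 17, 3) window as a (3, 17, T) GaitSample carrying the
    tracklet's labels."""
    return GaitSample(
        tensor=np.transpose(seq, (2, 1, 0)),
        label=t.track_id if label is None else label,
        viewpoint=t.meta.get("angle"),
        run=t.meta.get("run"),
    )


def make_views(t: Tracklet, cfg: AugmentConfig, rng: np.random.Generator,
               label: str | None = None) -> tuple[GaitSample, GaitSample]:
    """Two independently augmented views (the positive pair) of one tracklet.

    Both carry the same label — the tracklet id by default, or an explicit
    label (identity) during fine-tuning.
    """
    a = augment_once(t.data, cfg, rng)
    b = augment_once(t.data, cfg, rng)
    return to_sample(a, t, label), to_sample(b, t, label)
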