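"""Spatio-temporal graph-convolutional gait encoder.

Each block applies the graph layer

    f_out = Lambda^{-1/2}((A+I)(x)M)Lambda^{-1/2} f_in W

to a (C, V, T) feature map: spatial aggregation over the skeleton by the
normalized masked adjacency, then a standard 1xG 2D convolution along time
whose channel mixing realizes W, followed by a residual connection and a
ReLU. Every block owns a learnable edge-importance mask M (initialized to
ones). A global average pool over joints and frames and a two-layer
projection head map the last feature map to an embedding on the unit
sphere.

The encoder has no classification head: its parameter count is independent
of the number of identities, which is what lets one contrastive model scale
to arbitrarily many tracklet labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, graph_conv, temporal_conv
from .coco import N_JOINTS
from .graph import SkeletonGraph, base_normalized_adjacency


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    The default stack follows the original ST-GCN recipe scaled to
    desk-size: seven blocks widening 64->256 with two temporal
    downsamplings. ``small()`` is the CPU-friendly config used by the
    synthetic end-to-end experiments.
    """

    channels: tuple = (64, 64, 64, 128, 128, 256, 256)
    strides: tuple = (1, 1, 1, 2, 1, 2, 1)
    temporal_kernel: int = 9
    embedding_dim: int = 128
    projection_hidden: int = 128
    in_channels: int = 3  # (x, y, confidence)
    use_confidence: bool = True
    #: "mean" = global average pool over joints and frames; "mean_std"
    #: additionally concatenates the per-channel standard deviation, which
    #: preserves oscillation amplitudes that a plain mean cancels out
    pooling: str = "mean_std"

    def __post_init__(self) -> None:
        if self.temporal_kernel % 2 != 1:
            raise ValueError("temporal kernel size must be odd")
        if len(self.channels) != len(self.strides):
            raise ValueError("one stride per block required")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channel widths must be positive")
        if self.pooling not in ("mean", "mean_std"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not self.use_confidence:
            self.in_channels = 2

    @classmethod
    def small(cls) -> "EncoderConfig":
        return cls(channels=(16, 32, 32), strides=(1, 2, 2),
                   temporal_kernel=5, embedding_dim=32, projection_hidden=64)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        for k in ("channels", "strides"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EmbeddingSet:
    """Unit-norm embeddings with identity / viewpoint / run tags."""

    embeddings: np.ndarray                      # (n, d), rows on the unit sphere
    labels: np.ndarray                          # (n,) identity ids
    viewpoints: np.ndarray | None = None        # (n,) angles in degrees
    runs: np.ndarray | None = None              # (n,) run ids

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.embeddings.ndim != 2 or len(self.labels) != len(self.embeddings):
            raise ValueError("embeddings (n, d) and labels (n,) required")
        if len(self.labels) == 0:
            raise ValueError("empty embedding set")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("embeddings must be unit-norm")
        for name in ("viewpoints", "runs"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != len(self.labels):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "EmbeddingSet":
        return EmbeddingSet(
            self.embeddings[mask], self.labels[mask],
            None if self.viewpoints is None else self.viewpoints[mask],
            None if self.runs is None else self.runs[mask],
        )


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def stgcn_block(f_in, S, W, b=None, stride: int = 1,
                activation: bool = True, residual=None) -> Tensor:
    """One graph/temporal block applied functionally.

    ``f_in`` is an (N, C_in, V, T) map (array or tensor), ``S`` the (V, V)
    spatial operator, ``W`` a (C_out, C_in, G) temporal kernel with G odd.
    With G = 1, identity channel mixing, no bias and no activation the block
    reduces to the pure spatial adjacency multiply.
    """
    x = f_in if isinstance(f_in, Tensor) else Tensor(f_in)
    S = S if isinstance(S, Tensor) else Tensor(S)
    W = W if isinstance(W, Tensor) else Tensor(W)
    y = graph_conv(x, S)
    y = temporal_conv(y, W, b, stride=stride)
    if residual is not None:
        y = y + residual
    return y.relu() if activation else y


class STGCNEncoder:
    """The gait encoder: stacked graph/temporal blocks plus projection head."""

    def __init__(self, cfg: EncoderConfig | None = None,
                 graph: SkeletonGraph | None = None, seed: int = 0):
        self.cfg = cfg or EncoderConfig()
        self.graph = graph or SkeletonGraph()
        #: constant Lambda^{-1/2}(A+I)Lambda^{-1/2}; the learnable per-block
        #: mask multiplies it elementwise.
        self.base_S = base_normalized_adjacency(self.graph)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.cfg
        c_prev = c.in_channels
        self.running_stats: dict[str, np.ndarray] = {}
        for i, (c_out, _) in enumerate(zip(c.channels, c.strides)):
            G = c.temporal_kernel
            self.params[f"block{i}.M"] = Tensor(np.ones_like(self.graph.M), requires_grad=True)
            self.params[f"block{i}.W"] = Tensor(
                _he_init(rng, (c_out, c_prev, G), c_prev * G), requires_grad=True)
            self.params[f"block{i}.b"] = Tensor(np.zeros(c_out), requires_grad=True)
            self.params[f"block{i}.bn_gamma"] = Tensor(np.ones(c_out), requires_grad=True)
            self.params[f"block{i}.bn_beta"] = Tensor(np.zeros(c_out), requires_grad=True)
            self.running_stats[f"block{i}.bn_mean"] = np.zeros(c_out)
            self.running_stats[f"block{i}.bn_var"] = np.ones(c_out)
            if c_prev != c_out:
                self.params[f"block{i}.Wres"] = Tensor(
                    _he_init(rng, (c_out, c_prev, 1), c_prev), requires_grad=True)
            c_prev = c_out
        d_h, d_e = c.projection_hidden, c.embedding_dim
        c_prev = 2 * c_prev if c.pooling == "mean_std" else c_prev
        # projection head: Linear -> BN -> ReLU -> Linear; the BN keeps the
        # hidden ReLU pattern sample-dependent (without it, a batch of
        # near-identical inputs can share one active unit, and with a zero
        # output bias the normalized embeddings then collapse exactly)
        self.params["proj.W1"] = Tensor(_he_init(rng, (c_prev, d_h), c_prev), requires_grad=True)
        self.params["proj.bn_gamma"] = Tensor(np.ones(d_h), requires_grad=True)
        self.params["proj.bn_beta"] = Tensor(np.zeros(d_h), requires_grad=True)
        self.running_stats["proj.bn_mean"] = np.zeros(d_h)
        self.running_stats["proj.bn_var"] = np.ones(d_h)
        self.params["proj.W2"] = Tensor(_he_init(rng, (d_h, d_e), d_h), requires_grad=True)
        self.params["proj.b2"] = Tensor(np.zeros(d_e), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def param_groups(self) -> list[list[str]]:
        """Parameter names grouped by depth, input-side first; used for
        layer-wise learning rates during fine-tuning."""
        groups = []
        for i in range(len(self.cfg.channels)):
            names = [f"block{i}.M", f"block{i}.W", f"block{i}.b",
                     f"block{i}.bn_gamma", f"block{i}.bn_beta"]
            if f"block{i}.Wres" in self.params:
                names.append(f"block{i}.Wres")
            groups.append(names)
        groups.append(["proj.W1", "proj.bn_gamma", "proj.bn_beta",
                       "proj.W2", "proj.b2"])
        return groups

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward -------------------------------------------------------------

    def _batch_norm(self, x: Tensor, key: str, train: bool) -> Tensor:
        """Per-channel batch normalization built from differentiable
        primitives; running statistics serve inference. ``x`` is either a
        (N, C, V, T) feature map (channel axis 1, statistics over N, V, T)
        or a (N, C) matrix (statistics over N)."""
        gamma, beta = self.params[f"{key}.bn_gamma"], self.params[f"{key}.bn_beta"]
        C = x.shape[1]
        axes = (0, 2, 3) if len(x.shape) == 4 else (0,)
        pshape = (1, C, 1, 1) if len(x.shape) == 4 else (1, C)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            diff = x - mu
            var = (diff * diff).mean(axis=axes, keepdims=True)
            m = 0.9  # running-average momentum
            self.running_stats[f"{key}.bn_mean"] = (
                m * self.running_stats[f"{key}.bn_mean"] + (1 - m) * mu.data.ravel())
            self.running_stats[f"{key}.bn_var"] = (
                m * self.running_stats[f"{key}.bn_var"] + (1 - m) * var.data.ravel())
        else:
            mu = Tensor(self.running_stats[f"{key}.bn_mean"].reshape(pshape))
            var = Tensor(self.running_stats[f"{key}.bn_var"].reshape(pshape))
            diff = x - mu
        xhat = diff / (var + 1e-5).sqrt()
        return xhat * gamma.reshape(*pshape) + beta.reshape(*pshape)

    def forward(self, batch: np.ndarray, train: bool = False,
                return_features: bool = False) -> Tensor:
        """Embed a batch of gait samples.

        ``batch`` has shape (N, C_in, V, T); returns (N, embedding_dim)
        unit-norm embeddings as an autodiff tensor. ``train`` switches the
        batch-normalization layers to batch statistics (and updates the
        running averages); inference uses the stored running statistics and
        is deterministic.

        ``return_features`` returns the unit-normalized pooled backbone
        features instead of the projection output (for inspection; the
        projection output is the better retrieval embedding here, since
        the raw pooled statistics retain augmentation nuisance).
        """
        batch = np.asarray(batch, dtype=float)
        if batch.ndim != 4 or batch.shape[1] != self.cfg.in_channels or batch.shape[2] != N_JOINTS:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, {N_JOINTS}, T), got {batch.shape}")
        x = Tensor(batch)
        base = Tensor(self.base_S)
        for i, stride in enumerate(self.cfg.strides):
            S = base * self.params[f"block{i}.M"]
            y = graph_conv(x, S)
            y = temporal_conv(y, self.params[f"block{i}.W"],
                              self.params[f"block{i}.b"], stride=stride)
            y = self._batch_norm(y, f"block{i}", train)
            if f"block{i}.Wres" in self.params:
                res = temporal_conv(x, self.params[f"block{i}.Wres"], stride=stride)
            elif stride != 1:
                res = Tensor(x.data[:, :, :, ::stride], parents=())  # plain subsample
            else:
                res = x
            x = (y + res).relu()
        # statistics pooling over joints and frames -> (N, C) or (N, 2C)
        feat = x.mean(axis=(2, 3))
        if self.cfg.pooling == "mean_std":
            mu = x.mean(axis=(2, 3), keepdims=True)
            dev = x - mu
            var = (dev * dev).mean(axis=(2, 3))
            feat = concat([feat, (var + 1e-8).sqrt()], axis=1)
        if return_features:
            z = feat
        else:
            h = self._batch_norm(feat @ self.params["proj.W1"], "proj", train).relu()
            z = h @ self.params["proj.W2"] + self.params["proj.b2"]
        norm = (z * z).sum(axis=1, keepdims=True).sqrt() + 1e-12
        return z / norm

    def encode(self, samples, batch_size: int = 64) -> EmbeddingSet:
        """Inference-mode embedding of a list of :class:`GaitSample`.

        Deterministic given fixed parameters; raises on non-finite
        activations.
        """
        samples = list(samples)
        tensors = np.stack([s.tensor[: self.cfg.in_channels] for s in samples])
        chunks = []
        for lo in range(0, len(tensors), batch_size):
            z = self.forward(tensors[lo:lo + batch_size]).data
            if not np.all(np.isfinite(z)):
                raise FloatingPointError("non-finite activations while encoding")
            chunks.append(z)
        Z = np.concatenate(chunks, axis=0)
        return EmbeddingSet(
            embeddings=Z,
            labels=np.array([s.label for s in samples]),
            viewpoints=np.array([np.nan if s.viewpoint is None else s.viewpoint
                                 for s in samples]),
            runs=np.array([("" if s.run is None else str(s.run)) for s in samples]),
        )

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint: parameters plus the encoder config."""
        path = Path(path)
        arrays = {"p__" + k.replace(".", "__"): p.data for k, p in self.params.items()}
        arrays.update({"rs__" + k.replace(".", "__"): v
                       for k, v in self.running_stats.items()})
        np.savez(path, __config__=json.dumps(self.cfg.to_dict()), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "STGCNEncoder":
        with np.load(path, allow_pickle=False) as fh:
            cfg = EncoderConfig.from_dict(json.loads(str(fh["__config__"])))
            enc = cls(cfg)
            for k in enc.params:
                enc.params[k].data = fh["p__" + k.replace(".", "__")].copy()
            for k in enc.running_stats:
                enc.running_stats[k] = fh["rs__" + k.replace(".", "__")].copy()
        return enc
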