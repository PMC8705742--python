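"""Supervised-contrastive pretraining and few-shot fine-tuning.

Pretraining needs no human labels: each tracklet is its own contrastive
class, and its two augmented crops are the positives. For a multiviewed
batch of 2N unit-norm embeddings z with labels y, the loss is

    L = (1/2N) sum_i  -1/|P(i)| sum_{p in P(i)} log  exp(z_i.z_p / tau)
                                                    -------------------------
                                                    sum_{a != i} exp(z_i.z_a / tau)

where P(i) are the same-label indices other than i. A small temperature
(default tau = 0.01) sharpens the similarity distribution, which benefits
training. There is no classification head, so the model size does not grow
with the number of identities, and hard positive/negative weighting is
implicit in the loss.

Fine-tuning reuses the same objective with identity labels on a per-identity
subsample of runs, with layer-wise learning rates: the head trains at the
base rate and each group of layers below it at a geometrically decayed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .augmentation import AugmentConfig, make_views
from .autodiff import Adam, Tensor, logsumexp_rows
from .io import Tracklet, TrackletDataset
from .model import EncoderConfig, STGCNEncoder

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    temperature: float = 0.01
    batch_sources: int = 16           # N source tracklets per batch (2N views)
    learning_rate: float = 1e-3
    epochs: int = 20
    seed: int = 0
    layerwise_lr_decay: float = 0.5   # fine-tuning only
    optimizer: str = "adam"
    lr_schedule: str = "cosine"       # "cosine" or "constant"
    warmup_epochs: int = 0            # linear lr ramp over the first epochs
    grad_clip: float | None = None    # global-norm gradient clipping

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_sources < 2:
            raise ValueError("need at least 2 source samples per batch")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def supcon_loss(Z, labels, temperature: float = 0.01) -> Tensor:
    """Supervised contrastive loss of a multiviewed batch.

    ``Z`` is a (2N, d) tensor (or array) of unit-norm embeddings and
    ``labels`` the per-view class labels. Returns the mean over anchors of
    the per-anchor term, computed with a max-shifted log-sum-exp. Every
    anchor must have at least one positive — a batch without one is a batch
    construction bug.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    labels = np.asarray(labels)
    n = len(labels)
    if Z.shape[0] != n:
        raise ValueError("one label per embedding required")
    eye = np.eye(n, dtype=bool)
    pos_mask = (labels[:, None] == labels[None, :]) & ~eye
    n_pos = pos_mask.sum(axis=1)
    if np.any(n_pos == 0):
        raise ValueError("anchor without positives in contrastive batch")

    sim = (Z @ Z.T) * (1.0 / temperature)           # (n, n)
    lse = logsumexp_rows(sim, ~eye)                 # (n, 1) over A(i)
    log_prob = sim - lse                            # broadcast
    per_anchor = (log_prob * Tensor(pos_mask.astype(float))).sum(axis=1) * \
        Tensor(-1.0 / n_pos)
    return per_anchor.mean()


def supcon_loss_reference(Z: np.ndarray, labels, temperature: float = 0.01) -> float:
    """Direct double-loop transcription of the loss definition (the oracle
    the vectorized implementation is tested against)."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    total = 0.0
    for i in range(n):
        A = [a for a in range(n) if a != i]
        P = [p for p in A if labels[p] == labels[i]]
        denom = sum(np.exp(Z[i] @ Z[a] / temperature) for a in A)
        term = 0.0
        for p in P:
            term += np.log(np.exp(Z[i] @ Z[p] / temperature) / denom)
        total += -term / len(P)
    return total / n


@dataclass
class TrainResult:
    encoder: STGCNEncoder
    loss_trace: list = field(default_factory=list)  # per-epoch mean loss
    subset_ids: list | None = None                  # runs used (fine-tuning)


def _train_loop(encoder: STGCNEncoder, tracklets: list[Tracklet], labels: list[str],
                cfg: TrainConfig, aug: AugmentConfig, rng: np.random.Generator,
                lrs: list[float] | None = None) -> list[float]:
    params = encoder.parameters()
    base_lrs = list(lrs) if lrs is not None else [cfg.learning_rate] * len(params)
    opt = Adam(params, lr=cfg.learning_rate, lrs=base_lrs)
    trace = []
    n = len(tracklets)
    if n < 2:
        raise ValueError("training needs at least 2 tracklets")
    in_ch = encoder.cfg.in_channels
    for epoch in range(cfg.epochs):
        scale = 1.0
        if cfg.lr_schedule == "cosine":
            scale = 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, cfg.epochs)))
        if epoch < cfg.warmup_epochs:
            scale *= (epoch + 1) / cfg.warmup_epochs
        opt.lrs = [lr * scale for lr in base_lrs]
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_sources):
            idx = order[lo:lo + cfg.batch_sources]
            if len(idx) < 2:
                continue  # a single-source batch has anchors without negatives
            views, view_labels = [], []
            for i in idx:
                a, b = make_views(tracklets[i], aug, rng, label=labels[i])
                views += [a.tensor[:in_ch], b.tensor[:in_ch]]
                view_labels += [labels[i], labels[i]]
            Z = encoder.forward(np.stack(views), train=True)
            loss = supcon_loss(Z, view_labels, cfg.temperature)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params
                                    if p.grad is not None))
                if total > cfg.grad_clip:
                    for p in params:
                        if p.grad is not None:
                            p.grad *= cfg.grad_clip / total
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
        logger.info("epoch %d: mean loss %.4f", epoch, trace[-1])
    return trace


def pretrain(ds: TrackletDataset, cfg: TrainConfig | None = None,
             aug: AugmentConfig | None = None,
             encoder_cfg: EncoderConfig | None = None) -> TrainResult:
    """Contrastive pretraining with tracklet ids as labels.

    The dataset is expected to be filtered and normalized. Fully seeded:
    identical (dataset, config) pairs give identical loss traces and
    checkpoints.
    """
    cfg = cfg or TrainConfig()
    aug = aug or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    encoder = STGCNEncoder(encoder_cfg or EncoderConfig.small(), seed=cfg.seed)
    tracklets = list(ds)
    labels = [t.track_id for t in tracklets]
    trace = _train_loop(encoder, tracklets, labels, cfg, aug, rng)
    return TrainResult(encoder=encoder, loss_trace=trace)


def layerwise_learning_rates(encoder: STGCNEncoder, base_lr: float,
                             decay: float) -> list[float]:
    """Per-parameter learning rates: the projection head (top) gets
    ``base_lr`` and each parameter group below it ``base_lr * decay^k``,
    k levels from the top."""
    groups = encoder.param_groups()          # input-side first, head last
    name_to_lr = {}
    for depth_from_top, names in enumerate(reversed(groups)):
        for name in names:
            name_to_lr[name] = base_lr * decay ** depth_from_top
    return [name_to_lr[name] for name in encoder.params]


def sample_runs_per_identity(ds: TrackletDataset, identity_of, fraction: float,
                             rng: np.random.Generator) -> list[int]:
    """Indices of a per-identity random subsample of runs.

    Each identity keeps ``round(fraction * n_runs)`` runs, at least 1 (at
    fraction 0.10 of 12 runs that is one walk per person).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    by_id: dict[str, list[int]] = {}
    for i, t in enumerate(ds):
        by_id.setdefault(str(identity_of(t)), []).append(i)
    chosen: list[int] = []
    for ident in sorted(by_id):
        runs = by_id[ident]
        k = max(1, int(round(fraction * len(runs))))
        if k > len(runs):
            logger.warning("identity %s: fraction yields more runs than exist", ident)
            k = len(runs)
        chosen += [runs[j] for j in rng.choice(len(runs), size=k, replace=False)]
    return sorted(chosen)


def finetune(encoder: STGCNEncoder, ds: TrackletDataset, identity_of,
             fraction: float = 1.0, cfg: TrainConfig | None = None,
             aug: AugmentConfig | None = None) -> TrainResult:
    """Fine-tune a (pre)trained encoder on identity-labeled tracklets.

    ``identity_of`` maps a tracklet to its identity label (e.g.
    ``lambda t: t.meta["identity"]``). A per-identity random ``fraction``
    of runs is used; the same contrastive objective applies, now with
    identity labels, and learning rates decay geometrically from the head
    down (``layerwise_lr_decay`` per level).
    """
    cfg = cfg or TrainConfig()
    aug = aug or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    idx = sample_runs_per_identity(ds, identity_of, fraction, rng)
    tracklets = [ds[i] for i in idx]
    labels = [str(identity_of(t)) for t in tracklets]
    if len(set(labels)) < 2:
        raise ValueError("fine-tuning needs at least 2 identities")
    lrs = layerwise_learning_rates(encoder, cfg.learning_rate, cfg.layerwise_lr_decay)
    trace = _train_loop(encoder, tracklets, labels, cfg, aug, rng, lrs=lrs)
    return TrainResult(encoder=encoder, loss_trace=trace,
                       subset_ids=[ds[i].track_id for i in idx])
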