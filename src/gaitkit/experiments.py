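"""Scaled-down recognition experiments on the synthetic benchmark.

Three harnesses mirror the full-scale evaluation protocols at desk size:

* :func:`identity_recovery` — pretrain the small encoder contrastively on
  an uncooperative-style pool (many walkers, one tracklet each), then score
  cross-view rank-1 retrieval on the held-out identities of a separate
  multi-run benchmark (chance = 1/#eval-ids).
* :func:`pretraining_benefit` — few-shot fine-tuning at a 10% run fraction
  starting from a pretrained checkpoint versus from random initialization,
  repeated with reseeded run subsampling and averaged.
* :func:`corpus_size_trend` — direct-transfer accuracy as a function of the
  pretraining-pool size (10%, 50%, 100% of the walker pool), repeated over
  seeds.

The pretraining pool has one tracklet per walker on purpose: tracklet ids
are the contrastive classes, so a person appearing twice would make their
own runs mutual negatives and reward view-dependent features — the corpus
this method is designed for has exactly this single-appearance structure.
Problem sizes are the package's CPU-scale choices: a 160-walker pool, a
20-identity x 4-run x 2-viewpoint benchmark, the 3-block encoder with a
widened embedding. Evaluation embeds each tracklet as the average over
four deterministic crops, three squeeze renderings each, and their mirror
images — marginalizing the augmentation orbit out of the embedding
stabilizes retrieval without touching training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augmentation import AugmentConfig, mirror, squeeze
from .evaluation import cross_view_protocol
from .filters import apply_filters
from .io import TrackletDataset
from .model import EmbeddingSet, EncoderConfig, STGCNEncoder
from .normalization import normalize_dataset
from .synthetic import make_benchmark
from .training import TrainConfig, finetune, pretrain

logger = logging.getLogger(__name__)

#: augmentation recipe of the synthetic-benchmark experiments: the squeeze
#: range spans the full foreshortening ratio of the viewpoint model so
#: positives force the representation to survive near-total loss of the x
#: channel, which is what cross-view transfer requires here.
EXPERIMENT_AUG = AugmentConfig(squeeze_range=(0.0001, 1.2), p_mirror=0.5,
                               pace_factors=(1.0,), p_joint_dropout=0.0,
                               p_frame_dropout=0.0, p_timeflip=0.0)

#: encoder used by the experiments: the 3-block CPU backbone with a wider
#: embedding/projector than `EncoderConfig.small()` — the extra embedding
#: width measurably reduces contrastive feature suppression (more of the
#: identity-discriminative kinematics survive into the retrieval space).
EXPERIMENT_ENCODER = EncoderConfig(channels=(16, 32, 32), strides=(1, 2, 2),
                                   temporal_kernel=5, embedding_dim=64,
                                   projection_hidden=128)

#: squeeze factors marginalized at test time (see multiview_embed)
TTA_SQUEEZES = (1.0, 0.65, 0.35)


def multiview_embed(encoder: STGCNEncoder, ds: TrackletDataset,
                    identity_of=None, crop_length: int = 54,
                    n_crops: int = 4, squeezes=TTA_SQUEEZES) -> EmbeddingSet:
    """Deterministic test-time embedding.

    Each tracklet is embedded as the renormalized mean over ``n_crops``
    evenly spaced crops, each rendered at several squeeze factors and
    mirrored — averaging over the augmentation orbit marginalizes the
    viewpoint-dependent x-scale out of the embedding, which measurably
    stabilizes cross-view retrieval. Fully deterministic, applied
    identically to gallery and probe.
    """
    identity_of = identity_of or (lambda t: t.meta.get("identity", t.track_id))
    in_ch = encoder.cfg.in_channels
    Z, labels, views, runs = [], [], [], []
    for t in ds:
        T = len(t)
        starts = np.unique(np.linspace(0, max(0, T - crop_length),
                                       n_crops).astype(int))
        windows = []
        for s0 in starts:
            w = t.data[s0:s0 + crop_length]
            if len(w) < crop_length:
                reps = int(np.ceil(crop_length / T))
                w = np.concatenate([t.data] * reps, axis=0)[:crop_length]
            for sq in squeezes:
                ws = squeeze(w, sq)
                windows.append(ws)
                windows.append(mirror(ws))
        batch = np.stack([np.transpose(w, (2, 1, 0))[:in_ch] for w in windows])
        z = encoder.forward(batch).data.mean(axis=0)
        Z.append(z / np.linalg.norm(z))
        labels.append(str(identity_of(t)))
        views.append(float(t.meta.get("angle", np.nan)))
        runs.append(str(t.meta.get("run", "")))
    return EmbeddingSet(np.array(Z), np.array(labels),
                        viewpoints=np.array(views), runs=np.array(runs))


def pretraining_pool(seed: int, n_walkers: int = 80,
                     angles=(0.0, 90.0)) -> TrackletDataset:
    """A clean uncooperative-style pool: ``n_walkers`` identities, one
    tracklet each, viewpoints assigned round-robin; normalized and
    filtered."""
    rng = np.random.default_rng(seed)
    ds, _ = make_benchmark(n_walkers, 1, angles=angles, rng=rng)
    survivors, _ = apply_filters(normalize_dataset(ds))
    return survivors


def prepared_benchmark(seed: int, n_ids: int = 20, runs_per_id: int = 4,
                       angles=(0.0, 90.0)) -> TrackletDataset:
    """A clean multi-run benchmark, normalized and filtered."""
    rng = np.random.default_rng(seed)
    ds, _ = make_benchmark(n_ids, runs_per_id, angles=angles, rng=rng)
    survivors, _ = apply_filters(normalize_dataset(ds))
    return survivors


def _split_by_identity(ds: TrackletDataset, n_train: int):
    ids = sorted({t.meta["identity"] for t in ds})
    train_ids = set(ids[:n_train])
    train = TrackletDataset([t for t in ds if t.meta["identity"] in train_ids])
    evals = TrackletDataset([t for t in ds if t.meta["identity"] not in train_ids])
    return train, evals, ids[n_train:]


def _pretrain_pool(pool: TrackletDataset, seed: int, epochs: int):
    cfg = TrainConfig(epochs=epochs, batch_sources=min(40, len(pool)),
                      learning_rate=3e-3, temperature=0.01, seed=seed,
                      lr_schedule="constant", warmup_epochs=10, grad_clip=5.0)
    return pretrain(pool, cfg, EXPERIMENT_AUG, EXPERIMENT_ENCODER)


@dataclass
class RecoveryResult:
    accuracies: list = field(default_factory=list)   # one per seed
    per_angle: list = field(default_factory=list)
    chance: float = 0.0
    n_eval: int = 0                                  # evaluation tracklets per seed
    encoder: STGCNEncoder | None = None              # last seed's encoder

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def identity_recovery(seed: int = 0, n_seeds: int = 3, pool_walkers: int = 160,
                      n_ids: int = 20, runs_per_id: int = 4,
                      angles=(0.0, 90.0), epochs: int = 200) -> RecoveryResult:
    """Cross-view identity recovery on held-out benchmark identities.

    For each of ``n_seeds`` seeds: simulate the single-run pretraining pool
    and the multi-run benchmark, pretrain the small encoder with the
    supervised-contrastive objective (temperature 0.01, two crops per
    tracklet, tracklet ids as labels), and run the cross-view protocol on
    the benchmark's held-out identity half. The pretraining pool and the
    benchmark share no identities by construction (independent draws).
    """
    result = RecoveryResult()
    for k in range(n_seeds):
        s = int(seed) + 1000 * k
        pool = pretraining_pool(s, pool_walkers, angles)
        bench = prepared_benchmark(s + 7777, n_ids, runs_per_id, angles)
        _, evals, eval_ids = _split_by_identity(bench, n_ids // 2)
        res = _pretrain_pool(pool, s, epochs)
        es = multiview_embed(res.encoder, evals)
        per_angle, mean_acc = cross_view_protocol(es)
        logger.info("seed %d: cross-view rank-1 %.3f", s, mean_acc)
        result.accuracies.append(mean_acc)
        result.per_angle.append(per_angle)
        result.chance = 1.0 / len(eval_ids)
        result.n_eval = len(evals)
        result.encoder = res.encoder
    return result


@dataclass
class FinetuneComparison:
    pretrained: list = field(default_factory=list)
    scratch: list = field(default_factory=list)

    @property
    def mean_pretrained(self) -> float:
        return float(np.mean(self.pretrained))

    @property
    def mean_scratch(self) -> float:
        return float(np.mean(self.scratch))


def _clone(encoder: STGCNEncoder) -> STGCNEncoder:
    out = STGCNEncoder(encoder.cfg, graph=encoder.graph, seed=0)
    for k, p in encoder.params.items():
        out.params[k].data = p.data.copy()
    for k, v in encoder.running_stats.items():
        out.running_stats[k] = v.copy()
    return out


def pretraining_benefit(checkpoint: STGCNEncoder, seed: int = 0,
                        n_repeats: int = 5, fraction: float = 0.10,
                        n_ids: int = 12, runs_per_id: int = 8,
                        epochs: int = 40) -> FinetuneComparison:
    """Few-shot fine-tuning from a pretrained checkpoint vs from scratch.

    A fresh benchmark is simulated; its first identity half provides the
    labeled fine-tuning pool (a per-identity ``fraction`` of runs — at 10%
    of 8 runs that is one walk per person), the second half is the
    evaluation set. Each repeat reseeds the run subsample and the training;
    accuracies are averaged over repeats (the 5-repetition protocol in
    miniature). Fine-tuning uses identity labels, so multiple runs per
    person are positives here, not negatives.
    """
    comp = FinetuneComparison()
    base = prepared_benchmark(int(seed) + 77, n_ids, runs_per_id)
    train, evals, _ = _split_by_identity(base, n_ids // 2)
    identity_of = lambda t: t.meta["identity"]
    for k in range(n_repeats):
        s = int(seed) + 31 * k
        cfg = TrainConfig(epochs=epochs, batch_sources=8, learning_rate=1e-3,
                          temperature=0.01, seed=s, lr_schedule="constant")
        for tag, start in (("pretrained", _clone(checkpoint)),
                           ("scratch", STGCNEncoder(checkpoint.cfg, seed=s))):
            res = finetune(start, train, identity_of, fraction=fraction,
                           cfg=cfg, aug=EXPERIMENT_AUG)
            es = multiview_embed(res.encoder, evals)
            _, acc = cross_view_protocol(es)
            getattr(comp, tag).append(acc)
        logger.info("repeat %d: pretrained %.3f scratch %.3f",
                    k, comp.pretrained[-1], comp.scratch[-1])
    return comp


@dataclass
class CorpusSizeResult:
    fractions: list = field(default_factory=list)
    accuracies: dict = field(default_factory=dict)   # fraction -> per-seed list

    def means(self) -> list:
        return [float(np.mean(self.accuracies[f])) for f in self.fractions]

    def pooled_std(self) -> float:
        devs = [np.array(self.accuracies[f]) - np.mean(self.accuracies[f])
                for f in self.fractions]
        return float(np.sqrt(np.mean(np.concatenate(devs) ** 2)))


def corpus_size_trend(seed: int = 0, fractions=(0.10, 0.50, 1.00),
                      n_seeds: int = 5, pool_walkers: int = 40,
                      n_ids: int = 8, runs_per_id: int = 4,
                      epochs: int = 80) -> CorpusSizeResult:
    """Direct-transfer accuracy vs pretraining-pool size.

    For each seed and each fraction, a random subset of the walker pool is
    drawn, the encoder is pretrained on it with the *same* training
    procedure (fixed epochs), and the frozen encoder is evaluated
    cross-view on a fixed per-seed benchmark — larger pools therefore give
    both more diversity and more optimization signal, as in the full-scale
    protocol where the procedure is fixed and the corpus grows.
    """
    result = CorpusSizeResult(fractions=list(fractions))
    for f in fractions:
        result.accuracies[f] = []
    for k in range(n_seeds):
        s = int(seed) + 500 * k
        pool = pretraining_pool(s, pool_walkers)
        bench = prepared_benchmark(s + 3333, n_ids, runs_per_id)
        rng = np.random.default_rng(s + 1)
        for f in fractions:
            n_keep = max(4, int(round(f * len(pool))))
            idx = rng.choice(len(pool), size=min(n_keep, len(pool)),
                             replace=False)
            subset = TrackletDataset([pool[i] for i in sorted(idx)])
            res = _pretrain_pool(subset, s, epochs)
            es = multiview_embed(res.encoder, bench)
            _, acc = cross_view_protocol(es)
            result.accuracies[f].append(acc)
            logger.info("seed %d fraction %.2f: %.3f", s, f, acc)
    return result
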