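"""Gallery/probe retrieval metrics and evaluation harnesses.

Recognition is nearest-neighbor retrieval on the unit sphere: a probe is
assigned the identity of its most similar gallery embedding (cosine
similarity = dot product for unit-norm vectors), and rank-1 accuracy is the
fraction of probes whose nearest gallery item shares their identity.

The cross-view protocol measures viewpoint invariance: for each probe angle
the gallery contains all evaluation-identity samples from *other* angles,
so a correct match requires recognizing the same walk seen from a different
viewpoint. Identities are split disjointly into training and evaluation
sets; a sample is never simultaneously gallery and probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augmentation import GaitSample, to_sample
from .io import Tracklet, TrackletDataset
from .model import EmbeddingSet, STGCNEncoder

logger = logging.getLogger(__name__)


@dataclass
class ProtocolSpec:
    """Identity split and gallery/probe rules of an evaluation protocol."""

    train_identities: list = field(default_factory=list)
    eval_identities: list = field(default_factory=list)
    #: optional gallery predicate on (run, viewpoint) applied on top of the
    #: angle-exclusion rule; None keeps all non-probe-angle samples.
    gallery_rule: object = None

    def __post_init__(self) -> None:
        overlap = set(map(str, self.train_identities)) & set(map(str, self.eval_identities))
        if overlap:
            raise ValueError(f"train/eval identity overlap: {sorted(overlap)[:5]}")


def rank1_accuracy(gallery: EmbeddingSet, probe: EmbeddingSet) -> float:
    """Fraction of probes whose nearest gallery embedding shares their
    identity. Similarity is the dot product; ties break to the lowest
    gallery index, so the result is deterministic."""
    if len(gallery) == 0:
        raise ValueError("empty gallery")
    sim = probe.embeddings @ gallery.embeddings.T        # (n_probe, n_gallery)
    nearest = np.argmax(sim, axis=1)                      # argmax takes lowest index on ties
    return float(np.mean(gallery.labels[nearest] == probe.labels))


def cross_view_protocol(es: EmbeddingSet, spec: ProtocolSpec | None = None
                        ) -> tuple[dict, float]:
    """Per-angle rank-1 accuracies with the probe angle excluded from the
    gallery, plus their mean.

    For each angle theta present among the (evaluation-identity) samples:
    probes are the samples at theta, the gallery is everything at other
    angles. Angles without probes or without gallery are omitted with a
    warning.
    """
    if es.viewpoints is None or np.all(np.isnan(np.asarray(es.viewpoints, dtype=float))):
        raise ValueError("cross-view protocol requires viewpoint tags")
    if spec is not None and len(spec.eval_identities) > 0:
        keep = np.isin(es.labels, np.asarray(spec.eval_identities).astype(es.labels.dtype))
        es = es.subset(keep)
    angles = np.unique(np.asarray(es.viewpoints, dtype=float))
    per_angle: dict[float, float] = {}
    for theta in angles:
        probe_mask = es.viewpoints == theta
        gallery_mask = ~probe_mask
        if spec is not None and spec.gallery_rule is not None:
            extra = np.array([spec.gallery_rule(r, v)
                              for r, v in zip(es.runs, es.viewpoints)])
            gallery_mask &= extra
        if not probe_mask.any() or not gallery_mask.any():
            logger.warning("angle %s skipped: empty probe or gallery", theta)
            continue
        per_angle[float(theta)] = rank1_accuracy(es.subset(gallery_mask),
                                                 es.subset(probe_mask))
    if not per_angle:
        raise ValueError("no angle had both probes and gallery")
    return per_angle, float(np.mean(list(per_angle.values())))


def center_crop_sample(t: Tracklet, crop_length: int = 54,
                       identity_of=None) -> GaitSample:
    """Deterministic evaluation view: the central ``crop_length`` window
    (repeat-tiled from the start when shorter)."""
    T = len(t)
    if T >= crop_length:
        start = (T - crop_length) // 2
        window = t.data[start:start + crop_length]
    else:
        reps = int(np.ceil(crop_length / T))
        window = np.concatenate([t.data] * reps, axis=0)[:crop_length]
    label = None if identity_of is None else str(identity_of(t))
    return to_sample(window, t, label)


def embed_dataset(encoder: STGCNEncoder, ds: TrackletDataset, identity_of=None,
                  crop_length: int | None = None) -> EmbeddingSet:
    """Embed every tracklet with the frozen encoder (center crops)."""
    crop = crop_length or 54
    samples = [center_crop_sample(t, crop, identity_of) for t in ds]
    return encoder.encode(samples)


def direct_transfer_eval(encoder: STGCNEncoder, ds: TrackletDataset,
                         spec: ProtocolSpec, identity_of=None,
                         n_repeats: int = 1, seed: int = 0,
                         subsample: float | None = None) -> dict:
    """Evaluate a frozen encoder on a benchmark with the cross-view protocol.

    The benchmark dataset must have passed the same filtering/normalization
    pipeline. With ``n_repeats > 1`` (optionally with a random ``subsample``
    fraction of tracklets per repeat) accuracies are averaged and the
    standard deviation reported — the repeated-subsample protocol.
    """
    identity_of = identity_of or (lambda t: t.meta.get("identity", t.track_id))
    train_set = set(map(str, spec.train_identities))
    eval_tracklets = [t for t in ds if str(identity_of(t)) not in train_set]
    means, per_angle_runs = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        subset = eval_tracklets
        if subsample is not None and subsample < 1.0:
            k = max(2, int(round(subsample * len(eval_tracklets))))
            idx = rng.choice(len(eval_tracklets), size=k, replace=False)
            subset = [eval_tracklets[i] for i in idx]
        es = embed_dataset(encoder, TrackletDataset(subset), identity_of)
        per_angle, mean_acc = cross_view_protocol(es, spec)
        means.append(mean_acc)
        per_angle_runs.append(per_angle)
    return {
        "mean_accuracy": float(np.mean(means)),
        "std_accuracy": float(np.std(means)),
        "runs": means,
        "per_angle": per_angle_runs,
        "n_eval_tracklets": len(eval_tracklets),
    }


def embedding_plot(es: EmbeddingSet, color_by: str = "identity",
                   path=None, seed: int = 0):
    """2D neighbor-embedding scatter of an embedding set.

    Projects with t-SNE (perplexity capped for small sets) and colors points
    by identity or viewpoint. Returns the matplotlib figure; writes it to
    ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    if len(es) < 2:
        raise ValueError("need at least 2 samples to plot")
    if color_by == "identity":
        tags = es.labels
    elif color_by == "viewpoint":
        if es.viewpoints is None:
            raise ValueError("no viewpoint tags")
        tags = es.viewpoints
    else:
        raise ValueError("color_by must be 'identity' or 'viewpoint'")

    perplexity = max(2.0, min(30.0, (len(es) - 1) / 3.0))
    xy = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              init="pca").fit_transform(es.embeddings)
    fig, ax = plt.subplots(figsize=(6, 5))
    uniq = np.unique(tags)
    cmap = plt.colormaps["tab20"]
    for i, tag in enumerate(uniq):
        m = tags == tag
        ax.scatter(xy[m, 0], xy[m, 1], s=12, color=cmap(i % 20), label=str(tag))
    if len(uniq) <= 20:
        ax.legend(fontsize=6, markerscale=0.7, ncol=2)
    ax.set_title(f"embedding map colored by {color_by}")
    ax.set_xticks([]), ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
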