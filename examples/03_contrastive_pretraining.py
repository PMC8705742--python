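"""Contrastive pretraining on tracklet labels, end to end (small scale).

Pretrains the CPU-sized encoder on a simulated uncooperative corpus —
many walkers, one tracklet each, so every tracklet is its own contrastive
class and its two augmented crops are the positives — then checks
cross-view retrieval on a separate multi-run benchmark of identities the
model never saw. Takes a couple of minutes on one CPU.
"""

import numpy as np

import gaitkit as gk
from gaitkit.evaluation import cross_view_protocol
from gaitkit.experiments import (EXPERIMENT_AUG, EXPERIMENT_ENCODER,
                                 multiview_embed, prepared_benchmark,
                                 pretraining_pool)

# uncooperative-style pretraining corpus: 60 walkers, one tracklet each
pool = pretraining_pool(seed=3, n_walkers=60)
print(f"pretraining pool: {len(pool)} single-run walkers")

# evaluation benchmark: 8 fresh identities x 4 runs over two viewpoints
bench = prepared_benchmark(seed=99, n_ids=8, runs_per_id=4)
print(f"evaluation benchmark: {len(bench)} tracklets, "
      f"{len({t.meta['identity'] for t in bench})} identities")

cfg = gk.TrainConfig(epochs=100, batch_sources=30, learning_rate=3e-3,
                     temperature=0.01, seed=0, lr_schedule="constant",
                     warmup_epochs=10, grad_clip=5.0)
result = gk.pretrain(pool, cfg, EXPERIMENT_AUG, EXPERIMENT_ENCODER)
print(f"loss: first epoch {result.loss_trace[0]:.2f}, "
      f"last epoch {result.loss_trace[-1]:.2f}")

es = multiview_embed(result.encoder, bench)
per_angle, mean_acc = cross_view_protocol(es)
print("per-angle rank-1 on unseen identities:",
      {a: round(v, 3) for a, v in per_angle.items()})
print(f"mean cross-view rank-1: {mean_acc:.3f} (chance {1/8:.3f})")
# The falling loss shows tracklet discrimination being learned; accuracy
# far above chance on identities the model never saw shows the features
# encode gait, not tracklet quirks.
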