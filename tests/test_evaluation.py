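import numpy as np
import pytest

import gaitkit as gk
from gaitkit.evaluation import (ProtocolSpec, center_crop_sample,
                                cross_view_protocol, direct_transfer_eval,
                                embed_dataset, rank1_accuracy)
from gaitkit.model import EmbeddingSet, EncoderConfig, STGCNEncoder


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def es_from(vectors, labels, viewpoints=None):
    Z = np.stack([unit(v) for v in vectors])
    return EmbeddingSet(Z, np.asarray(labels),
                        None if viewpoints is None else np.asarray(viewpoints))


class TestRank1:
    def test_probe_equal_gallery_is_perfect(self):
        rng = np.random.default_rng(0)
        es = es_from(rng.normal(size=(10, 4)), [f"p{i}" for i in range(10)])
        assert rank1_accuracy(es, es) == 1.0

    def test_disjoint_identities_score_zero(self):
        gal = es_from([[1, 0], [0, 1]], ["a", "a"])
        probe = es_from([[1, 0]], ["b"])
        assert rank1_accuracy(gal, probe) == 0.0

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(1)
        gal = es_from(rng.normal(size=(30, 6)), rng.integers(0, 7, 30))
        probe = es_from(rng.normal(size=(50, 6)), rng.integers(0, 7, 50))
        hits = 0
        for z, lab in zip(probe.embeddings, probe.labels):
            best, best_sim = None, -np.inf
            for g, glab in zip(gal.embeddings, gal.labels):
                s = float(z @ g)
                if s > best_sim:
                    best, best_sim = glab, s
            hits += best == lab
        assert rank1_accuracy(gal, probe) == hits / 50

    def test_rotation_invariance(self):
        """Any common rotation preserves dot products, hence the ranking."""
        rng = np.random.default_rng(2)
        gal = es_from(rng.normal(size=(12, 5)), rng.integers(0, 4, 12))
        probe = es_from(rng.normal(size=(20, 5)), rng.integers(0, 4, 20))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        gal_r = EmbeddingSet(gal.embeddings @ Q, gal.labels)
        probe_r = EmbeddingSet(probe.embeddings @ Q, probe.labels)
        assert abs(rank1_accuracy(gal, probe) -
                   rank1_accuracy(gal_r, probe_r)) < 1e-9

    def test_empty_gallery_rejected(self):
        probe = es_from([[1, 0]], ["a"])
        with pytest.raises(ValueError):
            rank1_accuracy(probe.subset(np.zeros(1, bool)), probe)


class TestCrossView:
    def test_orthogonal_identity_clusters_are_perfect(self):
        vecs, labels, angles = [], [], []
        eye = np.eye(4)
        for i in range(4):
            for angle in (0.0, 90.0):
                for _ in range(2):
                    vecs.append(eye[i])
                    labels.append(f"id{i}")
                    angles.append(angle)
        per_angle, mean = cross_view_protocol(es_from(vecs, labels, angles))
        assert per_angle == {0.0: 1.0, 90.0: 1.0}
        assert mean == 1.0

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(3)
        k = 5
        n = 400
        es = es_from(rng.normal(size=(n, 16)), rng.integers(0, k, n),
                     rng.choice([0.0, 90.0], n))
        _, mean = cross_view_protocol(es)
        p = 1 / k
        sigma = np.sqrt(p * (1 - p) / (n / 2))
        assert abs(mean - p) < 3 * sigma

    def test_two_angle_handcrafted_instance(self):
        """4 samples, 2 angles: each probe's nearest cross-angle neighbor is
        hand-computable."""
        labels = ["a", "b", "a", "b"]
        vecs = [[1, 0, 0],      # a, 0
                [0, 1, 0],      # b, 0
                [0.9, 0.1, 0],  # a, 90 -> nearest 0-degree vec is a ✓
                [0.1, 0.9, 0]]  # b, 90 -> nearest 0-degree vec is b ✓
        angles = [0.0, 0.0, 90.0, 90.0]
        per_angle, mean = cross_view_protocol(es_from(vecs, labels, angles))
        assert per_angle == {0.0: 1.0, 90.0: 1.0} and mean == 1.0
        # flip one: b@90 closest to a@0 -> angle-90 accuracy drops to 0.5
        vecs[3] = [0.9, 0.05, 0]
        per_angle, _ = cross_view_protocol(es_from(vecs, labels, angles))
        assert per_angle[90.0] == 0.5

    def test_probe_angle_excluded_from_gallery(self):
        """Each identity's twin embedding exists only at the probe's own
        angle; if the protocol leaked same-angle samples into the gallery
        the score would be 1, with correct exclusion it is 0."""
        eye = np.eye(4)
        vecs = [eye[0], eye[0], eye[1], eye[1]]     # two ids, twin pairs at 0
        labels = ["a", "a", "b", "b"]
        angles = [0.0, 0.0, 0.0, 0.0]
        # at 90 degrees the identities' embeddings are swapped, so every
        # cross-angle nearest neighbor carries the wrong identity
        vecs += [[0.1, 0.9, 0, 0], [0.9, 0.1, 0, 0]]
        labels += ["a", "b"]
        angles += [90.0, 90.0]
        per_angle, _ = cross_view_protocol(es_from(vecs, labels, angles))
        assert per_angle[0.0] == 0.0

    def test_missing_viewpoints_rejected(self):
        es = es_from([[1, 0], [0, 1]], ["a", "b"])
        with pytest.raises(ValueError):
            cross_view_protocol(es)

    def test_identity_split_is_respected(self):
        rng = np.random.default_rng(5)
        es = es_from(rng.normal(size=(16, 4)),
                     ["train"] * 8 + ["eval"] * 8,
                     rng.choice([0.0, 90.0], 16))
        spec = ProtocolSpec(train_identities=["train"], eval_identities=["eval"])
        with pytest.raises(ValueError):
            ProtocolSpec(train_identities=["x"], eval_identities=["x"])
        per_angle, _ = cross_view_protocol(es, spec)
        assert per_angle  # computed on eval identities only


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(6)
    ds, _ = gk.make_benchmark(6, 4, angles=(0.0, 90.0), rng=rng)
    normed = gk.normalize_dataset(ds)
    enc = STGCNEncoder(EncoderConfig(channels=(8, 8), strides=(2, 2),
                                     temporal_kernel=3, embedding_dim=8,
                                     projection_hidden=8), seed=0)
    return enc, normed


class TestHarness:
    def test_direct_transfer_excludes_train_identities(self, setup):
        enc, ds = setup
        spec = ProtocolSpec(train_identities=["id000", "id001"],
                            eval_identities=[f"id{i:03d}" for i in range(2, 6)])
        report = direct_transfer_eval(enc, ds, spec,
                                      identity_of=lambda t: t.meta["identity"])
        assert report["n_eval_tracklets"] == 4 * 4  # 4 eval ids x 4 runs
        assert 0.0 <= report["mean_accuracy"] <= 1.0

    def test_repeated_runs_report_mean_and_std(self, setup):
        enc, ds = setup
        spec = ProtocolSpec(train_identities=["id000"], eval_identities=[])
        report = direct_transfer_eval(enc, ds, spec, n_repeats=5, seed=0,
                                      subsample=0.8,
                                      identity_of=lambda t: t.meta["identity"])
        assert len(report["runs"]) == 5
        assert report["std_accuracy"] >= 0.0

    def test_center_crop_shapes(self, setup):
        _, ds = setup
        s = center_crop_sample(ds[0], 54)
        assert s.tensor.shape == (3, 17, 54)
        short = ds[0].with_data(ds[0].data[:20])
        assert center_crop_sample(short, 54).tensor.shape == (3, 17, 54)

    def test_embedding_plot_writes_figure(self, setup, tmp_path):
        enc, ds = setup
        es = embed_dataset(enc, ds, lambda t: t.meta["identity"])
        out = tmp_path / "fig.png"
        gk.embedding_plot(es, color_by="identity", path=out, seed=0)
        assert out.exists() and out.stat().st_size > 0
        with pytest.raises(ValueError):
            gk.embedding_plot(es, color_by="nope")
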