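import numpy as np
import pytest

import gaitkit as gk
from gaitkit.coco import FEET, LEFT_SHOULDER, RIGHT_SHOULDER
from gaitkit.filters import FilterConfig, apply_filters, first_failing_filter, leg_velocity
from gaitkit.synthetic import EXPECTED_VERDICT, PopulationConfig, SceneParams


class TestSampleIdentity:
    def test_seeded_determinism(self):
        a = gk.sample_identity(np.random.default_rng(3))
        b = gk.sample_identity(np.random.default_rng(3))
        assert a == b

    def test_cadence_distribution_mean(self):
        rng = np.random.default_rng(0)
        cad = np.array([gk.sample_identity(rng).cadence for _ in range(1000)])
        # sample mean within 3 sigma of the population mean 0.9
        assert abs(cad.mean() - 0.9) < 3 * 0.1 / np.sqrt(1000)
        assert np.all(cad > 0.5)

    def test_zero_variance_population_collapses(self):
        pop = PopulationConfig(cadence_sd=0.0, stride_sd=0.0, knee_sd=0.0,
                               arm_sd=0.0, phase_jitter_sd=0.0, bounce_sd=0.0,
                               proportion_jitter=0.0)
        rng = np.random.default_rng(1)
        a = gk.sample_identity(rng, pop)
        b = gk.sample_identity(rng, pop)
        assert (a.cadence, a.stride_amplitude, a.leg_length) == \
               (b.cadence, b.stride_amplitude, b.leg_length)
        assert a.phase_left != b.phase_left  # global phase stays free


class TestSynthesizeTracklet:
    def test_standing_noise_free_has_zero_velocity(self):
        rng = np.random.default_rng(2)
        ident = gk.sample_identity(rng)
        scene = SceneParams(mode="standing", noise_sd=0.0)
        t = gk.synthesize_tracklet(ident, scene, 100, rng)
        normed = gk.normalize_tracklet(t)
        assert leg_velocity(normed) == pytest.approx(0.0, abs=1e-12)
        assert first_failing_filter(normed, FilterConfig()) == "velocity"

    def test_clean_walking_passes_all_default_filters(self):
        rng = np.random.default_rng(3)
        ident = gk.sample_identity(rng)
        for angle in (0.0, 90.0):
            t = gk.synthesize_tracklet(ident, SceneParams(viewpoint_angle=angle),
                                       120, rng)
            normed = gk.normalize_tracklet(t)
            assert first_failing_filter(normed, FilterConfig()) is None

    def test_low_confidence_mode_fails_feet_visibility(self):
        rng = np.random.default_rng(4)
        ident = gk.sample_identity(rng)
        t = gk.synthesize_tracklet(ident, SceneParams(mode="low-confidence"),
                                   120, rng)
        low = t.confidence[:, list(FEET)].min(axis=1) < 0.5
        runs = np.diff(np.flatnonzero(np.diff(
            np.concatenate([[0], low.astype(int), [0]]))).reshape(-1, 2), axis=1)
        assert runs.max() >= 4
        assert first_failing_filter(gk.normalize_tracklet(t),
                                    FilterConfig()) == "feet_visibility"

    def test_generated_tracklets_satisfy_frame_invariants(self):
        rng = np.random.default_rng(5)
        ident = gk.sample_identity(rng)
        t = gk.synthesize_tracklet(ident, SceneParams(), 60, rng)
        assert len(t) == 60
        assert np.all(np.isfinite(t.data))
        assert np.all((t.confidence >= 0) & (t.confidence <= 1))
        t.frame(0)  # SkeletonFrame invariants hold

    def test_viewpoint_foreshortens_but_never_degenerates(self):
        rng = np.random.default_rng(6)
        ident = gk.sample_identity(rng)
        widths = {}
        for angle in (0.0, 90.0):
            t = gk.synthesize_tracklet(ident, SceneParams(viewpoint_angle=angle,
                                                          noise_sd=0.0), 30, rng)
            w = np.abs(t.xy[:, RIGHT_SHOULDER, 0] - t.xy[:, LEFT_SHOULDER, 0])
            widths[angle] = w.mean()
            assert np.all(w > 1.0)  # pixels; normalization stays well-posed
        assert widths[90.0] < widths[0.0]

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(mode="running")

    def test_min_frames(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            gk.synthesize_tracklet(gk.sample_identity(rng), SceneParams(), 1, rng)


class TestMakeBenchmark:
    def test_counts_and_angle_assignment(self):
        rng = np.random.default_rng(8)
        ds, truth = gk.make_benchmark(20, 4, angles=(0.0, 90.0), rng=rng)
        assert len(ds) == 80
        assert truth.shape[0] == 80
        per_id = truth.groupby("identity").size()
        assert (per_id == 4).all()
        assert set(truth.angle) == {0.0, 90.0}

    def test_contamination_counting(self):
        rng = np.random.default_rng(9)
        ds, truth = gk.make_benchmark(10, 4, rng=rng, standing_fraction=0.25)
        assert (truth["mode"] == "standing").sum() == 10
        assert (truth.expected_verdict == "velocity").sum() == 10

    def test_same_seed_identical_dataset(self):
        a, ta = gk.make_benchmark(4, 2, rng=np.random.default_rng(10))
        b, tb = gk.make_benchmark(4, 2, rng=np.random.default_rng(10))
        assert ta.equals(tb)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)

    def test_ground_truth_matches_filter_verdicts_exactly(self):
        """The generator's expected verdicts and the filter cascade must
        agree tracklet by tracklet on contaminated benchmarks."""
        for seed in (11, 12):
            rng = np.random.default_rng(seed)
            ds, truth = gk.make_benchmark(12, 6, rng=rng,
                                          standing_fraction=0.15,
                                          low_conf_fraction=0.10)
            normed = gk.normalize_dataset(ds)
            _, report = apply_filters(normed, FilterConfig())
            verdicts = dict(report.verdicts)
            for row in truth.itertuples():
                assert verdicts[row.track_id] == row.expected_verdict, row.track_id

    def test_expected_verdict_table_is_consistent(self):
        assert EXPECTED_VERDICT == {"walking": "pass", "standing": "velocity",
                                    "low-confidence": "feet_visibility"}


def test_identity_separability():
    """Within-identity trajectory distance (per-joint RMS over a cycle after
    phase alignment) is smaller than between-identity distance for >= 95% of
    identity pairs — the property that makes end-to-end recovery testable."""
    rng = np.random.default_rng(13)
    n_ids, runs = 12, 2
    ds, _ = gk.make_benchmark(n_ids, runs, angles=(0.0,), rng=rng)
    normed = gk.normalize_dataset(ds)

    def cycle_signature(t, length=27):
        # best-aligned cyclic average distance needs a common window length
        xy = t.xy[:length * 3]
        return xy

    def aligned_distance(a, b):
        best = np.inf
        wa = a[:54]
        for shift in range(27):
            wb = b[shift:shift + 54]
            if len(wb) < 54:
                break
            d = np.sqrt(np.mean((wa - wb) ** 2))
            best = min(best, d)
        return best

    sigs = {}
    for t in normed:
        sigs.setdefault(t.meta["identity"], []).append(t.xy)
    ids = sorted(sigs)
    within = {i: aligned_distance(sigs[i][0], sigs[i][1]) for i in ids}
    ok = total = 0
    for i in ids:
        for j in ids:
            if i >= j:
                continue
            between = aligned_distance(sigs[i][0], sigs[j][0])
            total += 2
            ok += within[i] < between
            ok += within[j] < between
    assert ok / total >= 0.95
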