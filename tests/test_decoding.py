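import numpy as np
import pytest

from seqsplit.decoding import (
    build_pseudo_ensemble,
    classical_mds,
    coding_similarity,
    cv_accuracy,
    mds_embedding,
    shuffle_null_ci,
    split_half_similarity_matrix,
    splitting_vector,
    train_linear_decoder,
)
from seqsplit.model import predict_similarity_analytic
from seqsplit.synth import BasisSpec, GroundTruth, simulate_session


def toy_xy(n=20):
    X = np.vstack([np.tile([1.0, 0.0], (n, 1)), np.tile([0.0, 1.0], (n, 1))])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestLinearDecoder:
    def test_symmetric_toy_boundary(self):
        X, y = toy_xy()
        model = train_linear_decoder(X, y)
        w = model.w / np.linalg.norm(model.w)
        # boundary x1 = x2 -> w proportional to (1, -1)
        assert abs(w[0]) == pytest.approx(abs(w[1]), abs=1e-6)
        assert np.sign(w[0]) != np.sign(w[1])

    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 5)) + 4, rng.normal(0, 1, (30, 5)) - 4])
        y = np.array(["p"] * 30 + ["m"] * 30)
        model = train_linear_decoder(X, y)
        pred = np.where(X @ model.w + model.b > 0, model.classes[1], model.classes[0])
        assert np.all(pred == y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_decoder(np.ones((4, 2)), np.array(["A"] * 4))

    def test_duplicated_features_same_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 4))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, "A", "B")
        X_test = rng.normal(0, 1, (20, 4))
        m1 = train_linear_decoder(X, y)
        m2 = train_linear_decoder(np.hstack([X, X]), y)
        p1 = np.where(X_test @ m1.w + m1.b > 0, 1, 0)
        p2 = np.where(np.hstack([X_test, X_test]) @ m2.w + m2.b > 0, 1, 0)
        np.testing.assert_array_equal(p1, p2)


class TestSplittingVector:
    def test_unit_norm(self):
        from seqsplit.decoding import DecoderModel

        v = splitting_vector(DecoderModel(w=np.array([3.0, 4.0]), b=0.0, classes=("a", "b")))
        np.testing.assert_allclose(v, [0.6, 0.8])

    def test_orientation_convention(self):
        X, y = toy_xy()
        model = train_linear_decoder(X, y)
        v_a = splitting_vector(model, plus_label="A")
        v_b = splitting_vector(model, plus_label="B")
        np.testing.assert_allclose(v_a, -v_b)
        # A lives at (1,0): oriented vector must score A positively
        assert np.dot(v_a, [1.0, 0.0]) > 0

    def test_toy_direction(self):
        X, y = toy_xy()
        v = splitting_vector(train_linear_decoder(X, y), plus_label="A")
        np.testing.assert_allclose(v, [1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-6)

    def test_zero_vector_rejected(self):
        from seqsplit.decoding import DecoderModel

        with pytest.raises(ValueError):
            splitting_vector(DecoderModel(w=np.zeros(3), b=0.0, classes=("a", "b")))


class TestCodingSimilarity:
    def test_identical(self):
        assert coding_similarity(np.ones(4), np.ones(4)) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert coding_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_opposite(self):
        assert coding_similarity(np.ones(3), -np.ones(3)) == pytest.approx(-1.0)

    def test_scale_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        v1, v2 = rng.normal(size=8), rng.normal(size=8)
        c = coding_similarity(v1, v2)
        assert coding_similarity(3.7 * v1, 0.2 * v2) == pytest.approx(c)
        assert coding_similarity(-v1, v2) == pytest.approx(-c)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            coding_similarity(np.zeros(3), np.ones(3))


class TestPseudoEnsemble:
    def test_single_session_all_neurons(self, noisy_session, small_design):
        ens = build_pseudo_ensemble([noisy_session], noisy_session.n_neurons, seed=0,
                                    design=small_design)
        assert ens.activity.shape == (noisy_session.n_trials, noisy_session.n_neurons)
        # per-type multisets of epoch means preserved under permutation
        from seqsplit.splitting import epoch_trial_means

        means = epoch_trial_means(noisy_session, "overlap", small_design)
        col = ens.neuron_ids.index((0, 0))
        for tt in set(noisy_session.trial_type):
            vals = sorted(ens.activity[ens.labels == tt, col])
            orig = sorted(means[0, noisy_session.trials_of(tt)])
            np.testing.assert_allclose(vals, orig)

    def test_pooling_across_sessions(self, noisy_session, small_design, exact_basis, exact_spec):
        truth = GroundTruth(weights=(0.7, 0.7, 0.4, 0.4), signal_amplitude=2.0,
                            baseline_rate=2.0, noise_sd=0.5)
        s2 = simulate_session(small_design, truth, seed=99, basis=exact_basis,
                              spec=exact_spec)
        ens = build_pseudo_ensemble([noisy_session, s2], 150, seed=1, design=small_design)
        assert ens.n_neurons == 150
        assert len(set(ens.neuron_ids)) == 150

    def test_oversubscription_rejected(self, noisy_session, small_design):
        with pytest.raises(ValueError):
            build_pseudo_ensemble([noisy_session], 10_000, seed=0, design=small_design)

    def test_determinism(self, noisy_session, small_design):
        e1 = build_pseudo_ensemble([noisy_session], 50, seed=5, design=small_design)
        e2 = build_pseudo_ensemble([noisy_session], 50, seed=5, design=small_design)
        np.testing.assert_array_equal(e1.activity, e2.activity)
        assert e1.neuron_ids == e2.neuron_ids


class TestCvAccuracy:
    def test_separable_perfect(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(3, 0.1, (15, 6)), rng.normal(-3, 0.1, (15, 6))])
        y = np.array(["p"] * 15 + ["m"] * 15)
        assert cv_accuracy(X, y, n_folds=20, seed=0) == 1.0

    def test_label_shuffle_null_centered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (60, 10))
        y = np.array(["p", "m"] * 30)
        accs = [
            cv_accuracy(X, rng.permutation(y), n_folds=20, seed=k) for k in range(20)
        ]
        m = np.mean(accs)
        assert abs(m - 0.5) < 0.1

    def test_shuffle_null_ci_upper(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 8))
        y = np.array(["p", "m"] * 20)
        upper, accs = shuffle_null_ci(X, y, n_shuffles=20, n_folds=10, seed=0)
        assert accs.shape == (20,)
        assert 0.4 < np.mean(accs) < 0.6
        assert upper >= np.mean(accs)

    def test_min_shuffles_enforced(self):
        with pytest.raises(ValueError):
            shuffle_null_ci(np.ones((10, 2)), np.array(["a", "b"] * 5), n_shuffles=5)

    def test_strong_signal_beats_null(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(2, 1, (20, 10)), rng.normal(-2, 1, (20, 10))])
        y = np.array(["p"] * 20 + ["m"] * 20)
        acc = cv_accuracy(X, y, n_folds=20, seed=1)
        upper, _ = shuffle_null_ci(X, y, n_shuffles=20, n_folds=10, seed=2)
        assert acc > upper


def _generated_ensemble(weights, seed, design, amp=3.0, noise=0.5):
    spec = BasisSpec(n_neurons=100, mode="exact-orthogonal")
    truth = GroundTruth(
        weights=weights, signal_amplitude=amp, baseline_rate=2.0, noise_sd=noise
    )
    s = simulate_session(design, truth, seed=seed, spec=spec)
    return build_pseudo_ensemble([s], 100, seed=seed + 1, design=design)


class TestSplitHalfSimilarity:
    def test_pure_past_cue_pattern(self, small_design):
        # weights (1,0,0,0): orthogonal coding directions across pairs
        ens = _generated_ensemble((1, 0, 0, 0), 10, small_design)
        sim = split_half_similarity_matrix(
            ens.activity, ens.labels, small_design.pair_members, n_repeats=20, seed=0
        )
        off = sim.between_pair_values()
        assert np.all(np.abs(off) < 0.15)
        assert np.all(sim.within_pair_values() > 0.7)

    def test_pure_outcome_pattern(self, small_design):
        # weights (0,0,0,1): all pairs share one coding direction
        ens = _generated_ensemble((0, 0, 0, 1), 11, small_design)
        sim = split_half_similarity_matrix(
            ens.activity, ens.labels, small_design.pair_members, n_repeats=20, seed=0
        )
        within = sim.within_pair_values().mean()
        off = sim.between_pair_values()
        assert np.all(off > 0.8 * within)

    def test_pure_noise_within_shuffle_ci(self, small_design):
        rng = np.random.default_rng(12)
        labels = np.repeat(list(small_design.trial_types), 10)
        X = rng.normal(0, 1, (labels.size, 60))
        sim = split_half_similarity_matrix(
            X, labels, small_design.pair_members, n_repeats=20, seed=1
        )
        null = split_half_similarity_matrix(
            X, labels, small_design.pair_members, n_repeats=20, seed=2,
            shuffle_labels=True,
        )
        lo, hi = np.percentile(null.per_repeat, [2.5, 97.5])
        off = sim.between_pair_values()
        assert np.all(off > lo - 0.1) and np.all(off < hi + 0.1)

    def test_matrix_symmetry_and_order(self, small_design):
        ens = _generated_ensemble((0.5, 0.5, 0.5, 0.5), 13, small_design)
        sim = split_half_similarity_matrix(
            ens.activity, ens.labels, small_design.pair_members, n_repeats=5, seed=0
        )
        assert sim.pairs == ("1a", "2a", "1b", "2b")
        np.testing.assert_allclose(sim.mean, sim.mean.T)

    def test_too_few_trials_rejected(self, small_design):
        labels = np.repeat(list(small_design.trial_types), 3)
        X = np.random.default_rng(0).normal(size=(labels.size, 10))
        with pytest.raises(ValueError):
            split_half_similarity_matrix(X, labels, small_design.pair_members)


class TestGeneratorGeometryRecovery:
    def test_empirical_matches_analytic(self, small_design):
        # pipeline-level link: generated data -> empirical similarity
        # approximates noise_term * analytic prediction
        w = np.array([0.7, 0.7, 0.4, 0.4])
        ens = _generated_ensemble(tuple(w), 14, small_design, amp=4.0, noise=0.3)
        sim = split_half_similarity_matrix(
            ens.activity, ens.labels, small_design.pair_members, n_repeats=30, seed=3
        )
        noise = sim.within_pair_values().mean()
        pred = noise * predict_similarity_analytic(w)
        iu = np.triu_indices(4, k=1)
        assert np.abs(sim.mean[iu] - pred[iu]).max() < 0.12


class TestMds:
    def test_collinear_points_recovered(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        xy = classical_mds(d, k=2)
        rec = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_square_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        xy = classical_mds(d, k=2)
        rec = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_degenerate_zeros(self):
        xy = classical_mds(np.zeros((4, 4)), k=2)
        np.testing.assert_allclose(xy, 0.0, atol=1e-12)

    def test_embedding_from_activity(self, small_design):
        rng = np.random.default_rng(15)
        labels = np.repeat(list(small_design.trial_types), 5)
        X = rng.normal(0, 1, (labels.size, 20))
        coords, types = mds_embedding(X, labels)
        assert coords.shape == (8, 2)
        assert types == sorted(set(labels))

    def test_needs_three_types(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            mds_embedding(X, np.array(["a", "a", "b", "b"]))
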