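"""Attention math, clustering penalty, composite loss and training."""

import numpy as np
import pytest

import enzannot as ez
from enzannot.ec import parse_ec
from enzannot.model import (
    ModelConfig,
    TaskOutputs,
    attention_layer,
    composite_loss,
    task_clustering_penalty,
)


class TestAttention:
    def test_singleton_key_returns_value_row(self):
        Q = np.random.default_rng(0).normal(size=(4, 3))
        K = np.array([[0.3, -1.0, 2.0]])
        V = np.array([[5.0, 7.0]])
        out = attention_layer(Q, K, V, d_h=3)
        np.testing.assert_allclose(out, np.tile(V, (4, 1)))

    def test_two_key_hand_computed_softmax(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attention_layer(Q, K, V, d_h=1.0)
        w = np.exp(1.0) / (np.exp(1.0) + 1.0)  # ~0.7311
        np.testing.assert_allclose(out, [[w, 1 - w]], atol=1e-6)

    def test_identical_keys_give_uniform_mean(self):
        rng = np.random.default_rng(1)
        K = np.tile(rng.normal(size=(1, 4)), (6, 1))
        V = rng.normal(size=(6, 3))
        out = attention_layer(rng.normal(size=(2, 4)), K, V, d_h=4)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_rows_sum_to_one_and_convexity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, m, dh, dv = rng.integers(1, 6, size=4)
            Q, K = rng.normal(size=(n, dh)), rng.normal(size=(m, dh))
            V = rng.normal(size=(m, dv))
            scores = Q @ K.T / np.sqrt(dh)
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            w = e / e.sum(axis=-1, keepdims=True)
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
            out = attention_layer(Q, K, V, d_h=dh)
            # convex combination: within [min, max] of each value column
            for j in range(out.shape[1]):
                assert np.all(out[:, j] >= V[:, j].min() - 1e-9)
                assert np.all(out[:, j] <= V[:, j].max() + 1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            attention_layer(np.ones((1, 2)), np.ones((1, 2)), np.ones((1, 2)), 0)
        with pytest.raises(ValueError):
            attention_layer(np.ones((1, 3)), np.ones((2, 2)), np.ones((2, 2)), 1)


class TestClusteringPenalty:
    def test_zero_vectors(self):
        assert task_clustering_penalty([np.zeros(4)] * 3, (0.5, 0.1, 0.4)) == 0.0

    def test_identical_vectors_leave_only_mean_norm(self):
        v = np.array([1.0, -2.0, 0.5])
        omega = task_clustering_penalty([v, v, v], (0.5, 0.1, 0.4))
        assert omega == pytest.approx(float(v @ v), abs=1e-12)

    def test_hand_worked_triple(self):
        # a1=(1,0), a2=(0,1), a3=(1,1): mean (2/3,2/3), ||mean||^2 = 8/9,
        # deviations 5/9, 5/9, 2/9 -> 8/9 + .5*5/9 + .1*5/9 + .4*2/9 = 11.8/9
        omega = task_clustering_penalty(
            [(1.0, 0.0), (0.0, 1.0), (1.0, 1.0)], (0.5, 0.1, 0.4)
        )
        assert omega == pytest.approx(11.8 / 9, abs=1e-9)

    def test_monotone_under_contraction_toward_mean(self):
        """Pulling every task vector toward the (fixed) mean never
        increases the penalty."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            vecs = [rng.normal(size=6) for _ in range(3)]
            lambdas = rng.uniform(0.05, 1.0, size=3)
            a_bar = np.mean(vecs, axis=0)
            last = np.inf
            for alpha in (1.0, 0.7, 0.4, 0.1, 0.0):
                contracted = [a_bar + alpha * (v - a_bar) for v in vecs]
                omega = task_clustering_penalty(contracted, lambdas)
                assert omega <= last + 1e-12
                last = omega

    def test_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            task_clustering_penalty([np.ones(2), np.ones(3)], (0.5, 0.1))
        with pytest.raises(ValueError, match="non-negative"):
            task_clustering_penalty([np.ones(2), np.ones(2)], (0.5, -0.1))


def _outputs(p, count_idx, scores, k_max=3):
    dist = np.full(k_max, 1e-9)
    dist[count_idx] = 1.0 - dist.sum() + 1e-9
    dist = dist / dist.sum()
    return TaskOutputs(p_enzyme=p, count_dist=dist, ec_scores=np.asarray(scores))


class TestCompositeLoss:
    VOCAB = tuple(parse_ec(s) for s in ["1.1.1.1", "2.2.2.2"])

    def _config(self, penalty_weight=0.0):
        return ModelConfig(
            hidden_width=4, attention_heads=2, k_max=3,
            ec_vocabulary=self.VOCAB, penalty_weight=penalty_weight,
        )

    def test_perfect_predictions_leave_only_penalty(self):
        outputs = [
            _outputs(1.0, 0, [1.0, 0.0]),
            _outputs(0.0, 0, [0.0, 0.0]),
        ]
        labels = [(True, 1, np.array([1.0, 0.0])), (False, None, None)]
        vectors = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0])]
        total, parts = composite_loss(
            outputs, labels, self._config(penalty_weight=2.0), vectors
        )
        assert parts["task1"] == pytest.approx(0.0, abs=1e-5)
        assert parts["task2"] == pytest.approx(0.0, abs=1e-5)
        assert parts["task3"] == pytest.approx(0.0, abs=1e-5)
        assert parts["penalty"] == pytest.approx(2.0 * 11.8 / 9, rel=1e-9)
        assert total == pytest.approx(parts["penalty"], abs=1e-4)

    def test_matches_hand_computed_cross_entropies(self):
        outputs = [
            _outputs(0.8, 1, [0.9, 0.2]),
            _outputs(0.3, 0, [0.5, 0.5]),
        ]
        labels = [(True, 2, np.array([1.0, 0.0])), (False, None, None)]
        total, parts = composite_loss(outputs, labels, self._config())
        t1 = (-np.log(0.8) - np.log(0.7)) / 2
        t2 = -np.log(outputs[0].count_dist[1])
        t3 = -(np.log(0.9) + np.log(0.8)) / 2
        assert parts["task1"] == pytest.approx(t1, rel=1e-5)
        assert parts["task2"] == pytest.approx(t2, rel=1e-4)
        assert parts["task3"] == pytest.approx(t3, rel=1e-5)
        assert total == pytest.approx(t1 + t2 + t3, rel=1e-4)

    def test_penalty_weight_linearity(self):
        outputs = [_outputs(0.8, 1, [0.9, 0.2])]
        labels = [(True, 2, np.array([1.0, 0.0]))]
        vectors = [np.ones(2), np.zeros(2), np.ones(2)]
        omega = task_clustering_penalty(vectors, (0.5, 0.1, 0.4))
        t_a, _ = composite_loss(outputs, labels,
                                self._config(penalty_weight=1.0), vectors)
        t_b, _ = composite_loss(outputs, labels,
                                self._config(penalty_weight=2.0), vectors)
        assert t_b - t_a == pytest.approx(omega, rel=1e-9)

    def test_all_non_enzyme_batch_zeroes_tasks_2_and_3(self):
        outputs = [_outputs(0.2, 0, [0.5, 0.5])]
        labels = [(False, None, None)]
        _, parts = composite_loss(outputs, labels, self._config())
        assert parts["task2"] == 0.0 and parts["task3"] == 0.0


def _train_tiny(tasks=("task1", "task2", "task3"), seed=0, penalty_weight=0.01,
                max_epochs=8, n_records=100, mutation_rate=0.0,
                batch_size=32, learning_rate=1e-2):
    config = ez.SimConfig(
        n_records=n_records, length_range=(20, 30), label_counts=(2, 1, 1, 2),
        motif_len=4, non_enzyme_fraction=0.4, mutation_rate=mutation_rate,
        seed=3,
    )
    space = ez.build_label_space(2, 1, 1, 2, motif_len=4, seed=3)
    table, _ = ez.simulate_records(config, space)
    emb = ez.embed_table(table, "onehot", max_len=30)
    vocab = tuple(sorted(table.vocabulary))
    mc = ModelConfig(
        hidden_width=8, attention_heads=2, ec_vocabulary=vocab, tasks=tasks,
        batch_size=batch_size, max_epochs=max_epochs, patience=max_epochs,
        learning_rate=learning_rate, seed=seed, penalty_weight=penalty_weight,
    )
    model = ez.train(table, emb, mc)
    return model, table, emb, vocab


class TestTraining:
    def test_seeded_training_is_deterministic(self):
        a, *_ = _train_tiny(seed=11, max_epochs=2, n_records=60)
        b, *_ = _train_tiny(seed=11, max_epochs=2, n_records=60)
        assert a.parameter_hash() == b.parameter_hash()

    def test_training_loss_mostly_decreases(self):
        model, *_ = _train_tiny(seed=7, max_epochs=10, batch_size=64,
                                learning_rate=5e-3)
        losses = [h["loss_total"] for h in model.history]
        steps = sum(b < a for a, b in zip(losses, losses[1:]))
        assert steps >= 0.8 * (len(losses) - 1)

    def test_duplicate_inputs_get_identical_outputs(self):
        model, table, emb, vocab = _train_tiny(max_epochs=2, n_records=60)
        rid, other = table.ids[0], table.ids[1]
        outs = model.predict(
            {rid: emb[rid], other: emb[other]}, ids=[rid, rid, other]
        )
        np.testing.assert_array_equal(outs[0].ec_scores, outs[1].ec_scores)
        assert outs[0].p_enzyme == outs[1].p_enzyme

    def test_count_dist_normalized_for_every_input(self):
        model, table, emb, _ = _train_tiny(max_epochs=2, n_records=60)
        for out in model.predict(emb, ids=table.ids):
            assert out.count_dist.sum() == pytest.approx(1.0, abs=1e-6)

    def test_all_non_enzyme_data_leaves_task3_head_untouched(self):
        config = ez.SimConfig(
            n_records=40, length_range=(20, 30), label_counts=(2, 1, 1, 2),
            motif_len=4, non_enzyme_fraction=1.0, mutation_rate=0.0, seed=3,
        )
        space = ez.build_label_space(2, 1, 1, 2, motif_len=4, seed=3)
        table, _ = ez.simulate_records(config, space)
        emb = ez.embed_table(table, "onehot", max_len=30)
        vocab = tuple(parse_ec(s) for s in ["1.1.1.1", "1.1.1.2"])
        mc = ModelConfig(
            hidden_width=8, attention_heads=2, ec_vocabulary=vocab,
            batch_size=16, max_epochs=2, patience=2, seed=5,
        )
        from enzannot.model import _init_params

        init = _init_params(mc, 21, np.random.default_rng(mc.seed))
        before = {k: v.data.copy() for k, v in init.items()}
        model = ez.train(table, emb, mc)
        for name in model.params:
            if name.startswith("task3_") or name.startswith("task2_"):
                np.testing.assert_array_equal(model.params[name].data, before[name])
            if name.startswith("gru_") or name.startswith("task1_"):
                assert not np.array_equal(model.params[name].data, before[name])

    def test_predict_refuses_mismatched_embedding(self):
        model, table, emb, _ = _train_tiny(max_epochs=1, n_records=60)
        from enzannot.embedding import EmbeddingMatrix

        wrong_tag = {
            table.ids[0]: EmbeddingMatrix(
                np.zeros((5, 21)), np.ones(5, bool), "plugin:other:layer1"
            )
        }
        with pytest.raises(ValueError, match="method"):
            model.predict(wrong_tag)
        wrong_width = {
            table.ids[0]: EmbeddingMatrix(np.zeros((5, 8)), np.ones(5, bool), "onehot")
        }
        with pytest.raises(ValueError, match="width"):
            model.predict(wrong_width)

    def test_novel_validation_label_is_rejected_with_guidance(self):
        model, table, emb, vocab = _train_tiny(max_epochs=1, n_records=60)
        mc = ModelConfig(
            hidden_width=8, attention_heads=2, ec_vocabulary=vocab[:1],
            max_epochs=1, patience=1, seed=0,
        )
        train_ids = table.ids[:40]
        val_ids = table.ids[40:]
        with pytest.raises(ValueError, match="filter_novel_labels"):
            ez.train(
                table.subset(train_ids), {i: emb[i] for i in train_ids}, mc,
                table.subset(val_ids), {i: emb[i] for i in val_ids},
            )

    def test_checkpoint_roundtrip(self, tmp_path):
        model, table, emb, _ = _train_tiny(max_epochs=1, n_records=60)
        path = tmp_path / "model.npz"
        model.save(path)
        back = ez.model.TrainedModel.load(path)
        assert back.parameter_hash() == model.parameter_hash()
        assert back.config == model.config
        a = model.predict(emb, ids=table.ids[:3])
        b = back.predict(emb, ids=table.ids[:3])
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.ec_scores, y.ec_scores)


def test_predictions_are_padding_invariant():
    """The same sequences embedded at different max_len give identical
    predictions (masked attention + mask-gated recurrence)."""
    model, table, emb, _ = _train_tiny(max_epochs=2, n_records=60)
    ids = table.ids[:5]
    emb_wide = {i: ez.one_hot_embed(table[i].sequence, max_len=60) for i in ids}
    a = model.predict({i: emb[i] for i in ids}, ids=ids)
    b = model.predict(emb_wide, ids=ids)
    for x, y in zip(a, b):
        assert x.p_enzyme == pytest.approx(y.p_enzyme, abs=1e-9)
        np.testing.assert_allclose(x.ec_scores, y.ec_scores, atol=1e-9)


def test_stronger_penalty_shrinks_head_dispersion():
    """Scaling the clustering-penalty weight 10x reduces the trained
    heads' dispersion around their mean (majority over 3 seeds)."""
    wins = 0
    for seed in (0, 1, 2):
        weak, *_ = _train_tiny(seed=seed, penalty_weight=0.01, max_epochs=6)
        strong, *_ = _train_tiny(seed=seed, penalty_weight=0.1, max_epochs=6)

        def dispersion(model):
            vecs = model.task_vectors()
            a_bar = np.mean(vecs, axis=0)
            return sum(float((v - a_bar) @ (v - a_bar)) for v in vecs)

        wins += dispersion(strong) < dispersion(weak)
    assert wins >= 2
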