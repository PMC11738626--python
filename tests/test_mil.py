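"""Attention pooling algebra, permutation invariance, baselines."""

import numpy as np
import pytest

from dockmil import nn
from dockmil.errors import ConfigurationError, DataError
from dockmil.mil import (
    AttentionHead,
    attention_pool,
    baseline_avg,
    baseline_top,
    multihead_pool,
    predict_bag,
)


@pytest.fixture
def head():
    return AttentionHead(embedding_dim=8, fc_widths=(16, 8), rng=0)


class TestAttentionPool:
    def test_singleton_bag_gets_weight_one(self, head, rng):
        h = rng.normal(size=(1, 8))
        z, a = attention_pool(h, head)
        assert a == pytest.approx([1.0])
        assert np.allclose(z, h[0])

    def test_identical_embeddings_get_uniform_weights(self, head, rng):
        h = np.tile(rng.normal(size=(1, 8)), (4, 1))
        z, a = attention_pool(h, head)
        assert np.allclose(a, 0.25)
        assert np.allclose(z, h[0])

    def test_hand_oracle_softmax_of_plus_minus_one(self):
        """Logits (+1, -1): weights e/(e+1/e) = 0.8808 / 0.1192."""
        head = AttentionHead(embedding_dim=1, fc_widths=(4, 4), rng=0)
        # hand oracle: softmax of (+1, -1) is e/(e + 1/e) = 0.88079708...
        logits = np.array([1.0, -1.0])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        assert a == pytest.approx([0.8808, 0.1192], abs=1e-4)
        # drive tanh(W*h) to exactly +-1 with saturating arguments
        w = float(head.W.data[0, 0])
        H = np.array([[20.0 / w], [-20.0 / w]])
        _, a_impl = attention_pool(H, head)
        assert a_impl == pytest.approx([0.8808, 0.1192], abs=1e-4)

    def test_weights_normalized_on_random_bags(self, head, rng):
        for _ in range(20):
            K = int(rng.integers(1, 12))
            _, a = attention_pool(rng.normal(size=(K, 8)), head)
            assert np.all(a >= 0)
            assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_bag_rejected(self, head):
        with pytest.raises(DataError):
            attention_pool(np.zeros((0, 8)), head)

    def test_nonfinite_embedding_rejected(self, head):
        h = np.full((2, 8), np.nan)
        with pytest.raises(ValueError):
            attention_pool(h, head)


class TestPredictBag:
    def test_permutation_invariance_100_bags(self, head, rng):
        for _ in range(100):
            K = int(rng.integers(2, 11))
            H = rng.normal(size=(K, 8))
            ref = predict_bag(H, head)
            for _ in range(10):
                perm = rng.permutation(K)
                out = predict_bag(H[perm], head)
                assert out.y_hat == pytest.approx(ref.y_hat, rel=1e-6)
                assert np.allclose(out.attention_weights,
                                   ref.attention_weights[perm], atol=1e-12)

    def test_single_instance_equals_direct_fc(self, head, rng):
        h = rng.normal(size=(1, 8))
        direct = head.fc(nn.Tensor(h)).data.reshape(())
        assert predict_bag(h, head).y_hat == pytest.approx(float(direct))

    def test_zero_embeddings_zero_biases_give_zero(self):
        head = AttentionHead(embedding_dim=4, fc_widths=(4, 4), rng=1)
        for name, p in head.parameters().items():
            if name.endswith(".b"):
                p.data[:] = 0.0
        assert predict_bag(np.zeros((3, 4)), head).y_hat == 0.0

    def test_mil_reduces_to_avg_with_uniform_attention_identity_fc(self):
        # scalar embeddings, W = 0 (uniform weights), fc = identity on z > 0
        head = AttentionHead(embedding_dim=1, fc_widths=(1, 1), rng=0)
        head.W.data[:] = 0.0
        for layer in head.fc.layers:
            layer.W.data[:] = 1.0
            layer.b.data[:] = 0.0
        preds = [(1, 5.0), (2, 7.0)]
        H = np.array([[y] for _, y in preds])
        assert predict_bag(H, head).y_hat == pytest.approx(baseline_avg(preds))


class TestMultihead:
    def test_one_head_reduces_to_single(self, rng):
        H = rng.normal(size=(5, 8))
        single = AttentionHead(8, fc_widths=(16, 8), rng=3)
        multi = AttentionHead(8, fc_widths=(16, 8), mode="multihead", n_heads=1, rng=3)
        multi.load_state_dict(single.state_dict())
        z1, a1 = attention_pool(H, single)
        z2, a2 = multihead_pool(H, multi)
        assert np.allclose(z1, z2)
        assert np.allclose(a1, a2.ravel())

    def test_identical_embeddings_uniform_per_head(self, rng):
        head = AttentionHead(8, mode="multihead", n_heads=4, rng=2)
        H = np.tile(rng.normal(size=(1, 8)), (5, 1))
        _, a = multihead_pool(H, head)
        assert a.shape == (5, 4)
        assert np.allclose(a, 0.2)

    def test_permutation_invariance(self, rng):
        head = AttentionHead(8, mode="multihead", n_heads=2, rng=2)
        H = rng.normal(size=(6, 8))
        ref = predict_bag(H, head)
        perm = rng.permutation(6)
        out = predict_bag(H[perm], head)
        assert out.y_hat == pytest.approx(ref.y_hat, rel=1e-6)

    def test_indivisible_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            AttentionHead(10, mode="multihead", n_heads=3)


class TestAttentionSelectivity:
    def test_trained_head_upweights_the_informative_instance(self):
        """Bags where one instance carries the label signal (plus a quality
        signature) and the rest are noise: after training, the mean weight on
        the informative instance exceeds the uniform 1/K in >= 8/10 seeds."""
        from dockmil.structio import EmbeddingStore
        from dockmil.train import TrainConfig, train_mil

        D, K, n_bags = 8, 6, 100
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            store = EmbeddingStore()
            labels = {}
            informative_slot = {}
            for b in range(n_bags):
                y = float(rng.normal(loc=6.0, scale=1.5))
                slot = int(rng.integers(K))
                for k in range(K):
                    h = rng.normal(scale=0.5, size=D)
                    if k == slot:
                        h[0] = y - 6.0
                        h[1] = 1.0  # pose-quality signature
                    else:
                        h[1] = -1.0
                    store.write(f"b{b}", k + 1, h)
                labels[f"b{b}"] = y
                informative_slot[f"b{b}"] = slot
            head = train_mil(store, labels, TrainConfig(epochs=200, seed=seed),
                             fc_widths=(16, 8))
            weights = []
            for b in range(n_bags):
                H = np.array([v for _, v in store.read(f"b{b}")])
                pred = predict_bag(H, head)
                weights.append(pred.attention_weights[informative_slot[f"b{b}"]])
            if np.mean(weights) > 1.0 / K:
                successes += 1
        assert successes >= 8


class TestBaselines:
    def test_top_and_avg_definitions(self):
        preds = [(1, 5.0), (2, 7.0)]
        assert baseline_top(preds) == 5.0
        assert baseline_avg(preds) == 6.0

    def test_single_pose_top_equals_avg(self):
        preds = [(1, 4.2)]
        assert baseline_top(preds) == baseline_avg(preds) == 4.2

    def test_missing_rank_one_is_undefined(self):
        with pytest.raises(DataError):
            baseline_top([(2, 5.0), (3, 6.0)])


class TestBatchedForward:
    def test_ragged_batch_matches_per_bag_pooling(self, head, rng):
        bags = [rng.normal(size=(k, 8)) for k in (3, 1, 7)]
        H = nn.Tensor(np.vstack(bags))
        ids = np.concatenate([np.full(len(b), i) for i, b in enumerate(bags)])
        y, w = head.forward_bags(H, ids, 3)
        for i, b in enumerate(bags):
            ref = predict_bag(b, head)
            got = float(y.data[i]) * head.y_std + head.y_mean
            assert got == pytest.approx(ref.y_hat, rel=1e-9)
            assert np.allclose(w.data[ids == i, 0], ref.attention_weights)


def test_prediction_table_writer(tmp_path, rng):
    from dockmil.mil import write_predictions

    head = AttentionHead(embedding_dim=4, fc_widths=(4, 4), rng=0)
    preds = [predict_bag(rng.normal(size=(k, 4)), head, f"e{k}")
             for k in (1, 3)]
    path = tmp_path / "preds.tsv"
    write_predictions(preds, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["entity_id", "y_hat", "K",
                                     "attention_weights"]
    assert lines[1].split("\t")[0] == "e1"
    assert len(lines[2].split("\t")[3].split(",")) == 3
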