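"""Schedule closed form, determinism, extraction snapshot semantics."""

import numpy as np
import pytest

from dockmil.backbones import BackboneConfig
from dockmil.errors import DataError
from dockmil.mil import predict_bag
from dockmil.structio import EmbeddingStore
from dockmil.train import (
    TrainConfig,
    bag_instance_graphs,
    extract_embeddings,
    lr_at_epoch,
    train_backbone,
    train_mil,
    train_simultaneous,
)


class TestLrSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [
            (0, 1e-3),
            (4, 1e-3),
            (5, 9e-4),
            (12, 8.1e-4),  # past milestones 5 and 10
            (200, 1e-3 * 0.9**7),  # all seven milestones passed
        ],
    )
    def test_closed_form(self, epoch, expected):
        assert lr_at_epoch(TrainConfig(), epoch) == pytest.approx(expected, rel=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_milestones=(5, 5, 10))
        with pytest.raises(ValueError):
            TrainConfig(lr_gamma=1.5)


@pytest.fixture(scope="module")
def small_training(tiny_dataset):
    config = BackboneConfig(architecture="sgcnn", embedding_dim=16, hidden_dim=8)
    bags = tiny_dataset.bags
    graphs = bag_instance_graphs(bags, config)
    return bags, config, graphs


class TestTrainBackbone:
    def test_zero_epochs_returns_initialized_model(self, small_training):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=0, seed=1),
                               backbone_config=config, instance_graphs=graphs)
        assert model.history == []

    def test_same_seed_gives_identical_loss_traces(self, small_training):
        bags, config, graphs = small_training
        cfg = TrainConfig(epochs=3, seed=7)
        m1 = train_backbone(bags, cfg, backbone_config=config, instance_graphs=graphs)
        m2 = train_backbone(bags, cfg, backbone_config=config, instance_graphs=graphs)
        assert m1.history == m2.history
        for k, p in m1.parameters().items():
            assert np.array_equal(p.data, m2.parameters()[k].data)

    def test_lr_trace_follows_schedule(self, small_training):
        bags, config, graphs = small_training
        cfg = TrainConfig(epochs=12, seed=0)
        model = train_backbone(bags, cfg, backbone_config=config,
                               instance_graphs=graphs)
        assert model.lr_trace == [lr_at_epoch(cfg, e) for e in range(12)]

    def test_empty_training_set_rejected(self):
        with pytest.raises(DataError):
            train_backbone([], TrainConfig(epochs=1))


class TestExtractEmbeddings:
    def test_one_record_per_pose_and_snapshot_semantics(self, small_training):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=1, seed=0),
                               backbone_config=config, instance_graphs=graphs)
        store = extract_embeddings(model, bags, instance_graphs=graphs)
        for bag in bags:
            assert len(store.read(bag.entity_id)) == bag.K
        ref = store.read(bags[0].entity_id)[0][1].copy()
        # two extractions agree; mutating the model later leaves store intact
        store2 = extract_embeddings(model, bags, instance_graphs=graphs)
        assert np.array_equal(store2.read(bags[0].entity_id)[0][1], ref)
        for p in model.parameters().values():
            p.data += 1.0
        assert np.array_equal(store.read(bags[0].entity_id)[0][1], ref)

    def test_hdf5_store_roundtrips_through_structio(self, small_training, tmp_path):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=0, seed=0),
                               backbone_config=config, instance_graphs=graphs)
        with EmbeddingStore(tmp_path / "emb.h5") as store:
            extract_embeddings(model, bags, store=store, instance_graphs=graphs)
        with EmbeddingStore(tmp_path / "emb.h5", mode="r") as back:
            mem = extract_embeddings(model, bags, instance_graphs=graphs)
            for bag in bags:
                for (r1, v1), (r2, v2) in zip(back.read(bag.entity_id),
                                              mem.read(bag.entity_id)):
                    assert r1 == r2
                    assert np.array_equal(v1, v2)


class TestTrainMil:
    def test_store_order_does_not_change_training(self, small_training, rng):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=1, seed=0),
                               backbone_config=config, instance_graphs=graphs)
        labels = {b.entity_id: b.label for b in bags}
        store1 = extract_embeddings(model, bags, instance_graphs=graphs)
        shuffled = list(graphs)
        rng.shuffle(shuffled)
        store2 = extract_embeddings(model, bags, instance_graphs=shuffled)
        cfg = TrainConfig(epochs=5, seed=3)
        h1 = train_mil(store1, labels, cfg, fc_widths=(8, 4))
        h2 = train_mil(store2, labels, cfg, fc_widths=(8, 4))
        for k, p in h1.parameters().items():
            assert np.allclose(p.data, h2.parameters()[k].data)

    def test_label_without_embeddings_rejected(self, small_training):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=0, seed=0),
                               backbone_config=config, instance_graphs=graphs)
        store = extract_embeddings(model, bags, instance_graphs=graphs)
        labels = {b.entity_id: b.label for b in bags}
        labels["missing-entity"] = 5.0
        with pytest.raises(DataError):
            train_mil(store, labels, TrainConfig(epochs=1, seed=0))

    def test_mil_lr_trace_follows_schedule(self, small_training):
        bags, config, graphs = small_training
        model = train_backbone(bags, TrainConfig(epochs=0, seed=0),
                               backbone_config=config, instance_graphs=graphs)
        store = extract_embeddings(model, bags, instance_graphs=graphs)
        labels = {b.entity_id: b.label for b in bags}
        cfg = TrainConfig(epochs=8, seed=0)
        head = train_mil(store, labels, cfg, fc_widths=(8, 4))
        assert head.lr_trace == [lr_at_epoch(cfg, e) for e in range(8)]


def test_simultaneous_training_smoke(tiny_dataset):
    """Option 1 (end-to-end, one bag per step): loss decreases, heads usable."""
    bags = tiny_dataset.bags[:4]
    config = BackboneConfig(architecture="sgcnn", embedding_dim=8, hidden_dim=8)
    model, head = train_simultaneous(
        bags, TrainConfig(epochs=4, seed=0), backbone_config=config,
        fc_widths=(8, 4),
    )
    assert model.history[-1] < model.history[0]
    store = extract_embeddings(model, bags)
    H = np.array([v for _, v in store.read(bags[0].entity_id)])
    pred = predict_bag(H, head, bags[0].entity_id)
    assert np.isfinite(pred.y_hat)


def test_train_config_file_roundtrip(tmp_path):
    cfg = TrainConfig(epochs=42, seed=7, batch_size=10,
                      lr_milestones=(3, 6), train_pose_sources="docking")
    cfg.to_file(tmp_path / "train.cfg")
    back = TrainConfig.from_file(tmp_path / "train.cfg")
    assert back == cfg
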