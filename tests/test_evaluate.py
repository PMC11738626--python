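"""Metrics oracle, stratification, pairwise RMSD, ablation mechanics."""

import numpy as np
import pytest
from scipy import stats

from dockmil.backbones import BackboneConfig
from dockmil.errors import DataError
from dockmil.evaluate import (
    bag_size_ablation,
    compare_methods,
    compute_metrics,
    count_good_poses,
    group_metrics,
    pairwise_rmsd_stats,
)
from dockmil.mil import AttentionHead
from dockmil.structio import EmbeddingStore
from dockmil.train import TrainConfig, bag_instance_graphs, train_backbone, train_mil, extract_embeddings


def _textbook_metrics(y_hat, y):
    """Independent recomputation from the definitions."""
    y_hat, y = np.asarray(y_hat), np.asarray(y)
    n = len(y)
    rmse = (sum((a - b) ** 2 for a, b in zip(y_hat, y)) / n) ** 0.5
    mae = sum(abs(a - b) for a, b in zip(y_hat, y)) / n
    ss_res = sum((a - b) ** 2 for a, b in zip(y_hat, y))
    ss_tot = sum((b - y.mean()) ** 2 for b in y)
    r2 = 1 - ss_res / ss_tot
    cov = ((y_hat - y_hat.mean()) * (y - y.mean())).sum()
    pearson = cov / np.sqrt(((y_hat - y_hat.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum())
    rk_a = stats.rankdata(y_hat)
    rk_b = stats.rankdata(y)
    cov_r = ((rk_a - rk_a.mean()) * (rk_b - rk_b.mean())).sum()
    spearman = cov_r / np.sqrt(((rk_a - rk_a.mean()) ** 2).sum()
                               * ((rk_b - rk_b.mean()) ** 2).sum())
    return rmse, mae, r2, pearson, spearman


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([4.1, 5.2, 6.3], [4.1, 5.2, 6.3])
        assert rep.rmse == 0 and rep.mae == 0
        assert rep.r2 == 1 and rep.pearson_r == pytest.approx(1)
        assert rep.spearman_rho == pytest.approx(1)

    def test_closed_form_two_points(self):
        rep = compute_metrics([0, 0], [3, 4])
        assert rep.rmse == pytest.approx(np.sqrt(12.5))
        assert rep.mae == pytest.approx(3.5)

    def test_matches_textbook_formulas_on_random_vectors(self, rng):
        y_hat = rng.normal(size=100)
        y = 0.6 * y_hat + rng.normal(size=100)
        rep = compute_metrics(y_hat, y)
        rmse, mae, r2, pearson, spearman = _textbook_metrics(y_hat, y)
        assert abs(rep.rmse - rmse) < 1e-10
        assert abs(rep.mae - mae) < 1e-10
        assert abs(rep.r2 - r2) < 1e-10
        assert abs(rep.pearson_r - pearson) < 1e-10
        assert abs(rep.spearman_rho - spearman) < 1e-10

    def test_spearman_uses_average_ranks_on_ties(self):
        y_hat = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([2.0, 1.0, 3.0, 4.0])
        rep = compute_metrics(y_hat, y)
        assert rep.spearman_rho == pytest.approx(
            float(stats.spearmanr(y_hat, y).statistic))

    def test_zero_variance_reference_flags_undefined(self):
        rep = compute_metrics([1.0, 2.0], [3.0, 3.0])
        assert rep.rmse > 0
        assert rep.r2 is None and rep.pearson_r is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            compute_metrics([1.0], [1.0, 2.0])


class TestGoodPoses:
    @pytest.mark.parametrize(
        "rmsds,count,label",
        [
            ((1.0, 3.0, 2.4), 2, "1-4"),
            ((2.5, 2.5), 0, "none"),  # strict: exactly 2.5 is not good
            (tuple([0.5] * 10), 10, ">4"),
            ((2.499, 5.0), 1, "1-4"),
        ],
    )
    def test_count_and_partition(self, rmsds, count, label):
        got_count, got_label = count_good_poses(rmsds)
        assert got_count == count
        assert got_label == label

    def test_group_metrics_partitions_entities(self, rng):
        preds = {f"e{i}": float(rng.normal()) for i in range(12)}
        labels = {e: v + 0.1 for e, v in preds.items()}
        counts = {f"e{i}": [0, 2, 9][i % 3] for i in range(12)}
        out = group_metrics(preds, labels, counts)
        assert set(out) == {"none", "1-4", ">4"}
        assert sum(rep.n for rep in out.values()) == 12


class TestPairwiseRmsd:
    def test_k3_bag_has_three_pairs(self, tiny_dataset):
        bag = tiny_dataset.bags[0]
        bag3 = type(bag)(bag.entity_id, bag.label, bag.instances[:3],
                         bag.protein_atoms)
        vals, density, edges = pairwise_rmsd_stats(bag3)
        assert len(vals) == 3
        widths = np.diff(edges)
        assert (density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_poses_have_zero_pairwise_rmsd(self, tiny_dataset):
        bag = tiny_dataset.bags[0]
        same = type(bag)(bag.entity_id, bag.label,
                         [bag.instances[0]] * 3, bag.protein_atoms)
        vals, _, _ = pairwise_rmsd_stats(same)
        assert np.allclose(vals, 0.0)

    def test_single_pose_bag_warns_and_returns_empty(self, tiny_dataset):
        bag = tiny_dataset.bags[0]
        b1 = type(bag)(bag.entity_id, bag.label, bag.instances[:1],
                       bag.protein_atoms)
        with pytest.warns(UserWarning):
            vals, _, _ = pairwise_rmsd_stats(b1)
        assert len(vals) == 0


@pytest.fixture(scope="module")
def trained_small(tiny_dataset):
    config = BackboneConfig(architecture="sgcnn", embedding_dim=16, hidden_dim=8)
    bags = tiny_dataset.bags
    graphs = bag_instance_graphs(bags, config)
    model = train_backbone(bags, TrainConfig(epochs=2, seed=0),
                           backbone_config=config, instance_graphs=graphs)
    store = extract_embeddings(model, bags, instance_graphs=graphs)
    labels = {b.entity_id: b.label for b in bags}
    head = train_mil(store, labels, TrainConfig(epochs=5, seed=1),
                     fc_widths=(8, 4))
    return bags, model, head, store, labels, graphs


class TestCompareMethods:
    def test_table_shape_and_methods(self, trained_small):
        bags, model, head, store, labels, graphs = trained_small
        table, details = compare_methods(model, head, bags,
                                         instance_graphs=graphs, store=store)
        assert table.shape == (3, 5)
        assert list(table.index) == ["Top", "Avg", "MIL"]
        assert set(details["per_entity"]) == {b.entity_id for b in bags}

    def test_constant_backbone_makes_top_equal_avg(self, trained_small):
        bags, model, head, store, labels, graphs = trained_small
        # zero all parameters: every per-pose prediction becomes the same constant
        for p in model.parameters().values():
            p.data[:] = 0.0
        table, details = compare_methods(model, head, bags,
                                         instance_graphs=graphs)
        assert table.loc["Top", "rmse"] == pytest.approx(table.loc["Avg", "rmse"])


class TestBagSizeAblation:
    def test_full_bag_k_makes_all_trials_identical(self, trained_small):
        bags, model, head, store, labels, graphs = trained_small
        K = bags[0].K
        out = bag_size_ablation(head, store, labels, k_values=(K,), trials=5,
                                seed=0)
        assert out[K]["rmse"]["min"] == pytest.approx(out[K]["rmse"]["max"])

    def test_fixed_seed_reproduces_sampling(self, trained_small):
        bags, model, head, store, labels, graphs = trained_small
        a = bag_size_ablation(head, store, labels, k_values=(2, 3), trials=4,
                              seed=9)
        b = bag_size_ablation(head, store, labels, k_values=(2, 3), trials=4,
                              seed=9)
        assert a == b

    def test_k_larger_than_any_bag_rejected(self, trained_small):
        bags, model, head, store, labels, graphs = trained_small
        with pytest.raises(DataError):
            bag_size_ablation(head, store, labels, k_values=(99,), trials=2,
                              seed=0)
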