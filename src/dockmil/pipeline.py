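"""End-to-end convenience wrapper: featurize -> stage 1 -> stage 2 -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass, field

from .backbones import BackboneConfig, BackboneModel
from .evaluate import compare_methods
from .mil import AttentionHead
from .structio import Bag, EmbeddingStore
from .train import TrainConfig, bag_instance_graphs, extract_embeddings, train_backbone, train_mil

__all__ = ["TwoStageResult", "run_two_stage"]


@dataclass
class TwoStageResult:
    backbone: BackboneModel
    head: AttentionHead
    table: object  # 3x5 DataFrame over Top/Avg/MIL
    details: dict
    test_store: EmbeddingStore
    config: BackboneConfig
    train_cfg: TrainConfig = field(default=None)


def run_two_stage(
    train_bags: list[Bag],
    test_bags: list[Bag],
    architecture: str = "sgcnn",
    embedding_dim: int = 32,
    hidden_dim: int = 16,
    seed: int = 0,
    stage1_epochs: int = 8,
    stage2_epochs: int = 60,
    batch_size: int = 20,
    fc_widths: tuple[int, int] = (128, 64),
    pose_sources: str = "both",
    backbone_config: BackboneConfig | None = None,
) -> TwoStageResult:
    """Separate (two-stage) training on train_bags, Top/Avg/MIL report on test_bags."""
    if backbone_config is None:
        backbone_config = BackboneConfig(
            architecture=architecture,
            embedding_dim=embedding_dim,
            hidden_dim=hidden_dim,
        )
    cfg1 = TrainConfig(epochs=stage1_epochs, batch_size=batch_size, seed=seed,
                       train_pose_sources=pose_sources)
    cfg2 = TrainConfig(epochs=stage2_epochs, batch_size=batch_size, seed=seed + 1)

    train_graphs = bag_instance_graphs(train_bags, backbone_config, pose_sources)
    backbone = train_backbone(train_bags, cfg1, backbone_config=backbone_config,
                              instance_graphs=train_graphs)
    train_store = extract_embeddings(backbone, train_bags,
                                     instance_graphs=train_graphs)
    labels = {b.entity_id: b.label for b in train_bags}
    head = train_mil(train_store, labels, cfg2, fc_widths=fc_widths)

    test_graphs = bag_instance_graphs(test_bags, backbone_config, "both")
    test_store = extract_embeddings(backbone, test_bags,
                                    instance_graphs=test_graphs)
    table, details = compare_methods(backbone, head, test_bags,
                                     instance_graphs=test_graphs,
                                     store=test_store)
    return TwoStageResult(backbone, head, table, details, test_store,
                          backbone_config, cfg1)
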