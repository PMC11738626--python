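"""Two-stage ("separate") training.

Stage 1 trains a backbone on individual pose instances, each instance
inheriting its entity's affinity label.  Stage 2 freezes the backbone,
extracts one embedding per (entity, pose), and trains the attention head on
bags of embeddings.  Both stages minimize mean squared error with RMSprop
under a multi-step learning-rate schedule (initial 0.001, decayed by 0.9 at
epochs 5, 10, 20, 30, 50, 70 and 90); the last-epoch model is returned, with
no validation-based checkpoint selection.

Labels are standardized to zero mean / unit variance inside each stage and
de-standardized at prediction time; the scaling constants travel with the
model.

A single-stage end-to-end option (:func:`train_simultaneous`) trains backbone
and head jointly with a batch size of one bag.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .backbones import BackboneConfig, BackboneModel, batch_graphs
from .errors import DataError
from .featurize import atom_feature_table, featurize_complex
from .graphs import build_radius_graph, build_sgcnn_graph
from .mil import AttentionHead
from .structio import Bag, EmbeddingStore

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "train_backbone",
    "extract_embeddings",
    "train_mil",
    "train_simultaneous",
    "bag_instance_graphs",
]


@dataclass
class TrainConfig:
    optimizer: str = "rmsprop"
    lr0: float = 1e-3
    lr_milestones: tuple[int, ...] = (5, 10, 20, 30, 50, 70, 90)
    lr_gamma: float = 0.9
    batch_size: int = 20  # instances (stage 1) or bags (stage 2)
    epochs: int = 150
    seed: int = 0
    checkpoint_policy: str = "last-epoch"
    train_pose_sources: str = "both"  # "crystal" | "docking" | "both"

    def __post_init__(self):
        ms = tuple(self.lr_milestones)
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("lr_milestones must be strictly increasing")
        if not 0.0 < self.lr_gamma < 1.0:
            raise ValueError("lr_gamma must be in (0, 1)")
        self.lr_milestones = ms

    def to_file(self, path) -> None:
        """Flat key = value text file mirroring the config fields."""
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        kwargs = {}
        casts = {"lr0": float, "lr_gamma": float, "batch_size": int,
                 "epochs": int, "seed": int}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.strip().startswith("#"):
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            if k == "lr_milestones":
                kwargs[k] = tuple(int(x) for x in v.split(",") if x)
            elif k in casts:
                kwargs[k] = casts[k](v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def manifest(self, extra: dict | None = None) -> dict:
        out = asdict(self)
        if extra:
            out.update(extra)
        return out


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """lr0 * gamma**m where m counts milestones <= epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    m = sum(1 for ms in cfg.lr_milestones if ms <= epoch)
    return cfg.lr0 * cfg.lr_gamma**m


# ---------------------------------------------------------------------------
# featurization/graph plumbing shared by both stages
# ---------------------------------------------------------------------------


def _select_instances(bag: Bag, sources: str):
    for pose in bag.instances:
        if sources == "crystal" and not pose.is_crystal:
            continue
        if sources == "docking" and pose.is_crystal:
            continue
        yield pose


def bag_instance_graphs(bags: list[Bag], config: BackboneConfig,
                        sources: str = "both"):
    """Featurize and graph every selected pose of every bag.

    Returns a list of ``(entity_id, pose_rank, label, graph)``.  The protein
    feature table is computed once per bag and the ligand table once per pose
    molecule (features depend on topology, not coordinates).
    """
    build = build_sgcnn_graph if config.architecture == "sgcnn" else build_radius_graph
    out = []
    for bag in bags:
        prot_features = atom_feature_table(bag.protein_atoms, config.charge_model)
        lig_features = None
        for pose in _select_instances(bag, sources):
            if lig_features is None:
                lig_features = atom_feature_table(
                    pose.ligand_atoms, config.charge_model
                )
            inst = featurize_complex(
                bag.protein_atoms,
                pose,
                pocket_radius=config.pocket_radius,
                charge_model=config.charge_model,
                protein_features=prot_features,
                ligand_features=lig_features,
            )
            if config.architecture == "sgcnn":
                graph = build(inst, config.covalent_cutoff, config.noncovalent_cutoff)
            else:
                graph = build(inst, config.radius_cutoff)
            out.append((bag.entity_id, pose.pose_rank, bag.label, graph))
    return out


# ---------------------------------------------------------------------------
# stage 1: backbone
# ---------------------------------------------------------------------------


def train_backbone(
    train_bags: list[Bag],
    cfg: TrainConfig,
    architecture: str = "sgcnn",
    backbone_config: BackboneConfig | None = None,
    instance_graphs: list | None = None,
) -> BackboneModel:
    """Train a backbone on individual pose instances (entity-level labels)."""
    if backbone_config is None:
        backbone_config = BackboneConfig(architecture=architecture)
    if instance_graphs is None:
        if not train_bags:
            raise DataError("empty training set")
        instance_graphs = bag_instance_graphs(
            train_bags, backbone_config, cfg.train_pose_sources
        )
    if not instance_graphs:
        raise DataError("no trainable instances after pose-source filtering")

    rng = np.random.default_rng(cfg.seed)
    model = BackboneModel(backbone_config, rng)
    labels = np.array([y for _, _, y, _ in instance_graphs])
    model.y_mean = float(labels.mean())
    model.y_std = float(labels.std()) or 1.0
    y = (labels - model.y_mean) / model.y_std
    graphs = [g for _, _, _, g in instance_graphs]

    opt = nn.RMSprop(model.parameters(), lr=cfg.lr0)
    n = len(graphs)
    model.lr_trace = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        model.lr_trace.append(opt.lr)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            _, pred = model.forward_batch(batch)
            err = pred - nn.Tensor(y[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        model.history.append(total / n)
    return model


# ---------------------------------------------------------------------------
# stage 2: frozen extraction + attention head
# ---------------------------------------------------------------------------


def extract_embeddings(
    model: BackboneModel,
    bags: list[Bag],
    store: EmbeddingStore | None = None,
    sources: str = "both",
    instance_graphs: list | None = None,
    batch_size: int = 64,
) -> EmbeddingStore:
    """Embed every pose of every bag with the frozen backbone.

    No parameter updates occur; the store snapshots the embeddings, so later
    mutation of the model does not affect them.
    """
    if store is None:
        store = EmbeddingStore()
    if instance_graphs is None:
        instance_graphs = bag_instance_graphs(bags, model.config, sources)
    for start in range(0, len(instance_graphs), batch_size):
        chunk = instance_graphs[start : start + batch_size]
        emb = model.embed([g for _, _, _, g in chunk])
        for (entity_id, rank, _, _), vec in zip(chunk, emb):
            store.write(entity_id, rank, vec)
    return store


def train_mil(
    store: EmbeddingStore,
    labels: dict[str, float],
    cfg: TrainConfig,
    mode: str = "single",
    n_heads: int = 1,
    fc_widths: tuple[int, int] = (128, 64),
) -> AttentionHead:
    """Train the attention head on bags of frozen embeddings."""
    entities = sorted(labels)
    missing = [e for e in entities if e not in set(store.entities())]
    if missing:
        raise DataError(f"labeled entities without embeddings: {missing[:5]}")
    bags_H = []
    for e in entities:
        H = np.array([v for _, v in store.read(e)])
        if H.size == 0:
            raise DataError(f"entity {e} has no embeddings")
        bags_H.append(H)
    dim = bags_H[0].shape[1]

    rng = np.random.default_rng(cfg.seed)
    head = AttentionHead(dim, fc_widths=fc_widths, mode=mode, n_heads=n_heads, rng=rng)
    all_H = np.vstack(bags_H)
    head.h_mean = all_H.mean(axis=0)
    head.h_std = np.where(all_H.std(axis=0) < 1e-8, 1.0, all_H.std(axis=0))
    bags_H = [head.standardize(H) for H in bags_H]
    y_all = np.array([labels[e] for e in entities])
    head.y_mean = float(y_all.mean())
    head.y_std = float(y_all.std()) or 1.0
    y = (y_all - head.y_mean) / head.y_std

    opt = nn.RMSprop(head.parameters(), lr=cfg.lr0)
    n = len(entities)
    head.lr_trace = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        head.lr_trace.append(opt.lr)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            H = nn.Tensor(np.vstack([bags_H[i] for i in idx]))
            bag_ids = np.concatenate(
                [np.full(len(bags_H[i]), j) for j, i in enumerate(idx)]
            )
            pred, _ = head.forward_bags(H, bag_ids, len(idx))
            err = pred - nn.Tensor(y[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        head.history.append(total / n)
    return head


# ---------------------------------------------------------------------------
# option 1: simultaneous end-to-end training (batch = 1 bag)
# ---------------------------------------------------------------------------


def train_simultaneous(
    train_bags: list[Bag],
    cfg: TrainConfig,
    architecture: str = "sgcnn",
    backbone_config: BackboneConfig | None = None,
    fc_widths: tuple[int, int] = (128, 64),
) -> tuple[BackboneModel, AttentionHead]:
    """Joint training of backbone + head; gradients flow end to end."""
    if not train_bags:
        raise DataError("empty training set")
    if backbone_config is None:
        backbone_config = BackboneConfig(architecture=architecture)
    rng = np.random.default_rng(cfg.seed)
    model = BackboneModel(backbone_config, rng)
    head = AttentionHead(
        backbone_config.embedding_dim, fc_widths=fc_widths, rng=rng
    )
    per_bag = [
        [g for _, _, _, g in bag_instance_graphs([bag], backbone_config,
                                                 cfg.train_pose_sources)]
        for bag in train_bags
    ]
    y_all = np.array([bag.label for bag in train_bags])
    mean, std = float(y_all.mean()), float(y_all.std()) or 1.0
    for m in (model, head):
        m.y_mean, m.y_std = mean, std
    y = (y_all - mean) / std
    params = {**model.parameters("backbone."), **head.parameters("head.")}
    opt = nn.RMSprop(params, lr=cfg.lr0)
    n = len(train_bags)
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        total = 0.0
        for i in order:  # mini-batch of one bag
            emb, _ = model.forward_batch(batch_graphs(per_bag[i]))
            pred, _ = head.forward_bags(emb, np.zeros(emb.shape[0], dtype=int), 1)
            err = pred - nn.Tensor(np.array([y[i]]))
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
        model.history.append(total / n)
    head.history = list(model.history)
    return model, head


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def write_manifest(path, cfg: TrainConfig, backbone_config: BackboneConfig,
                   data_ids: list[str]) -> None:
    """Resolved settings + seed + a digest of the training entities."""
    digest = hashlib.sha256("\n".join(sorted(data_ids)).encode()).hexdigest()[:16]
    manifest = {
        "train": cfg.manifest(),
        "backbone": asdict(backbone_config),
        "rmsprop_defaults": {"alpha": 0.99, "eps": 1e-8},
        "data_digest": digest,
        "n_entities": len(data_ids),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
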