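"""Attention-based multi-instance pooling over a bag of pose embeddings.

The head computes one logit per instance, ``logit_k = tanh(W h_k^T)``, turns
the K logits into weights with a softmax, pools ``z = sum_k a_k h_k`` and maps
z through a three-layer fully-connected stack to the predicted affinity.  The
weights are nonnegative, sum to one per bag, and the whole map is invariant
to the order of instances.

A multi-head variant splits the embedding into ``n_heads`` contiguous slices,
attends over each slice with its own projection, and concatenates the
per-head pooled vectors.  ``n_heads=1`` reduces exactly to the single-head
form.

Bags of varying K are processed as ragged (concatenated) batches with a
segment softmax; instances absent from a bag simply contribute no rows, so
they carry exactly zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError

__all__ = [
    "AttentionHead",
    "BagPrediction",
    "attention_pool",
    "multihead_pool",
    "predict_bag",
    "baseline_top",
    "baseline_avg",
    "write_predictions",
]


@dataclass
class BagPrediction:
    entity_id: str
    y_hat: float
    attention_weights: np.ndarray  # (K,) single-head or (K, n_heads)


class AttentionHead(nn.Module):
    """Attention projection W + three fully-connected layers on pooled z."""

    def __init__(
        self,
        embedding_dim: int,
        fc_widths: tuple[int, int] = (128, 64),
        mode: str = "single",
        n_heads: int = 1,
        rng: np.random.Generator | int = 0,
    ):
        super().__init__()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        if mode not in ("single", "multihead"):
            raise ConfigurationError(f"unknown attention mode {mode!r}")
        if mode == "single":
            n_heads = 1
        if embedding_dim % n_heads != 0:
            raise ConfigurationError(
                f"embedding dim {embedding_dim} not divisible by {n_heads} heads"
            )
        self.embedding_dim = embedding_dim
        self.mode = mode
        self.n_heads = n_heads
        self.slice_dim = embedding_dim // n_heads
        bound = np.sqrt(6.0 / (self.slice_dim + 1))
        self.W = self.register(
            "W", nn.Tensor(rng.uniform(-bound, bound, (n_heads, self.slice_dim)), True)
        )
        self.fc = self.register(
            "fc",
            nn.MLP([embedding_dim, *fc_widths, 1], rng, activation="relu"),
        )
        # label standardization (set by training; identity by default)
        self.y_mean = 0.0
        self.y_std = 1.0
        # embedding standardization, fitted on the training store: keeps the
        # tanh attention out of saturation whatever the backbone's scale
        self.h_mean = np.zeros(embedding_dim)
        self.h_std = np.ones(embedding_dim)
        self.history: list[float] = []

    def standardize(self, H: np.ndarray) -> np.ndarray:
        return (np.asarray(H, dtype=float) - self.h_mean) / self.h_std

    # -- batched forward (training path) -------------------------------------
    def forward_bags(self, H: nn.Tensor, bag_ids: np.ndarray, n_bags: int):
        """Pool concatenated bag embeddings.

        ``H`` is (M, D) with ``bag_ids`` assigning each row to a bag.
        Returns (y_hat Tensor (n_bags,), weights Tensor (M, n_heads)).
        """
        zs, ws = [], []
        for head in range(self.n_heads):
            sl = slice(head * self.slice_dim, (head + 1) * self.slice_dim)
            Hs = H[:, sl]
            logits = nn.tanh(Hs @ self.W[head, :].reshape(-1, 1)).reshape(-1)
            a = nn.segment_softmax(logits, bag_ids, n_bags)
            zs.append(nn.segment_sum(a.reshape(-1, 1) * Hs, bag_ids, n_bags))
            ws.append(a.reshape(-1, 1))
        z = nn.concatenate(zs, axis=1)
        y = self.fc(z).reshape(-1)
        return y, nn.concatenate(ws, axis=1)

    def _validate(self, H: np.ndarray) -> np.ndarray:
        H = np.asarray(H, dtype=float)
        if H.ndim != 2 or H.shape[0] == 0:
            raise DataError(f"expected a (K, D) bag with K >= 1, got shape {H.shape}")
        if not np.all(np.isfinite(H)):
            raise ValueError("non-finite embedding in bag")
        if H.shape[1] != self.embedding_dim:
            raise ConfigurationError(
                f"embedding dim {H.shape[1]} != head dim {self.embedding_dim}"
            )
        return H


def attention_pool(H: np.ndarray, head: AttentionHead):
    """Single-head pooling of one bag: returns (z (D,), a (K,)).

    z is computed on the head's standardized embedding scale.
    """
    H = head.standardize(head._validate(H))
    logits = np.tanh(H @ head.W.data.reshape(-1))  # single head: W is (1, D)
    e = np.exp(logits - logits.max())
    a = e / e.sum()
    z = a @ H
    return z, a


def multihead_pool(H: np.ndarray, head: AttentionHead):
    """Per-head pooling: returns (z (D,), weights (K, n_heads))."""
    H = head.standardize(head._validate(H))
    zs, ws = [], []
    for hd in range(head.n_heads):
        sl = slice(hd * head.slice_dim, (hd + 1) * head.slice_dim)
        logits = np.tanh(H[:, sl] @ head.W.data[hd])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        zs.append(a @ H[:, sl])
        ws.append(a)
    return np.concatenate(zs), np.stack(ws, axis=1)


def predict_bag(
    bag_embeddings: np.ndarray, head: AttentionHead, entity_id: str = ""
) -> BagPrediction:
    """Pool a (K, D) bag and apply the fully-connected stack."""
    if head.n_heads == 1:
        z, a = attention_pool(bag_embeddings, head)
    else:
        z, a = multihead_pool(bag_embeddings, head)
    y = head.fc(nn.Tensor(z.reshape(1, -1))).data.reshape(())
    return BagPrediction(
        entity_id=entity_id,
        y_hat=float(y) * head.y_std + head.y_mean,
        attention_weights=a,
    )


def write_predictions(predictions: list[BagPrediction], path) -> None:
    """Tab-separated prediction table: entity_id, y_hat, K, a_1..a_K."""
    with open(path, "w") as fh:
        fh.write("entity_id\ty_hat\tK\tattention_weights\n")
        for p in predictions:
            a = np.asarray(p.attention_weights).ravel()
            fh.write(
                f"{p.entity_id}\t{p.y_hat:.6f}\t{len(a)}\t"
                + ",".join(f"{w:.6f}" for w in a)
                + "\n"
            )


def baseline_top(per_pose_predictions: list[tuple[int, float]]) -> float:
    """Prediction of the rank-1 (lowest docking score) pose."""
    if not per_pose_predictions:
        raise DataError("no per-pose predictions")
    for rank, y in per_pose_predictions:
        if rank == 1:
            return float(y)
    raise DataError("no rank-1 pose present; Top baseline undefined")


def baseline_avg(per_pose_predictions: list[tuple[int, float]]) -> float:
    """Unweighted mean of the per-pose predictions."""
    if not per_pose_predictions:
        raise DataError("no per-pose predictions")
    return float(np.mean([y for _, y in per_pose_predictions]))
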