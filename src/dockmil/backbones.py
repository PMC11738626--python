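"""Per-instance graph-network backbones G_psi.

Two architectures map a :class:`~dockmil.graphs.ComplexGraph` to a length-D
embedding h_k plus a scalar affinity (the scalar head is used in stage-1
training and by the Top/Avg baselines):

* ``sgcnn`` — a spatial graph network in the Potential-Net lineage: a gated
  graph sequence of 2 propagation steps over covalent edges, then 2 steps
  over noncovalent edges, with gated attention-sum readouts of width 16
  (covalent stage) and 12 (noncovalent stage).  The printed hyperparameters
  fix the stage/readout sizes; the remaining internals (GRU node updates,
  distance-conditioned linear messages, concatenated [covalent || noncovalent]
  readout projected to D) are a reconstruction in the style of the reference
  lineage.
* ``egnn`` — 6 E(n)-equivariant layers with residual node updates and
  per-edge sigmoid attention gating; one scalar edge feature (the pair
  distance).  Coordinates are updated equivariantly inside the stack but only
  the invariant node channel is read out (mean over nodes), so the embedding
  is invariant to rotations, translations and reflections.

Both readouts are sums/means over nodes, hence permutation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import scipy.sparse as sp

from . import nn
from .errors import GraphTypeError
from .graphs import ComplexGraph


def _aggregation_matrix(edges: np.ndarray, weights: np.ndarray, n: int):
    """CSR matrix with A[dst, src] = w, so A @ h sums weighted neighbors."""
    return sp.csr_matrix((weights, (edges[:, 1], edges[:, 0])), shape=(n, n))

__all__ = ["BackboneConfig", "BackboneModel", "BatchedGraph", "batch_graphs"]

# distance scales that keep edge inputs O(1)
_SGCNN_DIST_SCALE = 4.5
_EGNN_DIST_SCALE = 5.0


@dataclass
class BackboneConfig:
    architecture: str = "sgcnn"  # "sgcnn" | "egnn"
    embedding_dim: int = 128
    hidden_dim: int = 16  # node-state width (sgcnn) / feature width (egnn)
    n_egnn_layers: int = 6
    n_ggnn_steps: int = 2  # per stage, covalent then noncovalent
    gather_width_covalent: int = 16
    gather_width_noncovalent: int = 12
    pocket_radius: float = 8.0
    charge_model: str = "gasteiger"
    covalent_cutoff: float = 1.5
    noncovalent_cutoff: float = 4.5
    radius_cutoff: float = 5.0
    n_features: int = 19


@dataclass
class BatchedGraph:
    """Block-diagonal concatenation of instance graphs."""

    features: np.ndarray  # (sum N, F)
    coords: np.ndarray  # (sum N, 3)
    graph_ids: np.ndarray  # (sum N,) which instance each node belongs to
    n_graphs: int
    edge_sets: dict  # name -> (edges (E,2) with global node ids, dist (E,))
    node_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def batch_graphs(graphs: list[ComplexGraph]) -> BatchedGraph:
    feats, coords, gids, counts = [], [], [], []
    edge_sets: dict[str, list] = {
        "covalent": [], "covalent_d": [],
        "noncovalent": [], "noncovalent_d": [],
        "radius": [], "radius_d": [],
    }
    offset = 0
    for gi, g in enumerate(graphs):
        # the protein/ligand partition enters as an extra input channel:
        # affinity is a property of the intermolecular structure
        feats.append(
            np.hstack([g.node_features, g.role_mask.reshape(-1, 1).astype(float)])
        )
        coords.append(g.node_coords)
        gids.append(np.full(g.n_nodes, gi))
        counts.append(g.n_nodes)
        for name, edges, dist in (
            ("covalent", g.covalent_edges, g.covalent_dist),
            ("noncovalent", g.noncovalent_edges, g.noncovalent_dist),
            ("radius", g.radius_edges, g.radius_dist),
        ):
            if len(edges):
                edge_sets[name].append(edges + offset)
                edge_sets[name + "_d"].append(dist)
        offset += g.n_nodes
    packed = {}
    for name in ("covalent", "noncovalent", "radius"):
        if edge_sets[name]:
            packed[name] = (
                np.vstack(edge_sets[name]),
                np.concatenate(edge_sets[name + "_d"]),
            )
        else:
            packed[name] = (np.zeros((0, 2), dtype=np.intp), np.zeros(0))
    return BatchedGraph(
        features=np.vstack(feats),
        coords=np.vstack(coords),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
        edge_sets=packed,
        node_counts=np.array(counts),
    )


class _GGNNStage(nn.Module):
    """GGNN propagation over one edge set + gated attention-sum readout."""

    def __init__(self, hidden: int, n_in: int, gather_width: int, n_steps: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_steps = n_steps
        # two message channels, both linear in the node state: an ungated one
        # (plain neighbor aggregation, so hard within-cutoff counts are
        # representable) and a distance-gated one (distance sensitivity)
        self.msg = self.register("msg", nn.Linear(hidden, hidden, rng, bias=False))
        self.msg_gated = self.register(
            "msg_gated", nn.Linear(hidden, hidden, rng, bias=False)
        )
        self.gru = self.register("gru", nn.GRUCell(hidden, hidden, rng))
        self.readout = self.register(
            "readout", nn.GatedReadout(hidden, n_in, gather_width, rng)
        )

    def propagate(self, h, edges, dist):
        if len(edges) == 0:
            return h
        n = h.shape[0]
        # messages are linear in the neighbor state with scalar edge weights,
        # so aggregation commutes with the linear maps: sum neighbors first
        # (sparse matmul), then apply the channel weights at node size
        S_plain = _aggregation_matrix(edges, np.ones(len(dist)), n)
        S_gated = _aggregation_matrix(edges, np.exp(-dist / _SGCNN_DIST_SCALE), n)
        for _ in range(self.n_steps):
            m = self.msg(nn.sparse_matmul(S_plain, h)) + self.msg_gated(
                nn.sparse_matmul(S_gated, h)
            )
            h = self.gru(m, h)
        return h

    def gather(self, h, x0, graph_ids, n_graphs):
        return nn.segment_sum(self.readout(h, x0), graph_ids, n_graphs)


class _EGNNLayer(nn.Module):
    def __init__(self, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.phi_e = self.register(
            "phi_e", nn.MLP([2 * hidden + 2, hidden, hidden], rng, activation="silu",
                            final_activation="silu")
        )
        self.att = self.register("att", nn.Linear(hidden, 1, rng))
        self.phi_h = self.register(
            "phi_h", nn.MLP([2 * hidden, hidden, hidden], rng, activation="silu")
        )
        self.phi_x = self.register("phi_x", nn.Linear(hidden, 1, rng, bias=False))

    def __call__(self, h, x, edges, edge_attr, deg_inv):
        src, dst = edges[:, 0], edges[:, 1]
        xi, xj = nn.gather_rows(x, dst), nn.gather_rows(x, src)
        diff = xi - xj
        d2 = (diff * diff).sum(axis=1, keepdims=True) * (1.0 / _EGNN_DIST_SCALE**2)
        m = self.phi_e(
            nn.concatenate(
                [nn.gather_rows(h, dst), nn.gather_rows(h, src), d2, edge_attr],
                axis=1,
            )
        )
        gated = nn.sigmoid(self.att(m)) * m
        agg = nn.segment_sum(gated, dst, h.shape[0])
        h_new = h + self.phi_h(nn.concatenate([h, agg], axis=1))
        # equivariant coordinate update, normalized by node degree; the tanh
        # bounds the per-edge shift so deep stacks cannot blow coordinates up
        shift = nn.segment_sum(diff * nn.tanh(self.phi_x(m)), dst, h.shape[0]) * deg_inv
        return h_new, x + shift


class BackboneModel(nn.Module):
    """G_psi: instance graph -> (embedding of length D, scalar prediction)."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.config = config
        c = config
        if c.architecture not in ("sgcnn", "egnn"):
            raise ValueError(f"unknown architecture {c.architecture!r}")
        # label standardization (set by training; identity by default)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.history: list[float] = []
        n_in = c.n_features + 1  # 19 features + protein/ligand channel
        if c.architecture == "sgcnn":
            self.embed_in = self.register(
                "embed_in", nn.Linear(n_in, c.hidden_dim, rng)
            )
            self.cov_stage = self.register(
                "cov_stage",
                _GGNNStage(c.hidden_dim, n_in, c.gather_width_covalent,
                           c.n_ggnn_steps, rng),
            )
            self.ncov_stage = self.register(
                "ncov_stage",
                _GGNNStage(c.hidden_dim, n_in, c.gather_width_noncovalent,
                           c.n_ggnn_steps, rng),
            )
            gather = c.gather_width_covalent + c.gather_width_noncovalent
            self.embed_out = self.register(
                "embed_out", nn.Linear(gather, c.embedding_dim, rng)
            )
        else:
            self.embed_in = self.register(
                "embed_in", nn.Linear(n_in, c.hidden_dim, rng)
            )
            self.layers = [
                self.register(f"egnn{i}", _EGNNLayer(c.hidden_dim, rng))
                for i in range(c.n_egnn_layers)
            ]
            self.embed_out = self.register(
                "embed_out", nn.Linear(c.hidden_dim, c.embedding_dim, rng)
            )
        # two hidden layers: the affinity surface involves ratios of pooled
        # quantities (e.g. contacts per ligand atom), which a single hidden
        # layer approximates poorly
        head_hidden = max(c.embedding_dim // 2, 8)
        self.scalar_head = self.register(
            "scalar_head",
            nn.MLP([c.embedding_dim, c.embedding_dim, head_hidden, 1], rng),
        )

    # -- forward -------------------------------------------------------------
    def _check_flavor(self, batch: BatchedGraph):
        has_radius = len(batch.edge_sets["radius"][0]) > 0
        has_typed = (
            len(batch.edge_sets["covalent"][0]) > 0
            or len(batch.edge_sets["noncovalent"][0]) > 0
        )
        if self.config.architecture == "sgcnn" and has_radius and not has_typed:
            raise GraphTypeError("sgcnn backbone received a radius graph")
        if self.config.architecture == "egnn" and has_typed:
            raise GraphTypeError("egnn backbone received a covalent/noncovalent graph")

    def forward_batch(self, batch: BatchedGraph):
        """Returns (embeddings Tensor (B, D), scalar Tensor (B,))."""
        self._check_flavor(batch)
        x0 = nn.Tensor(batch.features)
        h = self.embed_in(x0)
        if self.config.architecture == "sgcnn":
            cov_e, cov_d = batch.edge_sets["covalent"]
            ncov_e, ncov_d = batch.edge_sets["noncovalent"]
            h = self.cov_stage.propagate(h, cov_e, cov_d)
            r_cov = self.cov_stage.gather(h, x0, batch.graph_ids, batch.n_graphs)
            h = self.ncov_stage.propagate(h, ncov_e, ncov_d)
            r_ncov = self.ncov_stage.gather(h, x0, batch.graph_ids, batch.n_graphs)
            emb = self.embed_out(nn.concatenate([r_cov, r_ncov], axis=1))
        else:
            edges, dist = batch.edge_sets["radius"]
            x = nn.Tensor(batch.coords)
            edge_attr = nn.Tensor((dist / _EGNN_DIST_SCALE).reshape(-1, 1))
            deg = np.zeros(batch.features.shape[0])
            if len(edges):
                np.add.at(deg, edges[:, 1], 1.0)
            deg_inv = nn.Tensor((1.0 / np.maximum(deg, 1.0)).reshape(-1, 1))
            for layer in self.layers:
                h, x = layer(h, x, edges, edge_attr, deg_inv)
            counts = nn.Tensor((1.0 / np.maximum(batch.node_counts, 1)).reshape(-1, 1))
            pooled = nn.segment_sum(h, batch.graph_ids, batch.n_graphs) * counts
            emb = self.embed_out(pooled)
        scalar = self.scalar_head(emb).reshape(-1)
        return emb, scalar

    # -- inference helpers ----------------------------------------------------
    def embed(self, graphs: list[ComplexGraph]) -> np.ndarray:
        """Embeddings for a list of instance graphs, shape (B, D)."""
        emb, _ = self.forward_batch(batch_graphs(graphs))
        return emb.data.copy()

    def predict_scalar(self, graphs: list[ComplexGraph]) -> np.ndarray:
        """Stage-1 per-instance affinity predictions in label units."""
        _, s = self.forward_batch(batch_graphs(graphs))
        return s.data * self.y_std + self.y_mean

    # -- checkpointing --------------------------------------------------------
    def checkpoint(self) -> dict:
        """Self-describing checkpoint: architecture + hyperparameters + weights."""
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "state": self.state_dict(),
        }

    @classmethod
    def from_checkpoint(cls, ckpt: dict) -> "BackboneModel":
        model = cls(BackboneConfig(**ckpt["config"]))
        model.load_state_dict(ckpt["state"])
        model.y_mean = float(ckpt["y_mean"])
        model.y_std = float(ckpt["y_std"])
        return model
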