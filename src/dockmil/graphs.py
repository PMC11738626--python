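"""Spatial graph construction and pose RMSD.

Two graph flavors feed the two backbones:

* the two-edge-type graph: covalent edges (0 < d <= 1.5 A) and noncovalent
  edges (1.5 < d <= 4.5 A), both with the Euclidean distance as attribute;
* the radius graph: all pairs with 0 < d <= 5 A, one scalar edge feature (d).

Edges are classified purely by distance; cutoffs are inclusive.  Both
directions of every undirected edge are stored, so message passing can treat
the pair lists as directed incidence.  Note the distance criterion can miss
long covalent bonds (e.g. S-S at ~2.05 A), which then land in the
noncovalent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AtomMatchingError, DegenerateGraphError
from .featurize import FeaturizedInstance
from .structio import PoseEntry

__all__ = ["ComplexGraph", "build_sgcnn_graph", "build_radius_graph",
           "pose_rmsd", "write_edge_list"]

COVALENT_CUTOFF = 1.5
NONCOVALENT_CUTOFF = 4.5
RADIUS_CUTOFF = 5.0


def _empty_edges():
    return np.zeros((0, 2), dtype=np.intp)


@dataclass
class ComplexGraph:
    """Node features/coords plus distance-attributed edge sets."""

    node_features: np.ndarray  # (N, 19)
    node_coords: np.ndarray  # (N, 3)
    role_mask: np.ndarray  # (N,)
    covalent_edges: np.ndarray = field(default_factory=_empty_edges)  # (Ec, 2)
    covalent_dist: np.ndarray = field(default_factory=lambda: np.zeros(0))
    noncovalent_edges: np.ndarray = field(default_factory=_empty_edges)
    noncovalent_dist: np.ndarray = field(default_factory=lambda: np.zeros(0))
    radius_edges: np.ndarray = field(default_factory=_empty_edges)
    radius_dist: np.ndarray = field(default_factory=lambda: np.zeros(0))
    entity_id: str = ""
    pose_rank: int = -1

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


def _pairs_within(coords: np.ndarray, cutoff: float):
    """All unordered pairs with 0 < d <= cutoff, plus their distances."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return _empty_edges(), np.zeros(0)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d > 0  # coincident atoms produce no edge
    return pairs[keep], d[keep]


def _symmetrize(pairs: np.ndarray, d: np.ndarray):
    both = np.vstack([pairs, pairs[:, ::-1]])
    return both, np.concatenate([d, d])


def _check_size(instance: FeaturizedInstance):
    if instance.n_atoms < 2:
        raise DegenerateGraphError(
            f"instance {instance.entity_id}/{instance.pose_rank} has "
            f"{instance.n_atoms} atom(s); need at least 2"
        )


def build_sgcnn_graph(
    instance: FeaturizedInstance,
    covalent_cutoff: float = COVALENT_CUTOFF,
    noncovalent_cutoff: float = NONCOVALENT_CUTOFF,
) -> ComplexGraph:
    """Covalent/noncovalent two-edge-type graph (distance-threshold bonds)."""
    _check_size(instance)
    pairs, d = _pairs_within(instance.coords, noncovalent_cutoff)
    cov = d <= covalent_cutoff
    cov_e, cov_d = _symmetrize(pairs[cov], d[cov])
    ncov_e, ncov_d = _symmetrize(pairs[~cov], d[~cov])
    return ComplexGraph(
        node_features=instance.features,
        node_coords=instance.coords,
        role_mask=instance.role_mask,
        covalent_edges=cov_e,
        covalent_dist=cov_d,
        noncovalent_edges=ncov_e,
        noncovalent_dist=ncov_d,
        entity_id=instance.entity_id,
        pose_rank=instance.pose_rank,
    )


def build_radius_graph(
    instance: FeaturizedInstance, cutoff: float = RADIUS_CUTOFF
) -> ComplexGraph:
    """Single radius graph with the distance as the one edge feature."""
    _check_size(instance)
    pairs, d = _pairs_within(instance.coords, cutoff)
    e, dist = _symmetrize(pairs, d)
    return ComplexGraph(
        node_features=instance.features,
        node_coords=instance.coords,
        role_mask=instance.role_mask,
        radius_edges=e,
        radius_dist=dist,
        entity_id=instance.entity_id,
        pose_rank=instance.pose_rank,
    )


def write_edge_list(graph: ComplexGraph, path) -> None:
    """Debug dump: one line per directed edge, ``type<TAB>i<TAB>j<TAB>dist``."""
    with open(path, "w") as fh:
        for name, edges, dists in (
            ("covalent", graph.covalent_edges, graph.covalent_dist),
            ("noncovalent", graph.noncovalent_edges, graph.noncovalent_dist),
            ("radius", graph.radius_edges, graph.radius_dist),
        ):
            for (i, j), d in zip(edges, dists):
                fh.write(f"{name}\t{i}\t{j}\t{d:.6f}\n")


def pose_rmsd(pose_a: PoseEntry, pose_b: PoseEntry) -> float:
    """Heavy-atom RMSD between two poses of the same entity.

    Atoms are matched by file order; no superposition is applied because the
    poses share the receptor frame.  (Topological-symmetry correction is not
    performed.)
    """
    if pose_a.entity_id != pose_b.entity_id:
        raise AtomMatchingError(
            f"poses belong to different entities: "
            f"{pose_a.entity_id!r} vs {pose_b.entity_id!r}"
        )
    a = np.array([r.coords for r in pose_a.ligand_atoms if not r.is_hydrogen])
    b = np.array([r.coords for r in pose_b.ligand_atoms if not r.is_hydrogen])
    if a.shape != b.shape:
        raise AtomMatchingError(
            f"heavy-atom count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
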