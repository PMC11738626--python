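"""Synthetic protein-ligand entities with controlled pose quality.

The generator emulates the structure of a docking campaign without any
chemistry engine: each entity is a random self-avoiding ligand chain placed
in a random shell-like pocket of protein atoms.  The affinity label is a
deterministic function of the TRUE pose's geometry,

    y = ALPHA * (protein-ligand contacts within 4.5 A) / n_ligand_atoms
        + BETA + Gaussian(0, label_noise_sd),

so decoy poses carry no label signal of their own — the premise a
multi-instance learner must exploit (at least one instance close to the
truth).  "Good" poses are perturbations of the true pose rescaled to an
exact target RMSD drawn from ``good_rmsd_range``; "bad" poses likewise from
``bad_rmsd_range``.  Docking scores are weakly informative,
``score = -7.0 + 0.2 * rmsd + N(0, 1)`` kcal/mol, mirroring the imperfect
rank/accuracy relation of real docking; pose ranks follow the scores.

Ligand chains mix C/N/O elements along an unbranched random walk, which makes
topological symmetry vanishingly unlikely, so matched-order RMSD equals
symmetry-corrected RMSD.  Chemistry realism is deliberately minimal (point
atoms, single bonds, distance-inferred protein connectivity): sufficient to
exercise featurization and graph contracts, not to mimic force fields.

Entities belong to ligand template families (shared chain topology and base
conformer); the group split keeps each family wholly in train or test, as a
scaffold-split analog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError
from .featurize import gasteiger_charges
from .structio import (
    CRYSTAL_RANK,
    AtomRecord,
    Bag,
    PoseEntry,
    infer_bonds,
    write_index,
)

__all__ = ["SyntheticSpec", "SyntheticEntity", "SyntheticDataset",
           "generate_entity", "generate_dataset", "contact_score"]

# label model constants (pK units); chosen so labels span a realistic 4-11 pK
# range with sd ~1.5 given the pocket geometry above
ALPHA = 0.7
BETA = 2.0
CONTACT_CUTOFF = 4.5  # Angstrom
# docking-score model (kcal/mol): weak association between score and accuracy
SCORE_BASE = -7.0
SCORE_RMSD_SLOPE = 0.2
SCORE_NOISE_SD = 1.0

_LIG_ELEMENTS = (["C"] * 14 + ["N"] * 3 + ["O"] * 3)
_PROT_ELEMENTS = (["C"] * 11 + ["N"] * 4 + ["O"] * 4 + ["S"] * 1)


@dataclass
class SyntheticSpec:
    n_entities: int = 100
    poses_per_entity: int = 10
    # int, inclusive (lo, hi) range, or {count: probability}
    n_informative: object = (1, 3)
    good_rmsd_range: tuple[float, float] = (0.3, 2.0)
    bad_rmsd_range: tuple[float, float] = (4.0, 10.0)
    ligand_size_range: tuple[int, int] = (8, 24)
    pocket_size_range: tuple[int, int] = (30, 80)
    label_noise_sd: float = 0.1
    seed: int = 0
    split: str = "random"  # "random" | "group"
    test_fraction: float = 2.0 / 7.0
    include_crystal: bool = False
    n_families: int | None = None

    def __post_init__(self):
        for name in ("good_rmsd_range", "bad_rmsd_range",
                     "ligand_size_range", "pocket_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")
        if isinstance(self.n_informative, int):
            if self.n_informative > self.poses_per_entity:
                raise ValueError("n_informative exceeds poses_per_entity")


@dataclass
class SyntheticEntity:
    entity_id: str
    family_id: int
    protein_atoms: list[AtomRecord]
    true_pose: PoseEntry
    poses: list[PoseEntry]  # ranked 1..K by docking score
    label: float
    rmsds: dict[int, float]  # pose_rank -> true RMSD (crystal rank included, 0.0)
    n_good: int


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    entities: list[SyntheticEntity]
    bags: list[Bag]
    train_ids: list[str]
    test_ids: list[str]
    index: pd.DataFrame
    outdir: Path | None = None

    def split_bags(self) -> tuple[list[Bag], list[Bag]]:
        by_id = {b.entity_id: b for b in self.bags}
        return ([by_id[e] for e in self.train_ids],
                [by_id[e] for e in self.test_ids])

    @property
    def labels(self) -> dict[str, float]:
        return {b.entity_id: b.label for b in self.bags}

    @property
    def good_counts(self) -> dict[str, int]:
        return {e.entity_id: e.n_good for e in self.entities}


def contact_score(protein_atoms: list[AtomRecord], ligand_atoms: list[AtomRecord],
                  cutoff: float = CONTACT_CUTOFF) -> float:
    """Protein-ligand contact count within `cutoff`, per ligand atom."""
    p = np.array([r.coords for r in protein_atoms if not r.is_hydrogen])
    l = np.array([r.coords for r in ligand_atoms if not r.is_hydrogen])
    pairs = cKDTree(p).query_ball_point(l, r=cutoff)
    return sum(len(x) for x in pairs) / len(l)


def _sample_n_informative(spec: SyntheticSpec, rng) -> int:
    ni = spec.n_informative
    if isinstance(ni, int):
        return ni
    if isinstance(ni, dict):
        counts = np.array(list(ni.keys()))
        probs = np.array(list(ni.values()), dtype=float)
        return int(rng.choice(counts, p=probs / probs.sum()))
    lo, hi = ni
    return int(rng.integers(lo, hi + 1))


def _grow_chain(n: int, rng) -> np.ndarray:
    """Self-avoiding 3-D chain with 1.5 A steps and 1.2 A exclusion."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = coords[-1] + 1.5 * u
            if len(coords) < 2 or np.min(
                np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
            ) >= 1.2:
                coords.append(cand)
                break
        else:  # dead end: restart the chain
            coords = [np.zeros(3)]
    arr = np.array(coords)
    return arr - arr.mean(axis=0)


def _make_template(spec: SyntheticSpec, rng):
    n = int(rng.integers(spec.ligand_size_range[0], spec.ligand_size_range[1] + 1))
    elements = ["C"] + [str(rng.choice(_LIG_ELEMENTS)) for _ in range(n - 1)]
    return elements, _grow_chain(n, rng)


def _ligand_records(elements, coords, charges=None) -> list[AtomRecord]:
    records = [
        AtomRecord(el, c, None if charges is None else float(charges[i]),
                   "ligand", i)
        for i, (el, c) in enumerate(zip(elements, coords))
    ]
    for i in range(len(records) - 1):
        records[i].bonds.append((i + 1, 1.0))
        records[i + 1].bonds.append((i, 1.0))
    return records


def _make_pocket(lig_coords: np.ndarray, n_pocket: int, rng) -> np.ndarray:
    out = []
    tree_pts = lig_coords
    while len(out) < n_pocket:
        anchor = tree_pts[rng.integers(len(tree_pts))]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = anchor + rng.uniform(3.0, 6.5) * u
        if np.min(np.linalg.norm(lig_coords - pos, axis=1)) < 2.9:
            continue
        if out and np.min(np.linalg.norm(np.array(out) - pos, axis=1)) < 1.7:
            continue
        out.append(pos)
    return np.array(out)


def _perturb_to_rmsd(coords: np.ndarray, target: float, rng) -> np.ndarray:
    """True coords + (translation + per-atom jitter) rescaled to exact RMSD."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    delta = target * u + rng.normal(scale=0.25 * target, size=coords.shape)
    rmsd = np.sqrt(np.mean(np.sum(delta**2, axis=1)))
    return coords + delta * (target / rmsd)


def generate_entity(spec: SyntheticSpec, rng: np.random.Generator,
                    entity_id: str = "E0", family_id: int = 0,
                    template=None) -> SyntheticEntity:
    """One entity: pocket, true pose, ranked decoy bag, label, true RMSDs."""
    if template is None:
        template = _make_template(spec, rng)
    elements, base_coords = template
    # conformer: family template plus a small jitter, randomly rotated
    from scipy.spatial.transform import Rotation

    coords = base_coords @ Rotation.random(random_state=int(rng.integers(2**31))).as_matrix().T
    coords = coords + rng.normal(scale=0.1, size=coords.shape)
    coords -= coords.mean(axis=0)
    charges = gasteiger_charges(_ligand_records(elements, coords))

    n_pocket = int(rng.integers(spec.pocket_size_range[0],
                                spec.pocket_size_range[1] + 1))
    pocket = _make_pocket(coords, n_pocket, rng)
    prot_elements = [str(rng.choice(_PROT_ELEMENTS)) for _ in range(n_pocket)]
    protein = [AtomRecord(el, c, None, "protein", i)
               for i, (el, c) in enumerate(zip(prot_elements, pocket))]
    infer_bonds(protein)

    true_pose = PoseEntry(entity_id, CRYSTAL_RANK, None,
                          _ligand_records(elements, coords, charges),
                          is_crystal=True)
    label = (ALPHA * contact_score(protein, true_pose.ligand_atoms)
             + BETA + rng.normal(scale=spec.label_noise_sd))

    n_good = min(_sample_n_informative(spec, rng), spec.poses_per_entity)
    targets = [float(rng.uniform(*spec.good_rmsd_range)) for _ in range(n_good)]
    targets += [float(rng.uniform(*spec.bad_rmsd_range))
                for _ in range(spec.poses_per_entity - n_good)]
    decoy_coords = [_perturb_to_rmsd(coords, t, rng) for t in targets]
    scores = [SCORE_BASE + SCORE_RMSD_SLOPE * t + rng.normal(scale=SCORE_NOISE_SD)
              for t in targets]
    order = np.argsort(scores)  # rank 1 = lowest docking score
    poses, rmsds = [], {CRYSTAL_RANK: 0.0}
    for rank, k in enumerate(order, start=1):
        poses.append(
            PoseEntry(entity_id, rank, float(scores[k]),
                      _ligand_records(elements, decoy_coords[k], charges))
        )
        rmsds[rank] = targets[k]
    return SyntheticEntity(entity_id, family_id, protein, true_pose, poses,
                           float(label), rmsds, n_good)


# ---------------------------------------------------------------------------
# dataset-level generation, file emission and splitting
# ---------------------------------------------------------------------------


def _write_pdb(records: list[AtomRecord], path: Path):
    lines = []
    for i, r in enumerate(records, start=1):
        x, y, z = r.coords
        lines.append(
            f"ATOM  {i:5d} {r.element:^4s} UNK A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{r.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_mol2(records: list[AtomRecord], name: str, path: Path):
    bonds = sorted(
        {(min(r.atom_index, j), max(r.atom_index, j)) for r in records
         for j, _ in r.bonds}
    )
    lines = [
        "@<TRIPOS>MOLECULE", name,
        f"{len(records)} {len(bonds)} 0 0 0", "SMALL", "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, r in enumerate(records, start=1):
        q = 0.0 if r.partial_charge is None else r.partial_charge
        x, y, z = r.coords
        lines.append(
            f"{i:>4d} {r.element}{i} {x:10.4f} {y:10.4f} {z:10.4f} "
            f"{r.element} 1 LIG {q:9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for n, (a, b) in enumerate(bonds, start=1):
        lines.append(f"{n:>4d} {a + 1:>4d} {b + 1:>4d} 1")
    path.write_text("\n".join(lines) + "\n")


def _split(entities: list[SyntheticEntity], spec: SyntheticSpec, rng):
    ids = [e.entity_id for e in entities]
    n_test = max(1, int(round(spec.test_fraction * len(ids))))
    if spec.split == "random":
        perm = rng.permutation(len(ids))
        test = sorted(ids[i] for i in perm[:n_test])
    elif spec.split == "group":
        families = sorted({e.family_id for e in entities})
        if len(families) < 2:
            raise DataError("group split needs at least 2 ligand families")
        fam_order = rng.permutation(families)
        test_set: set[int] = set()
        count = 0
        for fam in fam_order:
            if count >= n_test:
                break
            members = [e for e in entities if e.family_id == fam]
            test_set.add(fam)
            count += len(members)
        if len(test_set) == len(families):  # keep at least one family in train
            test_set.discard(int(fam_order[-1]))
        test = sorted(e.entity_id for e in entities if e.family_id in test_set)
    else:
        raise ValueError(f"unknown split {spec.split!r}")
    train = sorted(set(ids) - set(test))
    return train, test


def generate_dataset(spec: SyntheticSpec, outdir: str | Path | None = None
                     ) -> SyntheticDataset:
    """Generate entities, bags, index table and train/test split.

    With ``outdir`` set, also emit the same layout real data would use:
    ``receptors/<id>.pdb``, ``poses/<id>_r<rank>.mol2`` (one conformer each),
    a tab-separated ``index.tsv`` and a ``split.json`` manifest — all
    reproducible byte-for-byte from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_families = spec.n_families or max(2, spec.n_entities // 5)
    templates: dict[int, tuple] = {}
    entities = []
    for i in range(spec.n_entities):
        fam = int(rng.integers(n_families))
        if fam not in templates:
            templates[fam] = _make_template(spec, rng)
        entities.append(
            generate_entity(spec, rng, entity_id=f"E{i:04d}", family_id=fam,
                            template=templates[fam])
        )

    rows = []
    bags = []
    for e in entities:
        instances = list(e.poses)
        if spec.include_crystal:
            instances = [e.true_pose] + instances
        bags.append(Bag(e.entity_id, e.label, instances, e.protein_atoms))
        for p in instances:
            rows.append({
                "entity_id": e.entity_id,
                "label": round(e.label, 6),
                "pose_path": f"poses/{e.entity_id}_r{p.pose_rank}.mol2",
                "pose_rank": p.pose_rank,
                "docking_score": (np.nan if p.docking_score is None
                                  else round(p.docking_score, 4)),
                "is_crystal": p.is_crystal,
            })
    index = pd.DataFrame(rows)
    train, test = _split(entities, spec, rng)

    out = None
    if outdir is not None:
        out = Path(outdir)
        (out / "receptors").mkdir(parents=True, exist_ok=True)
        (out / "poses").mkdir(exist_ok=True)
        for e, bag in zip(entities, bags):
            _write_pdb(e.protein_atoms, out / "receptors" / f"{e.entity_id}.pdb")
            for p in bag.instances:
                _write_mol2(p.ligand_atoms, f"{e.entity_id}_r{p.pose_rank}",
                            out / "poses" / f"{e.entity_id}_r{p.pose_rank}.mol2")
        index2 = index.copy()
        index2["pose_path"] = [str(out / p) for p in index2["pose_path"]]
        write_index(index2, out / "index.tsv")
        (out / "split.json").write_text(json.dumps(
            {"split": spec.split, "train": train, "test": test}, indent=0
        ) + "\n")
    return SyntheticDataset(spec, entities, bags, train, test, index, out)


def receptor_paths(ds: SyntheticDataset) -> dict[str, str]:
    """entity_id -> receptor file path for an emitted dataset."""
    if ds.outdir is None:
        raise ValueError("dataset was not written to disk")
    return {e.entity_id: str(ds.outdir / "receptors" / f"{e.entity_id}.pdb")
            for e in ds.entities}
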