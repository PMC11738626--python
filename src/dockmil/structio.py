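"""Structure I/O: PDB / Mol2 / SDF readers, pose-bag assembly, HDF5 stores.

A protein-ligand *entity* is represented as a :class:`Bag`: one shared
receptor, an experimental affinity label in pK units, and an ordered list of
docking-pose instances.  Readers return plain :class:`AtomRecord` lists so the
rest of the pipeline is independent of the source dialect.

PDB files are parsed with Biopython, SDF with RDKit.  Mol2 is read by a small
TRIPOS parser because it must tolerate nonstandard atom types and carry the
per-atom partial charges of column 9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chem import COVALENT_RADII, KNOWN_ELEMENTS, normalize_element
from .errors import (
    DimensionError,
    DuplicateRankError,
    ElementError,
    EmptyInputError,
    MissingKeyError,
    MissingPoseError,
    StructureFormatError,
)

__all__ = [
    "AtomRecord",
    "PoseEntry",
    "Bag",
    "read_structure",
    "assemble_bags",
    "read_index",
    "write_index",
    "EmbeddingStore",
    "infer_bonds",
]

CRYSTAL_RANK = 0  # bookkeeping rank for an optional crystal instance


@dataclass
class AtomRecord:
    """One atom: element, position (Angstrom), charge, role and bond list.

    ``bonds`` holds ``(neighbor_atom_index, bond_order)`` pairs; aromatic
    bonds carry order 1.5.  ``partial_charge`` is ``None`` when the source
    dialect does not provide charges.
    """

    element: str
    coords: np.ndarray
    partial_charge: float | None
    role: str  # "protein" | "ligand"
    atom_index: int
    bonds: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_index}")
        if not self.element:
            raise ValueError("empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class PoseEntry:
    """One docking pose (or the crystal pose) of an entity's ligand."""

    entity_id: str
    pose_rank: int
    docking_score: float | None
    ligand_atoms: list[AtomRecord]
    source_path: str = ""
    is_crystal: bool = False


@dataclass
class Bag:
    """One labeled entity: shared receptor + K pose instances."""

    entity_id: str
    label: float
    instances: list[PoseEntry]
    protein_atoms: list[AtomRecord]

    @property
    def K(self) -> int:
        return len(self.instances)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_element(symbol: str, where: str) -> str:
    el = normalize_element(symbol)
    if el not in KNOWN_ELEMENTS:
        raise ElementError(f"unknown element symbol {symbol!r} in {where}")
    return el


def infer_bonds(records: list[AtomRecord], scale: float = 1.25) -> None:
    """Fill ``bonds`` by a covalent-radius distance rule (order 1 only).

    Used for dialects without a bond table (PDB).  Two atoms are bonded when
    their distance is at most ``scale`` times the sum of covalent radii.
    """
    if not records:
        return
    coords = np.array([r.coords for r in records])
    radii = np.array([COVALENT_RADII[r.element] for r in records])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2 * radii.max() * scale, output_type="ndarray")
    for r in records:
        r.bonds = []
    if len(pairs) == 0:
        return
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    ok = d <= scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    for i, j in pairs[ok]:
        records[i].bonds.append((int(j), 1.0))
        records[j].bonds.append((int(i), 1.0))


def _read_pdb(path: Path, role: str) -> list[list[AtomRecord]]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except Exception as exc:  # Biopython raises assorted types
        raise StructureFormatError(f"cannot parse PDB {path}: {exc}") from exc
    records: list[AtomRecord] = []
    idx = 0
    for atom in structure.get_atoms():
        el = atom.element if atom.element else atom.get_name()[0]
        el = _check_element(el, f"{path} atom {atom.get_serial_number()}")
        records.append(
            AtomRecord(el, np.array(atom.get_coord(), dtype=float), None, role, idx)
        )
        idx += 1
    if not records:
        raise EmptyInputError(f"no ATOM/HETATM records in {path}")
    infer_bonds(records)
    return [records]


def _records_from_rdkit(mol, role: str, where: str) -> list[AtomRecord]:
    conf = mol.GetConformer()
    records = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        p = conf.GetAtomPosition(i)
        el = _check_element(atom.GetSymbol(), where)
        records.append(AtomRecord(el, np.array([p.x, p.y, p.z]), None, role, i))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = 1.5 if bond.GetIsAromatic() else float(bond.GetBondTypeAsDouble())
        records[i].bonds.append((j, order))
        records[j].bonds.append((i, order))
    return records


def _read_sdf(path: Path, role: str) -> list[list[AtomRecord]]:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    text = path.read_text()
    blocks = [b for b in text.split("$$$$") if b.strip()]
    out = []
    for n, block in enumerate(blocks):
        mol = Chem.MolFromMolBlock(block + "\n$$$$\n", sanitize=False, removeHs=False)
        if mol is None:
            raise StructureFormatError(f"unparseable SDF record {n} in {path}")
        try:
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY, catchErrors=True
            )
        except Exception:
            pass  # aromaticity perception is best-effort on odd molecules
        recs = _records_from_rdkit(mol, role, f"{path} record {n}")
        if not recs:
            raise EmptyInputError(f"empty SDF record {n} in {path}")
        out.append(recs)
    if not out:
        raise EmptyInputError(f"no molecule records in {path}")
    return out


_MOL2_BOND_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0, "du": 1.0}


def _read_mol2(path: Path, role: str) -> list[list[AtomRecord]]:
    text = path.read_text()
    chunks = text.split("@<TRIPOS>MOLECULE")
    out = []
    for n, chunk in enumerate(chunks[1:]):
        lines = chunk.splitlines()
        section = None
        records: list[AtomRecord] = []
        remap: dict[int, int] = {}
        bonds: list[tuple[int, int, float]] = []
        for ln, line in enumerate(lines):
            s = line.strip()
            if s.startswith("@<TRIPOS>"):
                section = s[9:]
                continue
            if not s or s.startswith("#"):
                continue
            if section == "ATOM":
                parts = s.split()
                if len(parts) < 6:
                    raise StructureFormatError(
                        f"bad ATOM line {ln} in {path} molecule {n}: {s!r}"
                    )
                try:
                    aid = int(parts[0])
                    x, y, z = (float(v) for v in parts[2:5])
                except ValueError as exc:
                    raise StructureFormatError(
                        f"bad ATOM line {ln} in {path} molecule {n}: {s!r}"
                    ) from exc
                el = _check_element(parts[5].split(".")[0], f"{path} molecule {n}")
                charge = float(parts[8]) if len(parts) >= 9 else None
                remap[aid] = len(records)
                records.append(
                    AtomRecord(el, np.array([x, y, z]), charge, role, len(records))
                )
            elif section == "BOND":
                parts = s.split()
                if len(parts) < 4:
                    raise StructureFormatError(
                        f"bad BOND line {ln} in {path} molecule {n}: {s!r}"
                    )
                bonds.append(
                    (int(parts[1]), int(parts[2]), _MOL2_BOND_ORDER.get(parts[3], 1.0))
                )
        for a, b, order in bonds:
            i, j = remap[a], remap[b]
            records[i].bonds.append((j, order))
            records[j].bonds.append((i, order))
        if not records:
            raise EmptyInputError(f"molecule {n} in {path} has no atoms")
        out.append(records)
    if not out:
        raise EmptyInputError(f"no @<TRIPOS>MOLECULE blocks in {path}")
    return out


_READERS = {"pdb": _read_pdb, "mol2": _read_mol2, "sdf": _read_sdf}


def read_structure(path, format: str | None = None, role: str = "ligand"):
    """Read a structure file into AtomRecord lists.

    Returns a flat ``list[AtomRecord]`` for a single-conformer file, or a
    list of such lists when the file contains several models/conformers
    (multi-record SDF, multi-molecule Mol2).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in _READERS:
        raise ValueError(f"unsupported format {format!r}")
    if role not in ("protein", "ligand"):
        raise ValueError(f"role must be protein or ligand, got {role!r}")
    conformers = _READERS[format](path, role)
    return conformers[0] if len(conformers) == 1 else conformers


def _first_conformer(obj) -> list[AtomRecord]:
    return obj if obj and isinstance(obj[0], AtomRecord) else obj[0]


# ---------------------------------------------------------------------------
# bag assembly
# ---------------------------------------------------------------------------

INDEX_COLUMNS = [
    "entity_id",
    "label",
    "pose_path",
    "pose_rank",
    "docking_score",
    "is_crystal",
]


def read_index(path) -> pd.DataFrame:
    """Read the tab-separated bag index (header row, columns as INDEX_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(INDEX_COLUMNS) - set(df.columns)
    if missing:
        raise StructureFormatError(f"index {path} lacks columns {sorted(missing)}")
    return df


def write_index(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=INDEX_COLUMNS)


def assemble_bags(
    index_table: pd.DataFrame,
    receptor_paths: dict[str, str],
    max_poses: int = 10,
    include_crystal: bool = True,
) -> list[Bag]:
    """Build one :class:`Bag` per entity from an index table.

    Instances are sorted by ``pose_rank`` ascending.  Entities with more than
    ``max_poses`` docking poses are truncated to the best-ranked ones; a
    crystal instance (rank :data:`CRYSTAL_RANK`) is kept regardless when
    ``include_crystal`` is true, so K may reach ``max_poses + 1``.
    """
    if isinstance(index_table, (str, Path)):
        index_table = read_index(index_table)
    bags = []
    receptor_cache: dict[str, list[AtomRecord]] = {}
    for entity_id, group in index_table.groupby("entity_id", sort=True):
        entity_id = str(entity_id)
        label = float(group["label"].iloc[0])
        if not np.isfinite(label):
            raise ValueError(f"non-finite label for entity {entity_id}")
        ranks = group["pose_rank"].tolist()
        if len(ranks) != len(set(ranks)):
            raise DuplicateRankError(f"duplicate pose_rank for entity {entity_id}")
        if entity_id not in receptor_paths:
            raise MissingPoseError(f"no receptor path for entity {entity_id}")
        rpath = str(receptor_paths[entity_id])
        if rpath not in receptor_cache:
            receptor_cache[rpath] = _first_conformer(
                read_structure(rpath, role="protein")
            )
        poses = []
        for row in group.itertuples(index=False):
            is_crystal = bool(row.is_crystal)
            if is_crystal and not include_crystal:
                continue
            score = None if pd.isna(row.docking_score) else float(row.docking_score)
            atoms = _first_conformer(read_structure(str(row.pose_path), role="ligand"))
            poses.append(
                PoseEntry(
                    entity_id=entity_id,
                    pose_rank=int(row.pose_rank),
                    docking_score=score,
                    ligand_atoms=atoms,
                    source_path=str(row.pose_path),
                    is_crystal=is_crystal,
                )
            )
        docking = sorted(
            (p for p in poses if not p.is_crystal), key=lambda p: p.pose_rank
        )
        crystal = [p for p in poses if p.is_crystal]
        instances = sorted(crystal + docking[:max_poses], key=lambda p: p.pose_rank)
        if not instances:
            raise MissingPoseError(f"entity {entity_id} has a label but no poses")
        bags.append(Bag(entity_id, label, instances, receptor_cache[rpath]))
    return bags


# ---------------------------------------------------------------------------
# embedding / instance store
# ---------------------------------------------------------------------------


class EmbeddingStore:
    """Per-(entity, pose_rank) storage for embeddings and featurized instances.

    Backed by HDF5 when constructed with a path (one group per entity, one
    dataset per pose rank), or by an in-memory dict when ``path`` is None.
    Round-trips are bit-exact; the embedding dimension is fixed by the first
    write.
    """

    def __init__(self, path: str | Path | None = None, mode: str = "a"):
        self._path = None if path is None else Path(path)
        self._mem: dict[str, dict[int, np.ndarray]] = {}
        self._mem_inst: dict[str, dict[int, dict[str, np.ndarray]]] = {}
        self._dim: int | None = None
        self._h5 = h5py.File(self._path, mode) if self._path is not None else None
        if self._h5 is not None and "dim" in self._h5.attrs:
            self._dim = int(self._h5.attrs["dim"])

    # -- embeddings ---------------------------------------------------------
    def write(self, entity_id: str, pose_rank: int, embedding: np.ndarray) -> None:
        v = np.asarray(embedding, dtype=np.float64)
        if v.ndim != 1:
            raise DimensionError(f"embedding must be 1-D, got shape {v.shape}")
        if self._dim is None:
            self._dim = v.shape[0]
            if self._h5 is not None:
                self._h5.attrs["dim"] = self._dim
        elif v.shape[0] != self._dim:
            raise DimensionError(
                f"embedding dim {v.shape[0]} != store dim {self._dim}"
            )
        if self._h5 is not None:
            grp = self._h5.require_group(f"embeddings/{entity_id}")
            key = str(pose_rank)
            if key in grp:
                del grp[key]
            grp.create_dataset(key, data=v)
        else:
            self._mem.setdefault(entity_id, {})[int(pose_rank)] = v.copy()

    def read(self, entity_id: str) -> list[tuple[int, np.ndarray]]:
        if self._h5 is not None:
            key = f"embeddings/{entity_id}"
            if key not in self._h5:
                raise MissingKeyError(entity_id)
            grp = self._h5[key]
            items = [(int(k), np.array(grp[k])) for k in grp]
        else:
            if entity_id not in self._mem:
                raise MissingKeyError(entity_id)
            items = [(r, v.copy()) for r, v in self._mem[entity_id].items()]
        return sorted(items, key=lambda t: t[0])

    def entities(self) -> list[str]:
        if self._h5 is not None:
            return sorted(self._h5["embeddings"]) if "embeddings" in self._h5 else []
        return sorted(self._mem)

    @property
    def dim(self) -> int | None:
        return self._dim

    # -- featurized instances ----------------------------------------------
    def write_instance(
        self,
        entity_id: str,
        pose_rank: int,
        coords: np.ndarray,
        features: np.ndarray,
        role_mask: np.ndarray,
    ) -> None:
        arrs = {
            "coords": np.asarray(coords, float),
            "features": np.asarray(features, float),
            "role_mask": np.asarray(role_mask),
        }
        if self._h5 is not None:
            grp = self._h5.require_group(f"instances/{entity_id}/{pose_rank}")
            for k, v in arrs.items():
                if k in grp:
                    del grp[k]
                grp.create_dataset(k, data=v)
        else:
            self._mem_inst.setdefault(entity_id, {})[int(pose_rank)] = arrs

    def read_instance(self, entity_id: str, pose_rank: int) -> dict[str, np.ndarray]:
        if self._h5 is not None:
            key = f"instances/{entity_id}/{pose_rank}"
            if key not in self._h5:
                raise MissingKeyError(f"{entity_id}/{pose_rank}")
            grp = self._h5[key]
            return {k: np.array(grp[k]) for k in grp}
        try:
            return self._mem_inst[entity_id][int(pose_rank)]
        except KeyError as exc:
            raise MissingKeyError(f"{entity_id}/{pose_rank}") from exc

    def close(self):
        if self._h5 is not None:
            self._h5.close()
            self._h5 = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
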