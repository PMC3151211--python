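"""Dataset containers and readers for the kinase-inhibitor prediction pipeline.

The pipeline operates on a *bundle*: kinase sequences (FASTA), a multiple
sequence alignment of those sequences (aligned FASTA), per-kinase annotations
(TSV), inhibitor structures (SMILES or SDF), per-inhibitor annotations (TSV)
and an m x n binary binding matrix (CSV).  Feature tables produced by the
feature modules are typed (numeric/nominal) and carry a feature-group tag so
that classifiers can encode and normalize them correctly.

Pair instances are formed by concatenating the kinase feature row with the
inhibitor feature row, one instance per matrix cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_SET = frozenset(RESIDUES)

#: feature-group shorthand accepted in FeatureTable columns
GROUP_TAGS = frozenset(
    {
        "STTK", "PC", "PRO", "Apri", "glAli", "locAli", "PSF", "abPSF",
        "PT", "MS", "FTs", "KNN", "CF", "GF", "P",
    }
)


class ValidationError(ValueError):
    """Raised when an input file or record violates a contract."""


@dataclass
class KinaseRecord:
    """A protein kinase: sequence plus phylogenetic annotations."""

    id: str
    sequence: str
    sttk: str | None = None      # Ser/Thr vs Tyr kinase class
    group: str | None = None     # phylogenetic group (AGC, CAMK, ...)
    family: str | None = None    # kinase family within the group
    msa_row: int | None = None

    def __post_init__(self):
        bad = set(self.sequence) - _RESIDUE_SET
        if bad:
            raise ValidationError(
                f"kinase {self.id!r}: illegal residue letter(s) {sorted(bad)}"
            )
        if len(self.sequence) < 1:
            raise ValidationError(f"kinase {self.id!r}: empty sequence")


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    atoms: list of (element symbol, formal charge, attached-H count)
    bonds: list of (i, j, order) with order in {1, 2, 3, "aromatic"},
           each undirected pair listed once.
    coords2d: optional (x, y) per atom.
    """

    atoms: list[tuple[str, int, int]]
    bonds: list[tuple[int, int, object]]
    coords2d: list[tuple[float, float]] | None = None

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) endpoint out of range")
            if i == j:
                raise ValidationError(f"self-loop bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for idx, (sym, charge, nh) in enumerate(self.atoms):
            g.add_node(idx, element=sym, charge=charge, num_h=nh)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def to_rdkit(self):
        from rdkit import Chem

        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            "aromatic": Chem.BondType.AROMATIC,
        }
        mol = Chem.RWMol()
        for sym, charge, _nh in self.atoms:
            a = Chem.Atom(sym)
            a.SetFormalCharge(charge)
            mol.AddAtom(a)
        for i, j, order in self.bonds:
            mol.AddBond(i, j, order_map[order])
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return m

    @classmethod
    def from_rdkit(cls, mol, keep_coords: bool = True) -> "MolecularGraph":
        from rdkit import Chem

        atoms = [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC:
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        coords = None
        if keep_coords and mol.GetNumConformers() > 0:
            conf = mol.GetConformer()
            coords = [
                (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
                for i in range(mol.GetNumAtoms())
            ]
        return cls(atoms=atoms, bonds=bonds, coords2d=coords)

    def is_connected(self) -> bool:
        import networkx as nx

        g = self.to_networkx()
        return g.number_of_nodes() > 0 and nx.is_connected(g)


@dataclass
class InhibitorRecord:
    """A small-molecule kinase inhibitor with annotations."""

    id: str
    graph: MolecularGraph
    primary_target: str | None = None
    structure_cluster: str | None = None


@dataclass
class BindingMatrix:
    """m x n binary interaction labels (rows = kinases, cols = inhibitors)."""

    kinase_ids: list[str]
    inhibitor_ids: list[str]
    labels: np.ndarray  # int array of shape (m, n) with entries in {0, 1}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.kinase_ids), len(self.inhibitor_ids)):
            raise ValidationError("binding matrix shape mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("binding matrix entries must be 0 or 1")

    @property
    def m(self) -> int:
        return len(self.kinase_ids)

    @property
    def n(self) -> int:
        return len(self.inhibitor_ids)

    @property
    def binding_fraction(self) -> float:
        return float(self.labels.mean())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.labels, index=self.kinase_ids, columns=self.inhibitor_ids
        )
        df.to_csv(path)


@dataclass
class FeatureColumn:
    name: str
    kind: str  # "numeric" | "nominal"
    group: str  # group tag (Tables of feature groups)
    categories: tuple = ()  # explicit category set for nominal columns

    def __post_init__(self):
        if self.kind not in ("numeric", "nominal"):
            raise ValidationError(f"column {self.name!r}: bad kind {self.kind!r}")
        if self.group not in GROUP_TAGS:
            raise ValidationError(f"column {self.name!r}: bad group {self.group!r}")


class FeatureTable:
    """Typed, named features per entity (kinase, inhibitor or pair)."""

    def __init__(self, entity_ids, columns: list[FeatureColumn], values):
        self.entity_ids = list(entity_ids)
        self.columns = list(columns)
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature column names")
        self.data = pd.DataFrame(values, index=self.entity_ids, columns=names)
        # freeze nominal category sets from data if not given
        for c in self.columns:
            if c.kind == "nominal" and not c.categories:
                c.categories = tuple(
                    sorted(map(str, pd.unique(self.data[c.name])))
                )

    @property
    def width(self) -> int:
        return len(self.columns)

    def __len__(self) -> int:
        return len(self.entity_ids)

    def column(self, name: str) -> FeatureColumn:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def groups(self) -> list[str]:
        seen = []
        for c in self.columns:
            if c.group not in seen:
                seen.append(c.group)
        return seen

    def select_groups(self, groups) -> "FeatureTable":
        groups = set(groups)
        cols = [c for c in self.columns if c.group in groups]
        return FeatureTable(
            self.entity_ids,
            [replace(c) for c in cols],
            self.data[[c.name for c in cols]].copy(),
        )

    def row(self, entity_id: str):
        return self.data.loc[entity_id]

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        """Horizontal concatenation over identical entity id lists."""
        ids = tables[0].entity_ids
        for t in tables[1:]:
            if t.entity_ids != ids:
                raise ValidationError("cannot concat tables with different ids")
        cols = [replace(c) for t in tables for c in t.columns]
        data = pd.concat([t.data for t in tables], axis=1)
        return FeatureTable(ids, cols, data)

    # -- on-disk format: CSV with a two-line header (name / type:group) -------

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id," + ",".join(c.name for c in self.columns) + "\n")
            fh.write(
                "#types,"
                + ",".join(f"{c.kind}:{c.group}" for c in self.columns)
                + "\n"
            )
            for eid in self.entity_ids:
                row = self.data.loc[eid]
                cells = []
                for c in self.columns:
                    v = row[c.name]
                    if c.kind == "numeric":
                        cells.append(repr(float(v)))
                    else:
                        cells.append(str(v))
                fh.write(str(eid) + "," + ",".join(cells) + "\n")

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
            typeline = fh.readline().rstrip("\n").split(",")
            if typeline[0] != "#types":
                raise ValidationError(f"{path}: missing '#types' header line")
            names = header[1:]
            cols = []
            for name, spec in zip(names, typeline[1:]):
                kind, group = spec.split(":")
                cols.append(FeatureColumn(name, kind, group))
            ids, rows = [], []
            for line in fh:
                cells = line.rstrip("\n").split(",")
                ids.append(cells[0])
                row = []
                for c, cell in zip(cols, cells[1:]):
                    row.append(float(cell) if c.kind == "numeric" else cell)
                rows.append(row)
        return cls(ids, cols, pd.DataFrame(rows, index=ids, columns=names))


@dataclass
class PairInstance:
    """One kinase-inhibitor pair: concatenated features plus binary label."""

    kinase_id: str
    inhibitor_id: str
    features: pd.Series
    label: int

    @property
    def pair_id(self) -> str:
        return f"{self.kinase_id}|{self.inhibitor_id}"


@dataclass
class DatasetBundle:
    """Everything one experiment needs, in memory."""

    kinases: list[KinaseRecord]
    inhibitors: list[InhibitorRecord]
    matrix: BindingMatrix
    msa: "object" = None  # alignment_features.MSA
    active_columns: list[int] = field(default_factory=list)

    def kinase(self, kid: str) -> KinaseRecord:
        for k in self.kinases:
            if k.id == kid:
                return k
        raise KeyError(kid)


# ---------------------------------------------------------------------------
# Readers


def read_sequences(path) -> list[KinaseRecord]:
    """Read protein sequences from FASTA; header token before whitespace is the id."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely here
        raise ValidationError(f"{path}: malformed FASTA ({exc})") from exc
    for rec in parsed:
        records.append(KinaseRecord(id=rec.id, sequence=str(rec.seq).upper()))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sequence ids")
    return records


def read_binding_matrix(path) -> BindingMatrix:
    """Read the binary binding matrix (rows = kinases, columns = inhibitors)."""
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        rows, cols = np.where(df.isna())
        raise ValidationError(
            f"{path}: missing cell at row {df.index[rows[0]]!r}, "
            f"column {df.columns[cols[0]]!r}"
        )
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-binary cell {arr[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return BindingMatrix(
        kinase_ids=[str(i) for i in df.index],
        inhibitor_ids=[str(c) for c in df.columns],
        labels=arr.astype(int),
    )


def read_molecules(path) -> list[InhibitorRecord]:
    """Read inhibitors from a SMILES (.smi: 'SMILES id' per line) or SDF file."""
    from rdkit import Chem

    path = str(path)
    records: list[InhibitorRecord] = []
    if path.lower().endswith((".sdf", ".mol")):
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                raise ValidationError(f"{path}: unparsable SDF entry {idx}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
            records.append(_make_inhibitor(mol, name or f"mol{idx}", idx, path))
    else:
        with open(path) as fh:
            idx = 0
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                name = parts[1] if len(parts) > 1 else f"mol{idx}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    raise ValidationError(f"{path}: unparsable entry {idx} ({smiles!r})")
                records.append(_make_inhibitor(mol, name, idx, path))
                idx += 1
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate molecule ids")
    return records


def _make_inhibitor(mol, name, idx, path) -> InhibitorRecord:
    graph = MolecularGraph.from_rdkit(mol)
    if not graph.is_connected():
        raise ValidationError(f"{path}: entry {idx} ({name}) is disconnected")
    return InhibitorRecord(id=name, graph=graph)


def read_kinase_annotations(path, records: list[KinaseRecord]) -> list[KinaseRecord]:
    """Attach STTK/group/family annotations from a TSV (id, sttk, group, family)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sttk", "group", "family"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(required)}")
    table = df.set_index("id")
    for rec in records:
        if rec.id not in table.index:
            raise ValidationError(f"{path}: no annotation for kinase {rec.id!r}")
        row = table.loc[rec.id]
        rec.sttk, rec.group, rec.family = row["sttk"], row["group"], row["family"]
    return records


def read_inhibitor_annotations(path, records: list[InhibitorRecord]) -> list[InhibitorRecord]:
    """Attach primary target / structure cluster from a TSV (id, primary_target, structure_cluster)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "primary_target", "structure_cluster"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(required)}")
    table = df.set_index("id")
    for rec in records:
        if rec.id not in table.index:
            raise ValidationError(f"{path}: no annotation for inhibitor {rec.id!r}")
        row = table.loc[rec.id]
        rec.primary_target = row["primary_target"]
        rec.structure_cluster = row["structure_cluster"]
    return records


def read_active_columns(path) -> list[int]:
    """Read 1-based active-site MSA column indices (TSV, one per line) as 0-based."""
    cols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols.append(int(line.split()[0]) - 1)
    return cols


def assemble_pairs(
    kin_features: FeatureTable,
    inh_features: FeatureTable,
    matrix: BindingMatrix,
) -> list[PairInstance]:
    """Concatenate kinase and inhibitor feature rows into m*n pair instances.

    Instances come out row-major: all inhibitors of the first kinase, then the
    second kinase, and so on; labels are copied from the binding matrix.
    """
    for kid in matrix.kinase_ids:
        if kid not in kin_features.data.index:
            raise ValidationError(f"kinase {kid!r} missing from kinase feature table")
    for iid in matrix.inhibitor_ids:
        if iid not in inh_features.data.index:
            raise ValidationError(f"inhibitor {iid!r} missing from inhibitor feature table")
    instances = []
    for ki, kid in enumerate(matrix.kinase_ids):
        krow = kin_features.data.loc[kid]
        for ii, iid in enumerate(matrix.inhibitor_ids):
            irow = inh_features.data.loc[iid]
            feats = pd.concat([krow, irow])
            instances.append(
                PairInstance(
                    kinase_id=kid,
                    inhibitor_id=iid,
                    features=feats,
                    label=int(matrix.labels[ki, ii]),
                )
            )
    return instances


def pair_feature_table(
    kin_features: FeatureTable,
    inh_features: FeatureTable,
    matrix: BindingMatrix,
) -> tuple[FeatureTable, np.ndarray, list[tuple[int, int]]]:
    """Vectorized pair assembly: a pair FeatureTable plus labels and (ki, ii) index pairs.

    Equivalent to :func:`assemble_pairs` but returns one table of m*n rows,
    which is what the evaluation loop consumes.
    """
    for kid in matrix.kinase_ids:
        if kid not in kin_features.data.index:
            raise ValidationError(f"kinase {kid!r} missing from kinase feature table")
    for iid in matrix.inhibitor_ids:
        if iid not in inh_features.data.index:
            raise ValidationError(f"inhibitor {iid!r} missing from inhibitor feature table")
    m, n = matrix.m, matrix.n
    kin = kin_features.data.loc[matrix.kinase_ids].to_numpy()
    inh = inh_features.data.loc[matrix.inhibitor_ids].to_numpy()
    kin_rep = np.repeat(kin, n, axis=0)
    inh_rep = np.tile(inh, (m, 1))
    values = np.concatenate([kin_rep, inh_rep], axis=1)
    ids = [
        f"{kid}|{iid}" for kid in matrix.kinase_ids for iid in matrix.inhibitor_ids
    ]
    cols = [replace(c) for c in kin_features.columns] + [
        replace(c) for c in inh_features.columns
    ]
    # de-duplicate column names across the two sides if they collide
    seen: dict[str, int] = {}
    for c in cols:
        if c.name in seen:
            seen[c.name] += 1
            c.name = f"{c.name}__{seen[c.name]}"
        else:
            seen[c.name] = 0
    table = FeatureTable(ids, cols, values)
    labels = matrix.labels.reshape(-1).copy()
    index_pairs = [(ki, ii) for ki in range(m) for ii in range(n)]
    return table, labels, index_pairs
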