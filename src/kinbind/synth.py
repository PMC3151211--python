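"""Synthetic kinase-inhibitor bundles with a plantable binding signal.

The generator emulates the statistical shape of a dyadic binding screen:
m kinases x n inhibitors with a ~26/74 binding/no-binding split.  Kinase
sequences are drawn pre-aligned from a consensus (so the MSA is exact):
most positions are conserved up to noise, a designated set of *active-site*
columns is fully conserved, and a few *signal* columns carry one of two
archetype residue patterns.  Inhibitors are random acyclic molecules over
{C, N, O, S}; a designated fraction carries a planted amide-like fragment
(N-C(=O)).  The planted rule makes archetype-1 kinases bind fragment-bearing
inhibitors; labels interpolate between the rule and independent noise via
the signal strength s, and the matrix is rebalanced by a minimal number of
random flips to hit the target positive rate within +-2%.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import MSA
from .io import (
    RESIDUES,
    BindingMatrix,
    DatasetBundle,
    InhibitorRecord,
    KinaseRecord,
    MolecularGraph,
    ValidationError,
)

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}

STTK_CLASSES = ("Ser/Thr", "Tyr")
GROUPS = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK")


@dataclass
class SynthSpec:
    """Generator knobs; defaults emulate the 113 x 20 screen's shape."""

    m: int = 113
    n: int = 20
    seq_len: int = 120
    n_active_columns: int = 12   # fully conserved active-site columns
    n_signal_columns: int = 3    # archetype-discriminating active-site columns
    conservation: float = 1.0    # per-column consensus fidelity elsewhere
    n_archetypes: int = 2
    archetype_fraction: float = 0.55  # fraction of kinases in archetype 1
    fragment_fraction: float = 0.5    # fraction of inhibitors with the fragment
    mol_atoms: tuple[int, int] = (9, 14)
    signal: float = 1.0          # s in [0, 1]
    positive_rate: float = 0.264  # target pi
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.signal <= 1.0):
            raise ValidationError("signal strength must be in [0, 1]")
        if not (0.0 < self.positive_rate < 1.0):
            raise ValidationError("positive rate must be in (0, 1)")
        if not (0.0 <= self.conservation <= 1.0):
            raise ValidationError("conservation must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    archetypes: list[int]            # per kinase
    fragment_flags: list[int]        # per inhibitor
    signal_columns: list[int]        # archetype-discriminating MSA columns
    conserved_active_columns: list[int]
    active_columns: list[int]        # union, as handed to PSF
    fragment_elements: list[str]     # planted free tree
    fragment_bonds: list[tuple[int, int, object]]
    signal: float
    positive_rate: float

    def fragment_graph(self):
        import networkx as nx

        g = nx.Graph()
        for i, el in enumerate(self.fragment_elements):
            g.add_node(i, element=el)
        for i, j, order in self.fragment_bonds:
            g.add_edge(i, j, order=order)
        return g

    def as_dict(self) -> dict:
        return {
            "archetypes": self.archetypes,
            "fragment_flags": self.fragment_flags,
            "signal_columns": self.signal_columns,
            "conserved_active_columns": self.conserved_active_columns,
            "active_columns": self.active_columns,
            "fragment_elements": self.fragment_elements,
            "fragment_bonds": [list(b) for b in self.fragment_bonds],
            "signal": self.signal,
            "positive_rate": self.positive_rate,
        }


# planted fragment: N-C(=O), an amide-like free tree
_FRAGMENT_ELEMENTS = ["N", "C", "O"]
_FRAGMENT_BONDS: list[tuple[int, int, object]] = [(0, 1, 1), (1, 2, 2)]


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=length)]


def _mutate(rng: np.random.Generator, residue: str) -> str:
    choices = [r for r in RESIDUES if r != residue]
    return choices[int(rng.integers(0, len(choices)))]


def _free_valence(atoms, bonds, idx) -> int:
    sym = atoms[idx][0]
    used = sum(
        (2 if o == 2 else 3 if o == 3 else 1)
        for i, j, o in bonds
        if idx in (i, j)
    )
    return _VALENCE[sym] - used


def _build_molecule(
    rng: np.random.Generator, n_atoms: int, with_fragment: bool
) -> MolecularGraph:
    """Grow a random acyclic molecule; optionally splice in the amide fragment.

    Molecules without the fragment may contain N and C=O but never an
    N-C(=O) adjacency, so the planted tree separates the two classes.
    """
    atoms: list[list] = [["C", 0, 0]]
    bonds: list[tuple[int, int, object]] = []
    has_carbonyl: set[int] = set()   # carbons carrying =O
    has_nitrogen: set[int] = set()   # carbons bonded to N

    def attach(sym: str, to: int, order: int = 1) -> int:
        atoms.append([sym, 0, 0])
        idx = len(atoms) - 1
        bonds.append((to, idx, order))
        return idx

    while len(atoms) < n_atoms:
        open_atoms = [
            i for i in range(len(atoms)) if _free_valence(atoms, bonds, i) >= 1
        ]
        if not open_atoms:
            break
        to = int(open_atoms[int(rng.integers(0, len(open_atoms)))])
        r = rng.random()
        if r < 0.60:
            sym = "C"
        elif r < 0.75:
            sym = "S"
        elif r < 0.90:
            sym = "O"
        else:
            sym = "N"
        if sym == "N":
            # keep amide adjacency exclusive to fragment-flagged molecules
            if atoms[to][0] != "C" or to in has_carbonyl:
                sym = "C"
        idx = attach(sym, to)
        if sym == "N":
            has_nitrogen.add(to)
        # occasional carbonyl decoration on fresh carbons
        if (
            sym == "C"
            and rng.random() < 0.15
            and _free_valence(atoms, bonds, idx) >= 2
            and idx not in has_nitrogen
            and atoms[to][0] != "N"
        ):
            o = attach("O", idx, order=2)
            has_carbonyl.add(idx)
    if with_fragment:
        open_c = [
            i
            for i in range(len(atoms))
            if atoms[i][0] == "C"
            and _free_valence(atoms, bonds, i) >= 1
            and i not in has_carbonyl
        ]
        to = int(open_c[int(rng.integers(0, len(open_c)))]) if open_c else 0
        cstar = attach("C", to)
        attach("O", cstar, order=2)
        attach("N", cstar, order=1)
    # implicit hydrogens fill the remaining valence
    final_atoms = [
        (sym, charge, _free_valence(atoms, bonds, i))
        for i, (sym, charge, _h) in enumerate(atoms)
    ]
    return MolecularGraph(atoms=final_atoms, bonds=bonds)


def generate_bundle(spec: SynthSpec) -> tuple[DatasetBundle, GroundTruth]:
    """Generate a complete dataset bundle plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    target = spec.positive_rate
    if not (1 <= round(target * m * n) <= m * n - 1):
        raise ValidationError("positive rate infeasible for this matrix size")

    # --- kinases -----------------------------------------------------------
    consensus = _random_sequence(rng, spec.seq_len)
    all_cols = rng.permutation(spec.seq_len)
    conserved_active = sorted(int(c) for c in all_cols[: spec.n_active_columns])
    signal_cols = sorted(
        int(c)
        for c in all_cols[
            spec.n_active_columns : spec.n_active_columns + spec.n_signal_columns
        ]
    )
    active_columns = sorted(conserved_active + signal_cols)

    n_arch1 = int(math.floor(spec.archetype_fraction * m))
    archetypes = np.zeros(m, dtype=int)
    archetypes[rng.permutation(m)[:n_arch1]] = 1
    # archetype-specific residues at signal columns
    arch_residues = {}
    for c in signal_cols:
        base = consensus[c]
        alt = _mutate(rng, base)
        arch_residues[c] = (base, alt)

    kin_ids = [f"K{i:03d}" for i in range(m)]
    kinases, rows = [], []
    for i in range(m):
        seq = list(consensus)
        for c in signal_cols:
            seq[c] = arch_residues[c][archetypes[i]]
        for c in range(spec.seq_len):
            if c in arch_residues or c in conserved_active:
                continue
            if rng.random() > spec.conservation:
                seq[c] = _mutate(rng, seq[c])
        seq_s = "".join(seq)
        rows.append(seq_s)
        kinases.append(
            KinaseRecord(
                id=kin_ids[i],
                sequence=seq_s,
                sttk=STTK_CLASSES[int(rng.random() < 0.3)],
                group=GROUPS[int(rng.integers(0, len(GROUPS)))],
                family=None,
                msa_row=i,
            )
        )
        kinases[-1].family = f"{kinases[-1].group}_f{int(rng.integers(1, 4))}"
    msa = MSA(kin_ids, rows)

    # --- inhibitors --------------------------------------------------------
    n_frag = int(math.floor(spec.fragment_fraction * n))
    flags = np.zeros(n, dtype=int)
    flags[rng.permutation(n)[:n_frag]] = 1
    inh_ids = [f"I{j:02d}" for j in range(n)]
    inhibitors = []
    for j in range(n):
        n_atoms = int(rng.integers(spec.mol_atoms[0], spec.mol_atoms[1] + 1))
        graph = _build_molecule(rng, n_atoms, with_fragment=bool(flags[j]))
        inhibitors.append(
            InhibitorRecord(
                id=inh_ids[j],
                graph=graph,
                primary_target=None,
                structure_cluster=(
                    "amide" if flags[j] else f"plain{int(rng.integers(1, 3))}"
                ),
            )
        )

    # --- labels ------------------------------------------------------------
    rule = np.outer(archetypes, flags).astype(float)
    prob = spec.signal * rule + (1.0 - spec.signal) * target
    labels = (rng.random((m, n)) < prob).astype(int)
    labels = _rebalance(rng, labels, target, band=0.02)
    matrix = BindingMatrix(kin_ids, inh_ids, labels)

    # primary target annotation: the kinase an inhibitor binds most (first hit)
    for j, rec in enumerate(inhibitors):
        hits = np.flatnonzero(labels[:, j])
        rec.primary_target = kin_ids[int(hits[0])] if hits.size else "none"

    bundle = DatasetBundle(
        kinases=kinases,
        inhibitors=inhibitors,
        matrix=matrix,
        msa=msa,
        active_columns=active_columns,
    )
    truth = GroundTruth(
        archetypes=[int(a) for a in archetypes],
        fragment_flags=[int(f) for f in flags],
        signal_columns=signal_cols,
        conserved_active_columns=conserved_active,
        active_columns=active_columns,
        fragment_elements=list(_FRAGMENT_ELEMENTS),
        fragment_bonds=list(_FRAGMENT_BONDS),
        signal=spec.signal,
        positive_rate=target,
    )
    return bundle, truth


def _rebalance(
    rng: np.random.Generator, labels: np.ndarray, target: float, band: float
) -> np.ndarray:
    """Flip a minimal random subset of labels until the rate is within +-band."""
    labels = labels.copy()
    total = labels.size
    lo, hi = target - band, target + band
    rate = labels.mean()
    if lo <= rate <= hi:
        return labels
    want = int(round(target * total))
    have = int(labels.sum())
    if have < want:
        zeros = np.argwhere(labels == 0)
        flip = zeros[rng.permutation(len(zeros))[: want - have]]
        for a, b in flip:
            labels[a, b] = 1
    else:
        ones = np.argwhere(labels == 1)
        flip = ones[rng.permutation(len(ones))[: have - want]]
        for a, b in flip:
            labels[a, b] = 0
    return labels


# ---------------------------------------------------------------------------
# On-disk bundle


def write_bundle(bundle: DatasetBundle, truth: GroundTruth, directory) -> None:
    """Write the full bundle directory (FASTA, SMILES, TSV, CSV, JSON)."""
    from rdkit import Chem

    os.makedirs(directory, exist_ok=True)
    p = lambda name: os.path.join(directory, name)
    with open(p("sequences.fasta"), "w") as fh:
        for k in bundle.kinases:
            fh.write(f">{k.id}\n{k.sequence}\n")
    bundle.msa.write_fasta(p("msa.fasta"))
    with open(p("kinase_annotations.tsv"), "w") as fh:
        fh.write("id\tsttk\tgroup\tfamily\n")
        for k in bundle.kinases:
            fh.write(f"{k.id}\t{k.sttk}\t{k.group}\t{k.family}\n")
    with open(p("inhibitors.smi"), "w") as fh:
        for rec in bundle.inhibitors:
            smiles = Chem.MolToSmiles(rec.graph.to_rdkit())
            fh.write(f"{smiles} {rec.id}\n")
    with open(p("inhibitor_annotations.tsv"), "w") as fh:
        fh.write("id\tprimary_target\tstructure_cluster\n")
        for rec in bundle.inhibitors:
            fh.write(f"{rec.id}\t{rec.primary_target}\t{rec.structure_cluster}\n")
    bundle.matrix.to_csv(p("matrix.csv"))
    with open(p("active_columns.tsv"), "w") as fh:
        for c in bundle.active_columns:
            fh.write(f"{c + 1}\n")  # 1-based on disk
    with open(p("truth.json"), "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_bundle(directory) -> DatasetBundle:
    from . import io as kio

    p = lambda name: os.path.join(directory, name)
    kinases = kio.read_sequences(p("sequences.fasta"))
    kio.read_kinase_annotations(p("kinase_annotations.tsv"), kinases)
    inhibitors = kio.read_molecules(p("inhibitors.smi"))
    kio.read_inhibitor_annotations(p("inhibitor_annotations.tsv"), inhibitors)
    matrix = kio.read_binding_matrix(p("matrix.csv"))
    msa = MSA.read_fasta(p("msa.fasta"))
    for k in kinases:
        k.msa_row = msa.row_index(k.id)
    active = kio.read_active_columns(p("active_columns.tsv"))
    return DatasetBundle(
        kinases=kinases,
        inhibitors=inhibitors,
        matrix=matrix,
        msa=msa,
        active_columns=active,
    )


# ---------------------------------------------------------------------------
# Signal recovery


def majority_rate_soft(matrix: BindingMatrix) -> float:
    """Accuracy of the per-split majority baseline under soft-case LOOCV."""
    total = matrix.labels.size
    pos = int(matrix.labels.sum())
    correct = 0
    for label in matrix.labels.reshape(-1):
        train_pos = pos - int(label)
        train_neg = (total - 1) - train_pos
        pred = 1 if train_pos > train_neg else 0
        correct += int(pred == int(label))
    return correct / total


def signal_recovery_check(
    bundle: DatasetBundle,
    truth: GroundTruth,
    case: str = "soft",
    classifier=None,
    min_freq: float = 0.2,
    max_tree_size: int = 6,
    seed: int = 0,
) -> dict:
    """Run the full pipeline on a generated bundle and report signal recovery.

    Features: phylogeny nominals, position-specific residues at the active
    columns, mined free-tree border elements, nominal inhibitor annotations
    and (non-hard cases) KNN binding-profile features.  Reports test accuracy
    against the majority rate, whether the planted fragment is contained in a
    mined border element, and whether the planted columns are recovered.
    """
    from .alignment import conserved_columns
    from .classify import ClassifierSpec
    from .evaluate import SplitSpec, run_experiment
    from .inhibitor_features import (
        contains_tree,
        free_tree_feature_table,
        inhibitor_nominal_features,
        mine_free_trees,
    )
    from .kinase_features import phylo_features, position_specific_features

    if classifier is None:
        classifier = ClassifierSpec(kind="tree", seed=seed)

    kin_table = phylo_features(bundle.kinases)
    psf = position_specific_features(
        bundle.msa, bundle.kinases, bundle.active_columns
    )
    from .io import FeatureTable

    kin_table = FeatureTable.concat([kin_table, psf])

    trees = mine_free_trees(
        [r.graph for r in bundle.inhibitors],
        min_freq=min_freq,
        border_only=True,
        max_size=max_tree_size,
    )
    inh_table = FeatureTable.concat(
        [
            inhibitor_nominal_features(bundle.inhibitors),
            free_tree_feature_table(trees, bundle.inhibitors),
        ]
    )

    spec = SplitSpec(case=case, seed=seed)
    if case in ("mixed", "mixed_mixed"):
        spec = SplitSpec(case=case, kinase_amount=0.5, inhibitor_amount=0.5, seed=seed)
    report = run_experiment(
        bundle.matrix,
        kin_table,
        inh_table,
        spec,
        classifier,
        include_knn=(case != "hard"),
    )

    frag = truth.fragment_graph()
    fragment_mined = any(
        contains_tree(p.to_networkx(), frag) for p in trees
    )
    recovered = set(conserved_columns(bundle.msa))
    conserved_recovered = set(truth.conserved_active_columns) <= recovered
    psf_names = {c.name for c in psf.columns}
    signal_in_psf = all(
        f"psf_c{c}" in psf_names for c in truth.signal_columns
    )
    maj = majority_rate_soft(bundle.matrix)
    return {
        "case": case,
        "test_accuracy": report.test.accuracy,
        "train_accuracy": report.train.accuracy,
        "majority_rate": maj,
        "accuracy_gain": report.test.accuracy - maj,
        "fragment_mined": fragment_mined,
        "conserved_columns_recovered": conserved_recovered,
        "signal_columns_in_psf": signal_in_psf,
        "n_border_trees": len(trees),
        "metrics": report.test.as_dict(),
    }
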