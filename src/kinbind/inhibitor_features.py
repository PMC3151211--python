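"""Molecular descriptors for kinase inhibitors.

* maximal frequent *free trees*: unrooted, connected, acyclic substructures
  matched by element symbol and bond order, mined level-wise with support
  counted once per molecule;
* binding-profile similarity features: each inhibitor's k nearest neighbors
  under a common-binding count or the Tanimoto coefficient c/(a+b-c);
* physico-chemical descriptors (molecular weight, logP, H-bond donors and
  acceptors, rotatable bonds, tautomer count, topological polar surface
  area);
* 2D geometric descriptors (topological diameter, principal-axis length and
  width, their ratio, atom count);
* 3-point pharmacophores: unordered triples of role-bearing atoms
  (donor/acceptor/charged) keyed by sorted roles and discretized topological
  distances;
* nominal passthrough features (primary target, 2D structural cluster).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher, categorical_edge_match, categorical_node_match

from .io import (
    BindingMatrix,
    FeatureColumn,
    FeatureTable,
    InhibitorRecord,
    MolecularGraph,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Binding-profile similarity


def tanimoto(a: int, b: int, c: int) -> float:
    """Tanimoto coefficient c/(a+b-c) of two binding profiles.

    ``a`` and ``b`` are the binding counts of the two inhibitors, ``c`` the
    number of kinases both bind.  Two all-zero profiles score 0.
    """
    if c > min(a, b):
        raise ValidationError("common count c cannot exceed min(a, b)")
    denom = a + b - c
    if denom == 0:
        return 0.0
    return c / denom


def profile_similarity(p, q, metric: str = "tanimoto") -> float:
    """Similarity of two 0/1 binding profiles."""
    p = np.asarray(p, dtype=int)
    q = np.asarray(q, dtype=int)
    c = int((p & q).sum())
    if metric == "common_count":
        return float(c)
    if metric == "tanimoto":
        return tanimoto(int(p.sum()), int(q.sum()), c)
    raise ValidationError(f"unknown similarity metric {metric!r}")


def knn_binding_features(
    matrix: BindingMatrix,
    target: int | str,
    k: int = 3,
    metric: str = "tanimoto",
) -> np.ndarray:
    """n-dimensional neighbor-similarity vector for one inhibitor.

    Entry j holds the similarity of the target's binding profile to inhibitor
    j's if j ranks among the k most similar other inhibitors, else 0; the
    target's own entry is 0.  Ties at the k-th rank are broken by inhibitor
    index order.  The caller is responsible for masking any test-pair label
    out of the matrix before calling this under leave-one-out evaluation.
    """
    if isinstance(target, str):
        target = matrix.inhibitor_ids.index(target)
    n = matrix.n
    profile = matrix.labels[:, target]
    sims = np.zeros(n)
    order = []
    for j in range(n):
        if j == target:
            continue
        s = profile_similarity(profile, matrix.labels[:, j], metric)
        order.append((-s, j))
    order.sort()
    for negs, j in order[: min(k, len(order))]:
        sims[j] = -negs
    return sims


def knn_feature_table(
    matrix: BindingMatrix, k: int = 3, metric: str = "tanimoto"
) -> FeatureTable:
    """Group-KNN table: one row per inhibitor, one column per inhibitor."""
    cols = [
        FeatureColumn(f"knn_{iid}", "numeric", "KNN") for iid in matrix.inhibitor_ids
    ]
    values = [
        knn_binding_features(matrix, j, k=k, metric=metric)
        for j in range(matrix.n)
    ]
    return FeatureTable(matrix.inhibitor_ids, cols, np.array(values))


# ---------------------------------------------------------------------------
# Free trees

_node_match = categorical_node_match("element", None)
_edge_match = categorical_edge_match("order", None)


@dataclass(frozen=True)
class FreeTreePattern:
    """A labelled free tree: nodes are elements, edges carry bond orders.

    ``canonical`` is invariant under isomorphism: centroid-rooted canonical
    string (lexicographic minimum over the one or two centroids).
    """

    elements: tuple[str, ...]
    edges: tuple[tuple[int, int, object], ...]
    canonical: str
    support: int = 0

    @property
    def size(self) -> int:
        return len(self.elements)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        for i, j, order in self.edges:
            g.add_edge(i, j, order=order)
        return g


def _rooted_canonical(g: nx.Graph, root: int, parent: int | None = None) -> str:
    parts = []
    for nb in g.neighbors(root):
        if nb == parent:
            continue
        order = g.edges[root, nb]["order"]
        parts.append(f"{order}{_rooted_canonical(g, nb, root)}")
    parts.sort()
    return "(" + g.nodes[root]["element"] + "".join(parts) + ")"


def _centroids(g: nx.Graph) -> list[int]:
    # iterative leaf stripping; a tree has one or two centroids
    nodes = set(g.nodes)
    degree = {v: g.degree(v) for v in nodes}
    leaves = [v for v in nodes if degree[v] <= 1]
    remaining = len(nodes)
    while remaining > 2:
        new_leaves = []
        for leaf in leaves:
            nodes.discard(leaf)
            for nb in g.neighbors(leaf):
                if nb in nodes:
                    degree[nb] -= 1
                    if degree[nb] == 1:
                        new_leaves.append(nb)
        remaining -= len(leaves)
        leaves = new_leaves
    return sorted(nodes)


def tree_canonical_form(g: nx.Graph) -> str:
    """Isomorphism-invariant string encoding of a labelled free tree."""
    if g.number_of_nodes() == 0:
        raise ValidationError("empty tree")
    if not nx.is_tree(g):
        raise ValidationError("graph is not a tree")
    return min(_rooted_canonical(g, c) for c in _centroids(g))


def _pattern_from_nx(g: nx.Graph, support: int = 0) -> FreeTreePattern:
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    elements = tuple(g.nodes[v]["element"] for v in nodes)
    edges = tuple(
        (index[u], index[v], g.edges[u, v]["order"]) for u, v in g.edges
    )
    return FreeTreePattern(
        elements=elements,
        edges=edges,
        canonical=tree_canonical_form(g),
        support=support,
    )


def contains_tree(host: nx.Graph, pattern: nx.Graph) -> bool:
    """Subgraph (non-induced) monomorphism test with element/order matching."""
    gm = GraphMatcher(host, pattern, node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_monomorphic()


def _embeddings(host: nx.Graph, pattern: nx.Graph):
    """All pattern->host node mappings (monomorphisms)."""
    gm = GraphMatcher(host, pattern, node_match=_node_match, edge_match=_edge_match)
    for mapping in gm.subgraph_monomorphisms_iter():
        yield {pv: hv for hv, pv in mapping.items()}


def mine_free_trees(
    graphs: list[MolecularGraph],
    min_freq: float = 0.10,
    border_only: bool = True,
    max_size: int = 12,
) -> list[FreeTreePattern]:
    """Level-wise mining of frequent free trees over a set of molecules.

    A pattern is frequent when it embeds (element- and bond-order-matched,
    once per molecule) in at least ``ceil(min_freq * len(graphs))`` molecules.
    With ``border_only`` only maximal patterns — those with no frequent
    one-atom extension, hence no frequent proper supertree — are returned.
    """
    if not (0 < min_freq <= 1):
        raise ValidationError("min_freq must be in (0, 1]")
    if not graphs:
        return []
    hosts = [g.to_networkx() for g in graphs]
    minsup = math.ceil(min_freq * len(hosts))

    # level 1: single atoms
    level: dict[str, tuple[nx.Graph, list[int]]] = {}
    elements = sorted({d["element"] for h in hosts for _, d in h.nodes(data=True)})
    for el in elements:
        supp = [
            hi
            for hi, h in enumerate(hosts)
            if any(d["element"] == el for _, d in h.nodes(data=True))
        ]
        if len(supp) >= minsup:
            g = nx.Graph()
            g.add_node(0, element=el)
            level[f"({el})"] = (g, supp)

    all_frequent: dict[str, tuple[nx.Graph, list[int]]] = dict(level)
    non_maximal: set[str] = set()

    size = 1
    while level and size < max_size:
        candidates: dict[str, tuple[nx.Graph, set[int]]] = {}
        for canon, (pat, supp) in level.items():
            for hi in supp:
                host = hosts[hi]
                for emb in _embeddings(host, pat):
                    image = set(emb.values())
                    inv = {hv: pv for pv, hv in emb.items()}
                    for hu in image:
                        for hv in host.neighbors(hu):
                            if hv in image:
                                continue
                            ext = pat.copy()
                            new = pat.number_of_nodes()
                            ext.add_node(
                                new, element=host.nodes[hv]["element"]
                            )
                            ext.add_edge(
                                inv[hu], new, order=host.edges[hu, hv]["order"]
                            )
                            ccanon = tree_canonical_form(ext)
                            if ccanon not in candidates:
                                candidates[ccanon] = (ext, set())
                            candidates[ccanon][1].add(hi)
        nxt: dict[str, tuple[nx.Graph, list[int]]] = {}
        for ccanon, (ext, touched) in candidates.items():
            if len(touched) < minsup:
                continue  # occurrence molecules already bound support above
            supp = sorted(touched)
            nxt[ccanon] = (ext, supp)
            # every size-k subtree of a frequent size-(k+1) tree is non-maximal
            for leaf in [v for v in ext.nodes if ext.degree(v) == 1]:
                sub = ext.copy()
                sub.remove_node(leaf)
                non_maximal.add(tree_canonical_form(sub))
        all_frequent.update(nxt)
        level = nxt
        size += 1

    patterns = [
        _pattern_from_nx(g, support=len(supp))
        for canon, (g, supp) in all_frequent.items()
        if not border_only or canon not in non_maximal
    ]
    patterns.sort(key=lambda p: (p.size, p.canonical))
    return patterns


def free_tree_feature_table(
    patterns: list[FreeTreePattern], records: list[InhibitorRecord]
) -> FeatureTable:
    """Presence/absence bitvector per mined free tree (group FTs)."""
    cols = [
        FeatureColumn(f"ft_{i}_{p.canonical}", "numeric", "FTs")
        for i, p in enumerate(patterns)
    ]
    pat_graphs = [p.to_networkx() for p in patterns]
    values = []
    for rec in records:
        host = rec.graph.to_networkx()
        values.append(
            [1.0 if contains_tree(host, pg) else 0.0 for pg in pat_graphs]
        )
    return FeatureTable([r.id for r in records], cols, values)


# ---------------------------------------------------------------------------
# Chemical and geometric descriptors

CHEMICAL_DESCRIPTORS = (
    "mol_weight",
    "logp",
    "hbd",
    "hba",
    "rotatable_bonds",
    "tautomer_count",
    "tpsa",
)


def chemical_descriptors(g: MolecularGraph) -> dict[str, float]:
    """Physico-chemical descriptor vector (group CF) via the RDKit engine."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = g.to_rdkit()
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(256)
    return {
        "mol_weight": float(Descriptors.MolWt(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "hbd": float(Lipinski.NumHDonors(mol)),
        "hba": float(Lipinski.NumHAcceptors(mol)),
        "rotatable_bonds": float(Descriptors.NumRotatableBonds(mol)),
        "tautomer_count": float(len(enumerator.Enumerate(mol))),
        "tpsa": float(Descriptors.TPSA(mol)),
    }


def _coords2d(g: MolecularGraph) -> np.ndarray:
    if g.coords2d is not None:
        return np.asarray(g.coords2d, dtype=float)
    from rdkit.Chem import rdDepictor

    mol = g.to_rdkit()
    rdDepictor.Compute2DCoords(mol)
    conf = mol.GetConformer()
    return np.array(
        [(conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y) for i in range(g.n_atoms)]
    )


GEOMETRIC_DESCRIPTORS = ("diameter", "length", "width", "aspect_ratio", "atom_count")


def geometric_descriptors(g: MolecularGraph) -> dict[str, float]:
    """2D shape descriptors (group GF).

    Diameter is the maximum shortest-path bond distance; length and width are
    the extents of the principal-axis-aligned bounding box of the 2D
    coordinates (computed from a deterministic layout when absent).
    """
    if g.n_atoms == 1:
        return {
            "diameter": 0.0,
            "length": 0.0,
            "width": 0.0,
            "aspect_ratio": 0.0,
            "atom_count": 1.0,
        }
    nxg = g.to_networkx()
    diameter = float(nx.diameter(nxg))
    coords = _coords2d(g)
    centered = coords - coords.mean(axis=0)
    # principal axes from the 2x2 covariance
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    length = float(max(extents))
    width = float(min(extents))
    ratio = length / width if width > 1e-12 else 0.0
    return {
        "diameter": diameter,
        "length": length,
        "width": width,
        "aspect_ratio": ratio,
        "atom_count": float(g.n_atoms),
    }


# ---------------------------------------------------------------------------
# 3-point pharmacophores

ROLES = ("HBA", "HBD", "NEG", "POS")
DEFAULT_DISTANCE_BINS = (2, 4, 6)  # upper edges; >6 falls into the last bin


def atom_roles(g: MolecularGraph) -> list[str | None]:
    """Assign one pharmacophoric role per atom (or None).

    Charges dominate H-bonding roles; among the latter, donors (N/O carrying
    at least one hydrogen) beat acceptors (N/O with a free lone pair; oxygens
    in a nitro-like context are excluded).  Priority: NEG > POS > HBD > HBA.
    """
    nxg = g.to_networkx()
    roles: list[str | None] = []
    for idx, (sym, charge, num_h) in enumerate(g.atoms):
        if charge < 0:
            roles.append("NEG")
        elif charge > 0:
            roles.append("POS")
        elif sym in ("N", "O") and num_h >= 1:
            roles.append("HBD")
        elif sym == "N":
            roles.append("HBA")
        elif sym == "O":
            nitro_like = any(
                g.atoms[nb][0] == "N"
                and sum(1 for nb2 in nxg.neighbors(nb) if g.atoms[nb2][0] == "O") >= 2
                for nb in nxg.neighbors(idx)
            )
            roles.append(None if nitro_like else "HBA")
        else:
            roles.append(None)
    return roles


def _bin_distance(d: int, bins: tuple[int, ...]) -> int:
    for i, edge in enumerate(bins):
        if d <= edge:
            return i
    return len(bins)


@dataclass(frozen=True)
class PharmacophoreTriplet:
    roles: tuple[str, str, str]        # lexicographically sorted
    distances: tuple[int, int, int]    # sorted ascending bin indices

    def key(self) -> str:
        return "-".join(self.roles) + ":" + ",".join(map(str, self.distances))


def pharmacophore_triplets(
    g: MolecularGraph, bins: tuple[int, ...] = DEFAULT_DISTANCE_BINS
) -> Counter:
    """Count all 3-point pharmacophores of one molecule.

    Pairwise distances are topological (bond-count shortest paths) and
    discretized by ``bins``; keys are invariant under atom reordering because
    both roles and binned distances are sorted.
    """
    roles = atom_roles(g)
    role_atoms = [i for i, r in enumerate(roles) if r is not None]
    counts: Counter = Counter()
    if len(role_atoms) < 3:
        return counts
    nxg = g.to_networkx()
    sp = dict(nx.all_pairs_shortest_path_length(nxg))
    for a, b, c in itertools.combinations(role_atoms, 3):
        triple_roles = tuple(sorted((roles[a], roles[b], roles[c])))
        dists = tuple(
            sorted(
                (
                    _bin_distance(sp[a][b], bins),
                    _bin_distance(sp[a][c], bins),
                    _bin_distance(sp[b][c], bins),
                )
            )
        )
        counts[PharmacophoreTriplet(triple_roles, dists)] += 1
    return counts


def pharmacophore_feature_table(
    records: list[InhibitorRecord],
    bins: tuple[int, ...] = DEFAULT_DISTANCE_BINS,
    top_f: int = 50,
) -> FeatureTable:
    """Triplet-count columns (group P): the corpus-wide union of triplet keys,
    truncated to the ``top_f`` most frequent."""
    per_mol = [pharmacophore_triplets(r.graph, bins) for r in records]
    totals: Counter = Counter()
    for c in per_mol:
        totals.update(c)
    keys = sorted(totals, key=lambda t: (-totals[t], t.key()))[:top_f]
    cols = [FeatureColumn(f"p_{t.key()}", "numeric", "P") for t in keys]
    values = [[float(c.get(t, 0)) for t in keys] for c in per_mol]
    return FeatureTable([r.id for r in records], cols, values)


# ---------------------------------------------------------------------------
# Descriptor tables and nominal features


def chemical_feature_table(records: list[InhibitorRecord]) -> FeatureTable:
    cols = [FeatureColumn(f"cf_{d}", "numeric", "CF") for d in CHEMICAL_DESCRIPTORS]
    values = []
    for rec in records:
        desc = chemical_descriptors(rec.graph)
        values.append([desc[d] for d in CHEMICAL_DESCRIPTORS])
    return FeatureTable([r.id for r in records], cols, values)


def geometric_feature_table(records: list[InhibitorRecord]) -> FeatureTable:
    cols = [FeatureColumn(f"gf_{d}", "numeric", "GF") for d in GEOMETRIC_DESCRIPTORS]
    values = []
    for rec in records:
        desc = geometric_descriptors(rec.graph)
        values.append([desc[d] for d in GEOMETRIC_DESCRIPTORS])
    return FeatureTable([r.id for r in records], cols, values)


def inhibitor_nominal_features(records: list[InhibitorRecord]) -> FeatureTable:
    """Primary target (PT) and 2D structural cluster (MS) passthrough."""
    for rec in records:
        if rec.primary_target is None or rec.structure_cluster is None:
            raise ValidationError(f"inhibitor {rec.id!r}: missing annotation")
    cols = [
        FeatureColumn("primary_target", "nominal", "PT"),
        FeatureColumn("structure_cluster", "nominal", "MS"),
    ]
    values = [[rec.primary_target, rec.structure_cluster] for rec in records]
    return FeatureTable([r.id for r in records], cols, values)
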