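"""Independent brute-force oracles used to validate the mining and alignment code.

These deliberately avoid the library's own search logic: patterns are
enumerated exhaustively, alignments by recursion over all edit paths, and
subtrees by explicit edge-subset enumeration.  They are only feasible on
tiny inputs, which is the point.
"""

from __future__ import annotations

import itertools

import networkx as nx

WILDCARD = "?"


# ---------------------------------------------------------------------------
# Sequence patterns


def _matches_at(symbols, s, i) -> bool:
    if i + len(symbols) > len(s):
        return False
    return all(a == WILDCARD or a == b for a, b in zip(symbols, s[i:]))


def occurs(symbols, s) -> bool:
    return any(_matches_at(symbols, s, i) for i in range(len(s) + 1))


def support(symbols, seqs) -> int:
    return sum(1 for s in seqs if occurs(symbols, s))


def enumerate_frequent_patterns(
    seqs, minsup, max_wildcards=2, min_size=1, max_len=10
):
    """All frequent patterns (no end wildcards) by exhaustive enumeration.

    Candidates are all substrings of all sequences with every way of
    replacing up to ``max_wildcards`` interior positions by the wildcard.
    Any frequent pattern must match some sequence window, so this space is
    complete.
    """
    out = {}
    windows = set()
    for s in seqs:
        for length in range(min_size, min(max_len, len(s)) + 1):
            for i in range(len(s) - length + 1):
                windows.add(s[i : i + length])
    for w in windows:
        interior = range(1, len(w) - 1)
        for k in range(0, max_wildcards + 1):
            for pos in itertools.combinations(interior, k):
                symbols = tuple(
                    WILDCARD if i in pos else c for i, c in enumerate(w)
                )
                if symbols in out:
                    continue
                sup = support(symbols, seqs)
                if sup >= minsup:
                    out[symbols] = sup
    return out


def is_subpattern(p, q) -> bool:
    lp, lq = len(p), len(q)
    if lp > lq:
        return False
    for off in range(lq - lp + 1):
        if all(
            a == WILDCARD or a == b for a, b in zip(p, q[off : off + lp])
        ):
            return True
    return False


def border_of(patterns) -> set:
    """Maximal patterns by pairwise sub-pattern checks."""
    pats = list(patterns)
    return {
        p
        for p in pats
        if not any(
            q != p and is_subpattern(p, q) and not is_subpattern(q, p)
            for q in pats
        )
    }


# ---------------------------------------------------------------------------
# Global alignment


def nw_enumerate(a: str, b: str, score, gap: float) -> float:
    """Optimal global alignment score by recursion over all edit paths."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


# ---------------------------------------------------------------------------
# Free trees


def enumerate_tree_subgraphs(host: nx.Graph):
    """All connected acyclic subgraphs of ``host`` (nodes + edge subsets).

    Yields networkx graphs: every single node, and every edge subset that
    forms a tree.  Exponential; for hosts with <= ~12 edges only.
    """
    for v in host.nodes:
        g = nx.Graph()
        g.add_node(v, **host.nodes[v])
        yield g
    edges = list(host.edges)
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            g = nx.Graph()
            for u, v in subset:
                g.add_node(u, **host.nodes[u])
                g.add_node(v, **host.nodes[v])
                g.add_edge(u, v, **host.edges[u, v])
            if nx.is_tree(g):
                yield g


def frequent_tree_canonicals(hosts, minsup, canonical_form, max_size=None):
    """Map canonical form -> support by exhaustive subtree enumeration."""
    per_host = []
    for h in hosts:
        forms = set()
        for g in enumerate_tree_subgraphs(h):
            if max_size is not None and g.number_of_nodes() > max_size:
                continue
            forms.add(canonical_form(g))
        per_host.append(forms)
    all_forms = set().union(*per_host) if per_host else set()
    out = {}
    for f in all_forms:
        sup = sum(1 for forms in per_host if f in forms)
        if sup >= minsup:
            out[f] = sup
    return out
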