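"""Sequence-derived kinase features.

Four feature families live here:

* frequent amino-acid sequence patterns mined level-wise (APriori with
  pattern merging), allowing up to two single-residue wildcards per pattern
  but never at the ends; support is counted once per sequence;
* *border elements*: the maximal frequent patterns (no frequent proper
  super-pattern), used to shrink the solution set;
* PROSITE-style pattern matches encoded as presence/absence bitvectors;
* phylogeny annotations (Ser/Thr-vs-Tyr class, group, family) and
  position-specific features: the residue (or its physico-chemical class)
  at designated active-site columns of the MSA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import RESIDUES, FeatureColumn, FeatureTable, KinaseRecord, ValidationError

WILDCARD = "?"


@dataclass(frozen=True)
class SequencePattern:
    """A contiguous residue pattern; ``?`` matches exactly one arbitrary residue."""

    symbols: tuple[str, ...]
    support: int = 0

    def __post_init__(self):
        if len(self.symbols) < 1:
            raise ValidationError("empty pattern")

    def __str__(self) -> str:
        return "".join(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_wildcards(self) -> int:
        return sum(1 for s in self.symbols if s == WILDCARD)

    @property
    def valid_output(self) -> bool:
        """Wildcards only in the interior — end wildcards carry no information."""
        return self.symbols[0] != WILDCARD and self.symbols[-1] != WILDCARD


@dataclass
class PatternSet:
    patterns: list[SequencePattern]
    minsup: int
    corpus_size: int

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self):
        return len(self.patterns)

    def as_strings(self) -> set[str]:
        return {str(p) for p in self.patterns}


def pattern_matches(p: SequencePattern, s: str) -> bool:
    """True iff the pattern occurs contiguously in ``s`` (multiplicity ignored)."""
    rx = "".join("." if sym == WILDCARD else re.escape(sym) for sym in p.symbols)
    return re.search(rx, s) is not None


def _support(symbols: tuple[str, ...], seqs: list[str]) -> int:
    p = SequencePattern(symbols)
    return sum(1 for s in seqs if pattern_matches(p, s))


def mine_frequent(
    seqs: list[str],
    minsup: int,
    max_wildcards: int = 2,
    min_size: int = 1,
    max_size: int = 10,
) -> PatternSet:
    """Level-wise (APriori) search for all frequent contiguous patterns.

    Candidates at level k+1 are built by *pattern merging*: two frequent
    length-k patterns whose (k-1)-suffix/prefix agree merge into one
    length-(k+1) candidate.  The search space internally allows wildcards at
    pattern ends (support stays anti-monotone there, and interior-wildcard
    patterns such as ``A?C`` are only reachable through such intermediates);
    the returned set keeps only patterns without end wildcards, with length
    >= ``min_size`` and support >= ``minsup``.
    """
    if minsup < 1:
        raise ValidationError("minsup must be >= 1")
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    alphabet = sorted(set("".join(seqs)) - {WILDCARD})
    out: list[SequencePattern] = []
    # level 1
    level: dict[tuple[str, ...], int] = {}
    for sym in alphabet + ([WILDCARD] if max_wildcards >= 1 else []):
        sup = _support((sym,), seqs)
        if sup >= minsup:
            level[(sym,)] = sup
    k = 1
    while level and k < max_size:
        frequent = set(level)
        candidates = set()
        for p in frequent:
            for q in frequent:
                if p[1:] == q[:-1]:
                    cand = p + (q[-1],)
                    if sum(1 for s in cand if s == WILDCARD) <= max_wildcards:
                        candidates.add(cand)
        nxt: dict[tuple[str, ...], int] = {}
        for cand in candidates:
            # APriori prune: both length-k windows must be frequent (they are by
            # construction); count on the corpus.
            sup = _support(cand, seqs)
            if sup >= minsup:
                nxt[cand] = sup
        for symbols, sup in level.items():
            pat = SequencePattern(symbols, sup)
            if pat.valid_output and len(symbols) >= min_size:
                out.append(pat)
        level = nxt
        k += 1
    for symbols, sup in level.items():
        pat = SequencePattern(symbols, sup)
        if pat.valid_output and len(symbols) >= min_size:
            out.append(pat)
    out.sort(key=lambda p: (len(p), str(p)))
    return PatternSet(out, minsup=minsup, corpus_size=len(seqs))


def is_subpattern(p: SequencePattern, q: SequencePattern) -> bool:
    """True iff every occurrence of ``q`` implies an occurrence of ``p``.

    ``p`` is a sub-pattern of ``q`` when ``p`` matches some window of ``q``
    with the convention that a wildcard in ``p`` subsumes any symbol of ``q``
    (a residue in ``p`` also matches a window position only if ``q`` has that
    same residue there — a wildcard in ``q`` is *more general*, so it cannot
    guarantee the residue).
    """
    lp, lq = len(p), len(q)
    if lp > lq:
        return False
    for off in range(lq - lp + 1):
        ok = True
        for a, b in zip(p.symbols, q.symbols[off : off + lp]):
            if a != WILDCARD and a != b:
                ok = False
                break
        if ok:
            return True
    return False


def border_elements(ps: PatternSet) -> PatternSet:
    """Keep the maximal (most specific) patterns: no frequent proper super-pattern."""
    pats = ps.patterns
    border = []
    for p in pats:
        dominated = any(
            q is not p and is_subpattern(p, q) and not is_subpattern(q, p)
            for q in pats
        )
        if not dominated:
            border.append(p)
    return PatternSet(border, minsup=ps.minsup, corpus_size=ps.corpus_size)


def apriori_features(ps: PatternSet, records: list[KinaseRecord]) -> FeatureTable:
    """Presence/absence bitvector (group Apri) for each mined pattern."""
    cols = [
        FeatureColumn(f"Apri_{p}", "numeric", "Apri") for p in ps.patterns
    ]
    values = [
        [1.0 if pattern_matches(p, rec.sequence) else 0.0 for p in ps.patterns]
        for rec in records
    ]
    return FeatureTable([r.id for r in records], cols, values)


# ---------------------------------------------------------------------------
# PROSITE-style patterns

_ELEMENT_RX = re.compile(
    r"^(?P<body>[A-Za-z]|x|\[[A-Z]+\]|\{[A-Z]+\})(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$"
)


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE pattern (supported subset) into a Python regex.

    Supported: residue letters, ``x`` (any), ``[..]`` alternatives, ``{..}``
    exclusions, ``elem(n)`` / ``elem(n,m)`` repetition, ``<`` / ``>`` anchors.
    Anything else raises loudly rather than silently mis-matching.
    """
    pat = pattern.strip().rstrip(".")
    anchored_start = pat.startswith("<")
    anchored_end = pat.endswith(">")
    pat = pat.lstrip("<").rstrip(">")
    parts = pat.split("-")
    rx = []
    for part in parts:
        m = _ELEMENT_RX.match(part)
        if not m:
            raise ValidationError(
                f"unsupported PROSITE element {part!r} in pattern {pattern!r}"
            )
        body = m.group("body")
        if body == "x":
            piece = "."
        elif body.startswith("["):
            piece = body
        elif body.startswith("{"):
            piece = "[^" + body[1:-1] + "]"
        elif body.isalpha() and len(body) == 1 and body.isupper():
            piece = body
        else:
            raise ValidationError(
                f"unsupported PROSITE element {part!r} in pattern {pattern!r}"
            )
        if m.group("n"):
            if m.group("m"):
                piece += "{%s,%s}" % (m.group("n"), m.group("m"))
            else:
                piece += "{%s}" % m.group("n")
        rx.append(piece)
    return ("^" if anchored_start else "") + "".join(rx) + ("$" if anchored_end else "")


def prosite_features(
    patterns: list[tuple[str, str]] | list[str],
    records: list[KinaseRecord],
) -> FeatureTable:
    """0/1 columns (group PRO), one per PROSITE pattern.

    ``patterns`` is either a list of pattern strings or of (id, pattern) pairs.
    """
    named = [
        (p if isinstance(p, tuple) else (f"PRO_{i}", p))
        for i, p in enumerate(patterns)
    ]
    compiled = [(pid, re.compile(prosite_to_regex(pat))) for pid, pat in named]
    cols = [FeatureColumn(pid, "numeric", "PRO") for pid, _ in compiled]
    values = [
        [1.0 if rx.search(rec.sequence) else 0.0 for _, rx in compiled]
        for rec in records
    ]
    return FeatureTable([r.id for r in records], cols, values)


def read_prosite_file(path) -> list[tuple[str, str]]:
    """One pattern per line: ``ID<TAB>pattern``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, pat = line.split("\t")
            out.append((pid, pat))
    return out


# ---------------------------------------------------------------------------
# Phylogeny and position-specific features


def phylo_features(records: list[KinaseRecord]) -> FeatureTable:
    """Nominal STTK class plus phylogenetic group and family (groups STTK, PC)."""
    for rec in records:
        if rec.sttk is None or rec.group is None or rec.family is None:
            raise ValidationError(f"kinase {rec.id!r}: missing phylogeny annotation")
    cols = [
        FeatureColumn("sttk", "nominal", "STTK"),
        FeatureColumn("group", "nominal", "PC"),
        FeatureColumn("family", "nominal", "PC"),
    ]
    values = [[rec.sttk, rec.group, rec.family] for rec in records]
    return FeatureTable([r.id for r in records], cols, values)


#: default physico-chemical classes for the 20 residues (overridable by file)
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{r: "hydrophobic" for r in "AVLIMC"},
    **{r: "aromatic" for r in "FWY"},
    **{r: "polar" for r in "STNQGP"},
    **{r: "positive" for r in "KRH"},
    **{r: "negative" for r in "DE"},
}


def read_class_map(path) -> dict[str, str]:
    """TSV residue -> class."""
    cmap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, cls = line.split("\t")
            cmap[res] = cls
    missing = set(RESIDUES) - set(cmap)
    if missing:
        raise ValidationError(f"class map misses residues {sorted(missing)}")
    return cmap


def position_specific_features(
    msa,
    records: list[KinaseRecord],
    active_columns: list[int],
    abstract: bool = False,
    classmap: dict[str, str] | None = None,
) -> FeatureTable:
    """One nominal column per active-site MSA column (group PSF or abPSF).

    The value is the residue of the kinase at that column — a gap ``-`` is its
    own category — or, with ``abstract=True``, its physico-chemical class.
    """
    classmap = classmap or DEFAULT_CLASS_MAP
    group = "abPSF" if abstract else "PSF"
    width = msa.width
    for c in active_columns:
        if not (0 <= c < width):
            raise ValidationError(f"active column {c} outside MSA width {width}")
    cols = [
        FeatureColumn(f"{group.lower()}_c{c}", "nominal", group)
        for c in active_columns
    ]
    values = []
    for rec in records:
        try:
            row = msa.row(rec.id)
        except KeyError:
            raise ValidationError(f"kinase {rec.id!r} absent from MSA") from None
        vals = []
        for c in active_columns:
            res = row[c]
            if res == "-":
                vals.append("-")
            elif abstract:
                vals.append(classmap.get(res, "other"))
            else:
                vals.append(res)
        values.append(vals)
    return FeatureTable([r.id for r in records], cols, values)
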