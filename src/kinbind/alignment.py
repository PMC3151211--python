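"""Alignment-based kinase features.

Full-length sequences differ enormously in length across the kinome, so
global alignment scores over whole sequences can be dominated by gap noise.
The module therefore also supports *frames*: short stretches of the multiple
sequence alignment around highly conserved active-site positions.  Frame
pairs are scored column-wise straight out of the MSA, or after stripping
gaps and re-aligning the two cut-out substrings.

Scoring uses standard integer substitution matrices (PAM120, BLOSUM62 or a
custom table) with a linear gap model: gap opening and gap extension cost
the same per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .io import RESIDUES, FeatureColumn, FeatureTable, KinaseRecord, ValidationError

#: default gap penalty per position, by matrix name
DEFAULT_GAPS = {"PAM120": -8, "BLOSUM62": -4}

# Standard NCBI PAM120 table (not distributed with biopython).
_PAM120_TEXT = """\
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X
A  3 -3 -1  0 -3 -1  0  1 -3 -1 -3 -2 -2 -4  1  1  1 -7 -4  0  0 -1 -1
R -3  6 -1 -3 -4  1 -3 -4  1 -2 -4  2 -1 -5 -1 -1 -2  1 -5 -3 -2 -1 -2
N -1 -1  4  2 -5  0  1  0  2 -2 -4  1 -3 -4 -2  1  0 -4 -2 -3  3  0 -1
D  0 -3  2  5 -7  1  3  0  0 -3 -5 -1 -4 -7 -3  0 -1 -8 -5 -3  4  3 -2
C -3 -4 -5 -7  9 -7 -7 -4 -4 -3 -7 -7 -6 -6 -4  0 -3 -8 -1 -3 -6 -7 -4
Q -1  1  0  1 -7  6  2 -3  3 -3 -2  0 -1 -6  0 -2 -2 -6 -5 -3  0  4 -1
E  0 -3  1  3 -7  2  5 -1 -1 -3 -4 -1 -3 -7 -2 -1 -2 -8 -5 -3  3  4 -1
G  1 -4  0  0 -4 -3 -1  5 -4 -4 -5 -3 -4 -5 -2  1 -1 -8 -6 -2  0 -2 -2
H -3  1  2  0 -4  3 -1 -4  7 -4 -3 -2 -4 -3 -1 -2 -3 -3 -1 -3  1  1 -2
I -1 -2 -2 -3 -3 -3 -3 -4 -4  6  1 -3  1  0 -3 -2  0 -6 -2  3 -3 -3 -1
L -3 -4 -4 -5 -7 -2 -4 -5 -3  1  5 -4  3  0 -3 -4 -3 -3 -2  1 -4 -3 -2
K -2  2  1 -1 -7  0 -1 -3 -2 -3 -4  5  0 -7 -2 -1 -1 -5 -5 -4  0 -1 -2
M -2 -1 -3 -4 -6 -1 -3 -4 -4  1  3  0  8 -1 -3 -2 -1 -6 -4  1 -4 -2 -2
F -4 -5 -4 -7 -6 -6 -7 -5 -3  0  0 -7 -1  8 -5 -3 -4 -1  4 -3 -5 -6 -3
P  1 -1 -2 -3 -4  0 -2 -2 -1 -3 -3 -2 -3 -5  6  1 -1 -7 -6 -2 -2 -1 -2
S  1 -1  1  0  0 -2 -1  1 -2 -2 -4 -1 -2 -3  1  3  2 -2 -3 -2  0 -1 -1
T  1 -2  0 -1 -3 -2 -2 -1 -3  0 -3 -1 -1 -4 -1  2  4 -6 -3  0  0 -2 -1
W -7  1 -4 -8 -8 -6 -8 -8 -3 -6 -3 -5 -6 -1 -7 -2 -6 12 -2 -8 -6 -7 -5
Y -4 -5 -2 -5 -1 -5 -5 -6 -1 -2 -2 -5 -4  4 -6 -3 -3 -2  8 -3 -3 -5 -3
V  0 -3 -3 -3 -3 -3 -3 -2 -3  3  1 -4  1 -3 -2 -2  0 -8 -3  5 -3 -3 -1
B  0 -2  3  4 -6  0  3  0  1 -3 -4  0 -4 -5 -2  0  0 -6 -3 -3  4  2 -1
Z -1 -1  0  3 -7  4  4 -2  1 -3 -3 -1 -2 -6 -1 -1 -2 -7 -5 -3  2  4 -1
X -1 -2 -1 -2 -4 -1 -1 -2 -2 -1 -2 -2 -2 -3 -2 -1 -1 -5 -3 -1 -1 -1 -2
"""


def _parse_matrix_text(text: str) -> dict[tuple[str, str], int]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    scores = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for col, val in zip(header, parts[1:]):
            scores[(row, col)] = int(val)
    return scores


@dataclass
class SubstitutionMatrix:
    """Residue substitution scores plus a linear per-position gap penalty."""

    name: str
    scores: dict[tuple[str, str], float]
    gap: float

    def __post_init__(self):
        if self.gap > 0:
            raise ValidationError("gap penalty must be <= 0")
        for a, b in list(self.scores):
            if (b, a) not in self.scores:
                self.scores[(b, a)] = self.scores[(a, b)]

    @property
    def alphabet(self) -> str:
        return "".join(sorted({a for a, _ in self.scores}))

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise ValidationError(
                f"residue pair ({a!r},{b!r}) absent from matrix {self.name}"
            ) from None

    def to_biopython(self):
        alpha = self.alphabet
        arr = substitution_matrices.Array(alphabet=alpha, dims=2)
        for (a, b), v in self.scores.items():
            arr[a, b] = v
        return arr

    @classmethod
    def from_pairs(
        cls, pairs: dict[tuple[str, str], float], gap: float,
        alphabet: str = RESIDUES, default: float = 0.0, name: str = "custom",
    ) -> "SubstitutionMatrix":
        scores = {
            (a, b): default for a in alphabet for b in alphabet
        }
        for (a, b), v in pairs.items():
            scores[(a, b)] = v
            scores[(b, a)] = v
        return cls(name=name, scores=scores, gap=gap)


def load_matrix(name: str, gap: float | None = None) -> SubstitutionMatrix:
    """Load PAM120 or BLOSUM62 (or any biopython-distributed matrix by name)."""
    if gap is None:
        gap = DEFAULT_GAPS.get(name, -8)
    if name == "PAM120":
        scores = {
            k: float(v) for k, v in _parse_matrix_text(_PAM120_TEXT).items()
        }
        return SubstitutionMatrix(name=name, scores=scores, gap=gap)
    arr = substitution_matrices.load(name)
    scores = {}
    for a in arr.alphabet:
        for b in arr.alphabet:
            if a != "*" and b != "*":
                scores[(a, b)] = float(arr[a, b])
    return SubstitutionMatrix(name=name, scores=scores, gap=gap)


def global_align_score(a: str, b: str, m: SubstitutionMatrix) -> float:
    """Optimal Needleman-Wunsch score of two sequences under a linear gap model."""
    if not a or not b:
        raise ValidationError("sequences must be non-empty")
    alpha = set(m.alphabet)
    for s in (a, b):
        bad = set(s) - alpha
        if bad:
            raise ValidationError(
                f"residue(s) {sorted(bad)} absent from matrix {m.name}"
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m.to_biopython()
    aligner.open_gap_score = m.gap
    aligner.extend_gap_score = m.gap
    return float(aligner.score(a, b))


# ---------------------------------------------------------------------------
# MSA, conserved columns and frames


class MSA:
    """A multiple sequence alignment: equal-length rows over residues and '-'."""

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise ValidationError("MSA ids/rows length mismatch")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate MSA ids")
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise ValidationError("MSA rows have unequal lengths")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def row_index(self, seq_id: str) -> int:
        return self._index[seq_id]

    @classmethod
    def read_fasta(cls, path) -> "MSA":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


def conserved_columns(
    msa: MSA, min_count: int | None = None, min_fraction: float = 100 / 113
) -> list[int]:
    """Columns where a single residue (gaps excluded) occurs in more than
    ``min_count`` rows (strict inequality).

    Without an explicit ``min_count`` the threshold generalizes the
    113-kinase rule "more than 100 of 113" to a fraction of the MSA depth.
    """
    if min_count is None:
        min_count = min_fraction * msa.depth
    elif not (1 <= min_count <= msa.depth):
        raise ValidationError("min_count must be within [1, depth]")
    out = []
    for c in range(msa.width):
        counts: dict[str, int] = {}
        for row in msa.rows:
            res = row[c]
            if res != "-":
                counts[res] = counts.get(res, 0) + 1
        if counts and max(counts.values()) > min_count:
            out.append(c)
    return out


@dataclass
class Frame:
    """A conserved stretch of the MSA around active-site positions."""

    start: int  # inclusive
    end: int    # inclusive
    conserved_columns: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("frame start > end")

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)


def extract_frames(
    msa: MSA,
    conserved: list[int],
    active_columns: list[int],
    flank: int = 5,
) -> list[Frame]:
    """Build frames: a +-``flank`` window around each conserved active-site
    column, clipped to the MSA, with overlapping/adjacent windows merged."""
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    anchors = sorted(set(conserved) & set(active_columns))
    if not anchors:
        return []
    width = msa.width
    intervals = [
        (max(0, c - flank), min(width - 1, c + flank), c) for c in anchors
    ]
    frames: list[Frame] = []
    cur_s, cur_e, cur_cols = intervals[0][0], intervals[0][1], [intervals[0][2]]
    for s, e, c in intervals[1:]:
        if s <= cur_e + 1:  # overlapping or adjacent
            cur_e = max(cur_e, e)
            cur_cols.append(c)
        else:
            frames.append(Frame(cur_s, cur_e, cur_cols))
            cur_s, cur_e, cur_cols = s, e, [c]
    frames.append(Frame(cur_s, cur_e, cur_cols))
    return frames


def frame_pair_score(
    msa: MSA,
    frames: list[Frame],
    i: str,
    j: str,
    m: SubstitutionMatrix,
    realign: bool = False,
) -> float:
    """Total conserved-region similarity of two kinases.

    ``realign=False``: score each frame column-wise straight from the MSA; a
    position where exactly one row has a gap incurs the gap penalty, gap-gap
    positions score 0.  ``realign=True``: strip gaps from each cut-out frame
    substring and score the optimal global alignment of the two substrings.
    """
    row_i = msa.row(i)
    row_j = msa.row(j)
    total = 0.0
    for frame in frames:
        if realign:
            sub_i = row_i[frame.start : frame.end + 1].replace("-", "")
            sub_j = row_j[frame.start : frame.end + 1].replace("-", "")
            if not sub_i and not sub_j:
                continue
            if not sub_i or not sub_j:
                total += m.gap * max(len(sub_i), len(sub_j))
                continue
            total += global_align_score(sub_i, sub_j, m)
        else:
            for c in frame.columns:
                a, b = row_i[c], row_j[c]
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total += m.gap
                else:
                    total += m.score(a, b)
    return total


def score_vector_features(
    records: list[KinaseRecord],
    mode: str,
    matrix: SubstitutionMatrix,
    msa: MSA | None = None,
    frames: list[Frame] | None = None,
    realign: bool = False,
) -> FeatureTable:
    """Per-kinase alignment-score vectors, one numeric column per reference kinase.

    ``mode='glAli'`` scores full sequences with Needleman-Wunsch;
    ``mode='locAli'`` sums conserved-frame scores (optionally realigned).
    Both produce an m x m table; symmetric matrices give symmetric tables.
    """
    if mode not in ("glAli", "locAli"):
        raise ValidationError(f"unknown alignment feature mode {mode!r}")
    ids = [r.id for r in records]
    n = len(ids)
    scores = np.zeros((n, n))
    if mode == "glAli":
        for a in range(n):
            for b in range(a, n):
                s = global_align_score(
                    records[a].sequence, records[b].sequence, matrix
                )
                scores[a, b] = scores[b, a] = s
    else:
        if msa is None or frames is None:
            raise ValidationError("locAli mode needs an MSA and frames")
        for a in range(n):
            for b in range(a, n):
                s = frame_pair_score(msa, frames, ids[a], ids[b], matrix, realign)
                scores[a, b] = scores[b, a] = s
    cols = [FeatureColumn(f"{mode}_{rid}", "numeric", mode) for rid in ids]
    return FeatureTable(ids, cols, scores)
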