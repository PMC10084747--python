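"""Global pairwise alignment (Needleman–Wunsch with affine gaps, Gotoh
recurrences) and a progressive multiple aligner guided by a neighbor-joining
tree, plus import/export of aligned FASTA.

Scoring conventions
-------------------
Substitution scores come from the Biopython substitution-matrix collection
(default BLOSUM62).  Selenocysteine ``U`` is *scored* as Cys — BLOSUM has no
selenocysteine column and in Gpx families U occupies the Cys column — but the
letter itself is preserved verbatim in all output.  ``X`` scores 0 against
everything.  A gap run of length ``k`` costs ``gap_open + (k - 1) *
gap_extend``.  Traceback is deterministic with preference diagonal > up >
left (match state > gap-in-second > gap-in-first).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from numba import njit

from .records import GAP, ProteinRecord, check_unique_ids

#: Internal scoring alphabet: 20 canonical residues + U (selenocysteine) + X.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYUX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class AlignmentError(ValueError):
    pass


@functools.lru_cache(maxsize=8)
def load_matrix(name: str = "blosum62") -> np.ndarray:
    """Return a 22x22 score matrix over :data:`ALPHABET`.

    ``U`` inherits the Cys row/column; ``X`` scores 0 against everything
    (including itself).  Unknown matrix names raise ``AlignmentError``.
    """
    try:
        mat = substitution_matrices.load(name.upper())
    except Exception as exc:  # biopython raises FileNotFoundError on bad names
        raise AlignmentError(f"unknown substitution matrix {name!r}") from exc
    S = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                S[i, j] = 0.0
            else:
                aa = "C" if a == "U" else a
                bb = "C" if b == "U" else b
                S[i, j] = float(mat[aa, bb])
    return S


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as indices into :data:`ALPHABET`.

    Letters outside the alphabet (rare ambiguity codes) are treated as ``X``.
    """
    x = _INDEX["X"]
    return np.fromiter(
        (_INDEX.get(c, x) for c in sequence), dtype=np.int64, count=len(sequence)
    )


# DP states: 0 = M (diagonal), 1 = Ix (up, gap in b), 2 = Iy (left, gap in a).
@njit(cache=True)
def _affine_dp(C, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    n, m = C.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = M[i - 1, j - 1]
            if X[i - 1, j - 1] > d:
                d = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > d:
                d = Y[i - 1, j - 1]
            M[i, j] = d + C[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - gap_open,
                          max(X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open))
            Y[i, j] = max(M[i, j - 1] - gap_open,
                          max(X[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend))
    # terminal state, preference M > X > Y
    tol = 1e-9
    best = max(M[n, m], max(X[n, m], Y[n, m]))
    if M[n, m] >= best - tol:
        state = 0
    elif X[n, m] >= best - tol:
        state = 1
    else:
        state = 2
    # traceback
    ai = np.empty(n + m, dtype=np.int64)
    bi = np.empty(n + m, dtype=np.int64)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ai[k] = i - 1
            bi[k] = j - 1
            target = M[i, j] - C[i - 1, j - 1]
            if M[i - 1, j - 1] >= target - tol:
                state = 0
            elif X[i - 1, j - 1] >= target - tol:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            ai[k] = i - 1
            bi[k] = -1
            if j == 0:
                # leading gap column: stay in X until exhausted
                state = 1
            elif M[i - 1, j] - gap_open >= X[i, j] - tol:
                state = 0
            elif X[i - 1, j] - gap_extend >= X[i, j] - tol:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            ai[k] = -1
            bi[k] = j - 1
            if i == 0:
                state = 2
            elif M[i, j - 1] - gap_open >= Y[i, j] - tol:
                state = 0
            elif X[i, j - 1] - gap_open >= Y[i, j] - tol:
                state = 1
            else:
                state = 2
            j -= 1
    return best, ai[k:], bi[k:]


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    matrix_name: str = "blosum62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.aligned_a, self.aligned_b)):
            raise AlignmentError("column with gaps in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def identity(self) -> float:
        """Fractional identity: matches / columns (dual-gap columns cannot occur)."""
        cols = self.n_columns
        if cols == 0:
            return 0.0
        matches = sum(
            a == b and a != GAP for a, b in zip(self.aligned_a, self.aligned_b)
        )
        return matches / cols


def global_align(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix: str = "blosum62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (Gotoh, affine gaps).

    Deterministic: ties in the traceback are broken diagonal > up > left.
    """
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise AlignmentError("sequences must be non-empty")
    if gap_open < 0 or gap_extend < 0:
        raise AlignmentError("gap penalties must be >= 0")
    S = load_matrix(matrix)
    ea, eb = encode(sa), encode(sb)
    C = S[np.ix_(ea, eb)]
    score, ai, bi = _affine_dp(C, float(gap_open), float(gap_extend))
    row_a = "".join(sa[i] if i >= 0 else GAP for i in ai)
    row_b = "".join(sb[j] if j >= 0 else GAP for j in bi)
    return PairwiseAlignment(row_a, row_b, float(score), matrix, gap_open, gap_extend)


def percent_similarity(aln: PairwiseAlignment, mode: str = "similarity") -> float:
    """Percentage of positively scoring (or identical) ungapped columns.

    Denominator is the number of columns without a gap in either row; an
    alignment with no such columns scores 0.
    """
    if mode not in ("similarity", "identity"):
        raise ValueError(f"unknown mode {mode!r}")
    S = load_matrix(aln.matrix_name)
    total = 0
    hits = 0
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if a == GAP or b == GAP:
            continue
        total += 1
        if mode == "identity":
            hits += a == b
        else:
            hits += S[_INDEX.get(a, _INDEX["X"]), _INDEX.get(b, _INDEX["X"])] > 0
    if total == 0:
        return 0.0
    return 100.0 * hits / total


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered id -> gapped row."""

    ids: List[str]
    rows: Dict[str, str]

    def __post_init__(self) -> None:
        if set(self.ids) != set(self.rows):
            raise AlignmentError("ids and rows disagree")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            ragged = [i for i in self.ids if len(self.rows[i]) != len(self.rows[self.ids[0]])]
            raise AlignmentError(f"ragged alignment rows: {ragged}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    def row(self, seq_id: str) -> str:
        return self.rows[seq_id]

    def degap(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def column(self, col: int) -> str:
        """1-based column as a string in row order."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        return "".join(self.rows[i][col - 1] for i in self.ids)

    def matrix(self) -> np.ndarray:
        """Rows as a (n_rows, n_columns) array of single characters."""
        return np.array([list(self.rows[i]) for i in self.ids])

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        """New alignment keeping the given 1-based columns, in the given order."""
        idx = [c - 1 for c in cols]
        return Alignment(
            list(self.ids),
            {i: "".join(self.rows[i][c] for c in idx) for i in self.ids},
        )


def import_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; ``.`` and ``-`` both read as gaps."""
    ids: List[str] = []
    rows: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in rows:
            raise AlignmentError(f"duplicate id {rid!r} in {path}")
        ids.append(rid)
        rows[rid] = str(rec.seq).upper().replace(".", GAP)
    if not ids:
        raise AlignmentError(f"no records in {path}")
    return Alignment(ids, rows)


def export_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in aln.ids:
            fh.write(f">{rid}\n{aln.rows[rid]}\n")


def trim_terminal_gap_columns(aln: Alignment, max_gap_fraction: float = 0.8) -> Alignment:
    """Trim runs of heavily gapped columns from both alignment ends.

    Emulates removal of divergent, poorly aligned termini: leading and
    trailing columns whose gap fraction exceeds ``max_gap_fraction`` are
    dropped until the first/last dense column.
    """
    n = aln.n_columns
    gap_frac = [
        sum(aln.rows[i][c] == GAP for i in aln.ids) / aln.n_rows for c in range(n)
    ]
    lo = 0
    while lo < n and gap_frac[lo] > max_gap_fraction:
        lo += 1
    hi = n
    while hi > lo and gap_frac[hi - 1] > max_gap_fraction:
        hi -= 1
    return aln.subset_columns(range(lo + 1, hi + 1))


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile(rows: List[str], S: np.ndarray) -> np.ndarray:
    """Column frequency profile (n_cols x alphabet); gaps contribute nothing."""
    n_cols = len(rows[0])
    F = np.zeros((n_cols, len(ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                F[c, _INDEX.get(ch, _INDEX["X"])] += 1
    return F / len(rows)


def _merge(
    block_a: Tuple[List[str], List[str]],
    block_b: Tuple[List[str], List[str]],
    S: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> Tuple[List[str], List[str]]:
    """Profile–profile alignment of two aligned blocks ("once a gap, always a gap")."""
    ids_a, rows_a = block_a
    ids_b, rows_b = block_b
    FA = _profile(rows_a, S)
    FB = _profile(rows_b, S)
    C = FA @ S @ FB.T
    _, ai, bi = _affine_dp(C, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in zip(ai, bi):
        for k, row in enumerate(rows_a):
            out_a[k] += row[i] if i >= 0 else GAP
        for k, row in enumerate(rows_b):
            out_b[k] += row[j] if j >= 0 else GAP
    return ids_a + ids_b, out_a + out_b


def progressive_msa(
    records: Sequence[ProteinRecord],
    matrix: str = "blosum62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Progressive multiple alignment along a neighbor-joining guide tree.

    Guide-tree distances are ``1 - fractional identity`` from optimal global
    pairwise alignments.  Profiles are merged leaves-inward with plain affine
    gap penalties; established gaps are never removed.  Row order equals
    input order.
    """
    from .phylogeny import neighbor_joining  # local import avoids a cycle
    from skbio import DistanceMatrix

    records = list(records)
    check_unique_ids(records)
    if len(records) < 2:
        raise AlignmentError("progressive_msa needs at least 2 records")
    if len(records) == 2:
        pw = global_align(records[0], records[1], matrix, gap_open, gap_extend)
        return Alignment(
            [records[0].id, records[1].id],
            {records[0].id: pw.aligned_a, records[1].id: pw.aligned_b},
        )
    S = load_matrix(matrix)
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pw = global_align(records[i], records[j], matrix, gap_open, gap_extend)
            D[i, j] = D[j, i] = 1.0 - pw.identity()
    ids = [r.id for r in records]
    tree = neighbor_joining(DistanceMatrix(D, ids))
    by_id = {r.id: r for r in records}

    def build(node) -> Tuple[List[str], List[str]]:
        if node.is_tip():
            return [node.name], [by_id[node.name].sequence]
        blocks = [build(ch) for ch in node.children]
        acc = blocks[0]
        for blk in blocks[1:]:
            acc = _merge(acc, blk, S, gap_open, gap_extend)
        return acc

    out_ids, out_rows = build(tree)
    rows = dict(zip(out_ids, out_rows))
    return Alignment(ids, {i: rows[i] for i in ids})
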