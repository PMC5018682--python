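"""Pairwise and progressive multiple protein alignment with affine gaps.

Global (Needleman-Wunsch/Gotoh) pairwise alignment under BLOSUM62, a
progressive multiple aligner (guide tree by neighbor joining on pairwise
alignment-identity distances, then profile-profile merging), and a
gap-fraction column filter for removing unreliable alignment columns.

Conventions: a gap run of length L costs ``gap_open + L * gap_extend``;
terminal gaps are penalized like internal ones. Profile columns score as the
arithmetic mean of pairwise substitution scores with gaps contributing 0.
Once a gap column is inserted into a profile it is never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import FormatError, SeqRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def _load_matrix(name: str) -> np.ndarray:
    """Published substitution matrix as a 21x21 array over AA_ORDER."""
    sub = substitution_matrices.load(name)
    m = np.zeros((len(AA_ORDER), len(AA_ORDER)))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            m[i, j] = sub[a][b]
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both >= 0)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise FormatError("gap penalties must be non-negative")
        self._matrix = _load_matrix(self.matrix_name)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def score(self, a: str, b: str) -> float:
        return float(self._matrix[_AA_INDEX[a], _AA_INDEX[b]])


@dataclass
class Alignment:
    """A gapped alignment: equal-length rows over residues + '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.rows = tuple(self.rows)
        if len(self.ids) != len(self.rows):
            raise FormatError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError("alignment rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


# ---------------------------------------------------------------------------
# Gotoh dynamic programming on column-score matrices
# ---------------------------------------------------------------------------

_M, _X, _Y = 0, 1, 2  # states: match column, gap-in-B (consume A), gap-in-A (consume B)
_NEG = -1e30


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float) -> tuple[float, list[str]]:
    """Optimal global alignment over a column-score matrix.

    Returns (score, ops) where ops is a list over alignment columns:
    'M' consumes one column of each side, 'X' consumes A only (gap in B),
    'Y' consumes B only (gap in A). Ties prefer M, then Y (gap in A), then X.
    """
    n, m = S.shape
    go, ge = gap_open, gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
        ptr[_X, i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)
        ptr[_Y, 0, j] = _Y if j > 1 else _M

    for i in range(1, n + 1):
        Si = S[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            # match state: preference M > Y > X on ties
            best, arg = Mp[j - 1], _M
            if Yp[j - 1] > best:
                best, arg = Yp[j - 1], _Y
            if Xp[j - 1] > best:
                best, arg = Xp[j - 1], _X
            Mi[j] = best + Si[j - 1]
            ptr[_M, i, j] = arg
            # gap in B (consume A): come from row i-1, same j
            best, arg = Mp[j] - go - ge, _M
            if Yp[j] - go - ge > best:
                best, arg = Yp[j] - go - ge, _Y
            if Xp[j] - ge > best:
                best, arg = Xp[j] - ge, _X
            Xi[j] = best
            ptr[_X, i, j] = arg
            # gap in A (consume B): come from column j-1, same i
            best, arg = Mi[j - 1] - go - ge, _M
            if Yi[j - 1] - ge > best:
                best, arg = Yi[j - 1] - ge, _Y
            if Xi[j - 1] - go - ge > best:
                best, arg = Xi[j - 1] - go - ge, _X
            Yi[j] = best
            ptr[_Y, i, j] = arg

    finals = (M[n, m], X[n, m], Y[n, m])
    best = max(finals)
    state = next(s for s in (_M, _Y, _X) if finals[s] == best)  # tie pref M > Y > X
    score = finals[state]

    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == _M:
            ops.append("M")
            i, j = i - 1, j - 1
        elif state == _X:
            ops.append("X")
            i -= 1
        else:
            ops.append("Y")
            j -= 1
        state = prev
    ops.reverse()
    return float(score), ops


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue counts (columns x 21); gaps contribute nothing."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(AA_ORDER)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _AA_INDEX[ch]] += 1
    return counts


def _profile_score_matrix(rows_a: Sequence[str], rows_b: Sequence[str],
                          scheme: ScoringScheme) -> np.ndarray:
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    return (ca @ scheme.matrix @ cb.T) / (len(rows_a) * len(rows_b))


def _apply_ops(rows_a: Sequence[str], rows_b: Sequence[str], ops: Sequence[str]) -> tuple[list[str], list[str]]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align_pair(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None,
               return_score: bool = False):
    """Optimal global pairwise alignment of two protein records.

    Tie-breaking is deterministic: match/mismatch preferred over a gap in
    ``a``, which is preferred over a gap in ``b``.
    """
    scheme = scheme or ScoringScheme()
    for rec in (a, b):
        if rec.kind != "protein":
            raise FormatError(f"record {rec.id!r}: pairwise alignment requires proteins")
        if not rec.residues:
            raise FormatError(f"record {rec.id!r}: empty sequence")
    S = _profile_score_matrix([a.residues], [b.residues], scheme)
    score, ops = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    (row_a,), (row_b,) = _apply_ops([a.residues], [b.residues], ops)
    aln = Alignment(ids=(a.id, b.id), rows=(row_a, row_b))
    return (aln, score) if return_score else aln


def align_score(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None) -> float:
    return align_pair(a, b, scheme, return_score=True)[1]


def _nj_merge_order(labels: list[str], dist: np.ndarray) -> list[tuple[frozenset, frozenset]]:
    """Neighbor-joining agglomeration schedule (Saitou-Nei Q criterion).

    Returns the ordered list of cluster pairs joined, clusters identified by
    frozensets of member labels. Ties break lexicographically on the sorted
    member labels so the schedule is deterministic.
    """
    clusters = [frozenset([lab]) for lab in labels]
    d = dist.astype(float).copy()
    order: list[tuple[frozenset, frozenset]] = []
    while len(clusters) > 2:
        n = len(clusters)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted(clusters[i]))[0], tuple(sorted(clusters[j]))[0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        order.append((clusters[i], clusters[j]))
        new = clusters[i] | clusters[j]
        keep = [k for k in range(n) if k not in (i, j)]
        dn = np.zeros(len(keep))
        for t, k in enumerate(keep):
            dn[t] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dn[:, None]]),
                       np.hstack([dn, [0.0]])])
        clusters = [clusters[k] for k in keep] + [new]
    if len(clusters) == 2:
        order.append((clusters[0], clusters[1]))
    return order


def align_progressive(seqs: Sequence[SeqRecord], scheme: ScoringScheme | None = None) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on ``100 - pairwise alignment identity``
    (shorter-sequence denominator); profiles are merged in join order with
    the same affine-gap DP used for pairs.
    """
    from .similarity_metrics import pairwise_identity  # local import: avoid cycle

    scheme = scheme or ScoringScheme()
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate ids in progressive alignment input")
    if len(seqs) < 2:
        raise FormatError("progressive alignment needs at least 2 sequences")
    if len(seqs) == 2:
        return align_pair(seqs[0], seqs[1], scheme)

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(seqs[i], seqs[j], scheme)
            pid = pairwise_identity(aln, ids[i], ids[j], denominator="shorter")
            dist[i, j] = dist[j, i] = 100.0 - pid

    order = _nj_merge_order(ids, dist)
    profiles: dict[frozenset, tuple[list[str], list[str]]] = {
        frozenset([s.id]): ([s.id], [s.residues]) for s in seqs
    }
    for ca, cb in order:
        ids_a, rows_a = profiles.pop(ca)
        ids_b, rows_b = profiles.pop(cb)
        S = _profile_score_matrix(rows_a, rows_b, scheme)
        _, ops = _gotoh(S, scheme.gap_open, scheme.gap_extend)
        new_a, new_b = _apply_ops(rows_a, rows_b, ops)
        profiles[ca | cb] = (ids_a + ids_b, new_a + new_b)

    (_, (final_ids, final_rows)), = profiles.items()
    by_id = dict(zip(final_ids, final_rows))
    return Alignment(ids=tuple(ids), rows=tuple(by_id[i] for i in ids))


def filter_columns(aln: Alignment, max_gap_fraction: float) -> tuple[Alignment, list[int]]:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    All-gap columns are always dropped. Returns the filtered alignment and
    the mapping from new to old (0-based) column indices. Raises
    :class:`FormatError` if nothing survives.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise FormatError("max_gap_fraction must be within [0, 1]")
    nrow = len(aln.rows)
    keep: list[int] = []
    for j in range(aln.column_count):
        gaps = sum(1 for r in aln.rows if r[j] == "-")
        frac = gaps / nrow
        if frac <= max_gap_fraction and gaps < nrow:
            keep.append(j)
    if not keep:
        raise FormatError("column filtering removed every column")
    rows = tuple("".join(r[j] for j in keep) for r in aln.rows)
    return Alignment(ids=aln.ids, rows=rows), keep


# ---------------------------------------------------------------------------
# Aligned-FASTA IO
# ---------------------------------------------------------------------------

def write_alignment_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(aln.ids, aln.rows):
            fh.write(f">{seq_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        cur: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if ids:
                    rows.append("".join(cur))
                ids.append(line[1:].split()[0])
                cur = []
            elif line:
                cur.append(line.upper())
        if ids:
            rows.append("".join(cur))
    if not ids:
        raise FormatError(f"{path}: no aligned records found")
    return Alignment(ids=tuple(ids), rows=tuple(rows))
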