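"""Pairwise identity, group-based similarity, and normalized similarity.

Implements the SIAS-style percentage metrics over a shared multiple
alignment: identity counts columns with the same residue in both rows;
similarity additionally counts residues from the same physicochemical
equivalence group; the normalized score divides the summed BLOSUM62 score by
the smaller of the two self-scores so that self-comparison is exactly 1.

The denominator for the percentage metrics is configurable (the web tools in
this area offer several conventions); the default is the length of the
shorter ungapped sequence, which keeps self-identity at 100% regardless of
alignment gaps. Gapped columns never count as identical or similar, and an
``X`` (unknown residue) matches nothing, not even another ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import FormatError, PairMatrix, SeqRecord
from .msa_engine import Alignment, ScoringScheme

# The six equivalence groups used for the comparative study: positively
# charged, negatively charged, aliphatic, aromatic, polar amides, small.
SIAS_DEFAULT_GROUPS = (
    frozenset("RKH"),
    frozenset("DE"),
    frozenset("VIL"),
    frozenset("FYW"),
    frozenset("NQ"),
    frozenset("ATS"),
)

DENOMINATORS = ("shorter", "longer", "mean", "alignment_length")


@dataclass(frozen=True)
class EquivalenceScheme:
    """Named partition of residues into similarity groups (pairwise disjoint)."""

    name: str = "sias_default"
    groups: tuple[frozenset, ...] = SIAS_DEFAULT_GROUPS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for aa in g:
                if aa not in "ACDEFGHIKLMNPQRSTVWY":
                    raise FormatError(f"equivalence group contains non-standard residue {aa!r}")
                if aa in seen:
                    raise FormatError(f"residue {aa!r} appears in more than one group")
                seen.add(aa)
        object.__setattr__(self, "_group_of", {aa: i for i, g in enumerate(self.groups) for aa in g})

    def similar(self, a: str, b: str) -> bool:
        """Identical (X excluded) or members of the same group."""
        if a == "X" or b == "X":
            return False
        if a == b:
            return True
        ga = self._group_of.get(a)
        return ga is not None and ga == self._group_of.get(b)


def _pair_columns(aln: Alignment, i: str, j: str,
                  regions: dict[str, tuple[int, int]] | None = None):
    """Yield (residue_i, residue_j) for columns where both rows are in play.

    ``regions`` optionally restricts each row to a 0-based half-open interval
    of its own ungapped sequence. Yields '-' for a gap so callers can apply
    their own gap policy; columns where both rows are gaps (or out of region)
    are dropped entirely.
    """
    row_i, row_j = aln.row(i), aln.row(j)
    pos_i = pos_j = 0
    for a, b in zip(row_i, row_j):
        in_i = a != "-"
        in_j = b != "-"
        if regions is not None:
            if in_i:
                lo, hi = regions[i]
                in_i = lo <= pos_i < hi
            if in_j:
                lo, hi = regions[j]
                in_j = lo <= pos_j < hi
        if in_i or in_j:
            yield (a if in_i else "-", b if in_j else "-")
        if a != "-":
            pos_i += 1
        if b != "-":
            pos_j += 1


def _denominator(aln: Alignment, i: str, j: str, convention: str,
                 regions: dict[str, tuple[int, int]] | None = None) -> float:
    if convention not in DENOMINATORS:
        raise FormatError(f"unknown denominator convention {convention!r}")
    cols = list(_pair_columns(aln, i, j, regions))
    len_i = sum(1 for a, _ in cols if a != "-")
    len_j = sum(1 for _, b in cols if b != "-")
    if convention == "shorter":
        d = min(len_i, len_j)
    elif convention == "longer":
        d = max(len_i, len_j)
    elif convention == "mean":
        d = (len_i + len_j) / 2.0
    else:
        d = len(cols)
    if d == 0:
        raise FormatError(f"zero denominator for pair ({i!r}, {j!r})")
    return float(d)


def pairwise_identity(aln: Alignment, i: str, j: str, denominator: str = "shorter",
                      regions: dict[str, tuple[int, int]] | None = None) -> float:
    """Percentage of columns carrying the identical residue in both rows."""
    matches = sum(1 for a, b in _pair_columns(aln, i, j, regions)
                  if a != "-" and a == b and a != "X")
    return 100.0 * matches / _denominator(aln, i, j, denominator, regions)


def pairwise_similarity(aln: Alignment, i: str, j: str,
                        scheme: EquivalenceScheme | None = None,
                        denominator: str = "shorter",
                        regions: dict[str, tuple[int, int]] | None = None) -> float:
    """Percentage of columns identical or equivalent under the group scheme."""
    scheme = scheme or EquivalenceScheme()
    matches = sum(1 for a, b in _pair_columns(aln, i, j, regions)
                  if a != "-" and b != "-" and scheme.similar(a, b))
    return 100.0 * matches / _denominator(aln, i, j, denominator, regions)


def normalized_similarity(aln: Alignment, i: str, j: str,
                          scoring: ScoringScheme | None = None) -> float:
    """BLOSUM62-normalized similarity: S(i,j) / min(S(i,i), S(j,j)).

    S sums substitution-matrix values over columns where both rows carry a
    residue; self-scores sum the diagonal over each full ungapped sequence,
    so any row against itself scores exactly 1.0.
    """
    scoring = scoring or ScoringScheme()
    cross = sum(scoring.score(a, b) for a, b in _pair_columns(aln, i, j)
                if a != "-" and b != "-")
    self_i = sum(scoring.score(a, a) for a in aln.ungapped(i))
    self_j = sum(scoring.score(b, b) for b in aln.ungapped(j))
    denom = min(self_i, self_j)
    if denom <= 0:
        raise FormatError(f"non-positive self-score for pair ({i!r}, {j!r})")
    return cross / denom


def build_matrix(seqs_or_aln, metric: str = "identity",
                 scheme: EquivalenceScheme | None = None,
                 scoring: ScoringScheme | None = None,
                 denominator: str = "shorter",
                 regions: dict[str, tuple[int, int]] | None = None) -> PairMatrix:
    """Full symmetric pair matrix over a sequence set or existing alignment.

    Unaligned input is first put through one shared progressive multiple
    alignment (all pairs are then read off the same alignment). ``regions``
    restricts the computation to a per-sequence sub-region, e.g. for
    comparing N-terminal tails only.
    """
    from .msa_engine import align_progressive

    if isinstance(seqs_or_aln, Alignment):
        aln = seqs_or_aln
    else:
        seqs = list(seqs_or_aln)
        if len(seqs) < 2:
            raise FormatError("need at least 2 sequences to build a matrix")
        aln = align_progressive(seqs, scoring or ScoringScheme())
    ids = aln.ids
    n = len(ids)
    values = np.zeros((n, n))
    for a in range(n):
        values[a, a] = 1.0 if metric == "normalized_score" else 100.0
        for b in range(a + 1, n):
            if metric == "identity":
                v = pairwise_identity(aln, ids[a], ids[b], denominator, regions)
            elif metric == "similarity":
                v = pairwise_similarity(aln, ids[a], ids[b], scheme, denominator, regions)
            elif metric == "normalized_score":
                v = normalized_similarity(aln, ids[a], ids[b], scoring)
            else:
                raise FormatError(f"unknown matrix metric {metric!r}")
            values[a, b] = values[b, a] = v
    return PairMatrix(labels=ids, values=values, metric=metric)
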