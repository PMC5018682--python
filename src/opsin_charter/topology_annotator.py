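"""Hydropathy-based transmembrane topology prediction for opsins.

A Kyte-Doolittle sliding-window profile drives a segment caller (threshold,
minimum length, short-gap merging, and splitting of over-long runs at their
interior hydropathy minimum). Regions are labeled under the rhodopsin
convention of an extracellular N-terminus, giving the canonical 15-region
order N_tail, TM1, CL1, TM2, EL1, TM3, CL2, TM4, EL2, TM5, CL3, TM6, EL3,
TM7, C_tail when exactly seven membrane segments are found. Any other
membrane-segment count yields generic loop labels plus a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import FormatError, SeqRecord

# Kyte-Doolittle hydropathy scale (X treated as neutral 0).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

CANONICAL_LOOP_LABELS = ("CL1", "EL1", "CL2", "EL2", "CL3", "EL3")


@dataclass
class TopologyMap:
    """Per-residue region labels for one protein.

    ``segments`` tiles [0, length) with (label, (start, end)) entries in
    sequence order; ``tm_count`` is the number of TM segments; ``warning``
    is set when the membrane-segment count is not seven (loops then carry
    generic ``loop_k`` labels).
    """

    seq_id: str
    length: int
    segments: tuple[tuple[str, tuple[int, int]], ...]
    tm_count: int
    warning: bool = False

    def __post_init__(self) -> None:
        pos = 0
        for label, (start, end) in self.segments:
            if start != pos or end <= start:
                raise FormatError(f"{self.seq_id}: segments do not tile the sequence")
            pos = end
        if pos != self.length:
            raise FormatError(f"{self.seq_id}: segments do not cover the sequence")

    def region(self, label: str) -> tuple[int, int] | None:
        for lab, iv in self.segments:
            if lab == label:
                return iv
        return None

    def label_at(self, pos: int) -> str:
        for lab, (start, end) in self.segments:
            if start <= pos < end:
                return lab
        raise FormatError(f"{self.seq_id}: position {pos} outside sequence")


@dataclass
class TailStats:
    n_tail_length: int
    c_tail_length: int
    n_tail_asn_count: int
    c_tail_ser_thr_count: int


def hydropathy_profile(seq: SeqRecord | str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle value over a centered window, one score per residue.

    Terminal residues use truncated windows so every residue gets a score.
    Window must be odd and no longer than the sequence.
    """
    residues = seq.residues if isinstance(seq, SeqRecord) else seq
    n = len(residues)
    if window % 2 == 0:
        raise FormatError("hydropathy window must be odd")
    if not (3 <= window <= n):
        raise FormatError(f"window {window} outside [3, sequence length {n}]")
    vals = np.array([KYTE_DOOLITTLE[c] for c in residues])
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def call_tm_segments(profile: np.ndarray, threshold: float = 1.6,
                     min_len: int = 15, merge_gap: int = 3,
                     max_len: int = 35) -> list[tuple[int, int]]:
    """Membrane segments from a hydropathy profile.

    Maximal runs of scores >= threshold; runs separated by <= merge_gap
    positions are merged; runs longer than max_len are split at their
    interior minimum; runs shorter than min_len are discarded.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise FormatError("empty hydropathy profile")
    above = profile >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(profile)])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    def split_long(start: int, end: int) -> list[tuple[int, int]]:
        if end - start <= max_len:
            return [(start, end)]
        interior = profile[start + 1:end - 1]
        cut = start + 1 + int(np.argmin(interior))
        return split_long(start, cut) + split_long(cut + 1, end)

    final: list[tuple[int, int]] = []
    for start, end in merged:
        final.extend(split_long(start, end))
    return [(s, e) for s, e in final if e - s >= min_len]


def build_topology(seq: SeqRecord, window: int = 19, threshold: float = 1.6,
                   min_len: int = 15, merge_gap: int = 3,
                   max_len: int = 35) -> TopologyMap:
    """Full region labeling assuming an extracellular N-terminus.

    With exactly seven TM segments the loops get their canonical
    cytoplasmic/extracellular labels; otherwise generic ``loop_k`` labels are
    used and the warning flag is set.
    """
    if seq.kind != "protein":
        raise FormatError(f"record {seq.id!r}: topology requires a protein")
    profile = hydropathy_profile(seq, window)
    tms = call_tm_segments(profile, threshold, min_len, merge_gap, max_len)
    n = len(seq.residues)
    segments: list[tuple[str, tuple[int, int]]] = []
    if not tms:
        return TopologyMap(seq_id=seq.id, length=n,
                           segments=(("N_tail", (0, n)),), tm_count=0, warning=True)
    canonical = len(tms) == 7
    pos = 0
    for k, (start, end) in enumerate(tms):
        if start > pos:
            if k == 0:
                label = "N_tail"
            elif canonical:
                label = CANONICAL_LOOP_LABELS[k - 1]
            else:
                label = f"loop_{k}"
            segments.append((label, (pos, start)))
        elif k == 0:
            # TM1 starts at residue 0: record an empty-N convention is not
            # allowed (segments must tile), so treat as zero-length N-tail
            # by simply starting with TM1.
            pass
        segments.append((f"TM{k + 1}", (start, end)))
        pos = end
    if pos < n:
        segments.append(("C_tail", (pos, n)))
    return TopologyMap(seq_id=seq.id, length=n, segments=tuple(segments),
                       tm_count=len(tms), warning=not canonical)


def tail_stats(topo: TopologyMap, seq: SeqRecord) -> TailStats:
    """Tail lengths plus N-tail asparagine and C-tail serine/threonine counts."""
    if topo.length != len(seq.residues):
        raise FormatError(f"{seq.id!r}: topology/sequence length mismatch")
    n_iv = topo.region("N_tail")
    c_iv = topo.region("C_tail")
    n_seq = seq.residues[n_iv[0]:n_iv[1]] if n_iv else ""
    c_seq = seq.residues[c_iv[0]:c_iv[1]] if c_iv else ""
    return TailStats(
        n_tail_length=len(n_seq),
        c_tail_length=len(c_seq),
        n_tail_asn_count=n_seq.count("N"),
        c_tail_ser_thr_count=c_seq.count("S") + c_seq.count("T"),
    )
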