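"""Rhodopsin hallmark detection and the comparative feature report.

Detects, per protein, the features that distinguish a functional rhodopsin:
seven membrane segments, the chromophore-binding (Schiff base) lysine in
TM7, the LRTPXN motif in the first cytoplasmic loop, the DRY motif in the
second, the G-protein-contact QAKK motif in the third, the disulfide
cysteine pair in the second and third extracellular loops, and the spectral
tuning residue near the first cysteine of that pair (tyrosine = visible
light, phenylalanine = UV).

The functional verdict requires 7 TMs + Schiff lysine + LRTPXN + DRY +
cysteine pair; QAKK is reported separately and deliberately excluded from
the verdict, since functional rhodopsins lacking it are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_io import FormatError, SeqRecord
from .topology_annotator import TailStats, TopologyMap, build_topology, tail_stats

_TOPO_LABELS = {"N_tail", "C_tail"} | {f"TM{i}" for i in range(1, 8)} \
    | {f"CL{i}" for i in range(1, 4)} | {f"EL{i}" for i in range(1, 4)}


@dataclass(frozen=True)
class MotifPattern:
    """Residue pattern with X wildcard, valid only inside given regions.

    ``immutable`` lists 0-based pattern positions that may never mismatch
    when a mismatch budget is allowed.
    """

    name: str
    pattern: str
    regions: tuple[str, ...]
    max_mismatches: int = 0
    immutable: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern:
            raise FormatError(f"motif {self.name!r}: empty pattern")
        for lab in self.regions:
            if lab not in _TOPO_LABELS:
                raise FormatError(f"motif {self.name!r}: unknown region label {lab!r}")


# L and N of LRTPXN are necessary for a functional receptor and are never
# allowed to mismatch even under a mismatch budget.
LRTPXN = MotifPattern("LRTPXN", "LRTPXN", ("CL1",), immutable=(0, 5))
DRY = MotifPattern("DRY", "DRY", ("CL2",))
QAKK = MotifPattern("QAKK", "QAKK", ("CL3",))
DEFAULT_MOTIFS = (LRTPXN, DRY, QAKK)


@dataclass
class MotifHit:
    name: str
    start: int          # 0-based
    end: int            # 0-based half-open
    matched: str
    region: str
    mismatches: int = 0

    @property
    def position(self) -> int:
        """1-based start position for reports."""
        return self.start + 1


@dataclass
class HallmarkReport:
    seq_id: str
    has_7tm: bool
    low_confidence: bool
    schiff_lysine_pos: int | None          # 1-based
    schiff_ambiguous: bool
    lrtpxn: MotifHit | None
    dry: MotifHit | None
    qakk: MotifHit | None
    cys_pair: tuple[int, int] | None       # 1-based positions (EL2, EL3)
    cys_multiplicity_flag: bool
    tuning_position: int | None            # 1-based
    tuning_residue: str | None
    tuning_offset: int | None              # -3 or +3 relative to first cysteine
    tuning_in_tm3: bool
    spectral_class: str                    # visible | UV | unknown
    tails: TailStats | None
    verdict_functional: bool


def _region_intervals(topo: TopologyMap, labels: Sequence[str]) -> list[tuple[int, int]]:
    return [iv for lab, iv in topo.segments if lab in labels]


def find_motif(seq: SeqRecord, topo: TopologyMap, pattern: MotifPattern,
               whole_sequence: bool = False) -> MotifHit | None:
    """Leftmost pattern match lying entirely inside a required region.

    X in the pattern matches any residue. With ``whole_sequence`` the region
    gate is bypassed (used when the topology is unreliable).
    """
    residues = seq.residues
    plen = len(pattern.pattern)
    if whole_sequence:
        windows = [(0, len(residues))]
    else:
        windows = _region_intervals(topo, pattern.regions)
        if not windows:
            return None
    for lo, hi in windows:
        for start in range(lo, hi - plen + 1):
            mism = 0
            ok = True
            for k, pc in enumerate(pattern.pattern):
                rc = residues[start + k]
                if pc == "X" or pc == rc:
                    continue
                if k in pattern.immutable or mism >= pattern.max_mismatches:
                    ok = False
                    break
                mism += 1
            if ok:
                region = "whole_sequence" if whole_sequence else topo.label_at(start)
                return MotifHit(name=pattern.name, start=start, end=start + plen,
                                matched=residues[start:start + plen],
                                region=region, mismatches=mism)
    return None


def find_schiff_lysine(seq: SeqRecord, topo: TopologyMap) -> tuple[int | None, bool]:
    """Chromophore-binding lysine in TM7, as (1-based position, ambiguity flag).

    Exactly one K in TM7 -> that position. Several -> the one nearest the
    TM7 midpoint, flagged ambiguous. None (or no TM7) -> (None, False).
    """
    iv = topo.region("TM7")
    if iv is None:
        return None, False
    lysines = [p for p in range(iv[0], iv[1]) if seq.residues[p] == "K"]
    if not lysines:
        return None, False
    if len(lysines) == 1:
        return lysines[0] + 1, False
    mid = (iv[0] + iv[1] - 1) / 2.0
    best = min(lysines, key=lambda p: (abs(p - mid), p))
    return best + 1, True


def find_cys_pair(seq: SeqRecord, topo: TopologyMap) -> tuple[tuple[int, int] | None, bool]:
    """First cysteine in EL2 and first in EL3 (1-based), plus multiplicity flag."""
    positions = []
    multiple = False
    for label in ("EL2", "EL3"):
        iv = topo.region(label)
        if iv is None:
            return None, False
        cs = [p for p in range(iv[0], iv[1]) if seq.residues[p] == "C"]
        if not cs:
            return None, False
        if len(cs) > 1:
            multiple = True
        positions.append(cs[0] + 1)
    return (positions[0], positions[1]), multiple


def find_tuning_residue(seq: SeqRecord, topo: TopologyMap,
                        cys_pair: tuple[int, int]) -> tuple[int | None, str | None, int | None, bool, str]:
    """Spectral tuning residue three positions from the first cysteine.

    Examines the residues exactly 3 before and 3 after the more N-terminal
    cysteine of the disulfide pair; tyrosine (visible light) takes precedence
    over phenylalanine (UV). Returns (1-based position, residue, offset,
    lies-in-TM3 flag, spectral class).
    """
    first_cys = min(cys_pair) - 1  # back to 0-based
    candidates = []
    for offset in (-3, +3):
        p = first_cys + offset
        if 0 <= p < len(seq.residues):
            candidates.append((offset, p, seq.residues[p]))
    for wanted, klass in (("Y", "visible"), ("F", "UV")):
        for offset, p, res in candidates:
            if res == wanted:
                return p + 1, res, offset, topo.label_at(p) == "TM3", klass
    return None, None, None, False, "unknown"


def annotate(seq: SeqRecord, window: int = 19, threshold: float = 1.6,
             min_len: int = 15, merge_gap: int = 3, max_len: int = 35,
             motifs: Sequence[MotifPattern] = DEFAULT_MOTIFS) -> HallmarkReport:
    """Compose topology prediction with every hallmark finder.

    If the topology does not resolve seven membrane segments, motif searches
    fall back to the whole sequence and the report is flagged low-confidence
    (cysteine-pair and Schiff-lysine calls then stay absent, since their
    regions are undefined).
    """
    topo = build_topology(seq, window, threshold, min_len, merge_gap, max_len)
    has_7tm = topo.tm_count == 7
    low_confidence = not has_7tm

    hits: dict[str, MotifHit | None] = {}
    for pat in motifs:
        hits[pat.name] = find_motif(seq, topo, pat, whole_sequence=low_confidence)

    schiff_pos, schiff_amb = find_schiff_lysine(seq, topo) if has_7tm else (None, False)
    cys, cys_multi = find_cys_pair(seq, topo) if has_7tm else (None, False)
    if cys is not None:
        tun_pos, tun_res, tun_off, in_tm3, klass = find_tuning_residue(seq, topo, cys)
    else:
        tun_pos = tun_res = tun_off = None
        in_tm3, klass = False, "unknown"

    tails = tail_stats(topo, seq) if has_7tm else None
    verdict = bool(has_7tm and schiff_pos and hits.get("LRTPXN")
                   and hits.get("DRY") and cys)
    return HallmarkReport(
        seq_id=seq.id, has_7tm=has_7tm, low_confidence=low_confidence,
        schiff_lysine_pos=schiff_pos, schiff_ambiguous=schiff_amb,
        lrtpxn=hits.get("LRTPXN"), dry=hits.get("DRY"), qakk=hits.get("QAKK"),
        cys_pair=cys, cys_multiplicity_flag=cys_multi,
        tuning_position=tun_pos, tuning_residue=tun_res, tuning_offset=tun_off,
        tuning_in_tm3=in_tm3, spectral_class=klass,
        tails=tails, verdict_functional=verdict,
    )


def feature_table(reports: Sequence[HallmarkReport]) -> "pandas.DataFrame":
    """Cross-sequence feature comparison table (one row per protein)."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "seq_id": r.seq_id,
            "has_7tm": r.has_7tm,
            "schiff_lysine_pos": r.schiff_lysine_pos,
            "lrtpxn": r.lrtpxn is not None,
            "dry": r.dry is not None,
            "qakk": r.qakk is not None,
            "cys_pair": r.cys_pair is not None,
            "spectral_class": r.spectral_class,
            "n_tail_length": r.tails.n_tail_length if r.tails else None,
            "c_tail_length": r.tails.c_tail_length if r.tails else None,
            "verdict_functional": r.verdict_functional,
        })
    return pd.DataFrame(rows)
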