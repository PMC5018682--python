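"""Synthetic opsins, protein families, gene loci and CT tables with ground truth.

Every generator is deterministic for a fixed seed and returns, next to the
record(s), a truth object whose planted elements are verifiable by direct
string inspection — membrane segments drawn from a hydrophobic pool, loops
and tails from a mildly hydrophilic pool, hallmark motifs spliced at recorded
positions, one concrete RCSI instance placed at a configurable locus
position (background screened so no accidental consensus match survives),
and qPCR CT replicates with Gaussian cycle noise around a true ratio.

Pool compositions are chosen so the default hydropathy caller resolves the
planted segments without per-test tuning: the hydrophobic pool averages
about +4.1 on the Kyte-Doolittle scale (strong enough that a membrane
segment carrying the planted chromophore-binding lysine still clears the
calling threshold), the hydrophilic pool about -0.6, placing the default
threshold of 1.6 between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import FormatError, GeneModel, SeqRecord, revcomp
from .expression_qpcr import CtTable
from .rcsi_scanner import RCSI_CONSENSUS, scan

HYDROPHOBIC_POOL = ("IVLFAM", (0.45, 0.30, 0.15, 0.05, 0.025, 0.025))
HYDROPHILIC_POOL = ("STGAPNQDEKR",
                    (0.22, 0.18, 0.18, 0.22, 0.04, 0.04, 0.04, 0.03, 0.03, 0.01, 0.01))

_REGION_ORDER = ("N_tail", "TM1", "CL1", "TM2", "EL1", "TM3", "CL2",
                 "TM4", "EL2", "TM5", "CL3", "TM6", "EL3", "TM7", "C_tail")


def _draw(rng: np.random.Generator, pool, n: int) -> str:
    letters, weights = pool
    return "".join(rng.choice(list(letters), size=n, p=weights))


# ---------------------------------------------------------------------------
# Single synthetic opsin
# ---------------------------------------------------------------------------

@dataclass
class OpsinParams:
    """Region lengths and which hallmarks to plant (ablate by setting False).

    ``tuning`` plants Y (visible), F (UV) or nothing at three positions after
    the EL2 cysteine.
    """

    n_tail_len: int = 50
    c_tail_len: int = 45
    tm_len: int = 23
    loop_lens: tuple[int, ...] = (14, 12, 14, 15, 16, 14)  # CL1 EL1 CL2 EL2 CL3 EL3
    plant_schiff: bool = True
    plant_lrtpxn: bool = True
    plant_dry: bool = True
    plant_qakk: bool = True
    plant_cys_pair: bool = True
    tuning: Optional[str] = "Y"          # "Y" | "F" | None

    def __post_init__(self) -> None:
        if min(self.n_tail_len, self.c_tail_len, self.tm_len, *self.loop_lens) <= 0:
            raise FormatError("all region lengths must be positive")
        if len(self.loop_lens) != 6:
            raise FormatError("exactly six loop lengths required")
        if self.tuning not in (None, "Y", "F"):
            raise FormatError("tuning must be 'Y', 'F' or None")
        for loop_idx, need in ((0, 6), (2, 3), (4, 4)):
            if self.loop_lens[loop_idx] < need:
                raise FormatError(f"loop {loop_idx + 1} too short for its motif")
        if self.loop_lens[3] < 11:      # EL2 holds the cysteine plus tuning offset
            raise FormatError("EL2 too short for the cysteine/tuning arrangement")


@dataclass
class OpsinTruth:
    """Planted ground truth, 0-based coordinates on the emitted sequence."""

    regions: dict                        # label -> (start, end)
    tm_intervals: list                   # seven (start, end) pairs
    motif_positions: dict                # motif name -> start
    schiff_position: Optional[int]       # 0-based, or None
    cys_positions: Optional[tuple]       # (EL2 pos, EL3 pos) 0-based
    tuning_position: Optional[int]
    tuning_residue: Optional[str]


def make_opsin(seed: int, params: OpsinParams | None = None,
               seq_id: str = "synthetic_opsin") -> tuple[SeqRecord, OpsinTruth]:
    """A rhodopsin-shaped protein with all requested hallmarks planted.

    Background loop composition is re-drawn (rejection) if it accidentally
    creates a second, earlier occurrence of a planted motif inside its loop.
    """
    params = params or OpsinParams()
    rng = np.random.default_rng(seed)

    def loop_with(middle_inserts: list[tuple[int, str]], length: int,
                  forbid: list[str]) -> str:
        for _ in range(200):
            chars = list(_draw(rng, HYDROPHILIC_POOL, length))
            for at, text in middle_inserts:
                chars[at:at + len(text)] = list(text)
            s = "".join(chars)
            ok = True
            for pat in forbid:
                first = _first_wildcard_occurrence(s, pat)
                planted = [a for a, t in middle_inserts if _wildcard_eq(t, pat)]
                if first is not None and planted and first < planted[0]:
                    ok = False
            if ok:
                return s
        raise FormatError("could not draw a loop without accidental motifs")

    regions: dict[str, str] = {}
    regions["N_tail"] = _draw(rng, HYDROPHILIC_POOL, params.n_tail_len)
    regions["C_tail"] = _draw(rng, HYDROPHILIC_POOL, params.c_tail_len)
    for k in range(1, 8):
        regions[f"TM{k}"] = _draw(rng, HYDROPHOBIC_POOL, params.tm_len)

    loop_labels = ("CL1", "EL1", "CL2", "EL2", "CL3", "EL3")
    motif_local: dict[str, tuple[str, int]] = {}   # name -> (loop label, local pos)

    for label, length in zip(loop_labels, params.loop_lens):
        inserts: list[tuple[int, str]] = []
        forbid: list[str] = []
        if label == "CL1" and params.plant_lrtpxn:
            at = (length - 6) // 2
            inserts.append((at, "LRTPGN"))
            forbid.append("LRTPXN")
            motif_local["LRTPXN"] = (label, at)
        if label == "CL2" and params.plant_dry:
            at = (length - 3) // 2
            inserts.append((at, "DRY"))
            forbid.append("DRY")
            motif_local["DRY"] = (label, at)
        if label == "CL3" and params.plant_qakk:
            at = (length - 4) // 2
            inserts.append((at, "QAKK"))
            forbid.append("QAKK")
            motif_local["QAKK"] = (label, at)
        if label == "EL2" and params.plant_cys_pair:
            at = min(length // 2, length - 4)
            inserts.append((at, "C"))
            forbid.append("C")
            motif_local["cys_EL2"] = (label, at)
            if params.tuning:
                inserts.append((at + 3, params.tuning))
                motif_local["tuning"] = (label, at + 3)
        if label == "EL3" and params.plant_cys_pair:
            at = length // 2
            inserts.append((at, "C"))
            forbid.append("C")
            motif_local["cys_EL3"] = (label, at)
        regions[label] = loop_with(inserts, length, forbid)

    if params.plant_schiff:
        tm7 = list(regions["TM7"])
        tm7[params.tm_len // 2] = "K"
        regions["TM7"] = "".join(tm7)

    seq_parts = []
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for label in _REGION_ORDER:
        offsets[label] = (pos, pos + len(regions[label]))
        seq_parts.append(regions[label])
        pos += len(regions[label])
    residues = "".join(seq_parts)

    def absolute(name: str) -> Optional[int]:
        if name not in motif_local:
            return None
        label, local = motif_local[name]
        return offsets[label][0] + local

    truth = OpsinTruth(
        regions=dict(offsets),
        tm_intervals=[offsets[f"TM{k}"] for k in range(1, 8)],
        motif_positions={name: absolute(name) for name in ("LRTPXN", "DRY", "QAKK")
                         if absolute(name) is not None},
        schiff_position=(offsets["TM7"][0] + params.tm_len // 2
                         if params.plant_schiff else None),
        cys_positions=((absolute("cys_EL2"), absolute("cys_EL3"))
                       if params.plant_cys_pair else None),
        tuning_position=absolute("tuning"),
        tuning_residue=params.tuning if params.plant_cys_pair else None,
    )
    return SeqRecord(id=seq_id, kind="protein", residues=residues,
                     source="synthetic opsin"), truth


def _wildcard_eq(text: str, pattern: str) -> bool:
    return len(text) == len(pattern) and all(p == "X" or p == t
                                             for t, p in zip(text, pattern))


def _first_wildcard_occurrence(s: str, pattern: str) -> Optional[int]:
    for start in range(len(s) - len(pattern) + 1):
        if _wildcard_eq(s[start:start + len(pattern)], pattern):
            return start
    return None


# ---------------------------------------------------------------------------
# Protein families at controlled divergence
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    newick: str
    leaf_mutations: dict                 # leaf id -> {position: residue}
    subs_per_branch: int


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_family(root: SeqRecord, n_leaves: int, subs_per_branch: int,
                protect_positions: Sequence[int] = (), seed: int = 0,
                id_prefix: str = "leaf") -> tuple[list[SeqRecord], FamilyTruth]:
    """Evolve a root protein along a random bifurcating tree.

    Along every branch exactly ``subs_per_branch`` distinct positions mutate
    to a uniformly chosen *different* residue (no silent substitutions), so
    identity bookkeeping from the recorded per-leaf mutation maps is exact.
    Positions in ``protect_positions`` never mutate.
    """
    if n_leaves < 2:
        raise FormatError("need at least 2 leaves")
    mutable = [p for p in range(len(root.residues)) if p not in set(protect_positions)]
    if subs_per_branch >= len(mutable):
        raise FormatError("substitution budget exceeds mutable positions")
    rng = np.random.default_rng(seed)

    def mutate(seq: str) -> str:
        chars = list(seq)
        for p in rng.choice(mutable, size=subs_per_branch, replace=False):
            current = chars[p]
            alternatives = [a for a in _AA20 if a != current]
            chars[p] = alternatives[rng.integers(0, len(alternatives))]
        return "".join(chars)

    # random bifurcating topology: split leaf index ranges recursively
    counter = {"n": 0}

    def grow(n: int, seq: str) -> tuple[str, list[tuple[str, str]]]:
        if n == 1:
            counter["n"] += 1
            leaf_id = f"{id_prefix}{counter['n']}"
            return leaf_id, [(leaf_id, seq)]
        left_n = int(rng.integers(1, n))
        l_nwk, l_leaves = grow(left_n, mutate(seq))
        r_nwk, r_leaves = grow(n - left_n, mutate(seq))
        return f"({l_nwk},{r_nwk})", l_leaves + r_leaves

    newick, leaf_seqs = grow(n_leaves, root.residues)
    records = [SeqRecord(id=lid, kind="protein", residues=s, source="synthetic family")
               for lid, s in leaf_seqs]
    mutations = {
        lid: {p: s[p] for p in range(len(s)) if s[p] != root.residues[p]}
        for lid, s in leaf_seqs
    }
    return records, FamilyTruth(newick=newick + ";", leaf_mutations=mutations,
                                subs_per_branch=subs_per_branch)


# ---------------------------------------------------------------------------
# Genomic loci with a planted RCSI
# ---------------------------------------------------------------------------

@dataclass
class LocusParams:
    upstream_len: int = 200
    exon_lens: tuple[int, ...] = (150, 120, 150)
    intron_lens: tuple[int, ...] = (100, 120)
    downstream_len: int = 100
    strand: str = "+"
    placement: Optional[tuple[str, int]] = ("intron", 2)  # (kind, index/distance) or None
    gc: float = 0.5

    def __post_init__(self) -> None:
        if len(self.intron_lens) != len(self.exon_lens) - 1:
            raise FormatError("need exactly one intron between consecutive exons")
        if not (0.0 < self.gc < 1.0):
            raise FormatError("gc must be in (0, 1)")
        if self.strand not in ("+", "-"):
            raise FormatError("strand must be '+' or '-'")


@dataclass
class LocusTruth:
    gene_sequence: str                   # gene-oriented contig
    rcsi_start: Optional[int]            # 0-based on the gene-oriented contig
    rcsi_site: Optional[str]
    intended_label: Optional[str]


def _expand_consensus(rng: np.random.Generator, pattern: str = RCSI_CONSENSUS) -> str:
    from .core_io import IUPAC_SETS

    return "".join(sorted(IUPAC_SETS[p])[rng.integers(0, len(IUPAC_SETS[p]))]
                   for p in pattern)


def make_locus(seed: int, params: LocusParams | None = None,
               gene_id: str = "synthetic_locus") -> tuple[SeqRecord, GeneModel, LocusTruth]:
    """A gene locus with one concrete RCSI instance at a configured position.

    The background is redrawn until the consensus scan finds exactly the
    planted site (or none, for placement None), so accidental matches never
    survive. With ``strand='-'`` the emitted contig is the reverse complement
    of the gene orientation; the gene model keeps gene-oriented coordinates.
    """
    params = params or LocusParams()
    rng = np.random.default_rng(seed)
    motif_len = len(RCSI_CONSENSUS)

    exon_starts = []
    pos = params.upstream_len
    for k, el in enumerate(params.exon_lens):
        exon_starts.append(pos)
        pos += el
        if k < len(params.intron_lens):
            pos += params.intron_lens[k]
    total = pos + params.downstream_len
    exons = tuple((s, s + el) for s, el in zip(exon_starts, params.exon_lens))
    tss = params.upstream_len

    start = None
    intended = None
    if params.placement is not None:
        kind, val = params.placement
        if kind == "upstream":
            end = tss - val
            start = end - motif_len
            intended = f"upstream({val} bp)"
            if start < 0:
                raise FormatError("upstream placement does not fit")
        elif kind == "exon":
            s, e = exons[val - 1]
            start = (s + e - motif_len) // 2
            intended = f"exon {val}"
        elif kind == "intron":
            s = exons[val - 1][1]
            e = exons[val][0]
            start = (s + e - motif_len) // 2
            intended = f"intron {val}"
        else:
            raise FormatError(f"unknown placement kind {kind!r}")
        if start is None or not (0 <= start <= total - motif_len):
            raise FormatError("placement region shorter than the motif")

    site = _expand_consensus(rng) if start is not None else None
    bases = np.array(["A", "C", "G", "T"])
    probs = np.array([(1 - params.gc) / 2, params.gc / 2, params.gc / 2, (1 - params.gc) / 2])
    for _ in range(200):
        seq = rng.choice(bases, size=total, p=probs)
        if start is not None:
            seq[start:start + motif_len] = list(site)
        text = "".join(seq)
        hits = {h.start for h in scan(text, RCSI_CONSENSUS, both_strands=True)}
        wanted = {start} if start is not None else set()
        if hits == wanted:
            break
    else:
        raise FormatError("could not draw a background without accidental consensus matches")

    contig = text if params.strand == "+" else revcomp(text)
    record = SeqRecord(id=gene_id, kind="dna", residues=contig,
                       source="synthetic locus")
    model = GeneModel(gene_id=gene_id, contig_length=total, strand=params.strand,
                      tss=tss, exons=exons)
    truth = LocusTruth(gene_sequence=text, rcsi_start=start, rcsi_site=site,
                       intended_label=intended)
    return record, model, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

@dataclass
class CtTruth:
    true_ratio: float
    reference_mean_ct: float


def make_ct_table(seed: int, true_ratio: float, n_biological: int = 3,
                  n_technical: int = 2, noise_sd: float = 0.2,
                  target: str = "target", reference: str = "reference",
                  sample: str = "retina") -> tuple[CtTable, CtTruth]:
    """CT replicates with Gaussian cycle noise around a planted ratio.

    Reference CTs ~ Normal(20, sd); target CTs = 20 - log2(ratio) +
    Normal(0, sd). A ratio of 0 is the no-amplification sentinel: target
    rows carry empty CTs.
    """
    if n_biological < 1 or n_technical < 1:
        raise FormatError("replicate counts must be >= 1")
    if noise_sd < 0:
        raise FormatError("noise_sd must be >= 0")
    if true_ratio < 0:
        raise FormatError("true_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    base = 20.0
    rows = []
    for rep in range(1, n_biological + 1):
        for run in range(1, n_technical + 1):
            rows.append({"sample": sample, "gene": reference, "replicate": rep,
                         "run": run, "ct": base + rng.normal(0, noise_sd)})
            if true_ratio == 0:
                ct_t = float("nan")
            else:
                ct_t = base - float(np.log2(true_ratio)) + rng.normal(0, noise_sd)
            rows.append({"sample": sample, "gene": target, "replicate": rep,
                         "run": run, "ct": ct_t})
    return CtTable(pd.DataFrame(rows)), CtTruth(true_ratio=true_ratio,
                                                reference_mean_ct=base)
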