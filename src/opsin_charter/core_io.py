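"""Shared data model and file IO for the opsin characterization pipeline.

Defines the sequence/locus containers used by every downstream stage and the
readers/writers for the plain-text interchange formats: FASTA (protein and
DNA), a BED-like gene-model table, symmetric score matrices as TSV, newick
trees, JSON reports and flat key=value run configuration.

Coordinate conventions: 0-based half-open everywhere internally; 1-based
inclusive positions in rendered reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# Standard 20 amino acids; X = unknown (matches nothing downstream).
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class FormatError(ValueError):
    """Raised when an input file or record violates the format contract."""


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """One named protein or DNA sequence.

    Parameters
    ----------
    id : str
        Short unique label without whitespace.
    kind : str
        ``"protein"`` or ``"dna"``.
    residues : str
        Upper-case residues over the amino-acid alphabet (20 letters + X)
        or the IUPAC DNA alphabet.
    source : str
        Free-text provenance tag (e.g. the FASTA description line).
    """

    id: str
    kind: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id {self.id!r} is empty or contains whitespace")
        if self.kind not in ("protein", "dna"):
            raise FormatError(f"unknown molecule kind {self.kind!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.kind} character {ch!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, kind: str) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    Records come back in file order, residues upper-cased; the description
    after the first whitespace is stored in ``source``. Raises
    :class:`FormatError` on an empty file or on characters illegal for
    ``kind`` (naming the record and the 1-based position).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SeqRecord(id=rec.id, kind=kind, residues=str(rec.seq).upper(), source=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.source}" if rec.source else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string, honouring IUPAC degeneracy.

    Degenerate symbols complement set-wise (R<->Y, K<->M, S<->S, W<->W,
    B<->V, D<->H, N<->N). Applying the operation twice returns the input.
    """
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise FormatError(f"illegal DNA character(s): {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon structure for one gene locus.

    All coordinates are 0-based half-open on the gene-oriented contig (i.e.
    for a minus-strand gene the caller reverse-complements the contig first;
    :func:`read_gene_models` does this normalization). ``strand`` records the
    original contig strand for reporting.
    """

    gene_id: str
    contig_length: int
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.contig_length <= 0:
            raise FormatError(f"{self.gene_id}: non-positive contig length")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end <= self.contig_length):
                raise FormatError(f"{self.gene_id}: exon [{start}, {end}) out of bounds")
            if prev_end is not None and start < prev_end:
                raise FormatError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if not (0 <= self.tss <= self.exons[0][0]):
            raise FormatError(f"{self.gene_id}: tss must lie at or before the first exon")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )


def read_gene_models(path: str | Path, contig_lengths: dict[str, int]) -> list[GeneModel]:
    """Read a BED-like gene-model TSV.

    Columns: gene_id, contig, strand, tss, comma-separated exon starts,
    comma-separated exon ends — coordinates on the + strand of the contig.
    Minus-strand models are flipped into gene orientation using the contig
    length supplied in ``contig_lengths``.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
            gene_id, contig, strand, tss_s, starts_s, ends_s = parts
            if contig not in contig_lengths:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            length = contig_lengths[contig]
            tss = int(tss_s)
            starts = [int(x) for x in starts_s.split(",") if x]
            ends = [int(x) for x in ends_s.split(",") if x]
            if len(starts) != len(ends):
                raise FormatError(f"{path}:{lineno}: exon start/end count mismatch")
            exons = sorted(zip(starts, ends))
            if strand == "-":
                # flip into gene orientation: x -> length - x, intervals swap
                exons = sorted((length - e, length - s) for s, e in exons)
                tss = length - tss
            models.append(GeneModel(gene_id=gene_id, contig_length=length,
                                    strand=strand, tss=tss, exons=tuple(exons)))
    if not models:
        raise FormatError(f"{path}: no gene models found")
    return models


def write_gene_models(models: Iterable[GeneModel], contig_names: dict[str, str], path: str | Path) -> None:
    """Write gene models as the BED-like TSV (gene-oriented coordinates,
    i.e. a round trip through :func:`read_gene_models` with strand '+' on a
    gene-oriented contig is lossless)."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons)
            ends = ",".join(str(e) for _, e in m.exons)
            fh.write("\t".join([m.gene_id, contig_names[m.gene_id], "+",
                                str(m.tss), starts, ends]) + "\n")


# ---------------------------------------------------------------------------
# Pair matrices
# ---------------------------------------------------------------------------

@dataclass
class PairMatrix:
    """Symmetric per-pair score table over a set of sequence ids.

    ``metric`` is one of identity, similarity, normalized_score, distance.
    Diagonal is 100 for the percentage metrics, 1.0 for normalized_score and
    0 for distance.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in matrix")
        if self.values.shape != (n, n):
            raise FormatError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise FormatError("matrix is not symmetric")

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.labels.index(i), self.labels.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def write_matrix_tsv(m: PairMatrix, path: str | Path, decimals: int = 2) -> None:
    df = m.to_frame().round(decimals)
    df.to_csv(path, sep="\t", float_format=f"%.{decimals}f", index_label=f"#{m.metric}")


def read_matrix_tsv(path: str | Path, metric: str | None = None) -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = str(df.index.name or "")
    inferred = name.lstrip("#") if name.startswith("#") else "identity"
    vals = df.to_numpy(dtype=float)
    # symmetrize printed-precision asymmetries only; real asymmetry is an error
    if not np.allclose(vals, vals.T, atol=0.005001):
        raise FormatError(f"{path}: matrix is not symmetric")
    vals = (vals + vals.T) / 2.0
    return PairMatrix(labels=tuple(str(c) for c in df.columns), values=vals,
                      metric=metric or inferred)


# ---------------------------------------------------------------------------
# Newick / JSON reports
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write any object exposing ``to_newick()`` (or a newick string)."""
    text = tree if isinstance(tree, str) else tree.to_newick()
    if not text.rstrip().endswith(";"):
        text = text.rstrip() + ";"
    Path(path).write_text(text + "\n")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_report_json(report, path: str | Path) -> None:
    """Serialize a report (dataclasses allowed) as deterministic JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, cls=_ReportEncoder, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Serializable to/from a flat ``key = value`` text file; unknown keys are a
    hard error, missing keys take defaults.
    """

    seed: int = 0
    # pairwise/progressive alignment
    gap_open: float = 10.0
    gap_extend: float = 0.5
    max_gap_fraction: float = 0.5
    # identity/similarity
    denominator: str = "shorter"          # shorter | longer | mean | alignment_length
    # hydropathy topology
    window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    tm_merge_gap: int = 3
    tm_max_len: int = 35
    # trees
    bootstrap_replicates: int = 100
    # RCSI scanning
    rcsi_pattern: str = "TAATYNRATTA"
    rcsi_mismatches: int = 0

    _RANGES = {
        "gap_open": (0.0, None), "gap_extend": (0.0, None),
        "max_gap_fraction": (0.0, 1.0), "window": (5, None),
        "tm_min_len": (1, None), "tm_merge_gap": (0, None),
        "tm_max_len": (1, None), "bootstrap_replicates": (1, None),
        "rcsi_mismatches": (0, None),
    }

    def __post_init__(self) -> None:
        if self.denominator not in ("shorter", "longer", "mean", "alignment_length"):
            raise FormatError(f"unknown denominator convention {self.denominator!r}")
        if self.window % 2 == 0:
            raise FormatError("window must be odd")
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                raise FormatError(f"config {key}={v} outside legal range")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
                typ = fields[key].type
                if typ in ("int", int):
                    kwargs[key] = int(raw)
                elif typ in ("float", float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------

def load_reference_identity_matrix() -> PairMatrix:
    """Published pairwise amino-acid identity percentages (re-typed) among the
    seven D. melanogaster rhodopsins Rh1-Rh7 plus Bos taurus opsin and
    melanopsin, used as a ready-made input for distance clustering."""
    from importlib.resources import files

    path = files("opsin_charter").joinpath("data/dmel_rhodopsin_identity.tsv")
    return read_matrix_tsv(str(path), metric="identity")
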