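"""Degenerate cis-regulatory element (RCSI) scanning and localization.

The RCSI (Rhodopsin Core Sequence I) is an 11-bp element with IUPAC
consensus TAATYNRATTA found near phototransduction-gene promoters. This
module matches IUPAC-degenerate patterns against genomic sequence on both
strands, tests palindromicity (middle base ignored for odd lengths, since no
base is self-complementary), localizes hits against a gene model (upstream
distance, exon/intron index, downstream), and tabulates presence across
species loci.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .core_io import DNA_ALPHABET, FormatError, GeneModel, IUPAC_SETS, SeqRecord, revcomp

RCSI_CONSENSUS = "TAATYNRATTA"


@dataclass(frozen=True)
class LocationLabel:
    """Position of a hit relative to a gene model.

    kind: upstream | exon | intron | downstream. ``index`` is the 1-based
    exon/intron ordinal; ``distance`` the bp from hit end to the
    transcription start (upstream) or from the last exon end to hit start
    (downstream). ``straddle`` marks hits crossing a feature boundary
    (labeled by their midpoint).
    """

    kind: str
    index: Optional[int] = None
    distance: Optional[int] = None
    straddle: bool = False

    def __str__(self) -> str:
        s = "*" if self.straddle else ""
        if self.kind in ("upstream", "downstream"):
            return f"{self.kind}({self.distance} bp){s}"
        return f"{self.kind} {self.index}{s}"


@dataclass
class MotifHit:
    pattern_name: str
    strand: str                 # '+' or '-'
    start: int                  # 0-based on the given (+) sequence
    matched_text: str           # as written on the + strand
    location: Optional[LocationLabel] = None
    mismatches: int = 0

    @property
    def end(self) -> int:
        return self.start + len(self.matched_text)


def iupac_match(text: str, pattern: str) -> bool:
    """True iff every base of ``text`` is allowed by the IUPAC ``pattern``."""
    if len(text) != len(pattern):
        raise FormatError("text and pattern must have equal lengths")
    for t, p in zip(text.upper(), pattern.upper()):
        if p not in IUPAC_SETS:
            raise FormatError(f"illegal IUPAC pattern symbol {p!r}")
        if t not in IUPAC_SETS:
            raise FormatError(f"illegal DNA character {t!r}")
        if not (IUPAC_SETS[t] <= IUPAC_SETS[p]):
            return False
    return True


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for p in pattern.upper():
        if p not in IUPAC_SETS:
            raise FormatError(f"illegal IUPAC pattern symbol {p!r}")
        allowed = "".join(sorted(IUPAC_SETS[p]))
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def _scan_one_strand(seq: str, pattern: str, mismatches: int) -> list[tuple[int, int]]:
    """(start, n_mismatches) of all matches of pattern on the given string."""
    if mismatches == 0:
        return [(m.start(), 0) for m in _pattern_regex(pattern).finditer(seq)]
    sets = [IUPAC_SETS[p] for p in pattern.upper()]
    out = []
    plen = len(pattern)
    for start in range(len(seq) - plen + 1):
        mm = 0
        for k in range(plen):
            if seq[start + k] not in sets[k]:
                mm += 1
                if mm > mismatches:
                    break
        else:
            out.append((start, mm))
    return out


def scan(seq: SeqRecord | str, pattern: str = RCSI_CONSENSUS,
         both_strands: bool = True, mismatches: int = 0,
         pattern_name: str | None = None) -> list[MotifHit]:
    """All pattern occurrences, sorted by start position.

    Minus-strand occurrences are found by matching the reverse complement of
    the pattern against the + strand and are reported in + coordinates. For
    a self-reverse-complementary pattern every + hit therefore co-occurs
    with a - hit at the same start.
    """
    if isinstance(seq, SeqRecord):
        if seq.kind != "dna":
            raise FormatError(f"record {seq.id!r}: scanning requires DNA")
        text = seq.residues
    else:
        text = seq.upper()
    if len(text) < len(pattern):
        raise FormatError("sequence shorter than pattern")
    name = pattern_name or pattern
    hits = [MotifHit(pattern_name=name, strand="+", start=s,
                     matched_text=text[s:s + len(pattern)], mismatches=mm)
            for s, mm in _scan_one_strand(text, pattern, mismatches)]
    if both_strands:
        rc = revcomp(pattern)
        hits += [MotifHit(pattern_name=name, strand="-", start=s,
                          matched_text=text[s:s + len(pattern)], mismatches=mm)
                 for s, mm in _scan_one_strand(text, rc, mismatches)]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def is_palindromic(site: str) -> bool:
    """True iff the site equals its reverse complement, ignoring the middle
    position for odd lengths (no nucleotide is self-complementary)."""
    if not site:
        raise FormatError("empty site")
    site = site.upper()
    rc = revcomp(site)
    if len(site) % 2 == 1:
        mid = len(site) // 2
        site = site[:mid] + site[mid + 1:]
        rc = rc[:mid] + rc[mid + 1:]
    return site == rc


def localize(hit: MotifHit, model: GeneModel) -> LocationLabel:
    """Label a hit relative to the gene model.

    Fully before the transcription start: upstream(d) with d = tss - hit_end.
    Otherwise the exon or intron containing the hit midpoint (1-based index);
    hits straddling a feature boundary keep the midpoint label with a
    straddle flag; past the last exon: downstream(d).
    """
    if hit.end > model.contig_length or hit.start < 0:
        raise FormatError("hit lies beyond the contig")
    if hit.end <= model.tss:
        return LocationLabel(kind="upstream", distance=model.tss - hit.end)

    def feature_of(pos: int) -> tuple[str, int] | None:
        for k, (s, e) in enumerate(model.exons, 1):
            if s <= pos < e:
                return ("exon", k)
        for k, (s, e) in enumerate(model.introns, 1):
            if s <= pos < e:
                return ("intron", k)
        return None

    mid = (hit.start + hit.end - 1) // 2
    feat = feature_of(mid)
    straddle = feature_of(hit.start) != feature_of(hit.end - 1)
    if feat is None:
        last_end = model.exons[-1][1]
        if mid >= last_end:
            return LocationLabel(kind="downstream", distance=max(hit.start - last_end, 0),
                                 straddle=straddle)
        # between tss and first exon
        return LocationLabel(kind="upstream", distance=0, straddle=True)
    return LocationLabel(kind=feat[0], index=feat[1], straddle=straddle)


@dataclass
class SpeciesPresence:
    species: str
    present: bool
    site_count: int
    best_location: Optional[LocationLabel]


def species_presence(loci: Sequence[tuple[str, SeqRecord, Optional[GeneModel]]],
                     pattern: str = RCSI_CONSENSUS, both_strands: bool = True,
                     mismatches: int = 0) -> list[SpeciesPresence]:
    """Presence/absence table of the element across species loci.

    ``site_count`` counts distinct start positions (a palindromic consensus
    hits both strands at the same site). The best location is the first
    site's label when a gene model is supplied.
    """
    if not loci:
        raise FormatError("at least one locus required")
    table = []
    for species, seq, model in loci:
        hits = scan(seq, pattern, both_strands, mismatches)
        sites = sorted({h.start for h in hits})
        best = None
        if sites and model is not None:
            first = next(h for h in hits if h.start == sites[0])
            best = localize(first, model)
        table.append(SpeciesPresence(species=species, present=bool(sites),
                                     site_count=len(sites), best_location=best))
    return table
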