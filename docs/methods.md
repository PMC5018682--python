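# Methods

This note documents the models, conventions and defaults behind
opsin-charter, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh's
three-state recursion) under the published BLOSUM62 matrix. A gap run of
length L costs `gap_open + L·gap_extend` with defaults 10 and 0.5 — the
classic Clustal-W protein defaults. Terminal gaps are penalized like
internal gaps; ties in the traceback resolve deterministically
(match/mismatch over a gap in the first sequence over a gap in the second).

Multiple alignment is progressive: all-pairs alignment identities give a
distance matrix (d = 100 − %identity, shorter-sequence denominator), a
neighbor-joining agglomeration schedule supplies the merge order, and
profiles are merged with the same affine-gap dynamic program. Profile
columns score as the arithmetic mean of residue-pair substitution scores,
gaps contributing 0. Once a gap column enters a profile it is never
removed, so every row ungaps exactly to its input. This is a deliberately
simple stand-in for production aligners (no iterative refinement, no k-mer
prefilter); on substitution-only families it recovers the homology columns
exactly, which is the regime the tests certify.

Column filtering removes alignment columns whose gap fraction exceeds a
threshold (default 0.5); all-gap columns are always removed, and removing
every column is an explicit error.

## Identity and similarity

Identity counts aligned columns carrying the identical residue; similarity
additionally counts residues sharing one of six physicochemical groups
(positively charged {R,K,H}, negatively charged {D,E}, aliphatic {V,I,L},
aromatic {F,Y,W}, amide {N,Q}, small {A,T,S}). Gapped columns never count;
`X` (unknown) matches nothing, including another `X`.

Web tools in this space offer several percentage denominators and published
tables rarely say which was used. The default here is the **shorter
ungapped sequence length**, which guarantees 100% self-identity regardless
of alignment gaps; `longer`, `mean` and `alignment_length` are selectable.
Re-typed published values carry this convention uncertainty, which is why
matrix-level comparisons against printed tables should allow a couple of
percentage points.

The normalized similarity score is S(i,j)/min(S(i,i), S(j,j)), where S sums
BLOSUM62 entries over columns with residues in both rows and self-scores
sum the diagonal over each full sequence; self-comparison is exactly 1 by
construction.

A region option restricts any matrix to a per-sequence sub-interval (used
for N-terminal tail comparisons): only columns whose residues fall inside
both sequences' regions count, and the denominators shrink accordingly.

Note on the published table this package ships (re-typed printed identity
percentages over Rh1–Rh7 plus bovine opsin/melanopsin): the source text is
internally inconsistent in two places — it gives Rh7–Rh6 as 26.51% in prose
but 27.1% in the table, and Rh1–Rh6 as 51.65% in prose but 51.76% in the
table. The packaged file follows the table; neither value is adjudicated
here.

## Transmembrane topology

A Kyte–Doolittle hydropathy profile (mean scale value over a centered
window; truncated windows at the termini so every residue is scored) feeds
a segment caller: maximal runs of scores ≥ threshold, runs separated by ≤
merge_gap positions merged, runs longer than max_len split at their
interior minimum, runs shorter than min_len discarded. Defaults: window 19,
threshold 1.6, min_len 15, merge_gap 3, max_len 35. This is a transparent,
dependency-free predictor, not an HMM: it consumes only segment boundaries,
which is all the downstream annotation needs, and its boundary placement
carries a few residues of uncertainty — hence tail-length comparisons use
residue tolerances rather than exact equality.

Orientation is fixed to the rhodopsin convention (extracellular
N-terminus), not predicted. Exactly seven membrane segments yield the
canonical 15-region labeling; any other count returns generic `loop_k`
labels plus a warning flag, and downstream motif searches then fall back to
the whole sequence with a low-confidence flag so partial reports are still
produced.

## Hallmark annotation

Motifs are matched exactly, with `X` as a wildcard, gated to their required
topological region (LRTPXN in CL1, DRY in CL2, QAKK in CL3); an optional
per-motif mismatch budget exists, but the L and N of LRTPXN may never
mismatch (both are required for a functional receptor). The Schiff-base
lysine is the single K in TM7 (several Ks: nearest the TM7 midpoint, with
an ambiguity flag). The disulfide pair is the first cysteine in EL2 and the
first in EL3, with a multiplicity flag when a loop holds more than one.

The spectral tuning rule examines the residues exactly three positions
before and after the more N-terminal cysteine of the pair: tyrosine (either
offset, precedence) → visible; else phenylalanine → UV; else unknown. The
classical description places this residue in TM3 near "the first cysteine",
but under this package's loop inventory the disulfide cysteines sit in EL2
and EL3, whose ±3 neighborhoods cannot lie in TM3 — descriptions of the
landmark cysteine vary in the literature. The rule therefore keys on the
residue identity alone and records, per report, the chosen offset and
whether the position falls in TM3, rather than hard-gating on TM3.

The functional verdict is `7 TMs ∧ Schiff lysine ∧ LRTPXN ∧ DRY ∧ cysteine
pair`. QAKK is reported separately and deliberately excluded: functional
rhodopsins lacking the QAKK motif are documented (the mosquito Rh7 homolog
Op10 drives phototransduction without it), and Rh7 itself lacks it — which
is precisely the comparative signal the report surfaces.

## RCSI scanning and localization

IUPAC-degenerate matching treats a pattern symbol as a base set; scanning
uses a compiled regular expression with lookahead so overlapping sites are
all reported; the sliding-window definition serves as the test oracle.
Minus-strand hits come from matching the reverse complement of the pattern
against the forward strand and are reported in forward coordinates. The
RCSI consensus `TAATYNRATTA` is its own reverse complement, so every
forward hit co-occurs with a reverse hit at the same start; presence tables
therefore count distinct sites, not strand-hits.

Palindromicity for odd-length sites ignores the central base (no nucleotide
is self-complementary) — the convention under which the concrete Rh7 site
`TAATCAGATTA` is palindromic. Note that matching the consensus does not
imply palindromicity: a concrete match is palindromic exactly when its Y
(position 5) and R (position 7) are complementary.

Localization against a gene model: a hit wholly before the transcription
start is `upstream(d)` with d measured from hit end to TSS in gene
orientation; otherwise the exon or intron containing the hit midpoint
(1-based), with a straddle flag for boundary-crossing hits — published
descriptions report whole-feature membership and never define boundary
behavior, so the midpoint rule is this package's choice. Minus-strand gene
models are normalized into gene orientation at read time. An optional
≤ k-mismatch mode flags near-matches (the "modified site" case) separately
from exact hits.

## Trees and group assignment

Neighbor joining is the classical Saitou–Nei agglomeration on
d = (100 − identity)/100. It is a deliberate, declared substitute for
maximum-likelihood estimation: the conclusions consumed downstream are
cluster memberships (which taxa share a side of an internal edge), which NJ
reproduces on additive and near-additive matrices, not branch-length
inference. Q-matrix ties break lexicographically on taxon labels; negative
branch-length estimates clamp to zero and are counted on the tree;
triangle-inequality violations in an input matrix are reported, not hidden.
Bootstrap support resamples alignment columns with replacement, rebuilds
identity → distance → NJ per replicate, and scores each internal edge by
the fraction of replicates containing its bipartition (seeded,
reproducible).

Group assignment gives a query the reference group with the smallest mean
distance, reporting the margin to the runner-up; exact ties return
`unassigned`. It supports both a three-group reference set
(melanopsin-type, insect-type, Rh7-type) and two groups plus unassigned.

## qPCR relative expression

ΔCT = CT_target − CT_reference per biological replicate after averaging
technical runs arithmetically on the cycle scale; relative level =
2^−ΔCT; biological replicates combine by geometric mean on the ratio scale
(standard practice; arithmetic on cycles is arithmetic in log-expression).
No calibrator sample is used — the design compares detection within one
tissue — and ΔΔCT is deliberately not implemented. An empty CT is the
no-amplification sentinel: level 0 with a below-detection flag, mirroring a
negative result for a hypothesized isoform.

## Synthetic data: what it emulates, what it does not

Generators are bit-reproducible per seed, with no hidden global state.

- **Opsins**: membrane segments drawn from a hydrophobic pool (I/V/L-
  weighted, mean Kyte–Doolittle ≈ +4.1), loops/tails from a hydrophilic
  pool (mean ≈ −0.6), hallmarks spliced at recorded positions, with
  rejection of accidental earlier motif copies. The pool means flank the
  default calling threshold with margin so the defaults work without
  per-test tuning; the membrane default is 23 residues, in the range of
  real rhodopsin helices, so that the lysine-bearing TM7 (the Schiff base
  costs ≈ 8 hydropathy units against an otherwise hydrophobic segment)
  still clears the caller's minimum length.
- **Families**: a random bifurcating tree; along each branch exactly the
  stated number of positions mutate to a *different* residue, so identity
  bookkeeping from the recorded mutation maps is exact. No indels — the
  alignment engine's gap handling is tested separately on constructed
  cases, and family-based certifications speak only to the
  substitution-only regime.
- **Loci**: background bases by GC content; one concrete consensus
  expansion (uniform over all 16) spliced at the configured placement
  (upstream d / exon k / intron k / none); the background is redrawn until
  the scan finds exactly the planted site, so planted-count guarantees are
  absolute.
- **CT tables**: reference cycles ~ Normal(20, sd), target cycles shifted
  by −log2(ratio) with the same noise; ratio 0 emits the sentinel.

Passing on this synthetic corpus certifies the algorithms' correctness
against planted truth. It does not certify performance on real proteins:
real membrane helices have heterogeneous hydropathy, real families have
indels and rate variation, and real promoters have compositional structure.
The default parameters are reasonable starting points for real opsins, not
validated predictions; topology boundaries in particular should be treated
as ±(a few residues).

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale sizes chosen as
representative while keeping the full run in the minutes range: exhaustive
alignment oracles at lengths ≤ 8, 100 generator seeds for membrane-segment
recall/precision, 500-sequence scanning oracles, 25–100 loci/tables per
stochastic check, families of 2–9 sequences of opsin length. All randomness
flows from explicit seeds; two runs with the same inputs and configuration
produce byte-identical outputs.

## Known limitations

- The hydropathy predictor does not model signal peptides or re-predict
  orientation; a cleaved signal sequence would shift all tail statistics.
- The progressive aligner's guide tree uses identity distances; highly
  diverged pairs (<25% identity) can misplace gaps relative to curated
  alignments.
- Percentage-identity comparisons across tools inherit the denominator
  convention ambiguity described above.
- The spectral-class rule is a two-state (Y/F) reduction of spectral
  tuning; it does not predict absorption maxima.
- assign_cluster assumes reference groups are represented by at least one
  close relative in the matrix; margins near zero should be read as
  "unassigned in practice".
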