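# Methods

## Scope and model

`replifin` finishes hybrid bacterial assemblies in which a long-read draft
supplies structure and short-read data supply base-level accuracy. The
error model it targets is specific to high-GC genomes sequenced with
long-read chemistry: the dominant residual error is the omission of a
single C or G inside a homopolymeric run of three or more Cs or Gs, with
rare isolated substitutions. Because such genomes are ~85–90% coding,
these omissions are frameshifts and can be validated (or rejected)
without annotation by frame-specific GC statistics.

Coordinates are 0-based half-open internally; all user-facing output
(VCF, summaries) is 1-based. Sequences use the 5-letter alphabet ACGTN;
N never matches anything and never counts toward a homopolymer run.

## Alignment core

Contig/read-to-draft alignment is seeded on k-mers that occur exactly
once in the target (repeat-masked seeding, default k = 21), on both
strands. Co-diagonal consecutive seeds merge into maximal exact anchors;
the best collinear chain (anchored bases minus gap penalties, ties broken
toward the leftmost target start) is selected, inter-anchor gaps are
closed by global edit-distance alignment (edlib), and the ends are
extended semi-globally. End extensions are trimmed back to their
best-scoring prefix (match +1, difference −5) so that a partial terminal
repeat does not drag random flanking sequence into the block; the harsh
difference penalty biases extent estimates conservative on noisy repeats
and leaves clean planted repeats exact. An extension never emits bases
beyond the target boundary — a query prefix that outruns the target start
is reported as an unaligned overhang, which is exactly the signal the
terminus-extension stage consumes.

Edit scripts are runs of `=`, `X`, `I` (query-only base), `D`
(target-only base). Script bookkeeping (query/target span coverage) is
validated on every constructed block. Variant extraction decomposes runs
into single-base candidates, left-aligns every indel within its
homopolymer, and classifies a candidate `gc_homopolymer` when the allele
is a lone C or G whose run in the target **before editing** is at least
`hp_min_run` (default 3). The target-side reading means a correction
restoring a run of three (draft `GCC` → `GCCC`) is *not* in the
homopolymer class while `GCCC` → `GCCCC` is; every worked example of the
error class in the source data has a pre-correction run of ≥ 3, and the
simulator plants deletions only in truth runs of length ≥ `hp_min_run`+1
so planted drafts always show a qualifying run.

## Correction policies

**Contig stage.** Candidates from all aligned contigs are merged on the
exact key (position, kind, allele, occurrence). A contig whose alignment
covers a site with ≥ 10 bp margin but does not support a candidate
contradicts it. The default policy applies homopolymer-class insertions
unless contradicted; substitutions under unanimity of covering contigs or
a positive frame-repair verdict; all other indels only with the frame
verdict. Overlapping accepted edits are resolved leftmost-wins, and edits
are applied right-to-left so stored coordinates stay valid. Reports carry
the length-conservation invariant
`after = before + inserted − deleted`, checked after every run.

**Read stage.** Calls from two independent aligners are intersected on
the exact normalized key (no ±1 slop — left-normalization makes keys
deterministic). Indels in both sets are applied; single-caller indels
only with a frame-repair verdict; substitutions never. The two stages
deliberately carry different substitution policies (unanimity-or-frame
vs. never): contig-level consensus is itself strong evidence, whereas
read-level substitution calls in this setting are dominated by systematic
mapping artifacts. Both policies are explicit objects and overridable.

`pileup_calls` provides the per-column consensus caller used to derive
candidates from read alignments (own aligner output or SAM/BAM via
pysam): a site needs ≥ `min_depth` (10) covering reads with
≥ `min_fraction` (0.8) agreeing on one non-reference allele.

## Frame validation

`frame_gc_profile` computes windowed GC fractions at absolute positions
≡ 0, 1, 2 (mod 3) — window 360 bp (codon-resolution smoothing, a multiple
of 3 so each class contributes equally), step 30 bp. Classes use absolute
coordinates rather than gene-relative frames because no annotation exists
at correction time; a frameshift is visible as a transition of the argmax
class regardless of labeling. A frame break is a transition between
segments that hold one dominant class for ≥ 3 consecutive windows with
top-minus-second margin ≥ 0.1. `frame_repair_score` applies a candidate
edit to a ±3 kb local copy and answers *yes* iff a break within one
window of the site disappears, or the longest stop-free reading frame
overlapping the site (any of six frames; start codons not required, since
the check mirrors amino-acid-level inspection rather than gene calling)
grows by ≥ 300 bases. On simulated codon-biased genomes the corrective
edit for a deletion planted in the middle third of a ≥ 1.8 kb gene is
validated in ≥ 99% of cases; edits very close to gene boundaries give the
detector too little downstream signal and fall back to the conservative
*no*.

## Topology

**Circularization.** Candidate terminal direct repeat lengths are derived
from the supported seed diagonals between the first and last
`search_window` (20 kb) bases; each candidate r is verified by a global
alignment of the first against the last r bases and accepted at identity
≥ 0.99. The 3' copy is trimmed (an arbitrary but fixed choice, recorded
in the replicon notes), yielding the circle with its origin at former
position 0.

**TIR detection.** The reverse complement of the terminal 3' window is
aligned to the 5' half; the hit must be anchored at the 3' terminus but
its 5' partner may be internal (the geometry of a partially assembled
right TIR). Block ends are additionally trimmed to ≥ 15 bp terminal match
runs so a coincidental match just beyond the repeat cannot inflate the
reported extent by a few bases; the cost is a slight conservative bias on
repeats with differences within 15 bp of their boundary.

**TIR extent from coverage.** The sequence-level TIR hit and the full TIR
extent are deliberately separate estimates, mirroring the two available
lines of evidence (terminal sequence identity vs. a depth step where
reads of both TIR copies collapsed onto one). The changepoint is the
exhaustive single-split least-squares fit — exact and deterministic at
the track sizes involved — accepted only when the first/second segment
mean ratio is ≥ 1.5 and the two-segment fit reduces variance by ≥ 20%.
The estimate is scale-invariant in depth.

**Palindromes.** Within each terminal window (1 kb), all maximal
exact-arm inverted repeats with arm ≥ 8 and loop ≤ 50 are enumerated,
longest first. In GC-rich random sequence, arm-8 hits occur by chance at
an appreciable rate; the arm-length ordering puts planted long hairpins
first.

## Terminus extension and bridging

Extension looks for the contig (either orientation) with the longest
terminal overlap ≥ `min_overlap` (1 kb) at identity ≥ 0.99 whose
alignment reaches the draft end and leaves an unaligned overhang; the 3'
case is handled by reverse-complement symmetry. Multiple offers must
agree on their overlapping suffix — otherwise the conflict is an error
naming both contigs, not a silent choice.

Bridging first checks whether the two contigs simply overlap (then trims
the second). Otherwise, reads anchoring ≥ `min_anchor` (500) matched
bases on the 3' terminus of the first contig and the 5' terminus of the
second vote on the gap: at least `min_span_reads` (3) spanning reads with
gap lengths within ±10 bases are required, and the inserted sequence is
their star-alignment majority consensus (exact for identical segments).
A read-voted negative gap is treated as overlap and resolved by trimming.
Note that a uniform 20-read 10 kb tiling of a 132 kb replicon (1.5×
coverage) places exactly two reads across a 2.5 kb gap, so desk-scale
scenarios at that depth are run with `min_span_reads=2`; at realistic
bridging depths the default of 3 stands.

## Simulator

The generator's defaults are the study conditions: a 7,898,767 bp
chromosome with a 6,996 bp TIR fragment, ~85% coding at mean gene length
900 bp with third-position GC probability 0.9 (first/second positions
drawn at GC 0.725, overall GC ≈ 0.77), an 86,370 bp circular plasmid with
an 8,376 bp terminal duplication in its contig form, a 132,226 bp linear
plasmid whose interval [97005, 99529) is a 40-mer tandem array dropped
from the short-read contigs, 2,934 homopolymer deletions plus 42
substitutions at minimum spacing 100 bp, 40 contig tiles overlapping by
200 bp, and 10 kb reads. Stop codons inside genes are removed by flipping
their first base to C. Planted TIRs and duplications are pinned with a
deliberate flanking mismatch so the planted repeat is maximal at exactly
its nominal length and recovery tests have exact expectations.

What the simulator does **not** model: realistic long-read error
processes beyond G/C-run omissions and isolated substitutions (reads are
"corrected-read-like", substitution-only), quality values, chimeric
reads, short-read misassembly, or assembler behavior. Passing the
planted-truth suites therefore demonstrates correctness of the finishing
logic under the stated error phenomenology, not robustness to every
artifact of real data; the policies' conservative branches (conflict
rejection, frame-verdict gating, ambiguous-gap errors) exist for exactly
the cases the simulator does not generate.

Planted edits are kept ≥ 100 bp apart and ≥ 100 bp from replicon ends so
candidates never interact — this makes recovery counts exact. The
polisher itself makes no such assumption; adversarially overlapping
accepted edits are resolved deterministically (leftmost wins).

## Problem sizes used in the checks

Acceptance-scale runs use the full study dimensions (7.9 Mb polishing
twin, 1 Mb TIR twin, 132 kb bridging twin); the remaining unit and
property tests run on 20–120 kb genomes, which exercise every code path
of the k-mer index, chaining and policies at a fraction of the cost. The
DP-equivalence property compares the chained aligner's edit distance
against an independent full quadratic DP on ≤ 500 bp near-identical
pairs, where the full DP is feasible.

## Known limitations

* Alignment inside repeats longer than the unique-k-mer horizon relies on
  gap closing between flanking anchors; two near-identical multi-hundred-kb
  TIR copies with copy-specific variants would polish only where flanking
  unique anchors exist.
* `estimate_tir_boundary` fits a single changepoint; staged coverage
  (nested repeats) is out of scope.
* The star-consensus bridging is designed for corrected (low-error)
  reads; raw-read polishing is deliberately not supported.
* Circular replicons are not rotated to a canonical origin; the origin is
  wherever the contig opened the circle.
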