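# replifin

Hybrid genome finishing for high-GC actinomycete assemblies.

Long-read assemblies of GC-rich bacteria (*Streptomyces* and relatives,
often >70 mol% G+C) are structurally excellent but carry a characteristic
residual error: single-base omissions of a C or G inside homopolymeric
runs of three or more Cs or Gs. Because these genomes are densely coding,
almost every such omission is a frameshift. Short-read assemblies have the
opposite profile — nucleotide-accurate but fragmented, with repeat-rich
regions missing entirely. `replifin` implements the finishing workflow
that combines the two:

1. **Artifact flagging** — long-read contigs assembled from
   error-accumulated reads match the main assembly at ~92% identity over
   their whole length; they are detected and discarded.
2. **Contig-based polishing** — accurate contigs are aligned over the
   draft; G/C-homopolymer insertions are applied unless an overlapping
   contig contradicts them, substitutions require unanimity among
   overlapping contigs (or a positive frame-repair verdict), and all other
   indels require the frame verdict.
3. **Frame validation** — a *GC frame plot* computes windowed GC%
   separately at positions ≡ 0, 1, 2 (mod 3). In high-GC coding sequence
   the third codon position is GC-rich, so the dominant class tracks the
   reading frame and a single-base indel appears as a phase switch. A
   candidate edit is validated when applying it removes a local phase
   switch or grows the longest stop-free reading frame by ≥ 300 bases.
4. **Terminus extension** — a contig that aligns flush to a draft end with
   an unaligned overhang extends the replicon.
5. **Read-based polishing** — variant calls from two independent read
   aligners are intersected on the exact left-normalized
   (position, kind, allele) key; indels reported by both are applied,
   single-caller indels only with a frame-repair verdict, substitutions
   never.
6. **Topology resolution** — a linear contig whose first and last *r*
   bases are a direct repeat is the opened form of a circle of
   length L − r and is trimmed accordingly; terminal inverted repeats
   (TIRs) are detected by aligning the reverse complement of the 3' end
   against the 5' half, and the full TIR extent is estimated separately
   from a coverage changepoint (collapsed TIR copies double the apparent
   depth). The estimated full chromosome size is
   `assembled − right_tir_fragment + tir_len`.
7. **Bridging** — two contigs belonging to one replicon are joined across
   an unassembled gap by corrected long reads that anchor on both flanks;
   the gap sequence is their per-column majority consensus.

Every stage is testable without external data via a bundled simulator
(`replifin.simulate`) that generates codon-biased high-GC replicons with
planted, ledgered errors and the three archetypal topologies: a linear
chromosome with TIRs, a circular plasmid represented as a linear contig
with a terminal duplication, and a linear plasmid split by a repeat-rich
gap.

## Worked example

```python
from replifin.simulate import (SimConfig, build_truth, corrupt_longread_style,
                               make_contigs, linearize_with_duplication)
from replifin.polish import correct_with_contigs
from replifin.report import format_correction_rate
from replifin import topology

cfg = SimConfig(chromosome_length=500_000, tir_len=5_000,
                n_hp_del=150, n_subst=4,
                plasmid1_circle_len=40_000, plasmid1_dup_len=4_000,
                plasmid2_len=60_000, plasmid2_gap=(40_000, 42_500),
                n_contigs=10, seed=5)
truth_fs, _ = build_truth(cfg)
chrom = truth_fs.get("chrom")
draft, ledger = corrupt_longread_style(chrom, cfg.n_hp_del, cfg.n_subst,
                                       cfg.min_spacing, seed=6)
contigs = make_contigs(chrom, cfg.n_contigs, seed=7)

corrected, rep = correct_with_contigs(draft, contigs)
print(rep.summary())
print("correction rate:", format_correction_rate(rep))
print("matches truth:", corrected.seq == chrom.seq)

hit = topology.detect_tir(corrected)
print(f"TIR fragment: {hit.length} bp at {hit.identity:.2%} identity")

p1 = linearize_with_duplication(truth_fs.get("pcirc"), cfg.plasmid1_dup_len)
circ = topology.circularize(p1, topology.detect_terminal_direct_repeat(p1))
print(f"plasmid contig {len(p1.seq)} bp -> circular {len(circ.seq)} bp")
```

prints

```
154 corrections (150 ins, 0 del, 4 sub); 499850 -> 500000 bases
correction rate: 0.03080 %
matches truth: True
TIR fragment: 5000 bp at 100.00% identity
plasmid contig 44000 bp -> circular 40000 bp
```

All 150 planted homopolymer omissions are re-inserted and all 4 planted
substitutions corrected under unanimity, restoring the truth
byte-for-byte; the TIR detector recovers the planted 5 kb inverted
repeat, and trimming the 4 kb terminal duplication recovers the 40 kb
circle.

A command-line interface mirrors the library
(`replifin simulate | polish-contigs | polish-reads | extend | circularize |
tir | bridge | flag-artifacts | run`); `replifin run config.toml --outdir out`
executes the whole pipeline and writes per-replicon FASTA, a VCF of applied
edits, and JSON stage reports.

## Module map

| module     | contents |
|------------|----------|
| `seqmodel` | `Replicon`, `ParamSet`, FASTA/BED-graph I/O, GC%/GC-skew tracks |
| `align`    | unique-k-mer seeding, chaining, banded gap closing, edit scripts, variant candidates |
| `gcframe`  | frame-specific GC profiles, frame-break detection, frame-repair scoring |
| `polish`   | contig-based and dual-caller correction policies, pileup calling, VCF export |
| `topology` | terminal direct/inverted repeats, circularization, coverage changepoint, palindromes |
| `finish`   | artifact flagging, terminus extension, long-read bridging, pipeline |
| `simulate` | truth genomes, planted-edit ledgers, contig tiles, reads |
| `report`   | size arithmetic, correction rates, statistics tables |
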