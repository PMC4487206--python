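"""Synthetic genomes with the architecture and error phenomenology of a
high-GC actinomycete sequencing project, plus a planted-truth ledger.

The generator emulates:

* a codon-biased, high-GC linear chromosome with exact terminal inverted
  repeats;
* a circular plasmid (whose long-read contig representation carries the
  terminal direct repeat of the assembly overlap);
* a linear plasmid with a repeat-rich interior region that short-read
  contigs drop, splitting it in two;
* long-read drafts corrupted by single-base omissions in G/C homopolymer
  runs plus rare isolated substitutions;
* error-free but fragmented short-read contig tiles, and corrected long
  reads with optional residual substitution errors.

Planted edits are pairwise separated (``min_spacing``) so that recovery
tests have exact expected counts; every ledger is complete enough to
reproduce the truth from the draft byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .finish import FinishedSet, StageRecord
from .seqmodel import Replicon, codes_to_seq, revcomp, seq_to_codes

_BASE = "ACGT"


@dataclass(frozen=True)
class PlantedEdit:
    """One truth -> draft corruption (coordinates on the truth)."""

    replicon_id: str
    pos: int
    kind: str       # deletion | substitution
    ref: str
    alt: str
    context: str    # gc_homopolymer | other


@dataclass
class PlantedEditLedger:
    """Ground truth: per-edit records plus per-replicon architecture."""

    edits: list[PlantedEdit] = field(default_factory=list)
    architecture: dict = field(default_factory=dict)
    min_spacing: int = 100

    def for_replicon(self, rid: str) -> list[PlantedEdit]:
        return [e for e in self.edits if e.replicon_id == rid]

    def make_draft(self, truth: Replicon) -> str:
        """Apply this ledger's edits for *truth* to its sequence."""
        codes = seq_to_codes(truth.seq).copy()
        edits = self.for_replicon(truth.id)
        for e in edits:
            if e.kind == "substitution":
                codes[e.pos] = _BASE.index(e.alt)
        dels = sorted(e.pos for e in edits if e.kind == "deletion")
        if dels:
            codes = np.delete(codes, dels)
        return codes_to_seq(codes)

    def restore(self, draft_seq: str, rid: str) -> str:
        """Invert every ledger edit, reproducing the truth from the draft."""
        edits = sorted(self.for_replicon(rid), key=lambda e: e.pos)
        dels_before = 0
        out = draft_seq
        shift = 0
        for e in edits:
            dpos = e.pos - dels_before + shift
            if e.kind == "deletion":
                out = out[:dpos] + e.ref + out[dpos:]
                dels_before += 1
                shift += 1
            else:
                assert out[dpos] == e.alt
                out = out[:dpos] + e.ref + out[dpos + 1:]
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("replicon\tpos0\tkind\tref\talt\tcontext\n")
            for e in sorted(self.edits, key=lambda e: (e.replicon_id, e.pos)):
                fh.write(f"{e.replicon_id}\t{e.pos}\t{e.kind}\t{e.ref}"
                         f"\t{e.alt}\t{e.context}\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "min_spacing": self.min_spacing,
                "architecture": self.architecture,
                "edits": [e.__dict__ for e in
                          sorted(self.edits, key=lambda e: (e.replicon_id, e.pos))],
            }, fh, indent=2)


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic genome.

    The default dimensions follow the sequencing project the package is
    patterned on: a ~7.9 Mb chromosome with a ~7 kb assembled TIR fragment,
    an 86,370 bp circular plasmid whose long-read contig carries an
    8,376 bp terminal duplication, and a 132,226 bp linear plasmid whose
    short-read assembly drops the repeat-rich interval [97005, 99529).
    """

    chromosome_length: int = 7_898_767
    tir_len: int = 6_996
    mean_gene_len: int = 900
    coding_fraction: float = 0.85
    gc3: float = 0.9
    plasmid1_circle_len: int = 86_370
    plasmid1_dup_len: int = 8_376
    plasmid2_len: int = 132_226
    plasmid2_gap: tuple[int, int] = (97_005, 99_529)
    n_hp_del: int = 2_934
    n_subst: int = 42
    min_spacing: int = 100
    hp_min_run: int = 3
    n_contigs: int = 40
    contig_min_len: int = 5_000
    contig_overlap: int = 200
    read_len: int = 10_000
    read_depth: float = 20.0
    read_error: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("chromosome_length", "mean_gene_len",
                     "plasmid1_circle_len", "plasmid2_len", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tir_len < 0 or 2 * self.tir_len >= self.chromosome_length:
            raise ValueError("tir_len infeasible for the chromosome length")
        if self.plasmid1_dup_len >= self.plasmid1_circle_len:
            raise ValueError("terminal duplication exceeds the circle")
        g0, g1 = self.plasmid2_gap
        if not 0 <= g0 < g1 <= self.plasmid2_len:
            raise ValueError("plasmid2 gap outside the plasmid")
        if (self.n_hp_del + self.n_subst) * self.min_spacing >= self.chromosome_length:
            raise ValueError("edit count x spacing exceeds the genome length")
        if not 0.5 <= self.gc3 <= 1.0:
            raise ValueError("gc3 must lie in [0.5, 1.0]")


# ---------------------------------------------------------------------------
# sequence generators
# ---------------------------------------------------------------------------

# first/second codon position composition: GC ~0.725, matching a high-GC
# actinomycete; third position GC is the gc3 parameter
_P12 = np.array([0.115, 0.3625, 0.3625, 0.16])
_P_INTERGENIC = np.array([0.15, 0.35, 0.35, 0.15])


def _random_codes(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def coding_like_sequence(
    n_genes: int,
    mean_len: int = 900,
    gc3: float = 0.9,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Generate stop-free codon-biased genes separated by short spacers.

    Third codon positions are G or C with probability *gc3*; stop codons
    (TAA/TAG/TGA) are removed by flipping their first base to C. Returns
    the sequence and the 0-based half-open gene intervals.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 0.5 <= gc3 <= 1.0:
        raise ValueError("gc3 must lie in [0.5, 1.0]")
    if n_genes < 0 or mean_len < 60:
        raise ValueError("infeasible gene parameters")
    p3 = np.array([(1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2])
    n_codons_per_gene = np.maximum(
        (rng.normal(mean_len / 3, mean_len / 9, size=n_genes)).astype(int), 34
    ) if n_genes else np.zeros(0, dtype=int)
    total = int(n_codons_per_gene.sum())
    c1 = _random_codes(rng, total, _P12)
    c2 = _random_codes(rng, total, _P12)
    c3 = _random_codes(rng, total, p3)
    # stop codons: TAA, TAG, TGA  (T=3, A=0, G=2)
    stop = (c1 == 3) & (((c2 == 0) & ((c3 == 0) | (c3 == 2)))
                        | ((c2 == 2) & (c3 == 0)))
    c1[stop] = 1  # CAA/CAG/CGA are all sense codons
    codons = np.empty(total * 3, dtype=np.uint8)
    codons[0::3], codons[1::3], codons[2::3] = c1, c2, c3

    pieces: list[np.ndarray] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    cstart = 0
    for g in range(n_genes):
        spacer = _random_codes(rng, int(rng.integers(50, 250)), _P_INTERGENIC)
        pieces.append(spacer)
        pos += len(spacer)
        ncod = int(n_codons_per_gene[g])
        gene = codons[cstart * 3:(cstart + ncod) * 3]
        cstart += ncod
        pieces.append(gene)
        intervals.append((pos, pos + len(gene)))
        pos += len(gene)
    pieces.append(_random_codes(rng, int(rng.integers(50, 250)), _P_INTERGENIC))
    seq = codes_to_seq(np.concatenate(pieces) if pieces else np.zeros(0, np.uint8))
    return seq, intervals


def _random_highgc(rng: np.random.Generator, n: int) -> str:
    return codes_to_seq(_random_codes(rng, n, _P_INTERGENIC))


def _pin_mismatch(codes: np.ndarray, pos: int, avoid: int) -> None:
    """Force codes[pos] != avoid (breaks coincidental repeat extension)."""
    if codes[pos] == avoid:
        codes[pos] = (avoid + 1) % 4


def build_truth(cfg: SimConfig) -> tuple[FinishedSet, PlantedEditLedger]:
    """Construct the three-replicon truth genome and its architecture ledger."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # chromosome: coding sequence filled to length, exact TIRs imposed
    L = cfg.chromosome_length
    n_genes = max(1, int(L * cfg.coding_fraction / cfg.mean_gene_len))
    seq, genes = coding_like_sequence(n_genes, cfg.mean_gene_len, cfg.gc3, rng=rng)
    if len(seq) < L:
        seq += _random_highgc(rng, L - len(seq))
    seq = seq[:L]
    genes = [(a, b) for a, b in genes if b <= L]
    codes = seq_to_codes(seq).copy()
    T = cfg.tir_len
    if T > 0:
        left = codes[:T]
        codes[L - T:] = 3 - left[::-1]          # reverse complement in 2-bit space
        # keep the planted repeat maximal at exactly T: the base flanking
        # each copy must not extend the match
        _pin_mismatch(codes, L - T - 1, int(3 - codes[T]))
    chrom = Replicon("chrom", codes_to_seq(codes), "linear", "synthetic truth")

    # circular plasmid
    circ, _ = coding_like_sequence(
        max(1, int(cfg.plasmid1_circle_len * 0.8 / 600)), 600, cfg.gc3, rng=rng)
    if len(circ) < cfg.plasmid1_circle_len:
        circ += _random_highgc(rng, cfg.plasmid1_circle_len - len(circ))
    plasmid1 = Replicon("pcirc", circ[:cfg.plasmid1_circle_len], "circular",
                        "synthetic truth")

    # linear plasmid with a repeat-rich interior interval
    p2, _ = coding_like_sequence(
        max(1, int(cfg.plasmid2_len * 0.8 / 600)), 600, cfg.gc3, rng=rng)
    if len(p2) < cfg.plasmid2_len:
        p2 += _random_highgc(rng, cfg.plasmid2_len - len(p2))
    p2 = p2[:cfg.plasmid2_len]
    g0, g1 = cfg.plasmid2_gap
    unit = _random_highgc(rng, 40)
    tandem = (unit * ((g1 - g0) // len(unit) + 1))[: g1 - g0]
    p2 = p2[:g0] + tandem + p2[g1:]
    plasmid2 = Replicon("plin", p2, "linear", "synthetic truth")

    ledger = PlantedEditLedger(
        architecture={
            "chrom": {"tir_len": T},
            "pcirc": {"circle_len": cfg.plasmid1_circle_len,
                      "terminal_dup_len": cfg.plasmid1_dup_len},
            "plin": {"gap": list(cfg.plasmid2_gap)},
        },
        min_spacing=cfg.min_spacing,
    )
    fs = FinishedSet(replicons=[chrom, plasmid1, plasmid2])
    fs.log.append(StageRecord("build_truth", {"seed": cfg.seed}))
    return fs, ledger


def linearize_with_duplication(circle: Replicon, dup: int) -> Replicon:
    """Represent a circle as the linear contig a long-read assembler emits:
    the full circle plus its first *dup* bases appended (assembly overlap)."""
    if not 0 < dup < len(circle.seq):
        raise ValueError("duplication length out of range")
    return Replicon(circle.id + "_contig", circle.seq + circle.seq[:dup],
                    "linear", f"linearized circle + {dup} bp terminal repeat")


def corrupt_longread_style(
    truth: Replicon,
    n_hp_del: int,
    n_subst: int,
    min_spacing: int = 100,
    seed: int = 0,
    hp_min_run: int = 3,
    end_buffer: int = 100,
) -> tuple[Replicon, PlantedEditLedger]:
    """Corrupt a truth sequence the way raw long reads corrupt high-GC DNA.

    Deletes one base from *n_hp_del* distinct G/C homopolymer runs (runs of
    length >= hp_min_run+1 in the truth, so the corrupted draft still shows
    a qualifying run of >= hp_min_run) and substitutes *n_subst* isolated
    bases; all planted sites are pairwise >= *min_spacing* apart.
    """
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(truth.seq).copy()
    L = len(codes)

    # homopolymer runs via change points
    change = np.nonzero(np.diff(codes) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [L]])
    lens = ends - starts
    bases = codes[starts]
    eligible = ((lens >= hp_min_run + 1) & ((bases == 1) | (bases == 2))
                & (starts >= end_buffer) & (ends <= L - end_buffer))
    cand_runs = np.nonzero(eligible)[0]
    if len(cand_runs) < n_hp_del:
        raise ValueError(
            f"only {len(cand_runs)} eligible G/C runs for {n_hp_del} deletions")

    def free(pos: int) -> bool:
        b = pos // min_spacing
        return not any(
            abs(pos - p) < min_spacing
            for nb in (b - 1, b, b + 1)
            for p in bin_map.get(nb, ())
        )

    bin_map: dict[int, list[int]] = {}

    def take(pos: int) -> None:
        bin_map.setdefault(pos // min_spacing, []).append(pos)

    edits: list[PlantedEdit] = []
    order = rng.permutation(len(cand_runs))
    picked = 0
    for idx in order:
        if picked == n_hp_del:
            break
        run = cand_runs[idx]
        pos = int(starts[run])
        if not free(pos) or not free(int(ends[run]) - 1):
            continue
        take(pos)
        take(int(ends[run]) - 1)
        edits.append(PlantedEdit(truth.id, pos, "deletion",
                                 _BASE[codes[pos]], "", "gc_homopolymer"))
        picked += 1
    if picked < n_hp_del:
        raise ValueError(
            f"could only place {picked} of {n_hp_del} deletions at "
            f"spacing {min_spacing}")

    interior = (np.arange(1, L - 1) if end_buffer < 1
                else np.arange(end_buffer, L - end_buffer))
    isolated = ((codes[interior - 1] != codes[interior])
                & (codes[interior] != codes[interior + 1]))
    sub_cands = interior[isolated]
    order = rng.permutation(len(sub_cands))
    picked = 0
    for idx in order:
        if picked == n_subst:
            break
        pos = int(sub_cands[idx])
        if not free(pos):
            continue
        take(pos)
        forbidden = {int(codes[pos - 1]), int(codes[pos]), int(codes[pos + 1])}
        alt = next(b for b in rng.permutation(4) if int(b) not in forbidden)
        edits.append(PlantedEdit(truth.id, pos, "substitution",
                                 _BASE[codes[pos]], _BASE[int(alt)], "other"))
        picked += 1
    if picked < n_subst:
        raise ValueError(f"could only place {picked} of {n_subst} substitutions")

    ledger = PlantedEditLedger(edits=edits, min_spacing=min_spacing)
    draft_seq = ledger.make_draft(truth)
    draft = Replicon(truth.id, draft_seq, "linear",
                     f"long-read-style draft ({n_hp_del} hp deletions, "
                     f"{n_subst} substitutions)")
    return draft, ledger


def make_contigs(
    truth: Replicon,
    n: int,
    min_len: int = 5_000,
    dropped_regions: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    overlap: int = 200,
) -> list[Replicon]:
    """Error-free contig tiles of the truth, skipping *dropped_regions*.

    Adjacent tiles within one kept interval overlap by *overlap* bases
    (>= 2x the seed k-mer length so candidate extraction is redundant at
    tile joins); tile breakpoints are randomized.
    """
    rng = np.random.default_rng(seed)
    L = len(truth.seq)
    for a, b in dropped_regions:
        if not 0 <= a < b <= L:
            raise ValueError(f"dropped region ({a}, {b}) outside the sequence")
    kept: list[tuple[int, int]] = []
    cur = 0
    for a, b in sorted(dropped_regions):
        if a > cur:
            kept.append((cur, a))
        cur = max(cur, b)
    if cur < L:
        kept.append((cur, L))

    total_kept = sum(b - a for a, b in kept)
    contigs: list[Replicon] = []
    tile_no = 0
    remaining = n
    for i, (a, b) in enumerate(kept):
        li = b - a
        if i == len(kept) - 1:
            ni = max(1, remaining)
        else:
            ni = max(1, round(n * li / total_kept))
        ni = min(ni, max(1, li // max(min_len, 1)))
        remaining -= ni
        cuts = [a + round(j * li / ni) for j in range(ni + 1)]
        jitter = max(0, min(1000, li // (4 * ni) - 1))
        for j in range(1, ni):
            cuts[j] += int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        for j in range(ni):
            s = max(a, cuts[j] - (overlap if j > 0 else 0))
            e = min(b, cuts[j + 1])
            contigs.append(Replicon(f"{truth.id}_tile{tile_no:04d}",
                                    truth.seq[s:e], "linear",
                                    f"tile of {truth.id}[{s}:{e}]"))
            tile_no += 1
    return contigs


def simulate_long_reads(
    truth: Replicon,
    read_len: int = 10_000,
    depth: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Replicon], list[tuple[int, int]]]:
    """Uniformly sampled corrected-long-read-like reads (substitution errors
    only). Returns the reads and their truth-origin spans."""
    L = len(truth.seq)
    if L == 0:
        raise ValueError("empty truth sequence")
    if read_len > L:
        raise ValueError("read length exceeds the sequence")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    reads: list[Replicon] = []
    origins: list[tuple[int, int]] = []
    for i, s in enumerate(starts):
        s = int(s)
        codes = seq_to_codes(truth.seq[s : s + read_len]).copy()
        if error_rate > 0:
            k = rng.binomial(read_len, error_rate)
            if k:
                pos = rng.choice(read_len, size=k, replace=False)
                codes[pos] = (codes[pos] + rng.integers(1, 4, size=k)) % 4
        reads.append(Replicon(f"{truth.id}_read{i:05d}", codes_to_seq(codes)))
        origins.append((s, s + read_len))
    return reads, origins


def tiling_reads(truth: Replicon, read_len: int, n: int) -> list[Replicon]:
    """*n* exact reads evenly tiling the truth (deterministic layout)."""
    L = len(truth.seq)
    if read_len > L or n < 1:
        raise ValueError("infeasible tiling")
    if n == 1:
        starts = [0]
    else:
        starts = [round(i * (L - read_len) / (n - 1)) for i in range(n)]
    return [Replicon(f"{truth.id}_tread{i:05d}", truth.seq[s : s + read_len])
            for i, s in enumerate(starts)]


def write_fastq(reads: Sequence[Replicon], path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(r.seq), id=r.id, description="",
                  letter_annotations={"phred_quality": [40] * len(r.seq)})
        for r in reads
    ]
    seqio_write(records, str(path), "fastq")
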