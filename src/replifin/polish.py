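"""Draft-assembly correction policies.

Two stages are implemented, mirroring how a long-read draft of a high-GC
genome is finished against short-read data:

* **contig-based correction** — high-accuracy contigs are aligned over the
  draft and classified single-base differences are applied under a
  conservative policy: G/C-homopolymer insertions (the characteristic
  long-read omission class) are applied unless an overlapping contig
  contradicts them; substitutions need unanimity among overlapping contigs
  or a positive reading-frame repair verdict; all other indels need the
  frame verdict.

* **read-based correction** — variant calls from two independent read
  aligners are intersected; indels reported by both callers are applied,
  indels from a single caller only with a positive frame-repair verdict,
  and substitutions never.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import gcframe
from .align import (AlignmentBlock, TargetIndex, VariantCandidate, align_pair,
                    diff_variants)
from .seqmodel import ParamSet, Replicon


@dataclass
class RejectedCandidate:
    candidate: VariantCandidate
    reason: str


@dataclass
class CorrectionReport:
    """Ledger of applied and rejected edits with count conservation."""

    before_len: int
    after_len: int = 0
    applied: list[VariantCandidate] = field(default_factory=list)
    rejected: list[RejectedCandidate] = field(default_factory=list)
    inserted_bases: int = 0
    deleted_bases: int = 0
    substituted_bases: int = 0
    by_context: dict[str, int] = field(default_factory=dict)

    @property
    def total_corrections(self) -> int:
        return len(self.applied)

    def tally(self) -> None:
        self.inserted_bases = sum(
            len(c.alt) for c in self.applied if c.kind == "insertion")
        self.deleted_bases = sum(
            len(c.ref) for c in self.applied if c.kind == "deletion")
        self.substituted_bases = sum(
            len(c.ref) for c in self.applied if c.kind == "substitution")
        self.by_context = {}
        for c in self.applied:
            self.by_context[c.context] = self.by_context.get(c.context, 0) + 1

    def validate(self) -> None:
        if self.after_len != self.before_len + self.inserted_bases - self.deleted_bases:
            raise AssertionError("length bookkeeping violated")

    def to_json(self) -> str:
        def cand(c: VariantCandidate) -> dict:
            return {
                "tid": c.tid, "pos": c.tpos + 1, "ref": c.ref, "alt": c.alt,
                "kind": c.kind, "context": c.context,
                "support": sorted(c.support), "frame": c.frame_validated,
            }
        return json.dumps(
            {
                "before_len": self.before_len,
                "after_len": self.after_len,
                "total_corrections": self.total_corrections,
                "inserted_bases": self.inserted_bases,
                "deleted_bases": self.deleted_bases,
                "substituted_bases": self.substituted_bases,
                "by_context": self.by_context,
                "applied": [cand(c) for c in self.applied],
                "rejected": [
                    {**cand(r.candidate), "reason": r.reason}
                    for r in self.rejected
                ],
            },
            indent=2,
        )

    def summary(self) -> str:
        return (
            f"{self.total_corrections} corrections "
            f"({self.inserted_bases} ins, {self.deleted_bases} del, "
            f"{self.substituted_bases} sub); "
            f"{self.before_len} -> {self.after_len} bases"
        )


@dataclass(frozen=True)
class ContigPolicy:
    """Contig-stage policy (substitutions allowed under unanimity)."""

    apply_gc_homopolymer_insertions: bool = True
    substitutions: str = "unanimity_or_frame"   # or "never"
    other_indels: str = "frame"                 # or "never"
    cover_margin: int = 10


@dataclass(frozen=True)
class ReadCallPolicy:
    """Read-stage policy (substitutions never applied)."""

    substitutions: str = "never"
    single_caller_indels: str = "frame"


def apply_edits(seq: str, cands: Sequence[VariantCandidate],
                order: str = "right_to_left") -> str:
    """Apply accepted single-base edits to *seq*.

    ``right_to_left`` applies in descending coordinate order so stored
    positions stay valid; ``left_to_right_shifted`` applies ascending with
    an explicit running offset. Both orders produce identical results for
    non-overlapping edit sets.
    """
    if order == "right_to_left":
        out = seq
        for c in sorted(cands, key=lambda c: (c.tpos, c.occ), reverse=True):
            out = _apply_one(out, c.tpos, c)
        return out
    if order == "left_to_right_shifted":
        out = seq
        shift = 0
        for c in sorted(cands, key=lambda c: (c.tpos, c.occ)):
            out = _apply_one(out, c.tpos + shift, c)
            shift += len(c.alt) - len(c.ref)
        return out
    raise ValueError(f"unknown order {order!r}")


def _apply_one(seq: str, pos: int, c: VariantCandidate) -> str:
    if c.kind == "insertion":
        return seq[:pos] + c.alt + seq[pos:]
    end = pos + len(c.ref)
    if seq[pos:end] != c.ref:
        raise AssertionError(
            f"edit at {pos} expects {c.ref!r} but sequence has {seq[pos:end]!r}")
    return seq[:pos] + c.alt + seq[end:]


def _resolve_overlaps(accepted: list[VariantCandidate]
                      ) -> tuple[list[VariantCandidate], list[RejectedCandidate]]:
    """Leftmost-wins resolution of overlapping accepted edits."""
    kept: list[VariantCandidate] = []
    dropped: list[RejectedCandidate] = []
    occupied_until = -1          # last target position consumed by an edit
    ins_sites: dict[int, str] = {}
    for c in sorted(accepted, key=lambda c: (c.tpos, c.kind != "insertion", c.occ)):
        if c.kind == "insertion":
            prev = ins_sites.get(c.tpos)
            if prev is not None and prev != c.alt:
                dropped.append(RejectedCandidate(c, "overlap"))
                continue
            ins_sites[c.tpos] = c.alt
            kept.append(c)
        else:
            if c.tpos <= occupied_until:
                dropped.append(RejectedCandidate(c, "overlap"))
                continue
            occupied_until = c.tpos + len(c.ref) - 1
            kept.append(c)
    return kept, dropped


def merge_candidates(per_source: Iterable[list[VariantCandidate]]
                     ) -> list[VariantCandidate]:
    """Merge per-source candidate lists by exact key, unioning support."""
    merged: dict[tuple, VariantCandidate] = {}
    for cands in per_source:
        for c in cands:
            key = c.key()
            if key in merged:
                merged[key].support |= c.support
            else:
                merged[key] = c
    return sorted(merged.values(), key=lambda c: (c.tpos, c.kind, c.alt, c.occ))


def correct_with_contigs(
    draft: Replicon,
    contigs: Sequence[Replicon],
    params: ParamSet | None = None,
    policy: ContigPolicy | None = None,
    index: TargetIndex | None = None,
) -> tuple[Replicon, CorrectionReport]:
    """Correct a long-read draft with high-accuracy contigs.

    Contigs that do not align are passed through untouched (listed in the
    report's rejected section with reason ``unaligned-contig``). Edits are
    applied right-to-left so stored positions stay valid.
    """
    params = params or ParamSet()
    policy = policy or ContigPolicy()
    if index is None:
        index = TargetIndex(draft.seq, k=params.anchor_k)

    blocks: dict[str, AlignmentBlock] = {}
    per_source: list[list[VariantCandidate]] = []
    report = CorrectionReport(before_len=len(draft.seq))
    for contig in contigs:
        block = align_pair(contig.seq, draft.seq, k=params.anchor_k,
                           index=index, min_anchor=params.min_anchor,
                           qid=contig.id, tid=draft.id)
        if block is None:
            report.rejected.append(RejectedCandidate(
                VariantCandidate(tid=draft.id, tpos=0, ref="", alt="",
                                 kind="insertion", support={contig.id}),
                "unaligned-contig"))
            continue
        blocks[contig.id] = block
        per_source.append(diff_variants(block, contig.seq, draft.seq, params))

    spans = {cid: b.tspan for cid, b in blocks.items()}
    m = policy.cover_margin

    def covering(pos: int) -> set[str]:
        return {cid for cid, (ts, te) in spans.items()
                if ts <= pos - m and pos + m <= te}

    accepted: list[VariantCandidate] = []
    for cand in merge_candidates(per_source):
        cover = covering(cand.tpos)
        contradicting = cover - cand.support
        if cand.kind == "insertion" and cand.context == "gc_homopolymer":
            if policy.apply_gc_homopolymer_insertions and not contradicting:
                accepted.append(cand)
            else:
                report.rejected.append(RejectedCandidate(cand, "conflict"))
        elif cand.kind == "substitution":
            if policy.substitutions == "never":
                report.rejected.append(
                    RejectedCandidate(cand, "policy:no-substitutions"))
            elif not contradicting and cover & cand.support:
                accepted.append(cand)
            elif gcframe.frame_repair_score(draft.seq, cand)[1] == "yes":
                accepted.append(cand)
            else:
                report.rejected.append(RejectedCandidate(cand, "conflict"))
        else:
            if (policy.other_indels == "frame"
                    and gcframe.frame_repair_score(draft.seq, cand)[1] == "yes"):
                accepted.append(cand)
            else:
                report.rejected.append(RejectedCandidate(cand, "no-frame-support"))

    kept, dropped = _resolve_overlaps(accepted)
    report.rejected.extend(dropped)
    corrected_seq = apply_edits(draft.seq, kept)
    report.applied = sorted(kept, key=lambda c: (c.tpos, c.occ))
    report.after_len = len(corrected_seq)
    report.tally()
    report.validate()
    corrected = draft.with_seq(
        corrected_seq, note=f"contig-polished ({report.total_corrections} edits)")
    return corrected, report


def correct_with_read_calls(
    draft: Replicon,
    calls_a: Sequence[VariantCandidate],
    calls_b: Sequence[VariantCandidate],
    params: ParamSet | None = None,
    policy: ReadCallPolicy | None = None,
) -> tuple[Replicon, CorrectionReport]:
    """Dual-caller intersection correction with an indels-only policy.

    Indels with the same normalized (position, kind, allele) key in both
    call sets are applied; single-caller indels only on a positive
    frame-repair verdict; substitutions are always rejected.
    """
    params = params or ParamSet()
    policy = policy or ReadCallPolicy()
    report = CorrectionReport(before_len=len(draft.seq))
    keys_a = {c.key(): c for c in calls_a}
    keys_b = {c.key(): c for c in calls_b}

    accepted: list[VariantCandidate] = []
    for key in sorted(set(keys_a) | set(keys_b)):
        cand = keys_a.get(key) or keys_b.get(key)
        if key in keys_a and key in keys_b:
            cand.support = keys_a[key].support | keys_b[key].support
        if cand.kind == "insertion":
            in_range = 0 <= cand.tpos <= len(draft.seq)
        else:
            in_range = 0 <= cand.tpos and cand.tpos + len(cand.ref) <= len(draft.seq)
        if not in_range:
            report.rejected.append(RejectedCandidate(cand, "out-of-range"))
            continue
        if cand.kind == "substitution":
            report.rejected.append(
                RejectedCandidate(cand, "policy:no-substitutions"))
            continue
        if key in keys_a and key in keys_b:
            accepted.append(cand)
        elif (policy.single_caller_indels == "frame"
              and gcframe.frame_repair_score(draft.seq, cand)[1] == "yes"):
            accepted.append(cand)
        else:
            report.rejected.append(RejectedCandidate(cand, "single-caller"))

    kept, dropped = _resolve_overlaps(accepted)
    report.rejected.extend(dropped)
    corrected_seq = apply_edits(draft.seq, kept)
    report.applied = sorted(kept, key=lambda c: (c.tpos, c.occ))
    report.after_len = len(corrected_seq)
    report.tally()
    report.validate()
    corrected = draft.with_seq(
        corrected_seq, note=f"read-polished ({report.total_corrections} edits)")
    return corrected, report


# ---------------------------------------------------------------------------
# per-column consensus calling from read alignments
# ---------------------------------------------------------------------------

def pileup_calls(
    draft: Replicon,
    alignments: Sequence[tuple[Replicon, AlignmentBlock]] | str | Path,
    min_depth: int = 10,
    min_fraction: float = 0.8,
    params: ParamSet | None = None,
    source_label: str = "pileup",
) -> list[VariantCandidate]:
    """Per-column consensus variant calling from aligned reads.

    *alignments* is either a list of ``(read, block)`` pairs produced by
    this package's aligner, or a path to a SAM/BAM file whose reads were
    mapped to *draft*. A candidate is emitted where at least *min_depth*
    reads cover the site and at least *min_fraction* of them support the
    same non-reference allele (indels via left-normalized placement).
    """
    params = params or ParamSet()
    if isinstance(alignments, (str, Path)):
        alignments = sam_to_alignments(alignments, draft)

    n = len(draft.seq)
    cov = np.zeros(n + 1, dtype=np.int64)
    counts: dict[tuple, tuple[VariantCandidate, int]] = {}
    for read, block in alignments:
        ts, te = block.tspan
        cov[ts] += 1
        cov[te] -= 1
        for c in diff_variants(block, read.seq, draft.seq, params):
            key = c.key()
            if key in counts:
                prev, k = counts[key]
                prev.support |= c.support
                counts[key] = (prev, k + 1)
            else:
                counts[key] = (c, 1)
    depth = np.cumsum(cov)[:n]

    out: list[VariantCandidate] = []
    for key in sorted(counts):
        cand, k = counts[key]
        pos = min(cand.tpos, n - 1)
        d = int(depth[pos])
        if d >= min_depth and k / d >= min_fraction:
            cand.support = {source_label}
            out.append(cand)
    return out


def sam_to_alignments(path: str | Path, draft: Replicon
                      ) -> list[tuple[Replicon, AlignmentBlock]]:
    """Convert SAM/BAM records mapped to *draft* into internal blocks.

    The stored (already reference-oriented) read sequence is used, so all
    resulting blocks are ``+`` strand. M runs are split into ``=``/``X`` by
    direct comparison with the draft.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    pairs: list[tuple[Replicon, AlignmentBlock]] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            qseq = rec.query_sequence.upper()
            runs: list[tuple[str, int]] = []
            qp = rec.query_alignment_start
            tp = rec.reference_start
            q0, t0 = qp, tp
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X -> compare to draft
                    i = 0
                    while i < ln:
                        same = qseq[qp + i] == draft.seq[tp + i]
                        j = i
                        while j < ln and (qseq[qp + j] == draft.seq[tp + j]) == same:
                            j += 1
                        runs.append(("=" if same else "X", j - i))
                        i = j
                    qp += ln
                    tp += ln
                elif op == 1:  # I
                    runs.append(("I", ln))
                    qp += ln
                elif op == 2:  # D
                    runs.append(("D", ln))
                    tp += ln
                elif op in (4, 5):  # soft/hard clip: outside the block
                    continue
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            merged: list[tuple[str, int]] = []
            for op_, n_ in runs:
                if merged and merged[-1][0] == op_:
                    merged[-1] = (op_, merged[-1][1] + n_)
                else:
                    merged.append((op_, n_))
            block = AlignmentBlock(
                qid=rec.query_name, tid=draft.id, qlen=len(qseq),
                tlen=len(draft.seq), strand="+",
                qspan=(q0, qp), tspan=(t0, tp), edits=merged)
            block.validate()
            pairs.append((Replicon(id=rec.query_name, seq=qseq), block))
    return pairs


# ---------------------------------------------------------------------------
# VCF export of applied edits
# ---------------------------------------------------------------------------

def write_vcf(report: CorrectionReport, draft: Replicon, path: str | Path) -> None:
    """Write applied corrections as a minimal single-sample-free VCF.

    Positions follow VCF's 1-based anchored-indel convention; INFO carries
    the context class, supporting sources and frame-validation status.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={draft.id},length={len(draft.seq)}>\n")
        fh.write('##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Indel context class">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=.,Type=String,Description="Supporting sources">\n')
        fh.write('##INFO=<ID=FRAME,Number=1,Type=String,Description="Frame validation verdict">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in report.applied:
            if c.kind == "substitution":
                pos, ref, alt = c.tpos + 1, c.ref, c.alt
            elif c.kind == "insertion":
                if c.tpos == 0:
                    pos, ref, alt = 1, draft.seq[0], c.alt + draft.seq[0]
                else:
                    anchor = draft.seq[c.tpos - 1]
                    pos, ref, alt = c.tpos, anchor, anchor + c.alt
            else:  # deletion
                if c.tpos == 0:
                    nxt = draft.seq[c.tpos + len(c.ref)]
                    pos, ref, alt = 1, c.ref + nxt, nxt
                else:
                    anchor = draft.seq[c.tpos - 1]
                    pos, ref, alt = c.tpos, anchor + c.ref, anchor
            info = (f"CONTEXT={c.context};"
                    f"SUPPORT={','.join(sorted(c.support)) or '.'};"
                    f"FRAME={c.frame_validated}")
            fh.write(f"{draft.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
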