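"""Terminus extension, artifact flagging, long-read bridging, and the
full finishing pipeline.

The pipeline mirrors a hybrid finishing workflow for actinomycete genomes:
flag error-accumulation artifact contigs, correct the long-read draft with
the short-read contigs, extend the termini with contig overhangs, apply
read-based corrections if calls are supplied, resolve replicon topology
(circularization via terminal direct repeats, TIR detection, coverage
changepoint), and bridge split replicons with corrected long reads.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from . import topology
from .align import (AlignmentBlock, TargetIndex, VariantCandidate, align_pair,
                    _parse_cigar)
from .polish import (ContigPolicy, CorrectionReport, ReadCallPolicy,
                     correct_with_contigs, correct_with_read_calls)
from .seqmodel import ParamSet, Replicon, revcomp


class FinishError(RuntimeError):
    """Raised for unresolvable finishing situations (unbridged gaps etc.)."""


@dataclass
class StageRecord:
    stage: str
    params: dict
    info: dict = field(default_factory=dict)


@dataclass
class FinishedSet:
    """Topology-resolved replicons plus per-stage reports and provenance."""

    replicons: list[Replicon]
    reports: dict[str, object] = field(default_factory=dict)
    log: list[StageRecord] = field(default_factory=list)

    def get(self, rid: str) -> Replicon:
        for rep in self.replicons:
            if rep.id == rid:
                return rep
        raise KeyError(rid)


# ---------------------------------------------------------------------------
# artifact-contig flagging
# ---------------------------------------------------------------------------

def flag_artifact_contigs(
    contigs: Sequence[Replicon],
    assembly: Replicon | Sequence[Replicon],
    band: tuple[float, float] = (0.80, 0.95),
    min_cov: float = 0.9,
    params: ParamSet | None = None,
    indexes: dict[str, TargetIndex] | None = None,
) -> dict[str, list[Replicon]]:
    """Partition contigs into {artifact, genuine, unplaced}.

    A contig is an *artifact* when at least *min_cov* of its length aligns
    to the assembly at an overall identity inside *band* — the signature of
    a contig assembled from reads with accumulated errors; *genuine* when
    the identity is above the band; *unplaced* otherwise.
    """
    params = params or ParamSet()
    reps = [assembly] if isinstance(assembly, Replicon) else list(assembly)
    if indexes is None:
        indexes = {r.id: TargetIndex(r.seq, params.anchor_k) for r in reps}
    out: dict[str, list[Replicon]] = {"artifact": [], "genuine": [], "unplaced": []}
    for contig in contigs:
        best: AlignmentBlock | None = None
        for rep in reps:
            block = align_pair(contig.seq, rep.seq, k=params.anchor_k,
                               index=indexes[rep.id],
                               min_anchor=params.min_anchor,
                               qid=contig.id, tid=rep.id)
            if block is not None and (best is None or block.matches > best.matches):
                best = block
        if best is None:
            out["unplaced"].append(contig)
            continue
        qs, qe = best.qspan
        cov = (qe - qs) / len(contig.seq)
        lo, hi = band
        if cov >= min_cov and lo <= best.identity <= hi:
            out["artifact"].append(contig)
        elif cov >= min_cov and best.identity > hi:
            out["genuine"].append(contig)
        else:
            out["unplaced"].append(contig)
    return out


# ---------------------------------------------------------------------------
# terminus extension
# ---------------------------------------------------------------------------

def extend_terminus(
    draft: Replicon,
    contigs: Sequence[Replicon],
    end: str = "5prime",
    min_overlap: int = 1000,
    min_ident: float = 0.99,
    params: ParamSet | None = None,
) -> tuple[Replicon, int]:
    """Extend one terminus of a linear draft with a contig overhang.

    The contig with the longest terminal overlap (>= *min_overlap* at
    identity >= *min_ident*) whose alignment leaves an overhang beyond the
    draft end contributes its overhang. Contigs are tried in both
    orientations. Two contigs offering contradictory overhangs raise
    :class:`FinishError` naming both; bases_added is 0 when no contig
    extends the end.
    """
    if end not in ("5prime", "3prime"):
        raise ValueError("end must be '5prime' or '3prime'")
    if draft.topology == "circular":
        raise ValueError("cannot extend a circular replicon")
    params = params or ParamSet()
    if end == "3prime":
        flipped = Replicon(draft.id, revcomp(draft.seq), draft.topology, draft.notes)
        rc_contigs = [Replicon(c.id, revcomp(c.seq)) for c in contigs]
        extended, added = extend_terminus(flipped, rc_contigs, "5prime",
                                          min_overlap, min_ident, params)
        out = draft.with_seq(revcomp(extended.seq),
                             note=f"3' extended by {added} bases" if added else "")
        return out, added

    offers: list[tuple[str, str, int]] = []  # (contig id, overhang, overlap cols)
    wlen = max((len(c.seq) for c in contigs), default=0) + 200
    window = draft.seq[:wlen]
    if not window:
        return draft, 0
    index = TargetIndex(window, params.anchor_k)
    for contig in contigs:
        for oriented in (contig.seq, revcomp(contig.seq)):
            block = align_pair(oriented, window, k=params.anchor_k, index=index,
                               min_anchor=params.min_anchor,
                               qid=contig.id, tid=draft.id)
            if block is None or block.strand != "+":
                continue
            qs, qe = block.qspan
            ts, te = block.tspan
            if ts != 0 or qs == 0:
                continue   # does not reach the draft start, or no overhang
            if block.aligned_cols() < min_overlap or block.identity < min_ident:
                continue
            offers.append((contig.id, oriented[:qs], block.aligned_cols()))
            break   # an orientation matched; do not also try the other

    if not offers:
        return draft, 0
    offers.sort(key=lambda o: (-len(o[1]), o[0]))
    best_id, best_ov, _ = offers[0]
    for cid, ov, _ in offers[1:]:
        if best_ov[-len(ov):] != ov:
            raise FinishError(
                f"conflicting 5' overhangs from contigs {best_id!r} and {cid!r}")
    extended = draft.with_seq(best_ov + draft.seq,
                              note=f"5' extended by {len(best_ov)} bases "
                                   f"from {best_id}")
    return extended, len(best_ov)


# ---------------------------------------------------------------------------
# long-read bridging
# ---------------------------------------------------------------------------

def _star_consensus(segments: list[str]) -> str:
    """Majority-vote consensus of near-identical segments.

    The segment with median length is the star centre; the others are
    aligned to it pairwise and votes are tallied per centre column (with
    insertion slots). Exact for identical segments; robust to scattered
    independent errors given a handful of segments.
    """
    if len(set(segments)) == 1:
        return segments[0]
    by_len = sorted(segments, key=len)
    ref = by_len[len(by_len) // 2]
    n = len(ref)
    votes: list[Counter] = [Counter() for _ in range(n)]
    ins_votes: list[Counter] = [Counter() for _ in range(n + 1)]
    for seg in segments:
        if seg == ref:
            for i, b in enumerate(ref):
                votes[i][b] += 1
            continue
        res = edlib.align(seg, ref, mode="NW", task="path")
        qp = tp = 0
        for op, ln in _parse_cigar(res["cigar"]):
            if op in ("=", "X"):
                for i in range(ln):
                    votes[tp + i][seg[qp + i]] += 1
                qp += ln
                tp += ln
            elif op == "I":
                ins_votes[tp][seg[qp:qp + ln]] += 1
                qp += ln
            else:  # D
                for i in range(ln):
                    votes[tp + i][""] += 1
                tp += ln
    half = len(segments) / 2
    out: list[str] = []
    for i in range(n):
        ins, k = (ins_votes[i].most_common(1) or [("", 0)])[0]
        if k > half:
            out.append(ins)
        base, k = votes[i].most_common(1)[0]
        out.append(base)
    ins, k = (ins_votes[n].most_common(1) or [("", 0)])[0]
    if k > half:
        out.append(ins)
    return "".join(out)


def bridge_contigs(
    a: Replicon,
    b: Replicon,
    long_reads: Sequence[Replicon],
    min_anchor: int = 500,
    min_span_reads: int = 3,
    max_gap_disagreement: int = 10,
    params: ParamSet | None = None,
) -> tuple[Replicon, int]:
    """Join two linear contigs across a gap using corrected long reads.

    Reads anchoring >= *min_anchor* matched bases on a's 3' terminus and on
    b's 5' terminus vote on the intervening sequence; at least
    *min_span_reads* concordant spanning reads are required (gap lengths
    within +-*max_gap_disagreement* of each other). An overlap between a
    and b (directly, or a negative read-voted gap) is resolved by trimming
    b's start. Raises :class:`FinishError` ("unbridged" / "ambiguous gap").
    """
    params = params or ParamSet()
    W = max((len(r.seq) for r in long_reads), default=10_000) + 2_000
    wa = a.seq[-min(W, len(a.seq)):]
    wb = b.seq[: min(W, len(b.seq))]

    # a and b may simply overlap; check before consulting reads
    direct = align_pair(wb, wa, k=params.anchor_k, min_anchor=min_anchor,
                        qid=b.id, tid=a.id)
    if (direct is not None and direct.strand == "+"
            and direct.qspan[0] == 0
            and direct.tspan[1] == len(wa)
            and direct.aligned_cols() >= min_anchor
            and direct.identity >= 0.99):
        trim = direct.qspan[1]
        merged = Replicon(id=f"{a.id}+{b.id}", seq=a.seq + b.seq[trim:],
                          topology="linear",
                          notes=f"joined {a.id} and {b.id} (overlap {trim} bp)")
        return merged, 0

    idx_a = TargetIndex(wa, params.anchor_k)
    idx_b = TargetIndex(wb, params.anchor_k)
    spans: list[tuple[int, str]] = []   # (gap length, gap sequence)
    for read in long_reads:
        ba = align_pair(read.seq, wa, k=params.anchor_k, index=idx_a,
                        min_anchor=min_anchor, qid=read.id, tid=a.id)
        if ba is None or ba.matches < min_anchor or ba.tspan[1] != len(wa):
            continue
        bb = align_pair(read.seq, wb, k=params.anchor_k, index=idx_b,
                        min_anchor=min_anchor, qid=read.id, tid=b.id)
        if bb is None or bb.matches < min_anchor or bb.tspan[0] != 0:
            continue
        if ba.strand != bb.strand:
            continue
        oriented = read.seq if ba.strand == "+" else revcomp(read.seq)
        ra = ba.qspan[1]    # read position at a's 3' end
        rb = bb.qspan[0]    # read position at b's 5' start
        spans.append((rb - ra, oriented[ra:rb] if rb > ra else ""))

    if len(spans) < min_span_reads:
        raise FinishError("unbridged")
    lengths = [g for g, _ in spans]
    med = statistics.median(lengths)
    if max(lengths) - min(lengths) > 2 * max_gap_disagreement or any(
            abs(g - med) > max_gap_disagreement for g in lengths):
        raise FinishError("ambiguous gap")

    if med <= 0:
        trim = int(round(-med))
        merged_seq = a.seq + b.seq[trim:]
        gap_filled = 0
        note = f"joined {a.id} and {b.id} (read-voted overlap {trim} bp)"
    else:
        consensus = _star_consensus([s for g, s in spans if g > 0])
        merged_seq = a.seq + consensus + b.seq
        gap_filled = len(consensus)
        note = f"joined {a.id} and {b.id} (gap {gap_filled} bp, " \
               f"{len(spans)} spanning reads)"
    merged = Replicon(id=f"{a.id}+{b.id}", seq=merged_seq, topology="linear",
                      notes=note)
    return merged, gap_filled


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict) -> FinishedSet:
    """Run the full finishing pipeline from a configuration mapping.

    Recognised keys (paths may be replaced by in-memory Replicon lists):

    ``draft``            long-read draft FASTA / replicons (required)
    ``contigs``          high-accuracy contig FASTA / replicons
    ``reads``            corrected long reads FASTA / replicons
    ``calls_a, calls_b`` VariantCandidate lists from two callers
    ``coverage``         BED-graph path or (positions, depths) for the draft
    ``bridge_pairs``     explicit [(id_a, id_b), ...] to bridge
    ``params``           ParamSet (or dict of overrides)
    ``strict``           raise on stage errors instead of logging (default False)
    ``seed``             recorded in the provenance log

    Stage order: flag artifacts -> contig correction -> terminus extension
    -> read-call correction -> circularization -> TIR detection + coverage
    changepoint -> bridging.
    """
    from .seqmodel import read_fasta, read_bedgraph

    def load(key) -> list[Replicon]:
        val = config.get(key)
        if val is None:
            return []
        if isinstance(val, (str,)) or hasattr(val, "__fspath__"):
            return read_fasta(val)
        return list(val)

    params = config.get("params") or ParamSet()
    if isinstance(params, dict):
        params = ParamSet(**params)
    strict = bool(config.get("strict", False))
    drafts = load("draft")
    contigs = load("contigs")
    reads = load("reads")
    fs = FinishedSet(replicons=[], reports={})
    fs.log.append(StageRecord("config", {"seed": config.get("seed", 0),
                                         "strict": strict}))

    def guard(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            if strict:
                raise
            fs.log.append(StageRecord(stage, {}, {"error": str(exc)}))
            return None

    # 1. artifact flagging
    genuine = contigs
    if contigs and drafts:
        parts = flag_artifact_contigs(contigs, drafts,
                                      band=params.artifact_ident_band,
                                      params=params)
        genuine = parts["genuine"]
        unplaced = parts["unplaced"]
        fs.reports["artifacts"] = {k: [c.id for c in v] for k, v in parts.items()}
        fs.log.append(StageRecord(
            "flag_artifact_contigs",
            {"band": params.artifact_ident_band},
            {k: len(v) for k, v in parts.items()}))
    else:
        unplaced = []

    # 2. contig-based correction + 3. terminus extension, per draft replicon
    finished: list[Replicon] = []
    for draft in drafts:
        rep = draft
        if genuine:
            result = guard("correct_with_contigs", correct_with_contigs,
                           rep, genuine, params)
            if result is not None:
                rep, report = result
                fs.reports[f"polish:{draft.id}"] = report
                fs.log.append(StageRecord(
                    "correct_with_contigs", {"draft": draft.id},
                    {"corrections": report.total_corrections}))
            for end in ("5prime", "3prime"):
                result = guard("extend_terminus", extend_terminus, rep, genuine,
                               end, params.min_overlap, params.tir_min_ident,
                               params)
                if result is not None:
                    rep, added = result
                    fs.log.append(StageRecord(
                        "extend_terminus", {"draft": draft.id, "end": end},
                        {"bases_added": added}))
        finished.append(rep)

    # 4. read-call correction
    calls_a = config.get("calls_a")
    calls_b = config.get("calls_b")
    if calls_a is not None or calls_b is not None:
        for i, rep in enumerate(finished):
            ca = [c for c in (calls_a or []) if c.tid == rep.id]
            cb = [c for c in (calls_b or []) if c.tid == rep.id]
            if not ca and not cb:
                continue
            rep2, report = correct_with_read_calls(rep, ca, cb, params)
            finished[i] = rep2
            fs.reports[f"read_polish:{rep.id}"] = report
            fs.log.append(StageRecord(
                "correct_with_read_calls", {"draft": rep.id},
                {"corrections": report.total_corrections}))

    # 5-6. topology per replicon
    for i, rep in enumerate(finished):
        if len(rep.seq) > 2 * 1000:
            hit = guard("detect_terminal_direct_repeat",
                        topology.detect_terminal_direct_repeat, rep,
                        min_ident=params.tir_min_ident)
            if hit is not None:
                finished[i] = topology.circularize(rep, hit)
                fs.reports[f"circular:{rep.id}"] = hit
                fs.log.append(StageRecord(
                    "circularize", {"replicon": rep.id},
                    {"repeat_len": hit.span_b[1] - hit.span_b[0],
                     "circular_len": len(finished[i].seq)}))
                continue
        tir = guard("detect_tir", topology.detect_tir, rep,
                    min_ident=params.tir_min_ident)
        notes = []
        if tir is not None:
            fs.reports[f"tir:{rep.id}"] = tir
            notes.append(f"TIR fragment {tir.length} bp")
            fs.log.append(StageRecord("detect_tir", {"replicon": rep.id},
                                      {"length": tir.length}))
        cov = config.get("coverage")
        if cov is not None and i == 0:
            if isinstance(cov, (str,)) or hasattr(cov, "__fspath__"):
                pos, depth = read_bedgraph(cov)
                track = topology.CoverageTrack(pos, depth, source=str(cov))
            elif isinstance(cov, topology.CoverageTrack):
                track = cov
            else:
                track = topology.CoverageTrack(cov[0], cov[1])
            est = guard("estimate_tir_boundary",
                        topology.estimate_tir_boundary, track)
            if est is not None:
                fs.reports[f"tir_boundary:{rep.id}"] = est
                fs.log.append(StageRecord(
                    "estimate_tir_boundary", {"replicon": rep.id},
                    {"boundary": est[0], "ratio": est[1]}))
        rep = finished[i]
        if rep.topology == "unknown":
            finished[i] = Replicon(rep.id, rep.seq, "linear",
                                   (rep.notes + "; " + "; ".join(notes)).strip("; "))

    # 7. bridging
    pairs = config.get("bridge_pairs")
    if pairs is None and len(unplaced) == 2:
        pairs = [(unplaced[0].id, unplaced[1].id)]
    if pairs and reads:
        pool = {c.id: c for c in contigs}
        for ida, idb in pairs:
            a, b = pool[ida], pool[idb]
            merged = None
            for first, second in ((a, b), (b, a)):
                try:
                    merged, gap = bridge_contigs(
                        first, second, reads,
                        min_anchor=config.get("min_anchor", 500),
                        min_span_reads=config.get("min_span_reads", 3),
                        params=params)
                    break
                except FinishError as exc:
                    last_err = exc
            if merged is None:
                if strict:
                    raise last_err
                fs.log.append(StageRecord("bridge_contigs",
                                          {"pair": (ida, idb)},
                                          {"error": str(last_err)}))
            else:
                finished.append(merged)
                fs.log.append(StageRecord("bridge_contigs",
                                          {"pair": (ida, idb)},
                                          {"gap_filled": gap,
                                           "merged_len": len(merged.seq)}))

    fs.replicons = finished
    return fs
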