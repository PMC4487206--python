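"""Anchor-based pairwise alignment and variant-candidate extraction.

The aligner seeds on k-mers that are unique in the target (repeat-masked
seeding), merges co-diagonal seeds into maximal exact anchors, chains the
best collinear subset, and closes inter-anchor gaps with banded edit-distance
alignment (edlib). End overhangs are extended semi-globally and trimmed back
to the best-scoring prefix so a partial terminal repeat does not drag random
sequence into the block.

Edit scripts are runs of ``=`` (match), ``X`` (mismatch), ``I`` (base present
in the query only) and ``D`` (base present in the target only). Indels are
left-aligned within homopolymers before being reported as variant
candidates, so positions are deterministic and the dual-caller intersection
key is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .seqmodel import ParamSet, revcomp, seq_to_codes

Runs = list[tuple[str, int]]

_Q_OPS = {"=", "X", "I"}   # ops that consume query
_T_OPS = {"=", "X", "D"}   # ops that consume target


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match seeded at target-unique k-mers.

    ``qpos`` is a coordinate on the *oriented* query: the query itself for
    ``+`` anchors, its reverse complement for ``-`` anchors.
    """

    qpos: int
    tpos: int
    length: int
    strand: str = "+"


@dataclass
class AlignmentBlock:
    """A chained, extended alignment with an explicit edit script.

    ``qspan`` is expressed on the oriented query (see :class:`Anchor`);
    :meth:`qspan_original` converts back to original query coordinates.
    """

    qid: str
    tid: str
    qlen: int
    tlen: int
    strand: str
    qspan: tuple[int, int]
    tspan: tuple[int, int]
    edits: Runs
    identity: float = 0.0
    matches: int = 0

    def __post_init__(self) -> None:
        m = sum(n for op, n in self.edits if op == "=")
        cols = sum(n for op, n in self.edits)
        self.matches = m
        self.identity = m / cols if cols else 0.0

    def qspan_original(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.qspan
        return (self.qlen - self.qspan[1], self.qlen - self.qspan[0])

    def aligned_cols(self) -> int:
        return sum(n for _, n in self.edits)

    def validate(self) -> None:
        qlen = sum(n for op, n in self.edits if op in _Q_OPS)
        tlen = sum(n for op, n in self.edits if op in _T_OPS)
        if qlen != self.qspan[1] - self.qspan[0]:
            raise AssertionError("edit script does not cover the query span")
        if tlen != self.tspan[1] - self.tspan[0]:
            raise AssertionError("edit script does not cover the target span")
        if not 0.0 <= self.identity <= 1.0:
            raise AssertionError("identity out of range")

    def to_paf(self) -> str:
        qs, qe = self.qspan_original()
        cigar = "".join(f"{n}{op}" for op, n in self.edits)
        return "\t".join(
            str(x)
            for x in (
                self.qid, self.qlen, qs, qe, self.strand,
                self.tid, self.tlen, self.tspan[0], self.tspan[1],
                self.matches, self.aligned_cols(),
                f"{self.identity:.6f}", cigar,
            )
        )


@dataclass
class VariantCandidate:
    """A single proposed edit to the target (draft) sequence.

    For indels exactly one of ``ref``/``alt`` is empty; substitutions have
    both of length 1. ``occ`` disambiguates repeated identical edits that a
    multi-base run decomposes into.
    """

    tid: str
    tpos: int
    ref: str
    alt: str
    kind: str            # insertion | deletion | substitution
    context: str = "other"   # gc_homopolymer | other
    support: set[str] = field(default_factory=set)
    frame_validated: str = "untested"  # yes | no | untested
    occ: int = 0

    def key(self) -> tuple:
        return (self.tid, self.tpos, self.kind, self.ref, self.alt, self.occ)


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (windows free of N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_n = codes == 4
    safe = np.where(is_n, 0, codes).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | safe[j : j + n]
    ncum = np.concatenate([[0], np.cumsum(is_n)])
    valid = (ncum[k:] - ncum[:-k]) == 0
    return out, valid


class TargetIndex:
    """Sorted index of the k-mers that occur exactly once in the target.

    Building the index is the expensive step for megabase targets; callers
    polishing many contigs against one draft should build it once and pass
    it to :func:`seed_anchors`.
    """

    def __init__(self, target: str, k: int = 21):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.target = target
        self.k = k
        codes = seq_to_codes(target)
        kmers, valid = _kmer_codes(codes, k)
        pos = np.nonzero(valid)[0]
        kmers = kmers[valid]
        order = np.argsort(kmers, kind="stable")
        skmers = kmers[order]
        spos = pos[order]
        if len(skmers) == 0:
            self.ucodes = skmers
            self.upos = spos
            return
        first = np.concatenate([[True], skmers[1:] != skmers[:-1]])
        last = np.concatenate([skmers[1:] != skmers[:-1], [True]])
        uniq = first & last
        self.ucodes = skmers[uniq]
        self.upos = spos[uniq]

    def match(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, target positions) of shared unique k-mers."""
        codes = seq_to_codes(query)
        kmers, valid = _kmer_codes(codes, self.k)
        qpos = np.nonzero(valid)[0]
        kmers = kmers[valid]
        if len(kmers) == 0 or len(self.ucodes) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        idx = np.searchsorted(self.ucodes, kmers)
        idx_c = np.minimum(idx, len(self.ucodes) - 1)
        hit = self.ucodes[idx_c] == kmers
        return qpos[hit].astype(np.int64), self.upos[idx_c[hit]].astype(np.int64)


def _merge_seeds(qpos: np.ndarray, tpos: np.ndarray, k: int, strand: str
                 ) -> list[Anchor]:
    """Merge co-diagonal consecutive seed hits into maximal anchors."""
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    dq, dd = qpos[order], diag[order]
    breaks = np.nonzero((np.diff(dd) != 0) | (np.diff(dq) != 1))[0] + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(dq)]])
    anchors = []
    for s, e in zip(starts, ends):
        q0 = int(dq[s])
        anchors.append(
            Anchor(qpos=q0, tpos=q0 + int(dd[s]), length=int(dq[e - 1]) - q0 + k,
                   strand=strand)
        )
    return anchors


def seed_anchors(query: str, target: str, k: int = 21,
                 index: TargetIndex | None = None) -> list[Anchor]:
    """All maximal exact matches seeded at target-unique k-mers, both strands.

    Returns anchors sorted by target position. A *k* longer than either
    sequence yields an empty list.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    if k > min(len(query), len(target)):
        return []
    if index is None:
        index = TargetIndex(target, k)
    elif index.k != k:
        raise ValueError("index was built with a different k")
    anchors: list[Anchor] = []
    qp, tp = index.match(query)
    anchors.extend(_merge_seeds(qp, tp, k, "+"))
    qp, tp = index.match(revcomp(query))
    anchors.extend(_merge_seeds(qp, tp, k, "-"))
    anchors.sort(key=lambda a: (a.tpos, a.qpos))
    return anchors


# ---------------------------------------------------------------------------
# chaining and extension
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str) -> Runs:
    runs: Runs = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            if runs and runs[-1][0] == ch:
                runs[-1] = (ch, runs[-1][1] + n)
            else:
                runs.append((ch, n))
            n = 0
    return runs


def _append_runs(dst: Runs, src: Iterable[tuple[str, int]]) -> None:
    for op, n in src:
        if n == 0:
            continue
        if dst and dst[-1][0] == op:
            dst[-1] = (op, dst[-1][1] + n)
        else:
            dst.append((op, n))


def _align_gap(qseg: str, tseg: str) -> Runs:
    if not qseg and not tseg:
        return []
    if not qseg:
        return [("D", len(tseg))]
    if not tseg:
        return [("I", len(qseg))]
    res = edlib.align(qseg, tseg, mode="NW", task="path")
    return _parse_cigar(res["cigar"])


_MATCH_SCORE, _DIFF_SCORE = 1, -5


def _trim_far_end(runs_from_far: Runs) -> tuple[Runs, int, int]:
    """Drop a poorly scoring far-end prefix of an end extension.

    *runs_from_far* is ordered from the far (unanchored) end towards the
    anchor. Returns the kept runs (same order), plus the query and target
    lengths that were trimmed away.
    """
    total = 0
    for op, n in runs_from_far:
        total += n * (_MATCH_SCORE if op == "=" else _DIFF_SCORE)
    # score of suffix starting at run i, scanning from the far end
    best_cut, best_score = 0, total
    prefix = 0
    for i, (op, n) in enumerate(runs_from_far):
        prefix += n * (_MATCH_SCORE if op == "=" else _DIFF_SCORE)
        if total - prefix > best_score:
            best_score = total - prefix
            best_cut = i + 1
    cut_q = sum(n for op, n in runs_from_far[:best_cut] if op in _Q_OPS)
    cut_t = sum(n for op, n in runs_from_far[:best_cut] if op in _T_OPS)
    return runs_from_far[best_cut:], cut_q, cut_t


def _extend_left(oq: str, target: str, q0: int, t0: int, band: int
                 ) -> tuple[Runs, int, int]:
    """Extend an alignment leftwards from (q0, t0).

    Returns (runs in forward order ending at the anchor, new qstart, new
    tstart). Never emits bases beyond the target start: a query prefix that
    outruns the target remains unaligned (the caller sees qstart > 0 with
    tstart == 0 — a candidate terminal overhang).
    """
    if q0 == 0:
        return [], 0, t0
    qpre = oq[:q0]
    ts = max(0, t0 - len(qpre) - band)
    tpre = target[ts:t0]
    if not tpre:
        return [], q0, t0
    rq, rt = qpre[::-1], tpre[::-1]
    if len(rq) <= len(rt):
        res = edlib.align(rq, rt, mode="SHW", task="path")
        runs_rev = _parse_cigar(res["cigar"])
        consumed_q = len(rq)
        consumed_t = res["locations"][0][1] + 1
    else:
        res = edlib.align(rt, rq, mode="SHW", task="path")
        runs_rev = [( {"I": "D", "D": "I"}.get(op, op), n)
                    for op, n in _parse_cigar(res["cigar"])]
        consumed_q = res["locations"][0][1] + 1
        consumed_t = len(rt)
    # runs_rev is anchor->far; flip to far->anchor for trimming
    runs_far = runs_rev[::-1]
    runs_far, cut_q, cut_t = _trim_far_end(runs_far)
    return runs_far, q0 - (consumed_q - cut_q), t0 - (consumed_t - cut_t)


def _extend_right(oq: str, target: str, qe: int, te: int, band: int
                  ) -> tuple[Runs, int, int]:
    """Mirror of :func:`_extend_left` for the 3' side."""
    if qe == len(oq):
        return [], qe, te
    qsuf = oq[qe:]
    tsuf = target[te : te + len(qsuf) + band]
    if not tsuf:
        return [], qe, te
    if len(qsuf) <= len(tsuf):
        res = edlib.align(qsuf, tsuf, mode="SHW", task="path")
        runs = _parse_cigar(res["cigar"])
        consumed_q = len(qsuf)
        consumed_t = res["locations"][0][1] + 1
    else:
        res = edlib.align(tsuf, qsuf, mode="SHW", task="path")
        runs = [({"I": "D", "D": "I"}.get(op, op), n)
                for op, n in _parse_cigar(res["cigar"])]
        consumed_q = res["locations"][0][1] + 1
        consumed_t = len(tsuf)
    runs_far = runs[::-1]
    runs_far, cut_q, cut_t = _trim_far_end(runs_far)
    return runs_far[::-1], qe + (consumed_q - cut_q), te + (consumed_t - cut_t)


def _chain(anchors: list[Anchor], band: int, k: int) -> list[Anchor]:
    """Best collinear chain: anchored bases minus gap penalties.

    Ties are broken towards the leftmost target start for determinism.
    """
    if len(anchors) > 4000:
        anchors = sorted(anchors, key=lambda a: -a.length)[:4000]
    anchors = sorted(anchors, key=lambda a: (a.qpos, a.tpos))
    n = len(anchors)
    score = [float(a.length) for a in anchors]
    prev = [-1] * n
    ov = k - 1
    for i in range(n):
        ai = anchors[i]
        for j in range(i - 1, -1, -1):
            aj = anchors[j]
            dq = ai.qpos - (aj.qpos + aj.length)
            dt = ai.tpos - (aj.tpos + aj.length)
            if dq < -ov or dt < -ov or ai.tpos <= aj.tpos:
                continue
            if abs(dq - dt) > band:
                continue
            gap = abs(dq - dt) * 2.0 + 0.01 * max(dq, dt, 0) + 0.5
            cand = score[j] + ai.length - gap
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    best = int(np.argmax(score)) if n else -1
    chain: list[Anchor] = []
    while best >= 0:
        chain.append(anchors[best])
        best = prev[best]
    chain.reverse()
    return chain


def chain_and_extend(
    anchors: Sequence[Anchor],
    query: str,
    target: str,
    band: int = 100,
    min_anchor: int = 100,
    qid: str = "query",
    tid: str = "target",
    k: int = 21,
) -> AlignmentBlock | None:
    """Chain anchors and produce a full alignment block, or None.

    The dominant strand (most anchored bases) is chained; gaps between
    consecutive chain anchors are closed with global edit-distance
    alignment, and the block is extended semi-globally at both ends.
    Returns None when fewer than *min_anchor* anchored bases chain.
    """
    if not anchors:
        return None
    by_strand = {"+": [], "-": []}
    for a in anchors:
        by_strand[a.strand].append(a)
    strand = max("+-", key=lambda s: sum(a.length for a in by_strand[s]))
    chain = _chain(by_strand[strand], band=band, k=k)
    if not chain or sum(a.length for a in chain) < min_anchor:
        return None
    oq = query if strand == "+" else revcomp(query)

    runs: Runs = []
    first = chain[0]
    left_runs, qstart, tstart = _extend_left(oq, target, first.qpos, first.tpos, band)
    _append_runs(runs, left_runs)
    cur_q, cur_t = first.qpos, first.tpos
    for a in chain:
        aq, at, alen = a.qpos, a.tpos, a.length
        if aq < cur_q or at < cur_t:
            trim = max(cur_q - aq, cur_t - at)
            aq, at, alen = aq + trim, at + trim, alen - trim
            if alen <= 0:
                continue
        _append_runs(runs, _align_gap(oq[cur_q:aq], target[cur_t:at]))
        _append_runs(runs, [("=", alen)])
        cur_q, cur_t = aq + alen, at + alen
    right_runs, qend, tend = _extend_right(oq, target, cur_q, cur_t, band)
    _append_runs(runs, right_runs)

    block = AlignmentBlock(
        qid=qid, tid=tid, qlen=len(query), tlen=len(target), strand=strand,
        qspan=(qstart, qend), tspan=(tstart, tend), edits=runs,
    )
    block.validate()
    return block


def align_pair(query: str, target: str, k: int = 21,
               index: TargetIndex | None = None, band: int = 100,
               min_anchor: int = 100, qid: str = "query", tid: str = "target"
               ) -> AlignmentBlock | None:
    """Convenience wrapper: seed, chain and extend in one call."""
    anchors = seed_anchors(query, target, k=k, index=index)
    return chain_and_extend(anchors, query, target, band=band,
                            min_anchor=min_anchor, qid=qid, tid=tid, k=k)


def trim_block_ends(block: AlignmentBlock, min_terminal_match: int = 15
                    ) -> AlignmentBlock | None:
    """Trim a block until both ends are match runs >= *min_terminal_match*.

    Used where a reported repeat extent must not include short coincidental
    matches beyond the true repeat boundary. Returns None if nothing
    survives.
    """
    edits = list(block.edits)
    qs, qe = block.qspan
    ts, te = block.tspan
    while edits and (edits[0][0] != "=" or edits[0][1] < min_terminal_match):
        op, n = edits.pop(0)
        if op in _Q_OPS:
            qs += n
        if op in _T_OPS:
            ts += n
    while edits and (edits[-1][0] != "=" or edits[-1][1] < min_terminal_match):
        op, n = edits.pop()
        if op in _Q_OPS:
            qe -= n
        if op in _T_OPS:
            te -= n
    if not edits:
        return None
    return AlignmentBlock(qid=block.qid, tid=block.tid, qlen=block.qlen,
                          tlen=block.tlen, strand=block.strand,
                          qspan=(qs, qe), tspan=(ts, te), edits=edits)


# ---------------------------------------------------------------------------
# variant extraction
# ---------------------------------------------------------------------------

def left_normalize(target: str, pos: int, kind: str, allele: str) -> int:
    """Left-align a single-base indel within a homopolymer.

    For an insertion *before* target position ``pos`` (or a deletion *of*
    target position ``pos``), shifting left is string-equivalent while the
    preceding target base equals the indel allele.
    """
    while pos > 0 and target[pos - 1] == allele:
        pos -= 1
    return pos


def classify_context(target: str, pos: int, kind: str, allele: str,
                     hp_min_run: int = 3) -> str:
    """gc_homopolymer iff the allele is a lone C/G whose run in the target
    (before editing, spanning the left-normalized site) is >= hp_min_run."""
    if kind == "substitution" or allele not in ("C", "G"):
        return "other"
    run = 0
    i = pos
    while i < len(target) and target[i] == allele:
        run += 1
        i += 1
    return "gc_homopolymer" if run >= hp_min_run else "other"


def diff_variants(block: AlignmentBlock, query: str, target: str,
                  params: ParamSet | None = None) -> list[VariantCandidate]:
    """Decompose a block's edit script into classified single-base candidates.

    Runs longer than one base are decomposed base-by-base; every indel is
    left-normalized before classification, and repeated identical edits at
    one site are distinguished by their ``occ`` ordinal.
    """
    params = params or ParamSet()
    oq = query if block.strand == "+" else revcomp(query)
    out: list[VariantCandidate] = []
    seen: dict[tuple, int] = {}

    def emit(tpos: int, ref: str, alt: str, kind: str) -> None:
        allele = alt if kind == "insertion" else ref
        if kind != "substitution":
            tpos = left_normalize(target, tpos, kind, allele)
            if kind == "deletion":
                ref = target[tpos]
                allele = ref
        ctx = classify_context(target, tpos, kind, allele, params.hp_min_run)
        base_key = (block.tid, tpos, kind, ref, alt)
        occ = seen.get(base_key, 0)
        seen[base_key] = occ + 1
        out.append(
            VariantCandidate(tid=block.tid, tpos=tpos, ref=ref, alt=alt,
                             kind=kind, context=ctx,
                             support={block.qid}, occ=occ)
        )

    qp, tp = block.qspan[0], block.tspan[0]
    for op, n in block.edits:
        if op == "=":
            qp += n
            tp += n
        elif op == "X":
            for i in range(n):
                emit(tp + i, target[tp + i], oq[qp + i], "substitution")
            qp += n
            tp += n
        elif op == "I":
            for i in range(n):
                emit(tp, "", oq[qp + i], "insertion")
            qp += n
        elif op == "D":
            for i in range(n):
                emit(tp + i, target[tp + i], "", "deletion")
            tp += n
        else:  # pragma: no cover
            raise ValueError(f"unknown edit op {op!r}")
    return out
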