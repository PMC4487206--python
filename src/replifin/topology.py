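"""Replicon topology resolution.

Three signals are handled:

* **terminal direct repeats** — a linear contig whose two ends carry the
  same sequence in the same orientation is the overlap artifact of a
  circular molecule; trimming one copy yields the true circle;
* **terminal inverted repeats (TIRs)** — linear actinomycete chromosomes
  carry near-identical reverse-complement copies at both ends; the
  sequence-level detection reports the exact aligned extent, while the full
  TIR extent is estimated separately from a coverage changepoint (collapsed
  repeat copies double the apparent depth);
* **terminal palindromes** — short inverted repeats near the termini with
  the potential to fold into secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .align import (TargetIndex, align_pair, seed_anchors, trim_block_ends,
                    _parse_cigar)
from .seqmodel import Replicon, revcomp


@dataclass
class RepeatHit:
    """A direct or inverted repeat between two spans of one sequence."""

    kind: str                    # direct | inverted
    span_a: tuple[int, int]      # 0-based half-open
    span_b: tuple[int, int]
    identity: float
    length: int                  # alignment length (columns)

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise ValueError(f"bad repeat kind {self.kind!r}")
        if not (self.span_a[1] <= self.span_b[0] or self.span_b[1] <= self.span_a[0]):
            raise ValueError("repeat spans overlap")

    def to_bed(self, chrom: str) -> str:
        score = int(round(self.identity * 1000))
        return (f"{chrom}\t{self.span_a[0]}\t{self.span_a[1]}\t{self.kind}_a\t{score}\t+\n"
                f"{chrom}\t{self.span_b[0]}\t{self.span_b[1]}\t{self.kind}_b\t{score}\t"
                f"{'-' if self.kind == 'inverted' else '+'}\n")


@dataclass
class CoverageTrack:
    """Stepped per-position sequencing depth."""

    positions: np.ndarray
    depth: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def _identity_from_cigar(cigar: str) -> tuple[float, int]:
    runs = _parse_cigar(cigar)
    cols = sum(n for _, n in runs)
    matches = sum(n for op, n in runs if op == "=")
    return (matches / cols if cols else 0.0), cols


def detect_terminal_direct_repeat(
    rep: Replicon,
    min_len: int = 1000,
    min_ident: float = 0.99,
    search_window: int = 20_000,
    k: int = 21,
) -> RepeatHit | None:
    """Find a terminal-anchored direct repeat (circularity signal).

    The first *search_window* bases are seeded against the last
    *search_window*; candidate repeat lengths come from the supported
    diagonals and each is verified by global alignment of the two terminal
    copies. The longest candidate with identity >= *min_ident* wins.
    """
    L = len(rep.seq)
    if L <= 2 * min_len:
        raise ValueError("replicon too short for the requested repeat length")
    W = min(search_window, L // 2)
    prefix = rep.seq[:W]
    suffix = rep.seq[L - W:]
    anchors = [a for a in seed_anchors(prefix, suffix, k=k) if a.strand == "+"]
    if not anchors:
        return None
    support: dict[int, int] = {}
    for a in anchors:
        d = a.tpos - a.qpos
        support[d] = support.get(d, 0) + a.length
    # repeat length implied by diagonal d: prefix[i] pairs with suffix[i+d]
    cands = sorted(
        {W - d for d, bases in support.items()
         if bases >= min(200, min_len // 2) and min_len <= W - d <= W},
        reverse=True,
    )
    for r in cands:
        res = edlib.align(rep.seq[:r], rep.seq[L - r:], mode="NW", task="path")
        ident, cols = _identity_from_cigar(res["cigar"])
        if ident >= min_ident:
            return RepeatHit(kind="direct", span_a=(0, r), span_b=(L - r, L),
                             identity=ident, length=cols)
    return None


def circularize(rep: Replicon, hit: RepeatHit) -> Replicon:
    """Trim the 3' copy of a terminal direct repeat and declare a circle.

    The 5' copy is kept and the origin set at former position 0; the
    resulting length is the original minus one repeat copy.
    """
    L = len(rep.seq)
    if hit.kind != "direct":
        raise ValueError("circularization needs a direct repeat")
    if hit.span_a[0] != 0 or hit.span_b[1] != L:
        raise ValueError("repeat hit is not terminal-anchored")
    trim = hit.span_b[1] - hit.span_b[0]
    if trim <= 0:
        raise ValueError("degenerate repeat of length 0")
    out = Replicon(
        id=rep.id,
        seq=rep.seq[: L - trim],
        topology="circular",
        notes=(rep.notes + f"; circularized: trimmed {trim} bp 3' repeat copy"
               ).lstrip("; "),
    )
    return out


def detect_tir(
    rep: Replicon,
    min_len: int = 1000,
    min_ident: float = 0.99,
    search_window: int = 20_000,
    k: int = 21,
) -> RepeatHit | None:
    """Detect a terminal inverted repeat fragment.

    The reverse complement of the 3'-terminal window is aligned against the
    5' half of the sequence; the hit must be anchored at the 3' terminus,
    but the 5' span need not be terminal (it may end well inside the
    sequence when only a fragment of the right TIR was assembled).
    """
    L = len(rep.seq)
    W = min(search_window, L // 2)
    if W < min_len:
        return None
    query = revcomp(rep.seq[L - W:])
    target = rep.seq[: L // 2]
    block = align_pair(query, target, k=k, min_anchor=min(200, min_len),
                       qid="tir_query", tid=rep.id)
    if block is None or block.strand != "+":
        return None
    block = trim_block_ends(block)
    if block is None:
        return None
    qs, qe = block.qspan
    # the hit must be (near-)anchored at the 3' terminus; the small slack
    # tolerates a trimmed terminal mismatch in noisy repeats
    if qs > 50 or qe - qs < min_len or block.identity < min_ident:
        return None
    # query position i maps to original position L-1-i
    span_b = (L - qe, L - qs)
    hit = RepeatHit(kind="inverted", span_a=block.tspan, span_b=span_b,
                    identity=block.identity, length=block.aligned_cols())
    return hit


def estimate_tir_boundary(
    cov: CoverageTrack,
    min_ratio: float = 1.5,
    min_var_reduction: float = 0.2,
) -> tuple[int, float] | None:
    """Two-segment changepoint fit to a coverage track.

    An assembly whose left TIR absorbed the reads of both TIR copies shows
    roughly doubled depth over the repeat extent. The single changepoint
    minimizing total squared error is found exhaustively; the fit is
    reported as (boundary position, mean-depth ratio first/second segment)
    and rejected (None) when the ratio is < *min_ratio* or the variance
    reduction versus a flat fit is < *min_var_reduction*.
    """
    y = cov.depth
    n = len(y)
    if n < 10:
        raise ValueError("coverage track too short (need >= 10 points)")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    ks = np.arange(1, n)
    sse_left = c2[ks] - c1[ks] ** 2 / ks
    nr = n - ks
    sse_right = (c2[n] - c2[ks]) - (c1[n] - c1[ks]) ** 2 / nr
    total = sse_left + sse_right
    k = int(np.argmin(total))
    kk = k + 1
    mean_left = c1[kk] / kk
    mean_right = (c1[n] - c1[kk]) / (n - kk)
    sse1 = c2[n] - c1[n] ** 2 / n
    if sse1 <= 0:
        return None
    var_reduction = 1.0 - total[k] / sse1
    if mean_right <= 0:
        return None
    ratio = mean_left / mean_right
    if ratio < min_ratio or var_reduction < min_var_reduction:
        return None
    return int(cov.positions[kk]), float(ratio)


def find_terminal_palindromes(
    rep: Replicon,
    window: int = 1000,
    min_arm: int = 8,
    max_loop: int = 50,
) -> list[RepeatHit]:
    """Exact-arm inverted repeats (hairpins) within each terminal window.

    Every maximal arm >= *min_arm* with loop <= *max_loop* is reported,
    sorted by arm length descending. Spans are absolute coordinates on the
    replicon; ``span_a`` is the left arm and ``span_b`` the right arm.
    """
    L = len(rep.seq)
    w = min(window, L)
    regions = [(0, rep.seq[:w])]
    if L > w:
        regions.append((L - w, rep.seq[L - w:]))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": None}
    hits: list[RepeatHit] = []
    seen: set[tuple] = set()
    for offset, s in regions:
        n = len(s)
        for i in range(1, n):          # loop starts at i
            for loop in range(0, max_loop + 1):
                j = i + loop           # right arm starts at j
                arm = 0
                while (i - 1 - arm >= 0 and j + arm < n
                       and comp[s[i - 1 - arm]] == s[j + arm]):
                    arm += 1
                if arm >= min_arm:
                    span_a = (offset + i - arm, offset + i)
                    span_b = (offset + j, offset + j + arm)
                    key = (span_a, span_b)
                    if key not in seen:
                        seen.add(key)
                        hits.append(RepeatHit(kind="inverted", span_a=span_a,
                                              span_b=span_b, identity=1.0,
                                              length=arm))
    # drop hits entirely nested inside a longer hit with the same centre
    hits.sort(key=lambda h: (-h.length, h.span_a))
    kept: list[RepeatHit] = []
    for h in hits:
        nested = any(
            k.span_a[0] <= h.span_a[0] and h.span_b[1] <= k.span_b[1]
            and k.span_a[1] - k.span_a[0] > h.span_a[1] - h.span_a[0]
            and k.span_a[1] == h.span_a[1] and k.span_b[0] == h.span_b[0]
            for k in kept
        )
        if not nested:
            kept.append(h)
    return kept


def write_bed(hits: list[RepeatHit], chrom: str, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_bed(chrom))
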