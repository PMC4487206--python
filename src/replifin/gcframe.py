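"""Frame-specific GC profiling and frameshift detection.

In high-GC coding sequence the three codon positions carry very different
GC content (the third position especially is GC-rich), so plotting GC%
separately at positions congruent to 0, 1 and 2 mod 3 makes reading frames
visible without any annotation. A single-base indel inside a gene shifts
which absolute-position class is dominant downstream of the indel — a
frameshift signal that can be used to validate candidate corrections.

Classes are absolute position mod 3, not gene-relative frames: no
annotation exists at correction time, and a frameshift shows as a class
transition regardless of phase labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import VariantCandidate
from .seqmodel import revcomp, seq_to_codes

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class FrameProfile:
    """Windowed GC fractions per position-mod-3 class.

    ``gc`` has shape (n_windows, 3); ``dominant`` is the per-window argmax
    class and ``margin`` the gap between the top and second class.
    """

    centers: np.ndarray
    gc: np.ndarray
    dominant: np.ndarray
    margin: np.ndarray
    window: int
    step: int

    @property
    def gc1(self) -> np.ndarray:
        return self.gc[:, 0]

    @property
    def gc2(self) -> np.ndarray:
        return self.gc[:, 1]

    @property
    def gc3(self) -> np.ndarray:
        return self.gc[:, 2]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tgc1\tgc2\tgc3\tdominant\n")
            for i, c in enumerate(self.centers):
                fh.write(
                    f"{int(c) + 1}\t{self.gc[i,0]:.4f}\t{self.gc[i,1]:.4f}"
                    f"\t{self.gc[i,2]:.4f}\t{int(self.dominant[i])}\n"
                )


@dataclass(frozen=True)
class FrameBreak:
    """A transition of the dominant mod-3 class between stable segments."""

    position: int
    from_frame: int
    to_frame: int
    confidence: float

    def __post_init__(self) -> None:
        if self.from_frame == self.to_frame:
            raise ValueError("from_frame must differ from to_frame")


def frame_gc_profile(seq: str, window: int = 360, step: int = 30) -> FrameProfile:
    """Per-window GC fraction at each absolute-position-mod-3 class.

    *window* must be a multiple of 3 (each class then contributes exactly
    window/3 positions per window) and no longer than the sequence.
    """
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    if window % 3 != 0:
        raise ValueError("window must be a multiple of 3")
    codes = seq_to_codes(seq)
    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    starts = np.arange(0, n - window + 1, step)
    per_class = window // 3
    gc = np.empty((len(starts), 3), dtype=np.float64)
    for c in range(3):
        mask = np.zeros(n, dtype=np.int64)
        mask[c::3] = is_gc[c::3]
        cum = np.concatenate([[0], np.cumsum(mask)])
        counts = cum[starts + window] - cum[starts]
        # windows not starting at a multiple of 3 still contain exactly
        # window/3 positions of each class
        gc[:, c] = counts / per_class
    dominant = np.argmax(gc, axis=1)
    sorted_gc = np.sort(gc, axis=1)
    margin = sorted_gc[:, 2] - sorted_gc[:, 1]
    centers = starts + window // 2
    return FrameProfile(centers=centers, gc=gc, dominant=dominant,
                        margin=margin, window=window, step=step)


def detect_frame_breaks(profile: FrameProfile, min_margin: float = 0.1,
                        min_run: int = 3) -> list[FrameBreak]:
    """Dominant-class transitions flanked by stable segments.

    A break is reported between consecutive confident segments (>= *min_run*
    windows holding one class with margin >= *min_margin*) whose classes
    differ; its position is the midpoint of the transition window pair and
    its confidence the smaller flanking segment's mean margin.
    """
    if len(profile.centers) == 0:
        raise ValueError("empty profile")
    conf = profile.margin >= min_margin
    segments: list[tuple[int, int, int, float]] = []  # (frame, i0, i1, mean margin)
    i = 0
    n = len(profile.centers)
    while i < n:
        if not conf[i]:
            i += 1
            continue
        j = i
        while j < n and conf[j] and profile.dominant[j] == profile.dominant[i]:
            j += 1
        if j - i >= min_run:
            segments.append(
                (int(profile.dominant[i]), i, j,
                 float(profile.margin[i:j].mean()))
            )
        i = j
    breaks: list[FrameBreak] = []
    for (fa, _, a_end, ma), (fb, b_start, _, mb) in zip(segments, segments[1:]):
        if fa == fb:
            continue
        pos = int((profile.centers[a_end - 1] + profile.centers[b_start]) // 2)
        breaks.append(FrameBreak(position=pos, from_frame=fa, to_frame=fb,
                                 confidence=min(ma, mb)))
    return breaks


def _longest_orf_over(seq: str, site: int) -> int:
    """Longest stop-free stretch (bases) overlapping *site*, any of 6 frames.

    Start codons are not required: validation only needs stop-free stretch
    growth, mirroring manual amino-acid-level inspection.
    """
    best = 0
    n = len(seq)
    for forward in (True, False):
        s = seq if forward else revcomp(seq)
        site_f = site if forward else n - 1 - site
        for frame in range(3):
            stops = [frame - 3]  # sentinel before the sequence
            for p in range(frame, n - 2, 3):
                if s[p : p + 3] in STOPS:
                    stops.append(p)
            stops.append(n)  # sentinel past the end
            for a, b in zip(stops, stops[1:]):
                start = a + 3
                if start <= site_f < b or (start <= site_f + 1 and site_f < b):
                    best = max(best, b - start)
    return best


def frame_repair_score(
    seq: str,
    candidate: VariantCandidate,
    flank: int = 3000,
    window: int = 360,
    step: int = 30,
    min_margin: float = 0.1,
    min_orf_growth: int = 300,
) -> tuple[float, str]:
    """Score whether applying *candidate* repairs a local frameshift.

    Verdict ``yes`` iff (a) a frame break within +-window of the site before
    editing disappears after editing, or (b) the longest stop-free reading
    frame overlapping the site grows by >= *min_orf_growth* bases. The score
    is the removed break confidence plus ORF growth in codons. The
    candidate's ``frame_validated`` field is set as a side effect.
    """
    pos = candidate.tpos
    if candidate.ref == candidate.alt:
        candidate.frame_validated = "no"
        return 0.0, "no"
    a = max(0, pos - flank)
    b = min(len(seq), pos + flank)
    region = seq[a:b]
    local = pos - a
    edited = _apply_single(region, local, candidate)

    score = 0.0
    verdict = "no"
    if len(region) >= window and len(edited) >= window:
        before = detect_frame_breaks(
            frame_gc_profile(region, window, step), min_margin)
        after = detect_frame_breaks(
            frame_gc_profile(edited, window, step), min_margin)
        near_before = [br for br in before if abs(br.position - local) <= window]
        near_after = [br for br in after if abs(br.position - local) <= window]
        if near_before and not near_after:
            score += max(br.confidence for br in near_before)
            verdict = "yes"
    orf_before = _longest_orf_over(region, local)
    orf_after = _longest_orf_over(edited, min(local, len(edited) - 1))
    growth = orf_after - orf_before
    if growth >= min_orf_growth:
        verdict = "yes"
    if growth > 0:
        score += growth / 3.0
    candidate.frame_validated = verdict
    return score, verdict


def _apply_single(region: str, local: int, cand: VariantCandidate) -> str:
    if cand.kind == "insertion":
        return region[:local] + cand.alt + region[local:]
    if cand.kind == "deletion":
        return region[:local] + region[local + len(cand.ref):]
    return region[:local] + cand.alt + region[local + len(cand.ref):]
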