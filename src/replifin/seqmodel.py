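"""Core sequence types, coordinate conventions, and FASTA/BED-graph I/O.

Conventions used throughout the package:

* internal coordinates are 0-based, half-open;
* user-facing reports (VCF, summaries) are 1-based inclusive;
* sequences are upper-case strings over the 5-letter alphabet ``ACGTN``.

A circular replicon is stored linearized from a defined origin and its
length is the true circle length (no duplicated terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-value lookup used by the numpy helpers: A=0 C=1 G=2 T=3 N=4
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGTN", range(5)):
    _CODE_LUT[_b] = _c
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


class SequenceError(ValueError):
    """Raised for malformed sequence input (illegal characters, bad FASTA)."""


def clean_seq(seq: str, strict: bool = True) -> str:
    """Upper-case *seq* and validate it against the 5-letter alphabet.

    With ``strict=False``, lower-case and IUPAC ambiguity codes other than
    N are mapped to N instead of raising.
    """
    s = seq.upper()
    if set(s) <= ALPHABET:
        return s
    if strict:
        bad = sorted(set(s) - ALPHABET)
        raise SequenceError(f"illegal sequence characters: {bad!r}")
    return "".join(c if c in ALPHABET else "N" for c in s)


@dataclass
class Replicon:
    """A named DNA molecule with declared topology and provenance notes."""

    id: str
    seq: str
    topology: str = "unknown"  # linear | circular | unknown
    notes: str = ""

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular", "unknown"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.seq = clean_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def with_seq(self, seq: str, note: str = "") -> "Replicon":
        out = replace(self, seq=seq)
        if note:
            out.notes = (self.notes + "; " + note).lstrip("; ")
        return out


@dataclass
class ParamSet:
    """Shared tuning parameters.

    hp_min_run
        minimum length of a G/C homopolymer run (on the sequence being
        corrected) for an indel to be classified ``gc_homopolymer``.
    tir_min_ident
        identity threshold for terminal inverted repeat calls.
    artifact_ident_band
        identity band inside which a contig is flagged as an error
        accumulation artifact of the long-read assembler.
    gc_window / gc_step
        window and step for GC% and GC-skew tracks.
    anchor_k
        seed k-mer length for the anchor-based aligner.
    """

    hp_min_run: int = 3
    tir_min_ident: float = 0.99
    artifact_ident_band: tuple[float, float] = (0.80, 0.95)
    gc_window: int = 10_000
    gc_step: int = 200
    anchor_k: int = 21
    min_overlap: int = 1000
    min_anchor: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hp_min_run < 2:
            raise ValueError("hp_min_run must be >= 2")
        lo, hi = self.artifact_ident_band
        for frac in (self.tir_min_ident, lo, hi):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if lo > hi:
            raise ValueError("artifact_ident_band must be (low, high)")
        if self.gc_window <= 0 or self.gc_step <= 0:
            raise ValueError("gc window/step must be positive")


def revcomp(seq: str) -> str:
    """Reverse complement over ACGTN (N maps to N)."""
    s = seq.upper()
    if not set(s) <= ALPHABET:
        bad = sorted(set(s) - ALPHABET)
        raise SequenceError(f"illegal sequence characters: {bad!r}")
    return s.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if codes.max(initial=0) == 255:
        raise SequenceError("illegal sequence characters in encoded input")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """Overall G+C fraction of *seq* (N excluded from the denominator)."""
    codes = seq_to_codes(seq)
    acgt = int(np.sum(codes < 4))
    if acgt == 0:
        return 0.0
    gc = int(np.sum((codes == 1) | (codes == 2)))
    return gc / acgt


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Deliberately a small strict codec rather than a Bio.SeqIO wrapper: the
# contract here includes line-number error reporting and strict alphabet
# enforcement with an explicit N-mapping opt-out.
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, strict: bool = True) -> list[Replicon]:
    """Read a (possibly multi-record) FASTA file into Replicons.

    Record ids are taken from the header up to the first whitespace;
    topology is ``unknown``. Malformed headers or illegal characters raise
    :class:`SequenceError` naming the offending line.
    """
    path = Path(path)
    replicons: list[Replicon] = []
    rid: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if rid is not None:
            replicons.append(Replicon(id=rid, seq="".join(chunks)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise SequenceError(f"{path}:{lineno}: empty FASTA header")
                rid = header.split()[0]
                chunks = []
            else:
                if rid is None:
                    raise SequenceError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                try:
                    chunks.append(clean_seq(line, strict=strict))
                except SequenceError as exc:
                    raise SequenceError(f"{path}:{lineno}: {exc}") from None
    flush()
    return replicons


def write_fasta(
    replicons: Iterable[Replicon], path: str | Path, width: int = 70
) -> None:
    """Write Replicons as wrapped FASTA; inverse of :func:`read_fasta`."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, len(rep.seq), width):
                fh.write(rep.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# windowed GC tracks
# ---------------------------------------------------------------------------

@dataclass
class GCTracks:
    """Windowed GC-fraction and GC-skew tracks (window starts, stepped)."""

    starts: np.ndarray
    gc: np.ndarray      # (G+C)/window, in [0, 1]
    skew: np.ndarray    # (G-C)/(G+C), in [-1, 1]; 0 when G+C == 0
    window: int
    step: int


def gc_tracks(rep: Replicon, window: int | None = None, step: int | None = None,
              params: ParamSet | None = None) -> GCTracks:
    """Sliding-window GC% and GC-skew ``(G-C)/(G+C)`` over a replicon.

    All-AT windows report skew 0 by convention so the track is total.
    """
    params = params or ParamSet()
    window = window if window is not None else params.gc_window
    step = step if step is not None else params.gc_step
    n = len(rep.seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    if step < 1:
        raise ValueError("step must be >= 1")
    codes = seq_to_codes(rep.seq)
    is_g = np.concatenate([[0], np.cumsum(codes == 2)])
    is_c = np.concatenate([[0], np.cumsum(codes == 1)])
    starts = np.arange(0, n - window + 1, step)
    g = is_g[starts + window] - is_g[starts]
    c = is_c[starts + window] - is_c[starts]
    gc = (g + c) / window
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return GCTracks(starts=starts, gc=gc, skew=skew, window=window, step=step)


# ---------------------------------------------------------------------------
# BED-graph style coverage input (chrom, start, end, depth; 0-based half-open)
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, chrom: str | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Read a BED-graph coverage file, returning (positions, depths).

    Each interval contributes its start position; intervals must be sorted.
    If *chrom* is given, only matching rows are used.
    """
    positions: list[int] = []
    depths: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SequenceError(f"{path}:{lineno}: expected 4 columns")
            if chrom is not None and parts[0] != chrom:
                continue
            positions.append(int(parts[1]))
            depths.append(float(parts[3]))
    return np.asarray(positions, dtype=np.int64), np.asarray(depths)
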