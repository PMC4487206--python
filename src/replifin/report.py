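"""Assembly statistics and human-readable summaries.

The estimated full chromosome size accounts for a collapsed terminal
inverted repeat: when only a fragment of the right TIR made it into the
assembly, the full length is the assembled length minus that fragment plus
one whole TIR copy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .finish import FinishedSet
from .polish import CorrectionReport
from .seqmodel import Replicon, gc_fraction


def estimated_chromosome_size(assembled_len: int, right_tir_fragment: int,
                              tir_len: int) -> int:
    """Assembled length - assembled right-TIR fragment + full TIR copy."""
    if not 0 <= right_tir_fragment <= tir_len <= assembled_len:
        raise ValueError(
            "need 0 <= right_tir_fragment <= tir_len <= assembled_len")
    return assembled_len - right_tir_fragment + tir_len


def correction_rate(report: CorrectionReport) -> float:
    """Corrections per 100 bases of the final assembly (a percentage)."""
    if report.after_len <= 0:
        raise ValueError("empty assembly")
    return 100.0 * report.total_corrections / report.after_len


def format_correction_rate(report: CorrectionReport) -> str:
    """Display form, 5 decimal places (e.g. ``0.03768 %``)."""
    return f"{correction_rate(report):.5f} %"


@dataclass
class AssemblyStats:
    replicon_id: str
    length: int
    gc_percent: float
    topology: str
    tir_len: int | None = None
    estimated_full_length: int | None = None

    def row(self) -> str:
        tir = str(self.tir_len) if self.tir_len is not None else "-"
        est = (str(self.estimated_full_length)
               if self.estimated_full_length is not None else str(self.length))
        return (f"{self.replicon_id}\t{self.length}\t{self.gc_percent:.2f}"
                f"\t{self.topology}\t{tir}\t{est}")


def stats_table(fs: FinishedSet) -> tuple[str, list[AssemblyStats]]:
    """Per-replicon length / GC% / topology / TIR summary (text + records)."""
    rows: list[AssemblyStats] = []
    for rep in fs.replicons:
        tir = fs.reports.get(f"tir:{rep.id}")
        boundary = fs.reports.get(f"tir_boundary:{rep.id}")
        tir_len = None
        est = None
        if tir is not None:
            tir_len = tir.length
            full_tir = boundary[0] if boundary is not None else tir_len
            est = estimated_chromosome_size(len(rep.seq), tir_len,
                                            max(full_tir, tir_len))
        rows.append(AssemblyStats(
            replicon_id=rep.id, length=len(rep.seq),
            gc_percent=100.0 * gc_fraction(rep.seq),
            topology=rep.topology, tir_len=tir_len,
            estimated_full_length=est))
    header = "replicon\tlength\tGC%\ttopology\tTIR\testimated_full_length"
    text = "\n".join([header] + [r.row() for r in rows])
    return text, rows


def stats_json(fs: FinishedSet) -> str:
    _, rows = stats_table(fs)
    return json.dumps([r.__dict__ for r in rows], indent=2)
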