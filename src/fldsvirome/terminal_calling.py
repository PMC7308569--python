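"""Contig screening and terminal-end calling.

FLDS library construction ligates adapters onto the true ends of dsRNA
molecules, so sequencing reads pile up exactly at genome-segment
termini.  A contig position is recognised as a terminal end when more
than ten reads share it as their alignment terminus (≥11 with the
default config); contigs with both termini called — after passing the
length (≥500 bp) and coverage (≥3×) screens — are classified as
full-length potential genome segments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .alignment import CoverageProfile
from .config import PipelineConfig
from .errors import ConsistencyError, ParameterError

__all__ = [
    "SegmentRecord",
    "screen_contigs",
    "call_termini",
    "classify_contigs",
    "summarize_segments",
]


@dataclass(frozen=True)
class SegmentRecord:
    """One contig/segment with its screening and terminal-call status."""

    seq_id: str
    sequence: str
    mean_coverage: float
    terminus5_called: bool = False
    terminus3_called: bool = False
    status: str = "pending"  # pending | full_length | partial | discarded

    @property
    def length(self) -> int:
        return len(self.sequence)


def screen_contigs(contigs: dict[str, str],
                   profiles: dict[str, CoverageProfile],
                   config: PipelineConfig | None = None) -> list[SegmentRecord]:
    """Apply the length/coverage screen; failures become ``discarded``.

    Both thresholds read as "at least": a 500-bp contig at exactly 3×
    mean coverage is retained (status ``pending``, awaiting terminal
    calling).
    """
    config = config or PipelineConfig()
    records: list[SegmentRecord] = []
    for cid in contigs:
        if cid not in profiles:
            raise ConsistencyError(f"no coverage profile for contig {cid!r}")
        cov = profiles[cid].mean_coverage
        ok = len(contigs[cid]) >= config.min_contig_len and cov >= config.min_mean_cov
        records.append(SegmentRecord(
            seq_id=cid, sequence=contigs[cid], mean_coverage=cov,
            status="pending" if ok else "discarded"))
    return records


def call_termini(profile: CoverageProfile,
                 config: PipelineConfig | None = None) -> tuple[bool, bool]:
    """Call the 5' and 3' termini of one contig from its end pileups.

    The 5' terminus is called when at least ``terminal_min_reads``
    alignments start at position 0 (or within the ±W tolerance window,
    default W=0); symmetrically for the 3' terminus at the last base.
    """
    config = config or PipelineConfig()
    w = config.terminal_tolerance
    n = len(profile.starts5)
    if n == 0:
        return False, False
    head = profile.starts5[: w + 1]
    tail = profile.ends3[max(0, n - 1 - w):]
    t5 = bool((head >= config.terminal_min_reads).any())
    t3 = bool((tail >= config.terminal_min_reads).any())
    return t5, t3


def classify_contigs(contigs: dict[str, str],
                     profiles: dict[str, CoverageProfile],
                     config: PipelineConfig | None = None) -> list[SegmentRecord]:
    """Screen contigs, call termini, and set final statuses.

    ``full_length``: screen passed and both termini called;
    ``partial``: screen passed, at most one terminus (such contigs stay
    in the analysis — their RdRps still count); ``discarded``: screen
    failed.
    """
    config = config or PipelineConfig()
    out: list[SegmentRecord] = []
    for rec in screen_contigs(contigs, profiles, config):
        if rec.status == "discarded":
            out.append(rec)
            continue
        t5, t3 = call_termini(profiles[rec.seq_id], config)
        status = "full_length" if (t5 and t3) else "partial"
        out.append(replace(rec, terminus5_called=t5, terminus3_called=t3,
                           status=status))
    return out


def summarize_segments(records: list[SegmentRecord]) -> dict[str, int]:
    """Counts per status; the headline full-length segment tally."""
    if not records:
        raise ParameterError("no records to summarize")
    counts = Counter(r.status for r in records)
    return {s: counts.get(s, 0) for s in ("full_length", "partial", "discarded")}


def segments_table(records: list[SegmentRecord],
                   profiles: dict[str, CoverageProfile]) -> pd.DataFrame:
    """TSV-ready segment table (one row per contig)."""
    rows = []
    for r in records:
        p = profiles[r.seq_id]
        rows.append({
            "seq_id": r.seq_id,
            "length": r.length,
            "mean_coverage": round(r.mean_coverage, 3),
            "starts5_at_0": int(p.starts5[0]) if len(p.starts5) else 0,
            "ends3_at_end": int(p.ends3[-1]) if len(p.ends3) else 0,
            "status": r.status,
        })
    return pd.DataFrame(rows)
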