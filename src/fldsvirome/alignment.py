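"""Read mapping, SAM ingestion and coverage/end-pileup profiles.

The built-in mapper (exact 21-mer seeding + ungapped extension with
mismatch counting) is deliberately minimal: it is sound and complete for
the substitution-only reads the simulator produces, and real-data users
ingest SAM produced by any external mapper instead.  Each read reports
at most one best location; ties break deterministically by
(reference id, start, strand).

The :class:`CoverageProfile` carries, besides per-base depth, the
per-position counts of alignment 5'-most starts and 3'-most ends on the
reference — the raw signal for terminal-end calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .errors import ConsistencyError, FormatError, ParameterError
from .seqtools import revcomp

__all__ = [
    "ReadAlignment",
    "CoverageProfile",
    "KmerIndex",
    "map_reads",
    "read_sam",
    "write_sam",
    "pileup",
]

SEED_K = 21


@dataclass(frozen=True)
class ReadAlignment:
    """One read placed on a reference; 0-based half-open coordinates."""

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError("alignment interval must satisfy start < end")
        if self.strand not in "+-":
            raise FormatError("strand must be '+' or '-'")


@dataclass
class CoverageProfile:
    """Per-base depth plus read start/end pileups on one reference."""

    ref_id: str
    depth: np.ndarray
    starts5: np.ndarray
    ends3: np.ndarray

    @property
    def mean_coverage(self) -> float:
        return float(self.depth.sum() / len(self.depth)) if len(self.depth) else 0.0

    @property
    def n_alignments(self) -> int:
        return int(self.starts5.sum())


class KmerIndex:
    """Exact k-mer index over a reference set (forward strand)."""

    def __init__(self, refs: dict[str, str], k: int = SEED_K):
        if not refs:
            raise ParameterError("reference set must be nonempty")
        self.k = k
        self.refs = {rid: seq.upper() for rid, seq in refs.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for rid in sorted(self.refs):
            seq = self.refs[rid]
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((rid, i))


def _candidates(idx: KmerIndex, seq: str) -> set[tuple[str, int]]:
    k = idx.k
    cands: set[tuple[str, int]] = set()
    offsets = list(range(0, len(seq) - k + 1, k))
    if offsets and offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    for off in offsets:
        for rid, pos in idx.index.get(seq[off : off + k], ()):
            start = pos - off
            if start >= 0 and start + len(seq) <= len(idx.refs[rid]):
                cands.add((rid, start))
    return cands


def map_reads(reads: list[tuple[str, str, str]] | list[tuple[str, str]],
              refs: dict[str, str], min_identity: float = 0.95,
              k: int = SEED_K) -> list[ReadAlignment]:
    """Map reads to references; best hit per read, both strands searched.

    A read is placed where an exact k-mer seed anchors an ungapped
    full-length extension with identity ≥ ``min_identity``; among
    co-best candidates the (lowest ref id, lowest start, '+' before '-')
    one wins.  Unmappable reads are silently dropped.
    """
    if not (0.5 < min_identity <= 1.0):
        raise ParameterError("min_identity must be in (0.5, 1]")
    idx = KmerIndex(refs, k)
    out: list[ReadAlignment] = []
    for rec in reads:
        rid, seq = rec[0], rec[1].upper()
        if len(seq) < k:
            continue
        best: tuple[int, str, int, str] | None = None  # (mm, ref, start, strand)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for ref, start in _candidates(idx, s):
                ref_seq = idx.refs[ref]
                mm = sum(a != b for a, b in zip(s, ref_seq[start : start + len(s)]))
                key = (mm, ref, start, strand)
                if best is None or key < best:
                    best = key
        if best is not None and 1.0 - best[0] / len(seq) >= min_identity:
            mm, ref, start, strand = best
            out.append(ReadAlignment(rid, ref, start, start + len(seq), strand, mm))
    return out


def write_sam(alignments: list[ReadAlignment], refs: dict[str, str],
              path: str) -> None:
    """Write alignments as minimal SAM (header @SQ lines, FLAG/POS/CIGAR)."""
    names = sorted(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(refs[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            if aln.ref_id not in tid:
                raise FormatError(f"alignment to unknown reference {aln.ref_id!r}")
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = tid[aln.ref_id]
            a.reference_start = aln.start
            a.mapping_quality = 60
            a.cigarstring = f"{aln.end - aln.start}M"
            a.set_tag("NM", aln.n_mismatches)
            fh.write(a)


def read_sam(path: str) -> list[ReadAlignment]:
    """Read a SAM file into internal alignments.

    SAM 1-based coordinates become 0-based half-open; the terminal
    positions of an alignment are its reference start/end, so soft clips
    do not move them.  FLAG 16 yields strand '-'.
    """
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, "r") as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for rec in fh:
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in lengths:
                raise FormatError(f"alignment to unknown reference {ref!r}")
            if rec.reference_end > lengths[ref]:
                raise FormatError(
                    f"alignment beyond end of reference {ref!r}")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(ReadAlignment(
                rec.query_name, ref, rec.reference_start, rec.reference_end,
                "-" if rec.is_reverse else "+", int(nm)))
    return out


def pileup(alignments: list[ReadAlignment], ref_len: int,
           ref_id: str) -> CoverageProfile:
    """Per-base depth and per-position 5'-start / 3'-end counts.

    Invariants: sum(depth) equals the summed alignment lengths, and
    sum(starts5) = sum(ends3) = number of alignments.
    """
    depth_diff = np.zeros(ref_len + 1, dtype=np.int64)
    starts = np.zeros(ref_len, dtype=np.int64)
    ends = np.zeros(ref_len, dtype=np.int64)
    for aln in alignments:
        if aln.ref_id != ref_id:
            raise ConsistencyError(
                f"alignment on {aln.ref_id!r} given to pileup of {ref_id!r}")
        if aln.end > ref_len:
            raise ConsistencyError(
                f"alignment [{aln.start},{aln.end}) exceeds ref length {ref_len}")
        depth_diff[aln.start] += 1
        depth_diff[aln.end] -= 1
        starts[aln.start] += 1
        ends[aln.end - 1] += 1
    depth = np.cumsum(depth_diff[:-1])
    return CoverageProfile(ref_id=ref_id, depth=depth, starts5=starts, ends3=ends)


def pileup_all(alignments: list[ReadAlignment],
               refs: dict[str, str]) -> dict[str, CoverageProfile]:
    """One CoverageProfile per reference (empty profile when unmapped)."""
    by_ref: dict[str, list[ReadAlignment]] = {r: [] for r in refs}
    for aln in alignments:
        if aln.ref_id not in by_ref:
            raise ConsistencyError(f"alignment to unknown reference {aln.ref_id!r}")
        by_ref[aln.ref_id].append(aln)
    return {r: pileup(by_ref[r], len(refs[r]), r) for r in refs}
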