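"""Grouping full-length segments into putative complete genome sets.

Segments of one multipartite RNA virus share conserved 5' and 3'
terminal sequences.  Full-length segments are therefore grouped by
single-linkage clustering on the relation "terminal identity ≥ threshold
at both ends" (terminal windows of 20 nt, ≥80% identity by default; the
windows are compared 5'-to-5' and 3'-to-3' with both sequences oriented
5'→3').  Groups are then validated: GC% spread below 5 percentage
points, no cross-member ORF pair above 50% amino-acid identity, and a
coverage-dominance report (sets whose members all exceed 1000× mean
coverage, plus each set's share of the summed coverage over all
RdRp-encoding records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .annotation import Orf, protein_similarity
from .config import PipelineConfig
from .errors import ParameterError
from .seqtools import gc_percent, nt_identity
from .terminal_calling import SegmentRecord

__all__ = [
    "GenomeSet",
    "terminal_similarity",
    "group_segments",
    "validate_genome_set",
    "coverage_dominance",
    "segment_roster_stats",
]


@dataclass
class GenomeSet:
    """A group of full-length segments inferred to form one viral genome."""

    set_id: str
    members: list[str]
    consensus_terminal5: str
    consensus_terminal3: str
    gc_range: tuple[float, float]
    total_length: int
    min_member_cov: float
    gc_ok: bool | None = None
    orf_ok: bool | None = None
    dominant: bool | None = None
    offending_members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def terminal_similarity(a: SegmentRecord, b: SegmentRecord,
                        window: int = 20) -> tuple[float, float]:
    """Percent identity of the two 5' windows and of the two 3' windows.

    Identity comes from global alignment of the window sequences
    (1 − editdist/window length, in percent).  Both sequences are taken
    as already oriented 5'→3'.
    """
    for rec in (a, b):
        if rec.length < window:
            raise ParameterError(
                f"window {window} exceeds length of {rec.seq_id!r}")
    id5 = 100.0 * nt_identity(a.sequence[:window], b.sequence[:window])
    id3 = 100.0 * nt_identity(a.sequence[-window:], b.sequence[-window:])
    return id5, id3


def _consensus(seqs: list[str]) -> str:
    out = []
    for col in zip(*seqs):
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(out)


def group_segments(segments: list[SegmentRecord],
                   config: PipelineConfig | None = None,
                   threshold: float | None = None) -> list[GenomeSet]:
    """Single-linkage grouping of full-length segments by shared termini.

    Two segments link when both their 5' and their 3' window identities
    reach the grouping threshold; the transitive closure of that
    relation partitions the input (singletons allowed — a monopartite
    virus is a one-segment set).  ``threshold`` (a fraction; may exceed
    1 to force all-singleton output) overrides the config value.
    """
    config = config or PipelineConfig()
    thr = 100.0 * (config.terminal_identity if threshold is None else threshold)
    w = config.terminal_window
    segs = sorted(segments, key=lambda s: s.seq_id)
    n = len(segs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            id5, id3 = terminal_similarity(segs[i], segs[j], w)
            if id5 >= thr and id3 >= thr:
                parent[find(i)] = find(j)
    clusters: dict[int, list[SegmentRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(segs[i])
    ordered = sorted(clusters.values(), key=lambda c: c[0].seq_id)
    sets = []
    for k, members in enumerate(ordered):
        gcs = [gc_percent(m.sequence) for m in members]
        sets.append(GenomeSet(
            set_id=f"set{k + 1}",
            members=[m.seq_id for m in members],
            consensus_terminal5=_consensus([m.sequence[:w] for m in members]),
            consensus_terminal3=_consensus([m.sequence[-w:] for m in members]),
            gc_range=(min(gcs), max(gcs)),
            total_length=sum(m.length for m in members),
            min_member_cov=min(m.mean_coverage for m in members),
        ))
    return sets


def validate_genome_set(gset: GenomeSet, orfs_by_member: dict[str, list[Orf]],
                        config: PipelineConfig | None = None) -> GenomeSet:
    """Set the GC and ORF-redundancy flags on a genome set.

    ``gc_ok`` requires the within-set GC% spread to be strictly below
    ``gc_max_diff``.  ``orf_ok`` fails when any ORF pair from two
    different members exceeds ``orf_sim_max`` percent amino-acid
    identity (a duplicated gene across segments argues against the
    grouping); offending members are recorded.
    """
    config = config or PipelineConfig()
    gset.gc_ok = (gset.gc_range[1] - gset.gc_range[0]) < config.gc_max_diff
    offenders: set[str] = set()
    members = gset.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            for oa in orfs_by_member.get(members[i], []):
                for ob in orfs_by_member.get(members[j], []):
                    if protein_similarity(oa.protein, ob.protein) > config.orf_sim_max:
                        offenders.update((members[i], members[j]))
    gset.orf_ok = not offenders
    gset.offending_members = sorted(offenders)
    return gset


def coverage_dominance(sets: list[GenomeSet],
                       rdrp_records: list[tuple[str, float]],
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Coverage-dominance report over all RdRp-encoding records.

    ``rdrp_records`` lists (record id, mean coverage) for every
    RdRp-encoding segment or contig.  Each record's share of the summed
    mean coverage is reported (shares total 100%); a set is flagged
    dominant when all its members exceed ``dominance_cov``, and its
    share is the summed share of its member records.
    """
    config = config or PipelineConfig()
    if not rdrp_records:
        raise ParameterError("dominance share undefined: no RdRp records")
    total = sum(cov for _, cov in rdrp_records)
    if total <= 0:
        raise ParameterError("dominance share undefined: zero total coverage")
    member_of = {m: s.set_id for s in sets for m in s.members}
    rows = []
    for rid, cov in rdrp_records:
        rows.append({
            "record_id": rid,
            "set_id": member_of.get(rid, ""),
            "mean_coverage": cov,
            "share_percent": 100.0 * cov / total,
        })
    for s in sets:
        s.dominant = s.min_member_cov > config.dominance_cov
    return pd.DataFrame(rows)


def segment_roster_stats(segments: dict[str, str]) -> dict[str, int]:
    """Segment count and summed length of a genome's segment roster.

    Utility for checking a deposited multi-segment genome (e.g. a
    10-segment roster totalling its published genome length) or any
    reconstructed set exported as FASTA.
    """
    return {
        "n_segments": len(segments),
        "total_length": sum(len(s) for s in segments.values()),
    }
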