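"""ssRNA-seq read classification, host assignment and SSU composition.

Conventional (ssRNA) RNA-seq reflects what the sampled organism is
actively transcribing, so a virus whose reads exceed 0.1% of the
non-rRNA read pool is taken to infect the sampled organism (the host
assignment rule; strict ">").  Reads are classified by k-mer containment
against reference sets — a read is rRNA when ≥30% of its 21-mers occur
in the rRNA references, otherwise viral by the best-matching target
under the same rule, otherwise "other".  Per-virus fractions pool the
member segments of a genome set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .errors import ParameterError

from .seqtools import kmer_set

__all__ = [
    "ReadClassCounts",
    "HostCall",
    "classify_reads",
    "host_assignment",
    "ssu_composition",
]


@dataclass
class ReadClassCounts:
    """Read tallies per class; rrna + Σ viral + other = total."""

    total: int
    rrna: int
    viral_per_target: dict[str, int]
    other: int

    def __post_init__(self) -> None:
        if self.rrna + sum(self.viral_per_target.values()) + self.other != self.total:
            raise ParameterError("read class counts do not sum to total")

    @property
    def non_rrna(self) -> int:
        return self.total - self.rrna


@dataclass(frozen=True)
class HostCall:
    """Host-assignment verdict for one viral target."""

    target_id: str
    viral_reads: int
    frac_nonrrna: float  # percent of non-rRNA reads
    assigned: bool


def _containment(seq: str, kmers: set[str], k: int) -> float:
    n = len(seq) - k + 1
    if n <= 0:
        raise ParameterError("k-mer length exceeds read length")
    hits = sum(seq[i : i + k] in kmers for i in range(n))
    return hits / n


def classify_reads(reads: list[tuple[str, str, str]] | list[tuple[str, str]],
                   rrna_refs: dict[str, str],
                   viral_refs: dict[str, list[str]],
                   config: PipelineConfig | None = None) -> ReadClassCounts:
    """Classify reads as rRNA / viral-per-target / other.

    ``viral_refs`` maps a target (typically a genome set) to its member
    sequences, which are pooled into one k-mer set per target.  Both
    strands are indexed, so reverse-complement reads classify correctly.
    rRNA takes precedence; among viral targets the highest containment
    wins (ties by target id).
    """
    config = config or PipelineConfig()
    if not rrna_refs:
        raise ParameterError("rRNA reference set must be nonempty")
    k, thr = config.classify_k, config.classify_containment
    rrna_kmers = kmer_set(rrna_refs.values(), k)
    target_kmers = {t: kmer_set(seqs, k) for t, seqs in sorted(viral_refs.items())}
    rrna = other = 0
    per_target = {t: 0 for t in target_kmers}
    for rec in reads:
        seq = rec[1].upper()
        if _containment(seq, rrna_kmers, k) >= thr:
            rrna += 1
            continue
        best_t, best_c = None, thr
        for t, kmers in target_kmers.items():
            c = _containment(seq, kmers, k)
            if c > best_c or (c == best_c and c >= thr and best_t is None):
                best_t, best_c = t, c
        if best_t is None:
            other += 1
        else:
            per_target[best_t] += 1
    return ReadClassCounts(total=len(reads), rrna=rrna,
                           viral_per_target=per_target, other=other)


def host_assignment(counts: ReadClassCounts,
                    config: PipelineConfig | None = None) -> list[HostCall]:
    """Apply the >0.1%-of-non-rRNA-reads host rule per viral target.

    The fraction is viral reads / (total − rRNA) × 100; a target is
    assigned only when its fraction strictly exceeds ``host_min_frac``.
    """
    config = config or PipelineConfig()
    if counts.non_rrna <= 0:
        raise ParameterError("host fraction undefined: no non-rRNA reads")
    calls = []
    for target in sorted(counts.viral_per_target):
        n = counts.viral_per_target[target]
        frac = 100.0 * n / counts.non_rrna
        calls.append(HostCall(target_id=target, viral_reads=n,
                              frac_nonrrna=round(frac, 4),
                              assigned=frac > config.host_min_frac))
    return calls


def ssu_composition(reads: list[tuple[str, str, str]] | list[tuple[str, str]],
                    ssu_refs: dict[str, str],
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-reference composition of SSU-classified reads.

    Reads are assigned to the best-containment SSU reference (≥ the
    classifier threshold); fractions are over assigned reads and sum
    to 1.  An empty table is returned when no read classifies.
    """
    config = config or PipelineConfig()
    k, thr = config.classify_k, config.classify_containment
    ref_kmers = {r: kmer_set([s], k) for r, s in sorted(ssu_refs.items())}
    counts = {r: 0 for r in ref_kmers}
    for rec in reads:
        seq = rec[1].upper()
        best_r, best_c = None, thr
        for r, kmers in ref_kmers.items():
            c = _containment(seq, kmers, k)
            if c > best_c or (c == best_c and c >= thr and best_r is None):
                best_r, best_c = r, c
        if best_r is not None:
            counts[best_r] += 1
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["ref_id", "reads", "fraction"])
    return pd.DataFrame([
        {"ref_id": r, "reads": n, "fraction": n / total}
        for r, n in counts.items()
    ])
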