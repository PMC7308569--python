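"""Pipeline-wide numeric thresholds.

Every screening / calling / grouping rule in the pipeline reads its
threshold from a single :class:`PipelineConfig`, so a run is fully
described by one config object (serialised into the run manifest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Numeric rules applied along the dsRNA-seq virome pipeline.

    Attributes
    ----------
    min_contig_len:
        Minimum contig length (nt) to enter terminal calling; contigs
        shorter than this are discarded.
    min_mean_cov:
        Minimum mean per-base read coverage (×) for a contig; "at least"
        semantics, i.e. a contig at exactly this coverage is retained.
    terminal_min_reads:
        Minimum number of read ends piling up at a contig terminus for
        the position to be called a terminal end.  The rule is
        "more than 10 reads", hence the default of 11.
    terminal_tolerance:
        Tolerance window W (nt): a terminus is called if any position
        within W of the contig end carries the required pile-up.
        Default 0 (strict: exactly position 0 / len−1).
    terminal_window:
        Window (nt) of sequence compared when measuring terminal-sequence
        similarity between segments.
    terminal_identity:
        Minimum identity (fraction) at *both* ends for two full-length
        segments to be grouped into one genome set.
    otu_identity:
        Nucleotide identity (fraction) for greedy centroid OTU clustering
        of RdRp-encoding sequences.
    otu_min_len:
        Sequences of at most this length (nt) are dropped before OTU
        clustering (">1.5 kb" rule).
    dominance_cov:
        Coverage (×) above which a genome set counts as dominant.
    gc_max_diff:
        Maximum GC% spread (percentage points) within a genome set;
        the rule is strict ("difference < 5").
    orf_sim_max:
        Maximum cross-member ORF amino-acid identity (%) tolerated within
        a genome set; any pair *above* this fails validation.
    host_min_frac:
        Viral fraction of non-rRNA reads (%) that must be *exceeded*
        for a host assignment.
    map_min_identity:
        Minimum identity (fraction) for the built-in read mapper.
    classify_k:
        k-mer size used by the read classifier.
    classify_containment:
        Minimum fraction of a read's k-mers contained in a reference
        k-mer set for the read to be assigned to that class.
    min_orf_aa:
        Minimum ORF length (amino acids) reported by the ORF finder.
    variant_band:
        Maximum per-segment length difference (nt) accepted when aligning
        two versions of a genome.
    evalue_max:
        Recorded for provenance only (similarity-search cut-off used by
        the upstream annotation protocol); not consumed by this package.
    """

    min_contig_len: int = 500
    min_mean_cov: float = 3.0
    terminal_min_reads: int = 11
    terminal_tolerance: int = 0
    terminal_window: int = 20
    terminal_identity: float = 0.80
    otu_identity: float = 0.90
    otu_min_len: int = 1500
    dominance_cov: float = 1000.0
    gc_max_diff: float = 5.0
    orf_sim_max: float = 50.0
    host_min_frac: float = 0.1
    map_min_identity: float = 0.95
    classify_k: int = 21
    classify_containment: float = 0.3
    min_orf_aa: int = 100
    variant_band: int = 50
    evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        for name in (
            "min_contig_len", "min_mean_cov", "terminal_min_reads",
            "terminal_window", "otu_min_len", "dominance_cov",
            "gc_max_diff", "orf_sim_max", "host_min_frac",
            "classify_k", "min_orf_aa",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.terminal_tolerance < 0:
            raise ValueError("terminal_tolerance must be >= 0")
        for name in ("otu_identity", "map_min_identity",
                     "classify_containment", "terminal_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("pipeline", data))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"pipeline": self.to_dict()}, fh, sort_keys=False)
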