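"""SNV calling between two versions of a genome and Ti/Tv summary.

Two consensus genome versions (e.g. the same virus sampled in
consecutive years) are compared segment-by-segment with global
alignment; each mismatch column yields one single-nucleotide variant
record classified as a transition (A↔G, C↔T) or transversion.  Gap
columns are excluded from SNV records.  Positions are 0-based on the
first genome; the minimal VCF output converts to 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .errors import ConsistencyError, ParameterError
from .synthetic_data import TruthGenome

__all__ = [
    "VariantRecord",
    "align_versions",
    "call_snvs",
    "titv_summary",
    "write_vcf",
]

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide difference between two genome versions."""

    segment_id: str
    position: int  # 0-based on the first genome's segment
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ParameterError("ref and alt base must differ")

    @property
    def klass(self) -> str:
        return ("transition" if {self.ref_base, self.alt_base} in _TRANSITIONS
                else "transversion")


def _as_dict(genome: TruthGenome | dict[str, str]) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return genome.as_dict()


def align_versions(a: TruthGenome | dict[str, str],
                   b: TruthGenome | dict[str, str],
                   band: int = 50) -> dict[str, tuple[str, str]]:
    """Globally align matching segments of two genome versions.

    Requires identical segment rosters and per-segment length
    differences within ``band``.  Returns per-segment pairs of aligned
    (gapped) sequences; identical inputs yield gap-free identity
    alignments.
    """
    sa, sb = _as_dict(a), _as_dict(b)
    if set(sa) != set(sb):
        raise ConsistencyError(
            f"segment rosters differ: {sorted(set(sa) ^ set(sb))}")
    out: dict[str, tuple[str, str]] = {}
    for sid in sorted(sa):
        qa, qb = sa[sid].upper(), sb[sid].upper()
        if abs(len(qa) - len(qb)) > band:
            raise ConsistencyError(
                f"segment {sid!r} length difference exceeds band {band}")
        if len(qa) == len(qb):
            # consensus versions of equal length: positional comparison —
            # an optimal-edit path may co-optimally swap two mismatches for
            # an indel pair, which would misplace SNV columns
            out[sid] = (qa, qb)
        else:
            res = edlib.align(qb, qa, mode="NW", task="path")
            out[sid] = _expand_cigar(qa, qb, res["cigar"])
    return out


def _expand_cigar(ref: str, qry: str, cigar: str) -> tuple[str, str]:
    """Expand an extended cigar (=/X/I/D, query-vs-ref) into gapped strings."""
    ra, qa = [], []
    i = j = 0
    for n_str, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(n_str)
        if op in "=X":
            ra.append(ref[i : i + n])
            qa.append(qry[j : j + n])
            i += n
            j += n
        elif op == "D":  # consumes ref only (deletion in query)
            ra.append(ref[i : i + n])
            qa.append("-" * n)
            i += n
        else:  # "I": insertion in query
            ra.append("-" * n)
            qa.append(qry[j : j + n])
            j += n
    return "".join(ra), "".join(qa)


def call_snvs(alignments: dict[str, tuple[str, str]]) -> list[VariantRecord]:
    """One VariantRecord per mismatch column; gap columns are skipped."""
    variants: list[VariantRecord] = []
    for sid in sorted(alignments):
        aln_a, aln_b = alignments[sid]
        pos = 0
        for ca, cb in zip(aln_a, aln_b):
            if ca != "-" and cb != "-" and ca != cb:
                variants.append(VariantRecord(sid, pos, ca, cb))
            if ca != "-":
                pos += 1
    return variants


def titv_summary(variants: list[VariantRecord]) -> dict[str, float | int | None]:
    """Transition/transversion tally: {n, ti, tv, ti_percent}.

    ``ti_percent`` is reported as ``None`` when there are no variants.
    """
    n = len(variants)
    ti = sum(v.klass == "transition" for v in variants)
    return {
        "n": n,
        "ti": ti,
        "tv": n - ti,
        "ti_percent": (100.0 * ti / n) if n else None,
    }


def write_vcf(variants: list[VariantRecord], path: str,
              source: str = "fldsvirome") -> None:
    """Minimal VCF (CHROM, 1-based POS, REF, ALT, INFO klass)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=KLASS,Number=1,Type=String,'
                 'Description="transition or transversion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.segment_id}\t{v.position + 1}\t.\t{v.ref_base}\t"
                     f"{v.alt_base}\t.\tPASS\tKLASS={v.klass}\n")
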