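"""Small sequence helpers used throughout the package.

Coordinates are 0-based half-open everywhere inside the package;
conversion to 1-based conventions (SAM, VCF) happens only at I/O
boundaries.
"""

from __future__ import annotations

from typing import Iterable

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_NT = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    """GC content in percent (N bases count toward the denominator)."""
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    return 100.0 * gc / len(seq)


def nt_identity(a: str, b: str) -> float:
    """Global nucleotide identity in [0, 1].

    Defined as ``1 - editdistance(a, b) / max(len(a), len(b))`` — a
    function of the optimal edit distance only, hence independent of
    which co-optimal alignment a traceback would pick.
    """
    if not a or not b:
        raise FormatError("identity of an empty sequence is undefined")
    d = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def kmer_set(seqs: Iterable[str], k: int, both_strands: bool = True) -> set[str]:
    """Set of k-mers over one or more sequences (optionally both strands)."""
    out: set[str] = set()
    for seq in seqs:
        s = seq.upper()
        out.update(s[i : i + k] for i in range(len(s) - k + 1))
        if both_strands:
            r = revcomp(s)
            out.update(r[i : i + k] for i in range(len(r) - k + 1))
    return out


# --- FASTA / FASTQ plumbing (Biopython-backed) -------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """FASTA file → ordered {id: sequence} mapping."""
    recs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        recs[rec.id] = str(rec.seq).upper()
    return recs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    """FASTQ file → list of (id, sequence, quality-string)."""
    out = []
    try:
        for rec in SeqIO.parse(path, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ {path!r}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
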