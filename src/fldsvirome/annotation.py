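"""ORF finding, RdRp signature-motif scanning, protein identity and OTU clustering.

RNA viruses are recognised here by the conserved motif architecture of the
RNA-dependent RNA polymerase (RdRp): an aspartate-rich motif A
(``D-x(4,5)-D``), a motif B (``G-x(2,3)-T``) and the catalytic motif C
triplet (``[GSA]DD``, canonically GDD), in that order within a bounded
window.  RdRp-encoding nucleotide sequences are then collapsed into
operational taxonomic units (OTUs) by greedy centroid clustering at 90%
nucleotide identity, keeping only sequences longer than 1.5 kb.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .config import PipelineConfig
from .errors import FormatError
from .seqtools import VALID_NT, nt_identity, revcomp

__all__ = [
    "Orf",
    "RdRpHit",
    "RdRpOtu",
    "MotifTable",
    "find_orfs",
    "scan_rdrp_motifs",
    "protein_similarity",
    "cluster_rdrp_otus",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a nucleotide sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the parent; the interval includes the terminating stop
    codon when one exists.  ``frame`` is the reading frame on the strand
    the ORF was read from.
    """

    parent_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def orf_id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class MotifTable:
    """Regular-expression grammar for the RdRp signature motifs.

    The canonical catalytic triplet (motif C) must be corroborated by at
    least one upstream motif (A and/or B) within ``window`` residues;
    motif B is required to lie downstream of motif A when A is present.
    """

    motif_a: str = r"D.{4,5}D"
    motif_b: str = r"G.{2,3}T"
    motif_c: str = r"[GSA]DD"
    window: int = 150


@dataclass(frozen=True)
class RdRpHit:
    orf_ref: str
    motif_c_offset: int
    motif_c_seq: str
    motif_a_found: bool
    motif_b_found: bool

    @property
    def score(self) -> int:
        return 1 + int(self.motif_a_found) + int(self.motif_b_found)


@dataclass
class RdRpOtu:
    otu_id: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def member_count(self) -> int:
        return len(self.member_ids)


def _scan_strand(seq: str, strand: str, seq_len: int, min_aa: int,
                 parent_id: str) -> list[Orf]:
    orfs: list[Orf] = []
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if open_start is not None:
                    end = pos + 3
                    n_aa = (end - open_start) // 3 - 1
                    if n_aa >= min_aa:
                        orfs.append(_make_orf(seq, open_start, end, True,
                                              strand, frame, seq_len, parent_id))
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
            pos += 3
        if open_start is not None:
            end = pos  # last complete codon boundary in this frame
            n_aa = (end - open_start) // 3
            if n_aa >= min_aa:
                orfs.append(_make_orf(seq, open_start, end, False,
                                      strand, frame, seq_len, parent_id))
    return orfs


def _make_orf(strand_seq: str, s: int, e: int, has_stop: bool, strand: str,
              frame: int, seq_len: int, parent_id: str) -> Orf:
    coding = strand_seq[s : e - 3] if has_stop else strand_seq[s:e]
    protein = str(Seq(coding).translate())
    if strand == "+":
        start, end = s, e
    else:
        start, end = seq_len - e, seq_len - s
    return Orf(parent_id, start, end, strand, frame, protein)


def find_orfs(sequence: str, min_aa: int = 100, parent_id: str = "") -> list[Orf]:
    """Maximal ORFs on both strands (standard code, ATG start).

    An ORF starts at the first ATG following the previous in-frame stop
    and runs to the next stop codon, or to the last complete codon of the
    sequence when no stop intervenes.  Results are sorted by protein
    length (descending), then by forward-strand start.
    """
    seq = sequence.upper()
    if set(seq) - VALID_NT:
        bad = sorted(set(seq) - VALID_NT)
        raise FormatError(f"non-ACGTN characters in sequence: {bad}")
    n = len(seq)
    orfs = _scan_strand(seq, "+", n, min_aa, parent_id)
    orfs += _scan_strand(revcomp(seq), "-", n, min_aa, parent_id)
    orfs.sort(key=lambda o: (-len(o.protein), o.start, o.strand))
    return orfs


def scan_rdrp_motifs(protein: str, motifs: MotifTable | None = None) -> RdRpHit | None:
    """Scan a protein for the RdRp signature; ``None`` when absent.

    Motif C is the first ``[GSA]DD`` occurrence; a hit additionally
    requires motif A (``D-x(4,5)-D``) and/or motif B (``G-x(2,3)-T``)
    within ``window`` residues upstream of C, with B downstream of A
    whenever A is found.
    """
    motifs = motifs or MotifTable()
    c = re.search(motifs.motif_c, protein)
    if c is None:
        return None
    region = protein[max(0, c.start() - motifs.window) : c.start()]
    a = re.search(motifs.motif_a, region)
    b_space = region[a.end() :] if a else region
    b = re.search(motifs.motif_b, b_space)
    if a is None and b is None:
        return None
    return RdRpHit(
        orf_ref="",
        motif_c_offset=c.start(),
        motif_c_seq=c.group(),
        motif_a_found=a is not None,
        motif_b_found=b is not None,
    )


# --- global protein alignment ------------------------------------------------
#
# Needleman–Wunsch with linear gaps and a fixed traceback priority
# (diagonal > up > left), so the reported alignment — and hence the
# identity — is a deterministic function of the inputs.

def _nw_traceback(a: str, b: str, match: int, mismatch: int, gap: int
                  ) -> tuple[str, str]:
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    ptr = np.empty((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(m + 1)
    score[1:, 0] = gap * np.arange(1, n + 1)
    ptr[0, :] = 2
    ptr[1:, 0] = 1
    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + gap
        cand = np.maximum(diag, up)
        # row[j] = max(cand[j], row[j-1] + gap): prefix-max of cand - gap*j
        first = max(cand[0], score[i, 0] + gap)
        shifted = cand.astype(np.int64) - gap * jj
        shifted[0] = first - gap * 1
        row = np.maximum.accumulate(shifted) + gap * jj
        score[i, 1:] = row
        ptr[i, 1:] = np.where(row == diag, 0, np.where(row == up, 1, 2))
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def protein_similarity(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap: int = -2) -> float:
    """Percent identity of the global alignment of two proteins.

    Identity = matching columns / total alignment columns × 100, from a
    Needleman–Wunsch alignment with the given linear scores.
    """
    if not a or not b:
        raise FormatError("cannot align an empty protein")
    aln_a, aln_b = _nw_traceback(a, b, match, mismatch, gap)
    matches = sum(x == y for x, y in zip(aln_a, aln_b))
    return 100.0 * matches / len(aln_a)


def cluster_rdrp_otus(records: list[tuple[str, str]],
                      config: PipelineConfig | None = None) -> list[RdRpOtu]:
    """Greedy centroid clustering of RdRp-encoding nucleotide sequences.

    Records of length ≤ ``otu_min_len`` are dropped; the rest are visited
    by decreasing length (ties by id) and each joins the earliest-created
    centroid with nucleotide identity ≥ ``otu_identity``, otherwise it
    founds a new OTU.  Centroids are therefore pairwise below the
    identity threshold.
    """
    config = config or PipelineConfig()
    kept = [(rid, seq) for rid, seq in records if len(seq) > config.otu_min_len]
    kept.sort(key=lambda r: (-len(r[1]), r[0]))
    otus: list[RdRpOtu] = []
    centroids: list[str] = []
    for rid, seq in kept:
        for otu, cseq in zip(otus, centroids):
            if nt_identity(seq, cseq) >= config.otu_identity:
                otu.member_ids.append(rid)
                break
        else:
            otus.append(RdRpOtu(f"otu{len(otus) + 1:03d}", rid, [rid]))
            centroids.append(seq)
    return otus
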