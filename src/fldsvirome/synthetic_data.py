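"""Ground-truthed simulator for FLDS-style dsRNA-seq virome experiments.

The generator emulates the statistical structure the downstream pipeline
relies on, with full truth bookkeeping:

* multi-segment RNA virus genomes whose segments share conserved 5'/3'
  terminal sequences (the grouping signal), each genome carrying one
  RdRp-encoding segment and one labelled non-RdRp ORF per segment;
* a host background: one dominant host SSU rRNA, one minor eukaryote
  SSU, and a set of host mRNAs;
* dsRNA-seq read sets enriched for viral sequence (defaults ≈20% viral,
  ≈30% rRNA) whose read ends pile up at true segment termini — the FLDS
  terminal-preservation signature;
* ssRNA-seq read sets dominated by rRNA (≈80%) with rare viral reads
  (≈0.5%);
* mutated genome versions differing by a stated number of SNVs with a
  stated transition count, with a recorded mutation manifest.

Terminal pile-up model: fragments whose end coincides with a true
segment terminus are over-represented.  A terminal start position
aggregates two ligatable duplex ends (one per strand of the dsRNA), so
it receives sampling weight ``2 × terminal_end_boost`` against 1 for an
interior fragmentation point, and the anchored read counts are
apportioned deterministically (largest-remainder) so the pile-up depth
is a predictable function of coverage: ≈ 2·boost·coverage/read_len
reads start at position 0 of every segment (and symmetrically end at
the last base).

Every read gets exactly one truth record (read_id, source, 0-based
half-open interval, strand).  All randomness flows from ``SimParams.seed``
through independent :func:`numpy.random.default_rng` streams, so a seed
fully determines every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import find_orfs, scan_rdrp_motifs, protein_similarity
from .errors import ParameterError
from .seqtools import nt_identity, revcomp, write_fasta, write_fastq

__all__ = [
    "SimParams",
    "TruthGenome",
    "Background",
    "ReadSet",
    "Mutation",
    "generate_genomes",
    "generate_background",
    "simulate_dsrna_reads",
    "simulate_ssrna_reads",
    "mutate_genome",
    "make_decoys",
]

_NT = np.array(list("ACGT"))

# Codons per amino acid, standard code (used for back-translation).
_CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_STOP_CODONS = ["TAA", "TAG", "TGA"]
# Filler alphabet for designed proteins: no aspartate, so the RdRp motif
# grammar ([GSA]DD plus D-x(4,5)-D) can only arise where deliberately placed.
_FILLER_AA = np.array(list("ARNCQEGHILKMFPSTWYV".replace("D", "")))


@dataclass
class SimParams:
    """Study conditions for one simulated FLDS experiment.

    Defaults mirror the sponge-holobiont study design the pipeline
    targets: five viral genomes with segment counts 1, 2, 2, 10, 10;
    dsRNA-seq reads ≈20% viral / ≈30% rRNA; ssRNA-seq reads ≈80% rRNA /
    ≈0.5% viral; 250-nt single-end reads at 30× mean viral coverage.
    """

    segments_per_genome: Sequence[int] = (1, 2, 2, 10, 10)
    segment_len_range: tuple[int, int] = (1800, 4000)
    terminal_len: int = 20
    gc_targets: Sequence[float] = (0.36, 0.43, 0.50, 0.57, 0.64)
    dsrna_viral_frac: float = 0.20
    dsrna_rrna_frac: float = 0.30
    ssrna_rrna_frac: float = 0.80
    ssrna_viral_frac: float = 0.005
    # Share of the ssRNA viral read pool per genome; defaults put three of
    # the five genomes above the 0.1%-of-non-rRNA host-assignment threshold.
    ssrna_viral_split: Sequence[float] = (0.80, 0.10, 0.004, 0.09, 0.006)
    host_ssu_frac: float = 0.92
    read_len: int = 250
    coverage_mean: float = 30.0
    terminal_end_boost: float = 50.0
    subst_error_rate: float = 0.0
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return len(self.segments_per_genome)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.segments_per_genome):
            raise ParameterError("segment counts must be >= 1")
        if self.terminal_len < 10:
            raise ParameterError("terminal_len must be >= 10 nt")
        lo, hi = self.segment_len_range
        if lo < 600 or hi < lo:
            raise ParameterError("segment_len_range min must be >= 600 nt")
        if 2 * self.terminal_len >= lo:
            raise ParameterError("terminal_len too large for segment length")
        fracs = {
            "dsrna_viral_frac": self.dsrna_viral_frac,
            "dsrna_rrna_frac": self.dsrna_rrna_frac,
            "ssrna_rrna_frac": self.ssrna_rrna_frac,
            "ssrna_viral_frac": self.ssrna_viral_frac,
            "host_ssu_frac": self.host_ssu_frac,
            "subst_error_rate": self.subst_error_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.dsrna_viral_frac + self.dsrna_rrna_frac > 1.0:
            raise ParameterError("dsRNA class fractions sum above 1")
        if self.ssrna_viral_frac + self.ssrna_rrna_frac > 1.0:
            raise ParameterError("ssRNA class fractions sum above 1")
        if len(self.ssrna_viral_split) != self.n_genomes:
            raise ParameterError("ssrna_viral_split must have one entry per genome")
        if self.read_len >= lo:
            raise ParameterError("read_len must be below the minimum segment length")

    def to_json(self, path: str) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class TruthGenome:
    """One simulated segmented viral genome with its truth annotations."""

    genome_id: str
    segment_ids: list[str]
    segments: list[str]
    terminal5: str
    terminal3: str
    has_rdrp: bool
    gc_target: float
    rdrp_segment_index: int | None
    # (segment_index, orf_start, orf_end, is_rdrp) — designed, guaranteed ORFs
    orf_truth: list[tuple[int, int, int, bool]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.segments)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.segment_ids, self.segments))


@dataclass
class Background:
    """Host transcriptome stand-in: SSU rRNAs plus mRNAs."""

    rrna: dict[str, str]
    rrna_weights: dict[str, float]
    mrnas: dict[str, str]


@dataclass
class ReadSet:
    """Simulated reads plus their one-row-per-read truth alignment table."""

    reads: list[tuple[str, str, str]]
    truth: pd.DataFrame  # columns: read_id, ref_id, start, end, strand

    def write(self, fastq_path: str, truth_path: str) -> None:
        write_fastq(self.reads, fastq_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)


@dataclass(frozen=True)
class Mutation:
    segment_id: str
    position: int  # 0-based on the segment
    ref: str
    alt: str

    @property
    def is_transition(self) -> bool:
        return {self.ref, self.alt} in ({"A", "G"}, {"C", "T"})


# --- genome construction -----------------------------------------------------

def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _random_gc_block(rng: np.random.Generator, n: int, n_gc: int) -> str:
    """Random sequence of length n with exactly n_gc G/C bases."""
    n_gc = int(np.clip(n_gc, 0, n))
    strong = np.where(rng.integers(0, 2, n_gc) == 0, "G", "C")
    weak = np.where(rng.integers(0, 2, n - n_gc) == 0, "A", "T")
    arr = np.concatenate([strong, weak])
    rng.shuffle(arr)
    return "".join(arr)


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(_FILLER_AA[rng.integers(0, len(_FILLER_AA), n)])


def _make_rdrp_protein(rng: np.random.Generator) -> str:
    """Protein with motifs A (D-x(4,5)-D), B (G-x(2,3)-T) and C (GDD).

    Filler residues exclude aspartate, so the first [GSA]DD occurrence is
    the designed catalytic triplet.
    """
    a = "D" + _filler(rng, int(rng.integers(4, 6))) + "D"
    b = "G" + _filler(rng, int(rng.integers(2, 4))) + "T"
    return (
        "M" + _filler(rng, int(rng.integers(40, 61)))
        + a + _filler(rng, int(rng.integers(10, 21)))
        + b + _filler(rng, int(rng.integers(15, 31)))
        + "GDD" + _filler(rng, int(rng.integers(100, 141)))
    )


def _make_plain_protein(rng: np.random.Generator, existing: list[str]) -> str:
    """Non-RdRp protein, guaranteed motif-free and dissimilar to siblings."""
    while True:
        prot = "M" + _filler(rng, int(rng.integers(140, 241)))
        if scan_rdrp_motifs(prot) is not None:  # impossible without D; belt & braces
            continue
        if all(protein_similarity(prot, p) <= 40.0 for p in existing):
            return prot


def _distinct_terminal(rng: np.random.Generator, n: int, previous: list[str],
                       max_identity: float = 0.70) -> str:
    for _ in range(1000):
        cand = _random_nt(rng, n)
        if all(nt_identity(cand, p) < max_identity for p in previous):
            return cand
    raise ParameterError("could not draw mutually distinct terminal motifs")


def _build_segment(rng: np.random.Generator, prot: str, length: int,
                   t5: str, t3: str, gc_target: float) -> tuple[str, int, int]:
    """Assemble one segment: t5 | prefix | guard stop | ORF | suffix | t3.

    The in-frame stop immediately before the ORF's ATG guarantees the
    maximal-ORF finder reports exactly the designed protein.  The random
    prefix/suffix base composition is balanced so the whole segment hits
    the genome's GC target to the base.
    """
    orf_nt = _backtranslate(rng, prot) + _STOP_CODONS[rng.integers(0, 3)]
    min_prefix = 60
    guard = "TAA"
    terminal_len = len(t5)
    budget = length - 2 * terminal_len - len(orf_nt) - len(guard)
    if budget < min_prefix + 60:
        raise ParameterError("segment too short to host its ORF")
    prefix_len = int(rng.integers(min_prefix, budget - 59))
    suffix_len = budget - prefix_len
    orf_start = terminal_len + prefix_len + len(guard)
    orf_end = orf_start + len(orf_nt)
    target_gc = round(gc_target * length)
    fixed_gc = sum(s.count("G") + s.count("C") for s in (t5, t3, guard, orf_nt))
    block = _random_gc_block(rng, prefix_len + suffix_len, target_gc - fixed_gc)
    seq = t5 + block[:prefix_len] + guard + orf_nt + block[prefix_len:] + t3
    assert len(seq) == length
    return seq, orf_start, orf_end


def _rdrp_clean(seq: str, orf_start: int, orf_end: int, is_rdrp: bool,
                min_aa: int = 100) -> bool:
    """True when the only RdRp-positive ORFs are the designed one."""
    found_designed = False
    for orf in find_orfs(seq, min_aa):
        if scan_rdrp_motifs(orf.protein) is None:
            continue
        designed = (is_rdrp and orf.strand == "+"
                    and orf.start <= orf_start and orf_end <= orf.end)
        if not designed:
            return False
        found_designed = True
    return found_designed or not is_rdrp


def generate_genomes(params: SimParams) -> list[TruthGenome]:
    """Generate the truth roster of segmented viral genomes.

    Each genome gets distinct conserved 5'/3' terminal motifs (pairwise
    identity < 0.70 between genomes), every segment starts/ends with
    them, segment GC is pinned to the genome's target (exact base
    counts, so within-genome spread is < 0.2 percentage points), and
    exactly one segment per genome carries an RdRp-motif ORF; every
    other segment carries one labelled non-RdRp ORF.
    """
    rng = np.random.default_rng([params.seed, 1])
    lo, hi = params.segment_len_range
    genomes: list[TruthGenome] = []
    t5s: list[str] = []
    t3s: list[str] = []
    for gi, n_seg in enumerate(params.segments_per_genome):
        gc_target = params.gc_targets[gi % len(params.gc_targets)]
        t5 = _distinct_terminal(rng, params.terminal_len, t5s)
        t3 = _distinct_terminal(rng, params.terminal_len, t3s)
        t5s.append(t5)
        t3s.append(t3)
        gid = f"g{gi + 1}"
        seg_ids: list[str] = []
        segs: list[str] = []
        orf_truth: list[tuple[int, int, int, bool]] = []
        proteins: list[str] = []
        for si in range(n_seg):
            is_rdrp = si == 0
            if is_rdrp:
                prot = _make_rdrp_protein(rng)
            else:
                prot = _make_plain_protein(rng, proteins)
            proteins.append(prot)
            length = int(rng.integers(lo, hi + 1))
            # Random sequence occasionally spawns ORFs that satisfy the RdRp
            # grammar by chance; resample nucleotide-level randomness until
            # the segment's only RdRp-positive ORFs are the designed one
            # (none, on a non-RdRp segment) — the truth-roster invariant.
            for _attempt in range(200):
                seq, orf_start, orf_end = _build_segment(
                    rng, prot, length, t5, t3, gc_target)
                if _rdrp_clean(seq, orf_start, orf_end, is_rdrp):
                    break
            else:
                raise ParameterError("could not build an RdRp-clean segment")
            seg_ids.append(f"{gid}.s{si + 1:02d}")
            segs.append(seq)
            orf_truth.append((si, orf_start, orf_end, is_rdrp))
        genomes.append(TruthGenome(
            genome_id=gid, segment_ids=seg_ids, segments=segs,
            terminal5=t5, terminal3=t3, has_rdrp=True, gc_target=gc_target,
            rdrp_segment_index=0, orf_truth=orf_truth,
        ))
    return genomes


def generate_background(params: SimParams, n_mrna: int = 20) -> Background:
    """One dominant host SSU, one minor eukaryote SSU, plus host mRNAs."""
    rng = np.random.default_rng([params.seed, 2])
    rrna = {
        "host_SSU": _random_gc_block(rng, 1800, round(0.51 * 1800)),
        "minor_SSU": _random_gc_block(rng, 1800, round(0.49 * 1800)),
    }
    weights = {"host_SSU": params.host_ssu_frac,
               "minor_SSU": 1.0 - params.host_ssu_frac}
    mrnas = {}
    for i in range(n_mrna):
        n = int(rng.integers(800, 2501))
        mrnas[f"mrna_{i + 1:02d}"] = _random_gc_block(rng, n, round(0.45 * n))
    return Background(rrna=rrna, rrna_weights=weights, mrnas=mrnas)


# --- read simulation ---------------------------------------------------------

def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion `total` into integer counts proportional to `weights`."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ParameterError("apportionment weights must sum above 0")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p in pos:
        alts = [c for c in "ACGT" if c != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _segment_reads(rng: np.random.Generator, seq: str, ref_id: str, n_reads: int,
                   read_len: int, boost: float, err: float, prefix: str,
                   counter: list[int], both_strands: bool,
                   reads: list, truth: list) -> None:
    n_pos = len(seq) - read_len + 1
    if boost > 1 and n_pos >= 3:
        w_term = 2.0 * boost
        denom = (n_pos - 2) + 2 * w_term
        n5 = min(int(round(n_reads * w_term / denom)), n_reads)
        n3 = min(int(round(n_reads * w_term / denom)), n_reads - n5)
        interior = rng.integers(1, n_pos - 1, n_reads - n5 - n3)
        starts = np.concatenate([
            np.zeros(n5, dtype=int),
            np.full(n3, n_pos - 1, dtype=int),
            interior,
        ])
    else:
        starts = rng.integers(0, n_pos, n_reads)
    if both_strands:
        strands = np.where(rng.integers(0, 2, n_reads) == 0, "+", "-")
    else:
        strands = np.full(n_reads, "+")
    for s, strand in zip(starts, strands):
        s = int(s)
        frag = seq[s : s + read_len]
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_errors(rng, frag, err)
        rid = f"{prefix}_{counter[0]:07d}"
        counter[0] += 1
        reads.append((rid, frag, "I" * read_len))
        truth.append((rid, ref_id, s, s + read_len, strand))


def _background_reads(rng: np.random.Generator, background: Background,
                      n_rrna: int, n_other: int, read_len: int, err: float,
                      prefix: str, counter: list[int],
                      reads: list, truth: list) -> None:
    if n_rrna > 0:
        if not background.rrna:
            raise ParameterError("nonzero rRNA fraction but empty rRNA background")
        ids = sorted(background.rrna)
        w = np.array([background.rrna_weights.get(i, 0.0) for i in ids])
        picks = rng.choice(len(ids), size=n_rrna, p=w / w.sum())
        for k in picks:
            ref = ids[k]
            _segment_reads(rng, background.rrna[ref], ref, 1, read_len, 1.0,
                           err, prefix, counter, False, reads, truth)
    if n_other > 0:
        if not background.mrnas:
            raise ParameterError("nonzero 'other' fraction but no mRNA background")
        ids = sorted(background.mrnas)
        lens = np.array([len(background.mrnas[i]) for i in ids], dtype=float)
        picks = rng.choice(len(ids), size=n_other, p=lens / lens.sum())
        for k in picks:
            ref = ids[k]
            _segment_reads(rng, background.mrnas[ref], ref, 1, read_len, 1.0,
                           err, prefix, counter, False, reads, truth)


def _finish(reads: list, truth: list) -> ReadSet:
    df = pd.DataFrame(truth, columns=["read_id", "ref_id", "start", "end", "strand"])
    return ReadSet(reads=reads, truth=df)


def simulate_dsrna_reads(genomes: list[TruthGenome], background: Background,
                         params: SimParams, n_reads: int | None = None) -> ReadSet:
    """Simulate an FLDS dsRNA-seq library.

    Read classes (viral / rRNA / other) are a multinomial draw at the
    dsRNA fractions.  Viral reads are apportioned across segments in
    proportion to length (uniform expected coverage); read start
    positions within a segment follow the terminal-boost model described
    in the module docstring, and reads come off both strands.  When
    ``n_reads`` is omitted it is derived from ``coverage_mean``.
    """
    if not genomes:
        raise ParameterError("need at least one genome")
    rng = np.random.default_rng([params.seed, 3])
    total_len = sum(g.total_length for g in genomes)
    if n_reads is None:
        if params.dsrna_viral_frac <= 0:
            raise ParameterError("cannot derive library size with zero viral fraction")
        n_viral_target = round(params.coverage_mean * total_len / params.read_len)
        n_reads = round(n_viral_target / params.dsrna_viral_frac)
    probs = [params.dsrna_viral_frac, params.dsrna_rrna_frac,
             1.0 - params.dsrna_viral_frac - params.dsrna_rrna_frac]
    n_viral, n_rrna, n_other = rng.multinomial(n_reads, probs)
    seg_refs = [(sid, seq) for g in genomes for sid, seq in zip(g.segment_ids, g.segments)]
    seg_lens = np.array([len(s) for _, s in seg_refs], dtype=float)
    per_seg = _largest_remainder(int(n_viral), seg_lens)
    reads: list = []
    truth: list = []
    counter = [0]
    for (sid, seq), n in zip(seg_refs, per_seg):
        if n > 0:
            _segment_reads(rng, seq, sid, int(n), params.read_len,
                           params.terminal_end_boost, params.subst_error_rate,
                           "ds", counter, True, reads, truth)
    _background_reads(rng, background, int(n_rrna), int(n_other),
                      params.read_len, params.subst_error_rate, "ds", counter,
                      reads, truth)
    return _finish(reads, truth)


def simulate_ssrna_reads(genomes: list[TruthGenome], background: Background,
                         params: SimParams, n_reads: int = 100_000) -> ReadSet:
    """Simulate a conventional (ssRNA) RNA-seq library.

    rRNA dominates (default 80%); viral reads are rare (default 0.5%)
    and split across genomes by ``ssrna_viral_split``, then across a
    genome's segments by length.  No terminal boost; plus strand only.
    """
    if not genomes:
        raise ParameterError("need at least one genome")
    rng = np.random.default_rng([params.seed, 4])
    probs = [params.ssrna_viral_frac, params.ssrna_rrna_frac,
             1.0 - params.ssrna_viral_frac - params.ssrna_rrna_frac]
    n_viral, n_rrna, n_other = rng.multinomial(n_reads, probs)
    split = np.asarray(params.ssrna_viral_split, dtype=float)
    per_genome = (rng.multinomial(int(n_viral), split / split.sum())
                  if n_viral > 0 else np.zeros(len(genomes), dtype=int))
    reads: list = []
    truth: list = []
    counter = [0]
    for g, n_g in zip(genomes, per_genome):
        if n_g == 0:
            continue
        lens = np.array([len(s) for s in g.segments], dtype=float)
        per_seg = _largest_remainder(int(n_g), lens)
        for sid, seq, n in zip(g.segment_ids, g.segments, per_seg):
            if n > 0:
                _segment_reads(rng, seq, sid, int(n), params.read_len, 1.0,
                               params.subst_error_rate, "ss", counter, False,
                               reads, truth)
    _background_reads(rng, background, int(n_rrna), int(n_other),
                      params.read_len, params.subst_error_rate, "ss", counter,
                      reads, truth)
    return _finish(reads, truth)


# --- genome mutation ---------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def mutate_genome(genome: TruthGenome, n_snv: int, ti_count: int,
                  seed: int) -> tuple[TruthGenome, list[Mutation]]:
    """Return a mutated copy of a genome plus the mutation manifest.

    Exactly ``n_snv`` positions differ, ``ti_count`` of them transitions
    (A↔G / C↔T), the rest transversions.  Positions are uniform over the
    genome excluding the conserved terminal motifs, so mutation never
    disturbs genome grouping.  Segment ids and lengths are unchanged.
    """
    if ti_count > n_snv or n_snv < 0 or ti_count < 0:
        raise ParameterError("need 0 <= ti_count <= n_snv")
    t5, t3 = len(genome.terminal5), len(genome.terminal3)
    spans = [(si, t5, len(seq) - t3) for si, seq in enumerate(genome.segments)]
    sizes = [e - s for _, s, e in spans]
    total = sum(sizes)
    if n_snv > total:
        raise ParameterError(f"n_snv={n_snv} exceeds {total} mutable positions")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_snv, replace=False)
    flat.sort()
    is_ti = np.zeros(n_snv, dtype=bool)
    if n_snv:
        is_ti[rng.choice(n_snv, size=ti_count, replace=False)] = True
    offsets = np.cumsum([0] + sizes)
    new_segments = [list(s) for s in genome.segments]
    manifest: list[Mutation] = []
    for idx, ti in zip(flat, is_ti):
        si = int(np.searchsorted(offsets, idx, side="right") - 1)
        pos = int(idx - offsets[si]) + spans[si][1]
        ref = genome.segments[si][pos]
        if ti:
            alt = _TRANSITION[ref]
        else:
            choices = _TRANSVERSIONS[ref]
            alt = choices[rng.integers(0, 2)]
        new_segments[si][pos] = alt
        manifest.append(Mutation(genome.segment_ids[si], pos, ref, alt))
    mutated = TruthGenome(
        genome_id=genome.genome_id + "_v2",
        segment_ids=list(genome.segment_ids),
        segments=["".join(s) for s in new_segments],
        terminal5=genome.terminal5, terminal3=genome.terminal3,
        has_rdrp=genome.has_rdrp, gc_target=genome.gc_target,
        rdrp_segment_index=genome.rdrp_segment_index,
        orf_truth=list(genome.orf_truth),
    )
    return mutated, manifest


def make_decoys(genomes: list[TruthGenome], n_remove: int = 50,
                end: str = "3") -> dict[str, str]:
    """Truncated copies of each genome's first segment (one per genome).

    Decoys lack one true terminus, so a correct terminal caller must
    never classify them full-length.  Ids extend the source segment id
    (e.g. ``g1.s01_trunc3``), so best-hit ties on the shared sequence
    resolve to the original segment under the mapper's lexicographic
    tie-break.
    """
    out: dict[str, str] = {}
    for g in genomes:
        seq = g.segments[0]
        trunc = seq[:-n_remove] if end == "3" else seq[n_remove:]
        out[f"{g.segment_ids[0]}_trunc{end}"] = trunc
    return out


def genomes_to_fasta(genomes: list[TruthGenome], path: str) -> None:
    seqs = [(sid, seq) for g in genomes for sid, seq in zip(g.segment_ids, g.segments)]
    write_fasta(seqs, path)


def background_to_fasta(background: Background, path: str) -> None:
    seqs = dict(background.rrna)
    seqs.update(background.mrnas)
    write_fasta(seqs, path)
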