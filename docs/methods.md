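# Methods

This note documents the models, rules and design choices behind
`fldsvirome`, in the order the pipeline runs.

## Terminal calling

FLDS preserves the literal first and last nucleotide of every dsRNA
molecule, so alignments of FLDS reads over-represent the true termini
of a viral genome segment.  The caller works on a per-contig
`CoverageProfile`: per-base depth, plus per-position counts of the
5′-most alignment starts (`starts5`) and 3′-most alignment ends
(`ends3`).  "Mean coverage" is summed depth divided by the full contig
length.

Rules (all in `PipelineConfig`, defaults in brackets):

* contig screen — length ≥ `min_contig_len` [500 nt] and mean coverage
  ≥ `min_mean_cov` [3×]; both read as "at least", so a 500-bp contig at
  exactly 3.0× is retained;
* terminal end — "more than 10 reads defining the same terminal
  position" is read strictly: `starts5[0] ≥ terminal_min_reads` [11]
  calls the 5′ terminus, symmetrically `ends3[len−1]` for the 3′ one.
  Because assemblers may trim a few terminal bases on real data, an
  optional tolerance window `terminal_tolerance` [0] accepts a
  qualifying pile-up within ±W of the contig end; the default is
  strict.
* a contig with both termini is `full_length`, with at most one it
  stays `partial` (its ORFs and RdRp still enter annotation), a
  screen failure is `discarded`.

The terminal position of an alignment is its reference start/end;
soft-clipped bases in ingested SAM do not move it.

## Read mapping

The built-in mapper does exact 21-mer seeding plus ungapped extension
with mismatch counting, both strands, best hit only, ties broken by
(lowest reference id, lowest start, `+` before `−`).  It is sound and
complete for the substitution-only reads the simulator emits (any
error-free 250-nt read shares a 21-mer with its source); identity
threshold `map_min_identity` [0.95].  It is *not* a general-purpose
aligner — no gaps, no multi-mapping — and real-data users should ingest
SAM from any external mapper instead (`read_sam`/`write_sam`, via
pysam).

## Genome-set reconstruction

Segments of one multipartite RNA virus share conserved terminal
sequences.  The published procedure groups "based on the similarity of
terminal sequences" without stating a metric, window or threshold; this
package defines them explicitly and exposes all three:

* identity of two windows = `1 − editdistance/window length` (edlib
  global alignment), a function of the optimal edit distance only and
  therefore independent of traceback tie-breaks;
* window `terminal_window` [20 nt], compared 5′-to-5′ and 3′-to-3′ with
  both sequences oriented 5′→3′ (no cross-end reverse-complement
  matching);
* link two segments when both ends reach `terminal_identity` [0.80];
  single-linkage closure partitions the input (conserved termini are a
  transitive signal).  Singleton sets are legitimate — a monopartite
  virus is a one-segment set.

The window should not exceed the conserved terminal length of the data;
with shorter conserved termini (e.g. the 12-nt termini of the small
test study) the window must be lowered accordingly.

Validation per set: GC% spread strictly below `gc_max_diff` [5 points];
no ORF pair from two different members above `orf_sim_max` [50%]
amino-acid identity (a duplicated gene across segments argues against
co-membership); a dominance report flags sets whose members all exceed
`dominance_cov` [1000×] and gives each RdRp-encoding record's share of
the summed mean coverage (shares total 100%).

## RdRp annotation and OTUs

`find_orfs` reports *maximal* ORFs on both strands: the first ATG after
the previous in-frame stop, extended to the next stop (included in the
nucleotide interval) or the last complete codon.  Minimum protein
length `min_orf_aa` [100 aa].

The RdRp signature grammar is a deliberate, configurable approximation
of the conserved polymerase motifs: motif C is the first `[GSA]DD`
occurrence (canonically GDD); a hit additionally requires motif A
(`D-x(4,5)-D`) and/or motif B (`G-x(2,3)-T`) within 150 residues
upstream of C, with B downstream of A when A is present.  The exact
residue set of published signature collections is not reproduced here;
the grammar lives in a `MotifTable` so it can be swapped without
touching the scanner.

OTU clustering is greedy centroid clustering of RdRp-encoding
nucleotide sequences: drop records ≤ `otu_min_len` [1500 nt], visit by
decreasing length (ties by id), join the earliest centroid at
≥ `otu_identity` [0.90] nucleotide identity, else found a new OTU.
Identity is again `1 − editdistance/max(length)` — compatible with the
definitions used by standard centroid clusterers, and exactly
reproducible by an independent re-execution (the test suite does this
against a brute-force O(n²) oracle with its own edit-distance DP).

`protein_similarity` is percent identity (matches / alignment columns)
from a Needleman–Wunsch alignment with match +1, mismatch −1, linear
gap −2 and a fixed diagonal > up > left traceback priority, so its
output is a deterministic function of its inputs.  The published ">50%
similarity" ORF rule does not say whether a substitution matrix was
involved; plain identity was chosen and is exposed as a score
parameter.

## Host assignment and SSU composition

Reads are classified by k-mer containment: a read is rRNA when ≥
`classify_containment` [0.3] of its `classify_k` [21]-mers occur in the
rRNA reference set; otherwise it is assigned to the best-containment
viral target over the same threshold; otherwise "other".  Reference
k-mer sets include both strands.  This replaces dedicated rRNA filters
and SSU reconstruction tools with one deterministic, dependency-free
rule that is exact on clean synthetic reads (≥ 99% accuracy with 1%
read errors).

The host rule: a virus whose reads exceed `host_min_frac` [0.1%] of
non-rRNA reads (strict ">"; viral count / (total − rRNA) × 100) is
taken to infect the sampled organism.  Fractions are computed per
genome set with member segments pooled, since multi-segment viruses are
reported per virus; whether the original rule pooled segments is
unstated, so pooling is the documented choice.  Percentages are
reported to 4 decimals to resolve values like 0.0025%.

SSU composition assigns rRNA-like reads to the best-matching SSU
reference and reports per-reference fractions of assigned reads
(summing to 1).

## Variants

Two consensus versions of a genome are compared segment-by-segment.
Equal-length segments are compared positionally — the natural model for
consensus substitution differences, and immune to the fact that an
optimal edit path may co-optimally trade two mismatches for an indel
pair, which would misplace SNV columns.  Length-differing segments
(within `variant_band` [50 nt]) are globally aligned with edlib and gap
columns are excluded from SNV records.  Each mismatch column yields one
record classified as transition (A↔G, C↔T) or transversion;
`titv_summary` reports n, ti, tv and ti/n × 100 (absent when n = 0).
This consensus-vs-consensus comparison deliberately stands in for
read-level quality-weighted variant calling, which needs per-read
qualities the consensus workflow does not retain.

## Synthetic data generator

The generator emulates the statistical structure the pipeline exploits;
its defaults are the study conditions used throughout the tests.

* **Genome roster** [5 genomes, segment counts 1/2/2/10/10]: mirrors a
  community of one monopartite, two bipartite and two 10-segment
  viruses.  Segment lengths uniform in [1800, 4000] nt; conserved
  terminal motifs of `terminal_len` [20 nt] per genome, drawn to be
  mutually distinct (< 70% cross-genome identity, comfortably below the
  80% grouping threshold); per-genome GC targets spread over 36–64%,
  pinned exactly by balancing the base composition of the non-coding
  filler, so within-genome GC spread is < 0.2 points.
* **ORF content**: each genome's first segment carries one designed
  RdRp ORF (motifs A, B, C in order, aspartate-free filler so the
  designed GDD is the first `[GSA]DD`); every other segment carries one
  designed non-RdRp ORF (aspartate-free, pairwise ≤ 40% identity within
  a genome).  An in-frame stop codon immediately upstream of each
  designed ATG guarantees the maximal-ORF finder reports exactly the
  designed protein.  Because random sequence occasionally spawns
  chance ORFs that satisfy the RdRp grammar, segments are resampled at
  the nucleotide level until the only RdRp-positive ORFs (≥ 100 aa,
  either strand) are the designed ones — the truth labels are therefore
  exact, and the motif scanner shows sensitivity 1.0 / false-positive
  rate 0 on labelled ORFs by construction.
* **Background**: one dominant host SSU rRNA and one minor eukaryote
  SSU (92% / 8% of rRNA reads) plus 20 host mRNAs of 0.8–2.5 kb — a
  minimal stand-in for a host-dominated transcriptome.
* **dsRNA-seq library** [viral 20%, rRNA 30%, other 50%]: class counts
  are one multinomial draw; viral reads are apportioned across segments
  by length (uniform expected coverage, `coverage_mean` [30×], read
  length 250 nt, single-end, both strands).  Terminal pile-up model: a
  terminal start position aggregates two ligatable duplex ends (one per
  strand), so it gets sampling weight `2 × terminal_end_boost` [50]
  against 1 per interior fragmentation point, and the anchored counts
  are apportioned deterministically.  The expected pile-up is therefore
  ≈ `2·boost·coverage/read_len` ≈ 12 reads at each terminus under the
  defaults — reliably above the 11-read calling threshold.  The boost
  is a free parameter of the generative model, not an estimate of the
  real enrichment, which has not been quantified.
* **ssRNA-seq library** [rRNA 80%, viral 0.5%]: no terminal boost, plus
  strand only.  The viral pool splits across genomes as
  [0.80, 0.10, 0.004, 0.09, 0.006], putting three of five genomes above
  the 0.1% host threshold (≈ 2.0%, 0.25%, 0.22% of non-rRNA reads) and
  two below — matching the study design in which three viruses were
  attributable to the host and two were too rare to call.
* **Errors**: substitutions only, at `subst_error_rate` [0 by default;
  the terminal-calling contract is stated for error-free reads].  No
  indels, chimeras, adapters, quality trimming or paired-end structure;
  quality strings are constant.  Consequently, passing tests demonstrate
  the correctness of the decision rules, not robustness to platform
  error profiles or misassembly.
* **Mutated versions**: `mutate_genome` places exactly n SNVs uniformly
  outside the terminal motifs (so grouping is never disturbed), with an
  exact transition count; it returns the mutated genome together with
  its mutation manifest, which downstream tests use as the variant
  oracle.  The worked two-version comparison uses n = 54, ti = 49
  (ti 90.7%, printing as 90% at integer precision).

Every stochastic step draws from `numpy` generators seeded from
`SimParams.seed` through fixed stream tags, so a seed determines every
output byte (tested by checksum).

## Problem sizes used in the test and acceptance runs

The default study (25 segments, ≈ 45k dsRNA reads at 30×) runs the full
chain in ≈ 10 s and is shared across the suite via session fixtures.
Library-composition checks use 100,000 reads per library (3-binomial-SD
bands); the multinomial chi-square uses 20 seeds at 20,000 reads; the
grouping-recovery property uses the full chain on the default study
plus truth-roster grouping across 30 seeds; oracle-equivalence checks
use 100 random instances per primitive.  These sizes are the package's
own choice of a desk-scale experiment; all thresholds and generator
defaults above were fixed independently of them.

## Known limitations

* The mapper and classifier are exact-k-mer methods tuned for clean or
  low-error reads; diverged real reads need an external mapper.
* Headline counts of a real field study (hundreds of RdRp OTUs,
  100+ full-length segments per library) depend on deep raw read sets,
  a production assembler and database homology search, all outside this
  package's scope; the deposited-genome roster check is available as
  `segment_roster_stats` for users who download published segment sets.
* The RdRp motif grammar is a heuristic; profile-HMM search would be
  more sensitive on real data.
* Genome-set conflict resolution (ejecting members that break GC/ORF
  rules) reports offenders rather than re-clustering automatically; the
  original workflow resolved such conflicts manually.
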