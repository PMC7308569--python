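"""Generator contracts: truth invariants, determinism, read statistics."""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fldsvirome import (ParameterError, SimParams, generate_background,
                        generate_genomes, mutate_genome, simulate_dsrna_reads,
                        simulate_ssrna_reads)
from fldsvirome.annotation import find_orfs, scan_rdrp_motifs
from fldsvirome.seqtools import gc_percent, nt_identity, revcomp


class TestGenomeRoster:
    def test_default_roster_counts(self, default_genomes):
        """Five genomes with segment counts 1, 2, 2, 10, 10 — 25 segments."""
        assert [len(g.segments) for g in default_genomes] == [1, 2, 2, 10, 10]
        ids = [sid for g in default_genomes for sid in g.segment_ids]
        assert len(set(ids)) == 25

    def test_segments_carry_conserved_terminals(self, default_genomes):
        for g in default_genomes:
            for seq in g.segments:
                assert seq.startswith(g.terminal5)
                assert seq.endswith(g.terminal3)

    def test_gc_pinned_to_target(self, default_genomes):
        """Every segment's GC% is within 5 points of the genome target."""
        for g in default_genomes:
            for seq in g.segments:
                assert abs(gc_percent(seq) - 100 * g.gc_target) < 5.0

    def test_terminal_motifs_distinct_between_genomes(self, default_genomes):
        gs = default_genomes
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                assert nt_identity(gs[i].terminal5, gs[j].terminal5) < 0.80
                assert nt_identity(gs[i].terminal3, gs[j].terminal3) < 0.80

    def test_exactly_one_rdrp_segment_per_genome(self, small_genomes):
        """Only the designated segment carries an RdRp-motif ORF."""
        for g in small_genomes:
            hits = []
            for si, seq in enumerate(g.segments):
                if any(scan_rdrp_motifs(o.protein)
                       for o in find_orfs(seq, 100)):
                    hits.append(si)
            assert hits == [g.rdrp_segment_index]

    def test_labeled_orfs_scan_as_labeled(self, default_genomes):
        """RdRp scan: sensitivity 1 and zero false positives on truth ORFs."""
        for g in default_genomes:
            for si, seq in enumerate(g.segments):
                orfs = find_orfs(seq, 100, parent_id=g.segment_ids[si])
                for tsi, start, end, is_rdrp in g.orf_truth:
                    if tsi != si:
                        continue
                    match = [o for o in orfs if o.strand == "+"
                             and o.start <= start and end <= o.end]
                    assert match, "designed ORF must be discoverable"
                    hit = scan_rdrp_motifs(match[0].protein)
                    assert (hit is not None) == is_rdrp
                    if is_rdrp:
                        assert hit.motif_c_seq == "GDD"

    def test_minimal_single_segment_genome(self):
        params = SimParams(segments_per_genome=(1,), gc_targets=(0.5,),
                           ssrna_viral_split=(1.0,), terminal_len=15, seed=4)
        (g,) = generate_genomes(params)
        assert g.segments[0].startswith(g.terminal5)
        assert g.segments[0].endswith(g.terminal3)
        assert len(g.terminal5) == 15

    def test_same_seed_reproduces_identical_genomes(self, default_params,
                                                    default_genomes):
        again = generate_genomes(SimParams(seed=default_params.seed))
        assert [g.segments for g in again] == \
               [g.segments for g in default_genomes]

    @pytest.mark.parametrize("kwargs", [
        dict(segments_per_genome=(0,), ssrna_viral_split=(1.0,)),
        dict(terminal_len=9),
        dict(segment_len_range=(500, 4000)),
        dict(terminal_len=500, segment_len_range=(900, 1000)),
        dict(dsrna_viral_frac=0.7, dsrna_rrna_frac=0.5),
        dict(ssrna_viral_split=(1.0,)),
        dict(subst_error_rate=1.5),
    ])
    def test_contradictory_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimParams(seed=1, **kwargs)


class TestReadSimulation:
    def test_terminal_pileup_oracle(self, default_genomes, default_dsrna):
        """≥11 truth-table reads start at 0 (and end at the last base) of
        every segment at boost 50 / coverage 30."""
        truth = default_dsrna.truth
        for g in default_genomes:
            for sid, seq in zip(g.segment_ids, g.segments):
                sub = truth[truth.ref_id == sid]
                assert (sub.start == 0).sum() >= 11
                assert (sub.end == len(seq)).sum() >= 11

    def test_reads_are_exact_substrings_without_errors(self, default_genomes,
                                                       default_background,
                                                       default_dsrna):
        refs = {sid: s for g in default_genomes
                for sid, s in zip(g.segment_ids, g.segments)}
        refs.update(default_background.rrna)
        refs.update(default_background.mrnas)
        truth = default_dsrna.truth.set_index("read_id")
        for rid, seq, _ in default_dsrna.reads[::97]:
            row = truth.loc[rid]
            frag = refs[row.ref_id][row.start : row.end]
            assert seq == (frag if row.strand == "+" else revcomp(frag))

    def test_truth_table_complete_and_consistent(self, default_dsrna,
                                                 default_params):
        truth = default_dsrna.truth
        assert len(truth) == len(default_dsrna.reads)
        assert truth.read_id.is_unique
        assert set(truth.read_id) == {r[0] for r in default_dsrna.reads}
        assert ((truth.end - truth.start) == default_params.read_len).all()

    def test_dsrna_class_fractions_within_3sd(self, default_genomes,
                                              default_background):
        params = SimParams(seed=21)
        rs = simulate_dsrna_reads(default_genomes, default_background, params,
                                  n_reads=100_000)
        viral_ids = {sid for g in default_genomes for sid in g.segment_ids}
        nv = rs.truth.ref_id.isin(viral_ids).sum()
        sd = np.sqrt(100_000 * 0.2 * 0.8)
        assert abs(nv - 20_000) <= 3 * sd

    def test_ssrna_rrna_fraction_within_3sd(self, default_ssrna):
        nr = default_ssrna.truth.ref_id.str.endswith("SSU").sum()
        sd = np.sqrt(100_000 * 0.8 * 0.2)
        assert abs(nr - 80_000) <= 3 * sd

    def test_class_counts_are_multinomial(self, small_genomes,
                                          small_background):
        """Chi-square goodness of fit on read-class counts, 20 seeds."""
        probs = np.array([0.20, 0.30, 0.50])
        viral_ids = {sid for g in small_genomes for sid in g.segment_ids}
        pvals = []
        for seed in range(100, 120):
            p = SimParams(**{**small_params_dict(), "seed": seed})
            rs = simulate_dsrna_reads(small_genomes, small_background, p,
                                      n_reads=20_000)
            t = rs.truth
            nv = t.ref_id.isin(viral_ids).sum()
            nr = t.ref_id.str.endswith("SSU").sum()
            counts = [nv, nr, len(t) - nv - nr]
            pvals.append(stats.chisquare(counts, 20_000 * probs).pvalue)
        assert all(p > 0.001 for p in pvals)

    def test_substitution_errors_applied(self, small_genomes,
                                         small_background, small_params):
        p = SimParams(**{**small_params.__dict__, "subst_error_rate": 0.01})
        rs = simulate_dsrna_reads(small_genomes, small_background, p,
                                  n_reads=2000)
        refs = {sid: s for g in small_genomes
                for sid, s in zip(g.segment_ids, g.segments)}
        refs.update(small_background.rrna)
        refs.update(small_background.mrnas)
        mismatches = 0
        total = 0
        for (rid, seq, _), row in zip(rs.reads, rs.truth.itertuples()):
            frag = refs[row.ref_id][row.start : row.end]
            if row.strand == "-":
                frag = revcomp(frag)
            mismatches += sum(a != b for a, b in zip(seq, frag))
            total += len(seq)
        rate = mismatches / total
        assert 0.005 < rate < 0.02

    def test_zero_viral_fraction_leaves_no_viral_truth(self, small_genomes,
                                                       small_background,
                                                       small_params):
        p = SimParams(**{**small_params.__dict__, "ssrna_viral_frac": 0.0})
        rs = simulate_ssrna_reads(small_genomes, small_background, p,
                                  n_reads=5000)
        viral_ids = {sid for g in small_genomes for sid in g.segment_ids}
        assert not rs.truth.ref_id.isin(viral_ids).any()

    def test_same_seed_byte_identical_fastq(self, small_genomes,
                                            small_background, small_params):
        def render(rs):
            buf = io.StringIO()
            for rid, seq, q in rs.reads:
                buf.write(f"@{rid}\n{seq}\n+\n{q}\n")
            return buf.getvalue()

        a = simulate_dsrna_reads(small_genomes, small_background,
                                 small_params, n_reads=3000)
        b = simulate_dsrna_reads(small_genomes, small_background,
                                 small_params, n_reads=3000)
        assert render(a) == render(b)
        assert a.truth.equals(b.truth)

    def test_empty_background_with_nonzero_fraction_errors(self, small_genomes,
                                                           small_params):
        from fldsvirome.synthetic_data import Background
        empty = Background(rrna={}, rrna_weights={}, mrnas={})
        with pytest.raises(ParameterError):
            simulate_dsrna_reads(small_genomes, empty, small_params,
                                 n_reads=1000)


def small_params_dict() -> dict:
    return dict(segments_per_genome=(1, 3), segment_len_range=(1000, 1300),
                gc_targets=(0.45, 0.55), ssrna_viral_split=(0.7, 0.3),
                terminal_len=12, coverage_mean=40.0)


class TestMutateGenome:
    def test_worked_snv_example(self, default_genomes):
        """54 SNVs with 49 transitions on the 10-segment genome."""
        target = max(default_genomes, key=lambda g: g.total_length)
        mutated, manifest = mutate_genome(target, 54, 49, seed=7)
        diffs = []
        for sid, a, b in zip(target.segment_ids, target.segments,
                             mutated.segments):
            assert len(a) == len(b)
            diffs += [(sid, i, x, y) for i, (x, y) in enumerate(zip(a, b))
                      if x != y]
        assert len(diffs) == 54
        ti = sum({x, y} in ({"A", "G"}, {"C", "T"}) for _, _, x, y in diffs)
        assert ti == 49
        assert len(manifest) == 54
        assert sum(m.is_transition for m in manifest) == 49

    def test_zero_snvs_is_identity(self, small_genomes):
        mutated, manifest = mutate_genome(small_genomes[0], 0, 0, seed=1)
        assert mutated.segments == small_genomes[0].segments
        assert manifest == []

    def test_pure_transversions_by_naive_diff(self, small_genomes):
        g = small_genomes[1]
        mutated, _ = mutate_genome(g, 4, 0, seed=3)
        diffs = [(x, y) for a, b in zip(g.segments, mutated.segments)
                 for x, y in zip(a, b) if x != y]
        assert len(diffs) == 4
        assert all({x, y} not in ({"A", "G"}, {"C", "T"}) for x, y in diffs)

    def test_terminal_motifs_never_mutated(self, small_genomes):
        g = small_genomes[1]
        mutated, manifest = mutate_genome(g, 100, 50, seed=5)
        t5, t3 = len(g.terminal5), len(g.terminal3)
        for m in manifest:
            seg_len = len(g.as_dict()[m.segment_id])
            assert t5 <= m.position < seg_len - t3
        for seq in mutated.segments:
            assert seq.startswith(g.terminal5) and seq.endswith(g.terminal3)

    @given(n=st.integers(0, 100), frac=st.floats(0, 1))
    def test_diff_matches_requested_counts(self, small_genomes, n, frac):
        """diff(g, mutate(g, n, t)) has exactly n records, t transitions."""
        t = round(n * frac)
        g = small_genomes[1]
        mutated, _ = mutate_genome(g, n, t, seed=17)
        diffs = [(x, y) for a, b in zip(g.segments, mutated.segments)
                 for x, y in zip(a, b) if x != y]
        assert len(diffs) == n
        assert sum({x, y} in ({"A", "G"}, {"C", "T"}) for x, y in diffs) == t

    def test_excess_snvs_rejected(self, small_genomes):
        with pytest.raises(ParameterError):
            mutate_genome(small_genomes[0], 10**6, 0, seed=1)
        with pytest.raises(ParameterError):
            mutate_genome(small_genomes[0], 5, 6, seed=1)


def test_background_composition(default_background):
    bg = default_background
    assert set(bg.rrna) == {"host_SSU", "minor_SSU"}
    assert bg.rrna_weights["host_SSU"] == pytest.approx(0.92)
    assert len(bg.mrnas) == 20
    assert all(len(s) >= 800 for s in bg.mrnas.values())
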