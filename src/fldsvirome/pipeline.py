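"""End-to-end orchestration of the synthetic FLDS virome analysis.

``run_all`` drives the happy path: simulate → map → call termini →
reconstruct genome sets → annotate (ORFs, RdRp, OTUs) → host-assign →
variants, writing every stage output plus a JSON run manifest
(config snapshot, per-stage record counts, output checksums, seed) into
one output directory.  Identical config + seed reproduce identical
output bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict
from typing import Any

import yaml

from . import __version__
from .abundance_host import classify_reads, host_assignment
from .alignment import map_reads, pileup_all
from .annotation import find_orfs, scan_rdrp_motifs, cluster_rdrp_otus
from .config import PipelineConfig
from .errors import FldsError
from .genome_reconstruction import (coverage_dominance, group_segments,
                                    validate_genome_set)
from .seqtools import write_fasta
from .synthetic_data import (SimParams, generate_background, generate_genomes,
                             genomes_to_fasta, background_to_fasta,
                             mutate_genome, simulate_dsrna_reads,
                             simulate_ssrna_reads)
from .terminal_calling import classify_contigs, segments_table, summarize_segments
from .variants import align_versions, call_snvs, titv_summary, write_vcf

log = logging.getLogger("fldsvirome")

__all__ = ["run_all", "load_run_config"]


def load_run_config(path: str) -> tuple[SimParams, PipelineConfig]:
    """Load a YAML run config with ``sim:`` and ``pipeline:`` sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim_d = dict(data.get("sim", {}))
    for key in ("segments_per_genome", "gc_targets", "ssrna_viral_split"):
        if key in sim_d:
            sim_d[key] = tuple(sim_d[key])
    if "segment_len_range" in sim_d:
        sim_d["segment_len_range"] = tuple(sim_d["segment_len_range"])
    return SimParams(**sim_d), PipelineConfig.from_dict(data.get("pipeline", {}))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(params: SimParams, config: PipelineConfig | None = None,
            outdir: str = "flds_run", n_snv: int = 54, ti_count: int = 49,
            with_decoys: bool = False) -> dict[str, Any]:
    """Run the full synthetic pipeline; returns the summary manifest.

    The SNV stage mutates the largest genome (``n_snv`` variants,
    ``ti_count`` transitions) and compares the two versions — mirroring
    a two-timepoint consensus comparison.
    """
    config = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "fldsvirome", "version": __version__,
        "seed": params.seed,
        "sim_params": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(params).items()},
        "pipeline_config": config.to_dict(),
        "stages": {},
    }
    t0 = time.time()

    def stage(name: str, **counts: Any) -> None:
        manifest["stages"][name] = dict(counts, seconds=round(time.time() - t0, 2))
        log.info("stage %s: %s", name, counts)

    # -- simulate
    genomes = generate_genomes(params)
    background = generate_background(params)
    contigs = {sid: seq for g in genomes
               for sid, seq in zip(g.segment_ids, g.segments)}
    if with_decoys:
        from .synthetic_data import make_decoys
        contigs.update(make_decoys(genomes))
    genomes_to_fasta(genomes, os.path.join(outdir, "genomes.fasta"))
    background_to_fasta(background, os.path.join(outdir, "background.fasta"))
    ds = simulate_dsrna_reads(genomes, background, params)
    ss = simulate_ssrna_reads(genomes, background, params)
    ds.write(os.path.join(outdir, "dsrna.fastq"), os.path.join(outdir, "dsrna_truth.tsv"))
    ss.write(os.path.join(outdir, "ssrna.fastq"), os.path.join(outdir, "ssrna_truth.tsv"))
    stage("simulate", genomes=len(genomes), contigs=len(contigs),
          dsrna_reads=len(ds.reads), ssrna_reads=len(ss.reads))

    # -- map dsRNA reads onto contigs
    if not ds.reads:
        raise FldsError("mapping stage: empty read set")
    alignments = map_reads(ds.reads, contigs, config.map_min_identity)
    if not alignments:
        raise FldsError("mapping stage: no read aligned to any contig")
    profiles = pileup_all(alignments, contigs)
    stage("map", alignments=len(alignments))

    # -- terminal calling
    records = classify_contigs(contigs, profiles, config)
    counts = summarize_segments(records)
    segments_table(records, profiles).to_csv(
        os.path.join(outdir, "segments.tsv"), sep="\t", index=False)
    full = [r for r in records if r.status == "full_length"]
    write_fasta([(r.seq_id, r.sequence) for r in full],
                os.path.join(outdir, "full_length.fasta"))
    stage("call_termini", **counts)

    # -- annotation: ORFs, RdRp, OTUs
    orfs_by_member = {r.seq_id: find_orfs(r.sequence, config.min_orf_aa, r.seq_id)
                      for r in records if r.status != "discarded"}
    rdrp_ids = [sid for sid, orfs in sorted(orfs_by_member.items())
                if any(scan_rdrp_motifs(o.protein) for o in orfs)]
    cov_by_id = {r.seq_id: r.mean_coverage for r in records}
    otus = cluster_rdrp_otus(
        [(sid, contigs[sid]) for sid in rdrp_ids], config)
    with open(os.path.join(outdir, "otus.tsv"), "w") as fh:
        fh.write("otu_id\tcentroid_id\tmember_count\tmember_ids\n")
        for o in otus:
            fh.write(f"{o.otu_id}\t{o.centroid_id}\t{o.member_count}\t"
                     f"{','.join(o.member_ids)}\n")
    stage("annotate", rdrp_records=len(rdrp_ids), otus=len(otus))

    # -- genome reconstruction + validation
    gsets = group_segments(full, config)
    for gs in gsets:
        validate_genome_set(gs, orfs_by_member, config)
    dom = coverage_dominance(gsets, [(sid, cov_by_id[sid]) for sid in rdrp_ids],
                             config)
    dom.to_csv(os.path.join(outdir, "dominance.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "genome_sets.tsv"), "w") as fh:
        fh.write("set_id\tn_members\tgc_ok\torf_ok\tdominant\tmember_ids\n")
        for gs in gsets:
            fh.write(f"{gs.set_id}\t{gs.n_members}\t{gs.gc_ok}\t{gs.orf_ok}\t"
                     f"{gs.dominant}\t{','.join(gs.members)}\n")
    stage("reconstruct", genome_sets=len(gsets),
          validated=sum(bool(gs.gc_ok and gs.orf_ok) for gs in gsets))

    # -- host assignment from the ssRNA library
    viral_refs = {gs.set_id: [contigs[m] for m in gs.members] for gs in gsets}
    class_counts = classify_reads(ss.reads, background.rrna, viral_refs, config)
    calls = host_assignment(class_counts, config)
    with open(os.path.join(outdir, "host_calls.tsv"), "w") as fh:
        fh.write("target_id\tviral_reads\tfrac_nonrrna\tassigned\n")
        for c in calls:
            fh.write(f"{c.target_id}\t{c.viral_reads}\t{c.frac_nonrrna:.4f}\t"
                     f"{c.assigned}\n")
    stage("host_assign", assigned=sum(c.assigned for c in calls))

    # -- variants: two-version comparison of the largest genome
    target = max(genomes, key=lambda g: g.total_length)
    mutated, _ = mutate_genome(target, n_snv, ti_count, seed=params.seed + 1)
    variants = call_snvs(align_versions(target, mutated, config.variant_band))
    summary = titv_summary(variants)
    write_vcf(variants, os.path.join(outdir, "variants.vcf"))
    stage("variants", **{k: v for k, v in summary.items() if v is not None})

    manifest["summary"] = {
        "full_length": counts["full_length"],
        "genome_sets": len(gsets),
        "sets_validated": sum(bool(gs.gc_ok and gs.orf_ok) for gs in gsets),
        "hosts_assigned": sum(c.assigned for c in calls),
        "otus": len(otus),
        "titv": summary,
    }
    manifest["checksums"] = {
        f: _sha256(os.path.join(outdir, f))
        for f in sorted(os.listdir(outdir))
        if f != "manifest.json" and os.path.isfile(os.path.join(outdir, f))
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
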