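"""Shared fixtures: one default-scale simulation reused across the suite.

The default-scale chain (5 genomes / 25 segments, ~45k dsRNA reads) is
session-scoped so the expensive simulate→map→pileup work runs once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fldsvirome import (PipelineConfig, SimParams, classify_contigs,
                        generate_background, generate_genomes, make_decoys,
                        map_reads, pileup_all, simulate_dsrna_reads,
                        simulate_ssrna_reads)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_genomes(default_params):
    return generate_genomes(default_params)


@pytest.fixture(scope="session")
def default_background(default_params):
    return generate_background(default_params)


@pytest.fixture(scope="session")
def default_dsrna(default_genomes, default_background, default_params):
    return simulate_dsrna_reads(default_genomes, default_background,
                                default_params)


@pytest.fixture(scope="session")
def default_ssrna(default_genomes, default_background, default_params):
    return simulate_ssrna_reads(default_genomes, default_background,
                                default_params, n_reads=100_000)


@pytest.fixture(scope="session")
def default_contigs(default_genomes):
    contigs = {sid: seq for g in default_genomes
               for sid, seq in zip(g.segment_ids, g.segments)}
    contigs.update(make_decoys(default_genomes))
    return contigs


@pytest.fixture(scope="session")
def default_profiles(default_dsrna, default_contigs):
    alignments = map_reads(default_dsrna.reads, default_contigs)
    return pileup_all(alignments, default_contigs)


@pytest.fixture(scope="session")
def default_records(default_contigs, default_profiles):
    return classify_contigs(default_contigs, default_profiles,
                            PipelineConfig())


# Small, fast study: 2 genomes (1 + 3 segments), short segments.
@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(
        segments_per_genome=(1, 3),
        segment_len_range=(1000, 1300),
        gc_targets=(0.45, 0.55),
        ssrna_viral_split=(0.7, 0.3),
        terminal_len=12,
        coverage_mean=40.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def small_genomes(small_params):
    return generate_genomes(small_params)


@pytest.fixture(scope="session")
def small_background(small_params):
    return generate_background(small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
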