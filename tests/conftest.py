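"""Shared fixtures: toy genomes and a small simulated cohort."""

from __future__ import annotations

import pytest

from triomut.core_io import GenomeSequence
from triomut.synthetic_trio import SimulationConfig, simulate_cohort

#: compact simulation used by most integration tests: two independent
#: trios on a single 100-kb autosome, concordant callers
SMALL_CFG = dict(
    n_autosomes=1,
    chromosome_length=100_000,
    include_sex_chromosome=False,
    n_trios=2,
    true_denovo_count=10,
    true_denovo_indel_count=2,
    caller_discordance_rate=0.0,
)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    # chr1: homopolymer run for indel left-alignment, chrT with a T-run and
    # an N island for review-stage context flags
    return GenomeSequence(
        name="toy",
        sequences={
            "chr1": "GCATTTTCAGGACCTGATCGTACGATCG",
            "chrT": "ACGACGTAGC" + "T" * 12 + "GCATGCATGC" + "N" * 3 + "GATCGATCGA",
        },
        autosome_flags={"chr1": True, "chrT": True},
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Artifact-free cohort: every planted de novo should survive."""
    cfg = SimulationConfig(rng_seed=11, artifact_rates={}, **SMALL_CFG)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def artifact_sim():
    """Cohort with every artifact class planted."""
    cfg = SimulationConfig(rng_seed=13, **SMALL_CFG)
    return simulate_cohort(cfg)
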