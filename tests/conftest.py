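"""Shared simulated fixtures (session-scoped: simulation is the slow part)."""

from types import SimpleNamespace

import pytest

from regenmut.alignment_pileup import (
    build_coverage,
    build_pileup,
    filter_reads,
)
from regenmut.mutation_calling import call_homozygous, subtract_progenitor
from regenmut.synthetic_data import (
    IndelRequest,
    MutationSpec,
    SBSRequest,
    SimulationConfig,
    SVRequest,
    TEAmplificationRequest,
    generate_genome,
    plant_mutations,
    simulate_read_pairs,
)
from regenmut.transposon_analysis import TEElement


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(genome_length=100_000, depth=25.0, seed=101)


@pytest.fixture(scope="session")
def reference(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def p1_bundle(reference, sim_config):
    """Mutation-free progenitor sample at 25x."""
    sample, truth = plant_mutations(reference, MutationSpec(), 7, "P1")
    reads = filter_reads(simulate_read_pairs(sample, sim_config))
    columns = {(c.chrom, c.pos): c for c in build_pileup(reads, reference)}
    return SimpleNamespace(
        sample=sample,
        truth=truth,
        reads=reads,
        columns=columns,
        track=build_coverage(reads, reference),
    )


@pytest.fixture(scope="session")
def r1_bundle(reference, sim_config, p1_bundle):
    """Regenerant with hom/het SBSs and context-specific 1-2 bp indels."""
    spec = MutationSpec(
        sbs=tuple([SBSRequest("hom")] * 20 + [SBSRequest("het")] * 3),
        indels=(
            IndelRequest("del", 1, "homopolymer", "hom"),
            IndelRequest("del", 1, "homopolymer", "hom"),
            IndelRequest("del", 1, "homopolymer", "hom"),
            IndelRequest("ins", 1, "homopolymer", "hom"),
            IndelRequest("ins", 1, "homopolymer", "hom"),
            IndelRequest("del", 2, "polydinucleotide", "hom"),
            IndelRequest("del", 2, "polydinucleotide", "hom"),
            IndelRequest("del", 1, "other", "hom"),
            IndelRequest("del", 1, "homopolymer", "het"),
        ),
    )
    sample, truth = plant_mutations(reference, spec, 8, "R1")
    reads = filter_reads(simulate_read_pairs(sample, sim_config))
    columns = list(build_pileup(reads, reference))
    calls = call_homozygous(columns, reference, sample="R1")
    novel, unresolvable = subtract_progenitor(calls, p1_bundle.columns, reference)
    return SimpleNamespace(
        sample=sample,
        truth=truth,
        reads=reads,
        columns=columns,
        calls=calls,
        novel=novel,
        unresolvable=unresolvable,
        track=build_coverage(reads, reference),
    )


@pytest.fixture(scope="session")
def sv_sim_config():
    return SimulationConfig(
        genome_length=60_000, n_chromosomes=2, depth=25.0, seed=202
    )


@pytest.fixture(scope="session")
def sv_reference(sv_sim_config):
    return generate_genome(sv_sim_config)


@pytest.fixture(scope="session")
def te_elements():
    return [
        TEElement("TE1", "COPIA", "chr2", 40_000, 42_500),
        TEElement("TE2", "CACTA", "chr2", 5_000, 7_000),
    ]


@pytest.fixture(scope="session")
def sv_bundle(sv_reference, sv_sim_config, te_elements):
    """One planted inversion, translocation and (same-chromosome) copied
    insertion, plus one duplicative TE transposition."""
    spec = MutationSpec(
        svs=(
            SVRequest("inversion", "chr1", 15_000, 18_000),
            SVRequest(
                "translocation", "chr1", 35_000, 38_000,
                dest_chrom="chr2", dest_pos=20_000,
            ),
            SVRequest(
                "large_insertion", "chr1", 45_000, 47_000,
                dest_chrom="chr1", dest_pos=52_000,
            ),
        ),
        te_amplifications=(
            TEAmplificationRequest(
                "TE1", "chr2", 40_000, 42_500,
                extra_copies=1, dest_chrom="chr1", dest_pos=25_000,
            ),
        ),
    )
    r1_sample, truth = plant_mutations(sv_reference, spec, 31, "R1sv")
    p1_sample, _ = plant_mutations(sv_reference, MutationSpec(), 32, "P1sv")
    r1_reads = filter_reads(simulate_read_pairs(r1_sample, sv_sim_config))
    p1_reads = filter_reads(simulate_read_pairs(p1_sample, sv_sim_config))
    return SimpleNamespace(
        truth=truth,
        r1_reads=r1_reads,
        p1_reads=p1_reads,
        r1_track=build_coverage(r1_reads, sv_reference),
        p1_track=build_coverage(p1_reads, sv_reference),
    )
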