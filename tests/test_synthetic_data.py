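import re

import numpy as np
import pytest

from regenmut.alignment_pileup import read_alignments
from regenmut.genome import ReferenceGenome
from regenmut.synthetic_data import (
    ChromAlignment,
    ConfigurationError,
    IndelRequest,
    MutationSpec,
    SBSRequest,
    SimulationConfig,
    SimulationError,
    SVRequest,
    TruthSet,
    _SmallIndel,
    generate_genome,
    plant_mutations,
    simulate_read_pairs,
    write_fixture,
)


class TestSimulationConfig:
    def test_defaults(self):
        cfg = SimulationConfig()
        assert cfg.read_length == 76
        assert cfg.fragment_mean == 350
        assert cfg.gc_content == pytest.approx(0.36)
        assert cfg.depth == 25.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genome_length": 0},
            {"genome_length": -5},
            {"gc_content": 1.5},
            {"read_length": 400},
            {"depth": -1},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(SimulationConfig(genome_length=1000, gc_content=0.5, seed=7))
        b = generate_genome(SimulationConfig(genome_length=1000, gc_content=0.5, seed=7))
        assert a["chr1"] == b["chr1"]
        assert len(a["chr1"]) == 1000

    def test_different_seed_differs(self):
        a = generate_genome(SimulationConfig(genome_length=1000, seed=7))
        b = generate_genome(SimulationConfig(genome_length=1000, seed=8))
        assert a["chr1"] != b["chr1"]

    def test_degenerate_gc(self):
        g = generate_genome(SimulationConfig(genome_length=500, gc_content=1.0, seed=1))
        assert set(g["chr1"]) <= {"G", "C"}

    def test_gc_fraction_bound(self):
        # binomial bound: sd of GC fraction at n=100000 is ~0.0015, so +-0.02
        # is a >10-sigma envelope
        g = generate_genome(
            SimulationConfig(genome_length=100_000, gc_content=0.36, seed=3)
        )
        seq = g["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.36) < 0.02

    def test_context_runs_present(self):
        g = generate_genome(SimulationConfig(genome_length=100_000, seed=5))
        seq = g["chr1"]
        assert re.search(r"A{6,}|C{6,}|G{6,}|T{6,}", seq)
        found_dinuc = any(
            seq[i : i + 8] == seq[i : i + 2] * 4 and seq[i] != seq[i + 1]
            for i in range(len(seq) - 8)
        )
        assert found_dinuc

    def test_multiple_chromosomes(self):
        g = generate_genome(
            SimulationConfig(genome_length=2000, n_chromosomes=3, seed=2)
        )
        assert g.names == ["chr1", "chr2", "chr3"]


class TestChromAlignment:
    def test_identity_projection(self):
        aln = ChromAlignment.from_indels(100, [])
        ref, cigar = aln.project(10, 30)
        assert ref == 10 and cigar == [("M", 20)]

    def test_deletion_projection(self):
        aln = ChromAlignment.from_indels(100, [_SmallIndel("del", 50, "AA")])
        assert aln.hap_len == 98
        ref, cigar = aln.project(40, 60)
        assert ref == 40
        assert cigar == [("M", 10), ("D", 2), ("M", 10)]

    def test_insertion_projection(self):
        aln = ChromAlignment.from_indels(100, [_SmallIndel("ins", 49, "TT")])
        assert aln.hap_len == 102
        ref, cigar = aln.project(40, 60)
        assert ref == 40
        assert cigar == [("M", 10), ("I", 2), ("M", 8)]

    def test_edge_insertion_becomes_softclip(self):
        aln = ChromAlignment.from_indels(100, [_SmallIndel("ins", 49, "TTTT")])
        ref, cigar = aln.project(51, 70)  # starts inside the insertion
        assert cigar[0][0] == "S"
        assert ref == 50

    def test_hap_pos_roundtrip(self):
        aln = ChromAlignment.from_indels(
            100, [_SmallIndel("del", 20, "AAA"), _SmallIndel("ins", 60, "G")]
        )
        assert aln.hap_pos(0) == 0
        assert aln.hap_pos(19) == 19
        assert aln.hap_pos(23) == 20  # after the 3 bp deletion
        assert aln.hap_pos(100) == aln.hap_len


class TestPlantMutations:
    def test_hom_sbs_alter_both_haplotypes(self, reference):
        spec = MutationSpec(sbs=tuple([SBSRequest("hom")] * 10))
        sample, truth = plant_mutations(reference, spec, 3)
        assert len(truth.planted_sbs) == 10
        diffs = [
            i
            for i, (a, b) in enumerate(
                zip(reference["chr1"], sample.haplotypes[0].seqs["chr1"])
            )
            if a != b
        ]
        assert sorted(diffs) == sorted(s.pos for s in truth.planted_sbs)
        for s in truth.planted_sbs:
            for hap in sample.haplotypes:
                assert hap.seqs[s.chrom][s.pos] == s.alt

    def test_het_sbs_one_haplotype(self, reference):
        spec = MutationSpec(sbs=(SBSRequest("het"),))
        sample, truth = plant_mutations(reference, spec, 4)
        (s,) = truth.planted_sbs
        assert sample.haplotypes[0].seqs[s.chrom][s.pos] == s.alt
        assert sample.haplotypes[1].seqs[s.chrom][s.pos] == s.ref

    def test_homopolymer_indels_inside_runs(self, reference):
        spec = MutationSpec(
            indels=tuple([IndelRequest("del", 1, "homopolymer", "hom")] * 5)
        )
        _, truth = plant_mutations(reference, spec, 5)
        assert len(truth.planted_indels) == 5
        for ind in truth.planted_indels:
            # deleted base sits in a reference run of >=3 identical bases
            seq = reference[ind.chrom]
            base = ind.ref[1]
            run = 0
            i = ind.pos + 1
            while i < len(seq) and seq[i] == base:
                run += 1
                i += 1
            assert run >= 3

    def test_unplaceable_class_raises(self):
        tiny = ReferenceGenome({"chr1": "ACGT" * 50})
        spec = MutationSpec(sbs=(SBSRequest("hom"),))
        with pytest.raises(SimulationError):
            plant_mutations(tiny, spec, 1)

    def test_no_two_events_overlap(self, r1_bundle):
        intervals = []
        for s in r1_bundle.truth.planted_sbs:
            intervals.append((s.chrom, s.pos, s.pos + 1))
        for ind in r1_bundle.truth.planted_indels:
            intervals.append((ind.chrom, ind.pos, ind.pos + len(ind.ref)))
        intervals.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
            assert c1 != c2 or e1 <= s2

    def test_events_within_bounds(self, r1_bundle, reference):
        for s in r1_bundle.truth.planted_sbs:
            assert 0 <= s.pos < reference.length(s.chrom)
            assert s.zygosity in ("het", "hom")


class TestSimulateReadPairs:
    def test_coverage_close_to_requested(self):
        cfg = SimulationConfig(genome_length=1000, depth=20.0, seed=6, fragment_sd=5)
        genome = generate_genome(cfg)
        sample, _ = plant_mutations(genome, MutationSpec(), 1)
        reads = simulate_read_pairs(sample, cfg)
        aligned = sum(len(r.sequence) for r in reads)
        assert aligned / 1000 == pytest.approx(20, abs=2)

    def test_deterministic(self, reference, sim_config):
        sample, _ = plant_mutations(reference, MutationSpec(), 2)
        a = simulate_read_pairs(sample, sim_config)
        b = simulate_read_pairs(sample, sim_config)
        assert [(r.name, r.pos, r.sequence, r.cigar) for r in a] == [
            (r.name, r.pos, r.sequence, r.cigar) for r in b
        ]

    def test_depth_zero_empty(self, reference):
        cfg = SimulationConfig(genome_length=1000, depth=0, seed=1)
        genome = generate_genome(cfg)
        sample, _ = plant_mutations(genome, MutationSpec(), 1)
        assert simulate_read_pairs(sample, cfg) == []

    def test_noiseless_reads_match_reference(self):
        cfg = SimulationConfig(genome_length=5000, depth=10, seed=9)
        genome = generate_genome(cfg)
        sample, _ = plant_mutations(genome, MutationSpec(), 1)
        for rec in simulate_read_pairs(sample, cfg):
            assert rec.cigar == f"{len(rec.sequence)}M"
            assert (
                genome.fetch(rec.chrom, rec.pos, rec.end) == rec.sequence
            )

    def test_error_rate_injects_mismatches(self):
        cfg = SimulationConfig(
            genome_length=5000, depth=10, seed=9, base_error_rate=0.01
        )
        genome = generate_genome(cfg)
        sample, _ = plant_mutations(genome, MutationSpec(), 1)
        reads = simulate_read_pairs(sample, cfg)
        mismatches = sum(
            sum(
                a != b
                for a, b in zip(
                    genome.fetch(r.chrom, r.pos, r.end), r.sequence
                )
            )
            for r in reads
        )
        total = sum(len(r.sequence) for r in reads)
        assert mismatches / total == pytest.approx(0.01, rel=0.3)

    def test_inversion_produces_same_strand_pairs(self):
        cfg = SimulationConfig(genome_length=20_000, depth=25, seed=13)
        genome = generate_genome(cfg)
        spec = MutationSpec(svs=(SVRequest("inversion", "chr1", 8_000, 10_000),))
        sample, _ = plant_mutations(genome, spec, 2)
        reads = simulate_read_pairs(sample, cfg)
        same_strand = [
            r
            for r in reads
            if r.strand == r.mate_strand and r.chrom == r.mate_chrom
        ]
        assert len(same_strand) > 0
        # breakpoint-flanking: one end near a breakpoint
        assert any(
            min(abs(r.pos - 8000), abs(r.pos - 10000)) < 500 for r in same_strand
        )

    def test_mate_coordinates_are_reciprocal(self, r1_bundle):
        by_name = {}
        for r in r1_bundle.reads[:2000]:
            by_name.setdefault(r.name, []).append(r)
        for recs in by_name.values():
            if len(recs) != 2:
                continue
            a, b = recs
            assert a.mate_pos == b.pos and b.mate_pos == a.pos
            assert a.mate_chrom == b.chrom


class TestFixtureIO:
    def test_sam_roundtrip(self, reference, sim_config, tmp_path):
        sample, truth = plant_mutations(
            reference, MutationSpec(sbs=(SBSRequest("hom"),)), 3
        )
        records = simulate_read_pairs(sample, sim_config)[:100]
        paths = write_fixture("S", records, truth, reference, tmp_path)
        back = read_alignments(paths["sam"])
        key = lambda r: (r.chrom, r.pos, r.name, r.is_read1)
        assert sorted(map(key, back)) == sorted(map(key, records))
        orig = {key(r): r for r in records}
        for r in back:
            o = orig[key(r)]
            assert (r.sequence, r.cigar, r.mapq, r.unique, r.strand) == (
                o.sequence, o.cigar, o.mapq, o.unique, o.strand
            )
            assert (r.mate_chrom, r.mate_pos, r.mate_strand) == (
                o.mate_chrom, o.mate_pos, o.mate_strand
            )

    def test_empty_records(self, reference, tmp_path):
        paths = write_fixture("E", [], TruthSet(), reference, tmp_path)
        assert read_alignments(paths["sam"]) == []

    def test_truth_roundtrip(self, r1_bundle, tmp_path):
        p = tmp_path / "truth.json"
        r1_bundle.truth.to_json(p)
        assert TruthSet.from_json(p) == r1_bundle.truth


class TestInvariants:
    def test_byte_identical_fixtures(self, tmp_path):
        cfg = SimulationConfig(genome_length=5000, depth=10, seed=42)
        outs = []
        for sub in ("a", "b"):
            genome = generate_genome(cfg)
            spec = MutationSpec.from_counts(hom_sbs=3)
            sample, truth = plant_mutations(genome, spec, cfg.seed, "S")
            reads = simulate_read_pairs(sample, cfg)
            d = tmp_path / sub
            paths = write_fixture("S", reads, truth, genome, d)
            outs.append(
                (paths["sam"].read_bytes(), paths["truth"].read_bytes())
            )
        assert outs[0] == outs[1]

    def test_planted_events_observable_in_reads(self, r1_bundle, reference):
        # at 25x every hom event should be visible in at least one pileup
        # column allele
        cols = {(c.chrom, c.pos): c for c in r1_bundle.columns}
        for s in r1_bundle.truth.planted_sbs:
            if s.zygosity != "hom":
                continue
            col = cols[(s.chrom, s.pos)]
            assert any(a.startswith(s.alt) for a in col.allele_counts)
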