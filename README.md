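# regenmut

Analysis pipeline for mutations arising in regenerated plant lineages,
exercised end-to-end on simulated data with planted truth. Given a reference
genome, aligned paired-end reads for a progenitor (P1) and one or more
regenerant (R1) samples, the pipeline:

1. **filters reads** — drops non-uniquely mapped reads and reads with
   mapping quality < 20;
2. **calls homozygous variants** — SBSs and short (1–2 bp) indels from
   pileup columns where a single non-reference allele dominates
   (depth ≥ 5, allele fraction ≥ 0.9), left-normalized;
3. **subtracts the progenitor** — an R1 call is novel only when P1 is
   covered (depth ≥ 5) at the site and shows ≤ 10 % support for the same
   allele; sites P1 cannot resolve are reported separately, never silently
   called novel;
4. **classifies the spectrum** — six pyrimidine-strand-collapsed
   substitution classes, Ts:Tv ratio, homopolymer / polydinucleotide indel
   context, and GFF3-based coding effect (synonymous / nonsynonymous /
   truncating by codon translation);
5. **estimates the mutation frequency** — m = 4n/s, where n is the
   detected homozygous count, 4n scales for the ~25 % chance a heterozygous
   mutation is homozygous after one selfing generation, and s is the
   unique-reads-covered genome size; reported with the fold change over the
   spontaneous baseline (7×10⁻⁹/site/generation);
6. **detects structural variants** — read pairs with mates > 750 bp apart
   (or interchromosomal) are clustered (≥ 5 distant-pair depth), typed as
   inversion / translocation / large insertion from orientation and partner
   locus, and progenitor-shared candidates removed;
7. **scans transposons** — per-element mean coverage normalized by each
   sample's genome-wide average depth; elements with sample/control log2
   ratio > 0.75 are flagged (a single duplicative transposition scores ~1),
   and distant-pair clusters pointing at catalogued elements mark novel
   insertion sites.

A first-class simulator (`regenmut.synthetic_data`) generates reference
genomes, plants SBSs, context-specific indels, large SVs and TE
amplifications into diploid haplotypes, and emits aligned 76 bp paired-end
reads (~350 bp fragments, default 25×) by construction — no external
aligner needed — together with a machine-readable truth set for recovery
testing.

## CLI

```sh
regenmut simulate --outdir demo --seed 1 --genome-length 100000 \
    --hom-sbs 20 --hom-indels 5          # reference + P1/R1 SAM + truth JSON
regenmut call --r1 demo/R1.sam --p1 demo/P1.sam \
    --ref demo/reference.fa --out novel.vcf
regenmut spectrum --vcf novel.vcf --ref demo/reference.fa [--gff genes.gff3]
regenmut pileup --bam demo/R1.sam --ref demo/reference.fa --out covered.bed
regenmut rate --vcf novel.vcf --coverage covered.bed [--baseline 7e-9]
regenmut sv --r1 demo/R1.sam --p1 demo/P1.sam --out sv.tsv
regenmut te --sample demo/R1.sam --control demo/P1.sam \
    --ref demo/reference.fa --catalog te.tsv --out te.tsv
regenmut run --config pipeline.yaml     # full pipeline + combined report
regenmut selfing --generations 1        # homozygosity after selfing
```

`regenmut run` consumes a YAML file mirroring
`regenmut.cli_report.PipelineConfig` (paths plus all thresholds, every
default documented above) and writes per-sample VCF/BED/TSV artifacts and a
deterministic `report.json` / `report.txt`.

## Layout

```
src/regenmut/
  genome.py               reference genome container, FASTA I/O
  synthetic_data.py       simulator: genomes, planted truth, read pairs
  alignment_pileup.py     SAM I/O, read filters, pileups, coverage tracks
  mutation_calling.py     homozygous calling, progenitor subtraction, VCF
  spectrum_annotation.py  substitution classes, indel context, GFF3 effects
  rates_genetics.py       m = 4n/s, fold change, selfing homozygosity
  structural_variants.py  distant-pair extraction/clustering/typing
  transposon_analysis.py  TE coverage log2 ratios, insertion signatures
  cli_report.py           pipeline orchestration, config, CLI, report
```
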