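"""Mutation-spectrum classification and genomic-location annotation.

Substitution classes are collapsed onto the pyrimidine strand (six classes),
indel contexts are read from the reference sequence around the normalized
indel, and coding effects come from codon translation against GFF3 CDS
features, honoring strand and phase.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio.Seq import Seq

from .genome import ReferenceGenome, revcomp
from .mutation_calling import NovelMutation, VariantCall

logger = logging.getLogger(__name__)

PYRIMIDINES = {"C", "T"}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: the six pyrimidine-strand-collapsed classes
SUBSTITUTION_CLASSES = ("C>T", "C>A", "C>G", "T>C", "T>A", "T>G")
TRANSITIONS = {"C>T", "T>C"}


@dataclass(frozen=True)
class SubstitutionClass:
    collapsed: str  # one of SUBSTITUTION_CLASSES
    kind: str  # 'transition' | 'transversion'
    raw: str  # uncollapsed, e.g. 'G>A'


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Pyrimidine-strand-collapsed class of a single-base substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    raw = f"{ref}>{alt}"
    if ref in PYRIMIDINES:
        collapsed = raw
    else:
        collapsed = f"{_COMP[ref]}>{_COMP[alt]}"
    kind = "transition" if collapsed in TRANSITIONS else "transversion"
    return SubstitutionClass(collapsed, kind, raw)


def ts_tv_ratio(mutations: Iterable) -> float | None:
    """Transitions / transversions over the SBS calls in ``mutations``.

    Accepts VariantCall/NovelMutation objects or (ref, alt) pairs. Returns
    None (undefined) when there are no transversions.
    """
    ts = tv = 0
    for m in mutations:
        if isinstance(m, NovelMutation):
            m = m.call
        if isinstance(m, VariantCall):
            if m.type != "SBS":
                continue
            ref, alt = m.ref, m.alt
        else:
            ref, alt = m
        cls = classify_substitution(ref, alt)
        if cls.kind == "transition":
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def ts_tv_display(ratio: float | None, decimals: int = 2) -> float | None:
    """Truncate a Ts:Tv ratio for display (63/68 -> 0.92, not 0.93).

    Summary tables truncate to two decimals rather than round, matching the
    convention of the published figures this mirrors.
    """
    if ratio is None:
        return None
    scale = 10**decimals
    return math.floor(ratio * scale) / scale


@dataclass(frozen=True)
class IndelContext:
    context: str  # 'homopolymer' | 'polydinucleotide' | 'other'
    run_length: int
    repeat_unit: str


def classify_indel_context(
    genome: ReferenceGenome,
    indel: VariantCall,
    min_run: int = 3,
    min_units: int = 2,
) -> IndelContext:
    """Context of a left-normalized indel from the reference sequence.

    The indel unit is checked first against a homopolymer run containing the
    affected position, then against a tandem dinucleotide repeat.
    """
    chrom = indel.chrom
    L = genome.length(chrom)
    if not (0 <= indel.pos < L):
        raise ValueError(f"indel position {indel.pos} outside {chrom}")
    unit = indel.alt[1:] if len(indel.alt) > len(indel.ref) else indel.ref[1:]
    if not unit:
        raise ValueError("not an indel (empty unit)")
    first = indel.pos + 1  # first affected / adjacent reference base

    if len(set(unit)) == 1:
        base = unit[0]
        run = 0
        i = first
        while i < L and genome.base(chrom, i) == base:
            run += 1
            i += 1
        i = indel.pos
        while i >= 0 and genome.base(chrom, i) == base:
            run += 1
            i -= 1
        if run >= min_run:
            return IndelContext("homopolymer", run, base)
    if len(unit) == 2 and unit[0] != unit[1]:
        units = 0
        i = first
        while i + 2 <= L and genome.fetch(chrom, i, i + 2) == unit:
            units += 1
            i += 2
        i = first - 2
        while i >= 0 and genome.fetch(chrom, i, i + 2) == unit:
            units += 1
            i -= 2
        if units >= min_units:
            return IndelContext("polydinucleotide", units, unit)
    return IndelContext("other", 0, unit)


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


class GeneAnnotation:
    """GFF3 feature index (gffutils in-memory database)."""

    def __init__(self, db: gffutils.FeatureDB):
        self.db = db

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneAnnotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        return cls(db)

    @classmethod
    def from_string(cls, text: str) -> "GeneAnnotation":
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
        return cls(db)

    def features_at(self, chrom: str, pos: int) -> list[gffutils.Feature]:
        """All features overlapping a 0-based position."""
        return list(self.db.region(region=(chrom, pos + 1, pos + 1)))


@dataclass(frozen=True)
class LocationAnnotation:
    category: str  # CDS_nonsynonymous | CDS_synonymous | UTR | intron | intergenic ...
    gene_id: str | None = None
    aa_change: str | None = None
    truncating: bool = False


def _gene_id_of(feature: gffutils.Feature) -> str | None:
    for key in ("gene_id", "Parent", "ID"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def _codon_effect(
    genome: ReferenceGenome, cds: gffutils.Feature, pos: int, ref: str, alt: str
) -> tuple[str, str | None, bool]:
    """(category, aa_change, truncating) for an SBS inside one CDS feature."""
    try:
        phase = int(cds.frame)
    except (TypeError, ValueError):
        logger.warning("CDS %s has malformed phase %r; skipped", cds.id, cds.frame)
        return "CDS_unknown", None, False
    chrom = cds.seqid
    c_start, c_end = cds.start - 1, cds.end  # to 0-based half-open
    if cds.strand == "+":
        offset = pos - (c_start + phase)
        if offset < 0:
            return "CDS_unknown", None, False
        codon_g = c_start + phase + 3 * (offset // 3)
        if codon_g + 3 > genome.length(chrom):
            return "CDS_unknown", None, False
        codon = genome.fetch(chrom, codon_g, codon_g + 3)
        idx = pos - codon_g
        mut = codon[:idx] + alt + codon[idx + 1 :]
    else:
        offset = (c_end - 1 - phase) - pos
        if offset < 0:
            return "CDS_unknown", None, False
        codon_end = c_end - phase - 3 * (offset // 3)  # exclusive
        if codon_end - 3 < 0:
            return "CDS_unknown", None, False
        fwd = genome.fetch(chrom, codon_end - 3, codon_end)
        idx = pos - (codon_end - 3)
        mut_fwd = fwd[:idx] + alt + fwd[idx + 1 :]
        codon, mut = revcomp(fwd), revcomp(mut_fwd)
    if "N" in codon or "N" in mut:
        return "CDS_unknown", None, False
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mut).translate())
    if aa_ref == aa_alt:
        return "CDS_synonymous", f"{aa_ref}={aa_alt}", False
    truncating = aa_alt == "*"
    return "CDS_nonsynonymous", f"{aa_ref}>{aa_alt}", truncating


def annotate_location(
    mutation: VariantCall,
    annotation: GeneAnnotation,
    genome: ReferenceGenome,
) -> LocationAnnotation:
    """Genomic-location category with CDS > UTR > intron > intergenic priority."""
    feats = annotation.features_at(mutation.chrom, mutation.pos)
    cds = [f for f in feats if f.featuretype == "CDS"]
    utr = [f for f in feats if f.featuretype in _UTR_TYPES]
    exon = [f for f in feats if f.featuretype == "exon"]
    gene = [f for f in feats if f.featuretype in ("gene", "mRNA", "transcript")]
    if cds:
        f = cds[0]
        gid = _gene_id_of(f)
        if mutation.type == "SBS":
            category, aa, trunc = _codon_effect(
                genome, f, mutation.pos, mutation.ref, mutation.alt
            )
            return LocationAnnotation(category, gid, aa, trunc)
        frameshift = (len(mutation.ref) - len(mutation.alt)) % 3 != 0
        return LocationAnnotation(
            "CDS_nonsynonymous",
            gid,
            "frameshift" if frameshift else "inframe_indel",
            truncating=frameshift,
        )
    if utr:
        return LocationAnnotation("UTR", _gene_id_of(utr[0]))
    if exon:
        # exonic but no CDS/UTR feature at the site
        return LocationAnnotation("UTR_or_noncoding_exon", _gene_id_of(exon[0]))
    if gene:
        return LocationAnnotation("intron", _gene_id_of(gene[0]))
    return LocationAnnotation("intergenic")


def write_annotated_vcf(
    mutations: Iterable[NovelMutation],
    genome: ReferenceGenome,
    path: str | Path,
    annotation: GeneAnnotation | None = None,
    min_run: int = 3,
    min_units: int = 2,
) -> None:
    """VCF with CLASS/CONTEXT/LOCATION/AACHANGE INFO annotations."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Collapsed substitution class">',
        '##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Indel sequence context">',
        '##INFO=<ID=LOCATION,Number=1,Type=String,Description="Genomic location category">',
        '##INFO=<ID=AACHANGE,Number=1,Type=String,Description="Amino-acid change">',
    ]
    lines += [
        f"##contig=<ID={name},length={genome.length(name)}>"
        for name in genome.names
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for m in sorted(mutations, key=lambda m: (m.call.chrom, m.call.pos)):
        c = m.call
        info = []
        if c.type == "SBS":
            info.append(f"CLASS={classify_substitution(c.ref, c.alt).collapsed}")
        else:
            ctx = classify_indel_context(genome, c, min_run, min_units)
            info.append(f"CONTEXT={ctx.context}")
        if annotation is not None:
            loc = annotate_location(c, annotation, genome)
            info.append(f"LOCATION={loc.category}")
            if loc.aa_change:
                info.append(f"AACHANGE={loc.aa_change}")
        lines.append(
            f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSummary:
    n_sbs: int
    n_indels: int
    total: int
    theoretical: int  # 4 x total
    ts_tv: float | None
    class_counts: dict[str, int]  # six collapsed classes
    class_counts_12: dict[str, int]
    context_counts: dict[str, int]
    location_counts: dict[str, int]
    chromosome_counts: dict[str, int]
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sbs": self.n_sbs,
            "n_indels": self.n_indels,
            "total": self.total,
            "theoretical": self.theoretical,
            "ts_tv": ts_tv_display(self.ts_tv),
            "class_counts": dict(self.class_counts),
            "class_counts_12": dict(self.class_counts_12),
            "context_counts": dict(self.context_counts),
            "location_counts": dict(self.location_counts),
            "chromosome_counts": dict(self.chromosome_counts),
            "per_sample": self.per_sample,
        }


def spectrum_summary(
    mutations: Iterable[NovelMutation],
    genome: ReferenceGenome,
    annotation: GeneAnnotation | None = None,
    min_run: int = 3,
    min_units: int = 2,
) -> SpectrumSummary:
    muts = list(mutations)
    classes: Counter = Counter({c: 0 for c in SUBSTITUTION_CLASSES})
    classes12: Counter = Counter()
    contexts: Counter = Counter()
    locations: Counter = Counter()
    chroms: Counter = Counter()
    per_sample: dict[str, Counter] = {}
    n_sbs = n_indels = 0
    for m in muts:
        c = m.call
        chroms[c.chrom] += 1
        ps = per_sample.setdefault(c.sample or ".", Counter())
        if c.type == "SBS":
            n_sbs += 1
            ps["SBS"] += 1
            cls = classify_substitution(c.ref, c.alt)
            classes[cls.collapsed] += 1
            classes12[cls.raw] += 1
        else:
            n_indels += 1
            ps["indel"] += 1
            ctx = classify_indel_context(genome, c, min_run, min_units)
            contexts[ctx.context] += 1
        if annotation is not None:
            locations[annotate_location(c, annotation, genome).category] += 1
    total = n_sbs + n_indels
    return SpectrumSummary(
        n_sbs=n_sbs,
        n_indels=n_indels,
        total=total,
        theoretical=4 * total,
        ts_tv=ts_tv_ratio(muts),
        class_counts=dict(classes),
        class_counts_12=dict(classes12),
        context_counts=dict(contexts),
        location_counts=dict(locations),
        chromosome_counts=dict(chroms),
        per_sample={
            s: {"SBS": c.get("SBS", 0), "indel": c.get("indel", 0)}
            for s, c in per_sample.items()
        },
    )
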