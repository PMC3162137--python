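"""Homozygous SBS/short-indel calling with progenitor subtraction.

Calls are made per sample from filtered pileup columns; a regenerant call is
reported as novel only when the progenitor sample is adequately covered at
the site and shows essentially no support for the alternate allele. Sites
the progenitor cannot resolve are set aside explicitly, never silently
reported as novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .alignment_pileup import PileupColumn
from .genome import ReferenceGenome
from .synthetic_data import TruthSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 0-based, VCF-style anchored for indels
    ref: str
    alt: str
    type: str  # 'SBS' | 'insertion' | 'deletion'
    depth: int
    alt_fraction: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.type == "SBS":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"malformed SBS call {self!r}")
        elif len(self.ref) == len(self.alt):
            raise ValueError(f"indel call without length change {self!r}")
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt_fraction outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class NovelMutation:
    call: VariantCall
    progenitor_depth: int
    progenitor_alt_fraction: float


def left_normalize(
    genome: ReferenceGenome, chrom: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and trim an indel to its minimal VCF representation."""
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt) == 1:
        return pos, ref, alt
    # shift left while the trailing base can rotate to the front
    while pos > 0 and ref[-1] == alt[-1]:
        prev = genome.base(chrom, pos - 1)
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt


def _column_alleles(
    column: PileupColumn, genome: ReferenceGenome
) -> list[tuple[str, str, str, int]]:
    """Expand pileup allele keys to (ref, alt, type, count), skipping '*'.

    Keys are ``<base>``, ``<base>+<ins>`` and ``<base>-<dellen>`` as produced
    by the pileup builder.
    """
    out = []
    for key, count in column.allele_counts.items():
        if key == "*" or key == "N":
            continue
        base = key[0]
        if "+" in key:
            ins = key.split("+", 1)[1].split("-", 1)[0]
            out.append((base, base + ins, "insertion", count))
        elif "-" in key:
            dlen = int(key.split("-", 1)[1])
            deleted = genome.fetch(
                column.chrom, column.pos + 1, column.pos + 1 + dlen
            )
            out.append((base + deleted, base, "deletion", count))
        else:
            out.append((base, base, "SBS", count))
    return out


def call_homozygous(
    columns: Iterable[PileupColumn],
    genome: ReferenceGenome,
    min_depth: int = 5,
    min_alt_fraction: float = 0.9,
    sample: str = "",
) -> list[VariantCall]:
    """Emit a call where one non-reference allele dominates a deep column.

    Heterozygous-looking columns (no allele reaching ``min_alt_fraction``)
    and multi-allelic columns yield no call. Indel calls are left-normalized.
    """
    calls: list[VariantCall] = []
    for col in columns:
        if col.depth < min_depth:
            continue
        for ref_a, alt_a, vtype, count in _column_alleles(col, genome):
            if vtype == "SBS":
                if alt_a == col.ref_base:
                    continue
                pos, ref, alt = col.pos, col.ref_base, alt_a
            else:
                pos, ref, alt = left_normalize(
                    genome, col.chrom, col.pos, ref_a, alt_a
                )
            frac = count / col.depth
            if frac < min_alt_fraction:
                continue
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    type=vtype,
                    depth=col.depth,
                    alt_fraction=frac,
                    sample=sample,
                )
            )
    return sorted(calls, key=lambda c: (c.chrom, c.pos))


def _progenitor_support(
    call: VariantCall,
    p1_columns: Mapping[tuple[str, int], PileupColumn],
    genome: ReferenceGenome,
) -> tuple[int, float]:
    """Progenitor depth and alt-allele fraction at (around) a call site.

    Indel support in the progenitor is matched on the left-normalized
    representation so that differing anchor columns still compare equal.
    """
    col = p1_columns.get((call.chrom, call.pos))
    if col is None:
        return 0, 0.0
    if col.depth == 0:
        return 0, 0.0
    support = 0
    for ref_a, alt_a, vtype, count in _column_alleles(col, genome):
        if vtype == "SBS":
            if call.type == "SBS" and alt_a == call.alt:
                support += count
        else:
            pos, ref, alt = left_normalize(
                genome, col.chrom, col.pos, ref_a, alt_a
            )
            if (pos, ref, alt) == (call.pos, call.ref, call.alt):
                support += count
    return col.depth, support / col.depth


def subtract_progenitor(
    r1_calls: Iterable[VariantCall],
    p1_columns: Mapping[tuple[str, int], PileupColumn] | None,
    genome: ReferenceGenome,
    min_p1_depth: int = 5,
    max_p1_alt_fraction: float = 0.1,
) -> tuple[list[NovelMutation], list[VariantCall]]:
    """Keep R1 calls the progenitor can positively exclude.

    Returns (novel, unresolvable). A site is unresolvable when progenitor
    depth is below ``min_p1_depth``; it is inherited (dropped) when the
    progenitor supports the same alt allele above ``max_p1_alt_fraction``.
    """
    if p1_columns is None:
        calls = list(r1_calls)
        logger.error(
            "no progenitor pileup available: all %d calls unresolvable",
            len(calls),
        )
        return [], calls
    novel: list[NovelMutation] = []
    unresolvable: list[VariantCall] = []
    for call in r1_calls:
        depth, frac = _progenitor_support(call, p1_columns, genome)
        if depth < min_p1_depth:
            unresolvable.append(call)
        elif frac <= max_p1_alt_fraction:
            novel.append(NovelMutation(call, depth, frac))
    return novel, unresolvable


@dataclass
class RecoveryReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    sensitivity: float | None
    precision: float | None
    by_class: dict[str, dict[str, int]] = field(default_factory=dict)
    missed: list[tuple] = field(default_factory=list)
    spurious: list[tuple] = field(default_factory=list)


def recover_truth(
    novel: Iterable[NovelMutation],
    truth: TruthSet,
    genome: ReferenceGenome,
    include_het: bool = False,
) -> RecoveryReport:
    """Match calls against the planted truth by normalized position+allele.

    Only homozygous truth events are expected by default (the caller is
    homozygous-only). Degenerate denominators report None rather than NaN.
    """
    expected: dict[tuple, str] = {}
    for sbs in truth.planted_sbs:
        if sbs.zygosity == "hom" or include_het:
            expected[(sbs.chrom, sbs.pos, sbs.ref, sbs.alt)] = "SBS"
    for ind in truth.planted_indels:
        if ind.zygosity == "hom" or include_het:
            pos, ref, alt = left_normalize(
                genome, ind.chrom, ind.pos, ind.ref, ind.alt
            )
            kind = "insertion" if ind.kind == "ins" else "deletion"
            expected[(ind.chrom, pos, ref, alt)] = kind

    called = {m.call.key for m in novel}
    tp = called & set(expected)
    fp = called - set(expected)
    fn = set(expected) - called
    by_class: dict[str, dict[str, int]] = {}
    for key, kind in expected.items():
        d = by_class.setdefault(kind, {"tp": 0, "fn": 0})
        d["tp" if key in tp else "fn"] += 1
    return RecoveryReport(
        true_positives=len(tp),
        false_positives=len(fp),
        false_negatives=len(fn),
        sensitivity=len(tp) / len(expected) if expected else None,
        precision=len(tp) / len(called) if called else None,
        by_class=by_class,
        missed=sorted(fn),
        spurious=sorted(fp),
    )


# -- VCF output --------------------------------------------------------------


def write_vcf(
    mutations: Iterable[NovelMutation],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Minimal VCF 4.2 with depth/fraction INFO fields (1-based positions)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered sample depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">',
        '##INFO=<ID=PDP,Number=1,Type=Integer,Description="Progenitor depth">',
        '##INFO=<ID=PAF,Number=1,Type=Float,Description="Progenitor alt fraction">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SBS/insertion/deletion">',
    ]
    lines += [
        f"##contig=<ID={name},length={genome.length(name)}>"
        for name in genome.names
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for m in sorted(mutations, key=lambda m: (m.call.chrom, m.call.pos)):
        c = m.call
        info = (
            f"DP={c.depth};AF={c.alt_fraction:.3f};PDP={m.progenitor_depth};"
            f"PAF={m.progenitor_alt_fraction:.3f};SAMPLE={c.sample or '.'};"
            f"TYPE={c.type}"
        )
        lines.append(
            f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[NovelMutation]:
    out: list[NovelMutation] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _, ref, alt, _, _, info = line.split("\t")[:8]
        kv = dict(
            item.split("=", 1) for item in info.split(";") if "=" in item
        )
        call = VariantCall(
            chrom=chrom,
            pos=int(pos) - 1,
            ref=ref,
            alt=alt,
            type=kv.get(
                "TYPE",
                "SBS"
                if len(ref) == len(alt) == 1
                else ("insertion" if len(alt) > len(ref) else "deletion"),
            ),
            depth=int(kv.get("DP", 0)),
            alt_fraction=float(kv.get("AF", 0.0)),
            sample=kv.get("SAMPLE", "."),
        )
        out.append(
            NovelMutation(
                call,
                int(kv.get("PDP", 0)),
                float(kv.get("PAF", 0.0)),
            )
        )
    return out
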