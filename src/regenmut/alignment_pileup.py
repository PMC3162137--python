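"""Alignment reading, read-level filtering, pileups and coverage tracks.

All coordinates are 0-based half-open internally; conversion to 1-based
happens only in the VCF/BED writers.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume the reference / the read
_REF_OPS = set("MDN=X")
_READ_OPS = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or sum(n for _, n in ops) == 0:
        raise ValueError(f"unparseable CIGAR: {cigar!r}")
    return ops


@dataclass
class AlignmentRecord:
    """One mapped read: position, strand, quality, uniqueness, mate info."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # '+' or '-'
    mapq: int
    unique: bool
    mate_chrom: str
    mate_pos: int
    mate_strand: str
    sequence: str
    cigar: str
    is_read1: bool = True

    def __post_init__(self) -> None:
        if self.pos < 0 or self.mapq < 0 or not self.sequence:
            raise ValueError(f"invalid alignment record: {self!r}")

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in parse_cigar(self.cigar) if op in _REF_OPS)

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.pos + self.reference_length


def filter_reads(
    records: Iterable[AlignmentRecord],
    min_mapq: int = 20,
    require_unique: bool = True,
) -> list[AlignmentRecord]:
    """Drop reads below ``min_mapq`` and, optionally, non-unique mappers.

    A read with mapq exactly ``min_mapq`` is retained ("less than" is the
    exclusion rule). Input order is preserved.
    """
    return [
        r
        for r in records
        if r.mapq >= min_mapq and (r.unique or not require_unique)
    ]


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    allele_counts: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())


def _read_alleles(
    record: AlignmentRecord, chrom_len: int
) -> list[tuple[int, str]] | None:
    """Per-position alleles contributed by one read.

    Matches contribute their base; a read carrying an insertion contributes
    ``<base>+<inserted>`` at the anchor (the preceding reference position),
    a deletion contributes ``<base>-<deleted-length-placeholder>`` at its
    anchor and ``*`` over the deleted span, so every covered position gets
    exactly one allele per read.
    """
    ops = parse_cigar(record.cigar)
    out: list[tuple[int, str]] = []
    ref = record.pos
    off = 0
    for op, n in ops:
        if op in "S":
            off += n
        elif op == "H":
            continue
        elif op in "M=X":
            if ref + n > chrom_len:
                return None
            for i in range(n):
                out.append((ref + i, record.sequence[off + i]))
            ref += n
            off += n
        elif op == "I":
            ins = record.sequence[off : off + n]
            if out:
                p, a = out[-1]
                out[-1] = (p, a + "+" + ins)
            off += n
        elif op in "DN":
            if ref + n > chrom_len:
                return None
            if out and op == "D":
                p, a = out[-1]
                out[-1] = (p, a + "-" + str(n))
                for i in range(n):
                    out.append((ref + i, "*"))
            ref += n
        else:  # pragma: no cover - P ops never emitted here
            raise ValueError(f"unsupported CIGAR op {op}")
    return out


def build_pileup(
    records: Iterable[AlignmentRecord], genome: ReferenceGenome
) -> Iterator[PileupColumn]:
    """Columns for every reference position overlapped by >=1 read.

    Records should be pre-filtered; reads overhanging a chromosome end are
    rejected with a warning.
    """
    counts: dict[tuple[str, int], Counter] = {}
    for rec in records:
        if rec.chrom not in genome:
            logger.warning("read %s on unknown chromosome %s", rec.name, rec.chrom)
            continue
        alleles = _read_alleles(rec, genome.length(rec.chrom))
        if alleles is None:
            logger.warning(
                "read %s overhangs end of %s; rejected", rec.name, rec.chrom
            )
            continue
        for pos, allele in alleles:
            counts.setdefault((rec.chrom, pos), Counter())[allele] += 1
    for (chrom, pos) in sorted(counts):
        yield PileupColumn(
            chrom=chrom,
            pos=pos,
            ref_base=genome.base(chrom, pos),
            allele_counts=counts[(chrom, pos)],
        )


@dataclass
class CoverageTrack:
    """Per-position filtered depth, one array per chromosome."""

    depths: dict[str, np.ndarray]

    def mean_depth(self, masked: bool = True) -> float:
        """Genome-wide average depth; ``masked`` restricts to covered positions."""
        total = np.concatenate([d for d in self.depths.values()])
        if masked:
            total = total[total > 0]
        if total.size == 0:
            return 0.0
        return float(total.mean())


def build_coverage(
    records: Iterable[AlignmentRecord], genome: ReferenceGenome
) -> CoverageTrack:
    depths = {
        name: np.zeros(genome.length(name), dtype=np.int32) for name in genome.names
    }
    for rec in records:
        if rec.chrom not in depths:
            continue
        arr = depths[rec.chrom]
        ref = rec.pos
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                arr[ref : min(ref + n, arr.size)] += 1
                ref += n
            elif op in "DN":
                ref += n
    return CoverageTrack(depths)


def covered_genome_size(track: CoverageTrack, min_depth: int = 1) -> int:
    """Number of positions at depth >= ``min_depth``, summed over chromosomes."""
    return int(
        sum((d >= min_depth).sum() for d in track.depths.values())
    )


def write_coverage_bed(track: CoverageTrack, path: str | Path, min_depth: int = 1) -> None:
    """BED of maximal intervals with depth >= min_depth."""
    with open(path, "w") as fh:
        for chrom, depth in track.depths.items():
            mask = depth >= min_depth
            if not mask.any():
                continue
            edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
            for start, end in zip(edges[::2], edges[1::2]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


# -- SAM I/O -----------------------------------------------------------------

_UNIQUE_TAG = "XU"


def _sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": genome.length(name)} for name in genome.names
            ],
        }
    )


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Coordinate-sorted SAM with a standard header; sorts if needed."""
    header = _sam_header(genome)
    order = {name: i for i, name in enumerate(genome.names)}
    recs = sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30), r.pos))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in recs:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.name
            a.query_sequence = rec.sequence
            a.reference_name = rec.chrom
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = rec.cigar
            a.next_reference_name = rec.mate_chrom
            a.next_reference_start = rec.mate_pos
            a.flag = (
                0x1
                | 0x2
                | (0x10 if rec.strand == "-" else 0)
                | (0x20 if rec.mate_strand == "-" else 0)
                | (0x40 if rec.is_read1 else 0x80)
            )
            a.set_tag(_UNIQUE_TAG, 1 if rec.unique else 0)
            out.write(a)


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read SAM/BAM mapped records.

    Uniqueness comes from the simulator's tag when present, otherwise from
    mapq>0 with secondary/supplementary excluded (the aligner-agnostic rule).
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.has_tag(_UNIQUE_TAG):
                unique = bool(a.get_tag(_UNIQUE_TAG))
            else:
                unique = a.mapping_quality > 0
            out.append(
                AlignmentRecord(
                    name=a.query_name,
                    chrom=a.reference_name,
                    pos=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mapq=a.mapping_quality,
                    unique=unique,
                    mate_chrom=(
                        a.next_reference_name
                        if a.next_reference_id >= 0
                        else "*"
                    ),
                    mate_pos=max(a.next_reference_start, 0),
                    mate_strand="-" if a.mate_is_reverse else "+",
                    sequence=a.query_sequence,
                    cigar=a.cigarstring,
                    is_read1=not a.is_read2,
                )
            )
    return out
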