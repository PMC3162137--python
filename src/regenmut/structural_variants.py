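"""Distant-pair structural-variant detection.

Read pairs whose mates map more than ``min_distance`` apart on one
chromosome (strictly greater), or to different chromosomes, are extracted;
their footprints are merged into clusters that must reach a minimum
distant-pair depth; clusters are typed from dominant orientation and partner
locus, and candidates shared with the progenitor are excluded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .alignment_pileup import AlignmentRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistantPair:
    read1: AlignmentRecord
    read2: AlignmentRecord
    interchromosomal: bool
    separation: int | None  # leftmost-to-leftmost, same chromosome only
    orientation: str  # 'convergent' | 'divergent' | 'same-strand'


def _orientation(a: AlignmentRecord, b: AlignmentRecord) -> str:
    if a.strand == b.strand:
        return "same-strand"
    left, right = (a, b) if (a.chrom, a.pos) <= (b.chrom, b.pos) else (b, a)
    return "convergent" if left.strand == "+" else "divergent"


def pair_records(
    records: Iterable[AlignmentRecord],
) -> tuple[list[tuple[AlignmentRecord, AlignmentRecord]], int]:
    """Group mapped records into mate pairs by read name.

    Returns (pairs, n_unpaired); records whose mate is absent/unmapped are
    counted, not paired.
    """
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_name[rec.name].append(rec)
    pairs = []
    unpaired = 0
    for recs in by_name.values():
        if len(recs) == 2:
            pairs.append((recs[0], recs[1]))
        else:
            unpaired += len(recs)
    return pairs, unpaired


def extract_distant_pairs(
    records: Iterable[AlignmentRecord], min_distance: int = 750
) -> list[DistantPair]:
    """Pairs separated strictly more than ``min_distance``, plus all
    interchromosomal pairs. Separation is leftmost-to-leftmost."""
    pairs, unpaired = pair_records(records)
    if unpaired:
        logger.info("%d reads without a mapped mate skipped", unpaired)
    out: list[DistantPair] = []
    for a, b in pairs:
        if a.chrom != b.chrom:
            out.append(DistantPair(a, b, True, None, _orientation(a, b)))
            continue
        sep = abs(a.pos - b.pos)
        if sep > min_distance:
            out.append(DistantPair(a, b, False, sep, _orientation(a, b)))
    return out


@dataclass
class DistantPairCluster:
    chrom: str
    start: int  # 0-based half-open
    end: int
    support: int  # max distant-pair depth over the interval
    partner_chrom: str
    partner_start: int
    partner_end: int
    orientation: str  # dominant orientation among supporting pairs
    interchromosomal: bool
    excluded_region: bool = False


def _merge_intervals(
    items: list[tuple[int, int, int]],
) -> list[tuple[int, int, list[int]]]:
    """Merge overlapping (start, end, pair_index) footprints."""
    items = sorted(items)
    merged: list[tuple[int, int, list[int]]] = []
    for s, e, idx in items:
        if merged and s < merged[-1][1]:
            ps, pe, ids = merged[-1]
            merged[-1] = (ps, max(pe, e), ids + [idx])
        else:
            merged.append((s, e, [idx]))
    return merged


def _max_depth(intervals: list[tuple[int, int]]) -> int:
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e, -1))
    depth = best = 0
    for _, d in sorted(events):
        depth += d
        best = max(best, depth)
    return best


def cluster_pairs(
    pairs: Sequence[DistantPair],
    min_support: int = 5,
    excluded_regions: Sequence[tuple[str, int, int]] = (),
) -> list[DistantPairCluster]:
    """Merge distant-pair read footprints per chromosome into clusters.

    A cluster is emitted where the distant-pair depth reaches ``min_support``
    at some position; its partner locus is the union of the mate footprints.
    Clusters overlapping an excluded region (centromere/telomere BED) are
    flagged, not removed.
    """
    footprints: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    mate_of: dict[int, AlignmentRecord] = {}
    side_of: dict[int, AlignmentRecord] = {}
    orient: dict[int, str] = {}
    fp_id = 0
    for p in pairs:
        for rec, mate in ((p.read1, p.read2), (p.read2, p.read1)):
            footprints[rec.chrom].append((rec.pos, rec.end, fp_id))
            side_of[fp_id] = rec
            mate_of[fp_id] = mate
            orient[fp_id] = p.orientation
            fp_id += 1
    clusters: list[DistantPairCluster] = []
    for chrom, items in footprints.items():
        for start, end, ids in _merge_intervals(items):
            depth = _max_depth([(side_of[i].pos, side_of[i].end) for i in ids])
            if depth < min_support:
                continue
            mates = [mate_of[i] for i in ids]
            partner_chroms = {m.chrom for m in mates}
            inter = partner_chroms != {chrom}
            # dominant partner chromosome for the partner locus
            counts = defaultdict(int)
            for m in mates:
                counts[m.chrom] += 1
            pchrom = max(counts, key=counts.get)
            psel = [m for m in mates if m.chrom == pchrom]
            ori_counts = defaultdict(int)
            for i in ids:
                ori_counts[orient[i]] += 1
            dominant = max(ori_counts, key=ori_counts.get)
            excluded = any(
                c == chrom and s < end and e > start
                for c, s, e in excluded_regions
            )
            clusters.append(
                DistantPairCluster(
                    chrom=chrom,
                    start=start,
                    end=end,
                    support=depth,
                    partner_chrom=pchrom,
                    partner_start=min(m.pos for m in psel),
                    partner_end=max(m.end for m in psel),
                    orientation=dominant,
                    interchromosomal=inter,
                    excluded_region=excluded,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


@dataclass
class SVCandidate:
    type: str  # 'large_insertion' | 'inversion' | 'translocation' | 'ambiguous'
    chrom: str
    start: int
    end: int
    partner_chrom: str
    partner_start: int
    partner_end: int
    support: int
    shared_with_progenitor: bool = False


def type_candidates(clusters: Iterable[DistantPairCluster]) -> list[SVCandidate]:
    """Orientation/partner typing.

    same-strand dominant -> inversion; interchromosomal partner ->
    translocation; same-chromosome convergent distant pairs -> large
    insertion (one mate in the target flank, one on the donor copy);
    anything else (notably divergent) -> ambiguous.
    """
    out = []
    for c in clusters:
        if c.interchromosomal:
            sv_type = "translocation"
        elif c.orientation == "same-strand":
            sv_type = "inversion"
        elif c.orientation == "convergent":
            sv_type = "large_insertion"
        else:
            sv_type = "ambiguous"
        out.append(
            SVCandidate(
                type=sv_type,
                chrom=c.chrom,
                start=c.start,
                end=c.end,
                partner_chrom=c.partner_chrom,
                partner_start=c.partner_start,
                partner_end=c.partner_end,
                support=c.support,
            )
        )
    return out


def _reciprocal_overlap(
    a: SVCandidate, b: SVCandidate, fraction: float
) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return (
        ov >= fraction * (a.end - a.start) and ov >= fraction * (b.end - b.start)
    )


def subtract_shared(
    r1_candidates: Iterable[SVCandidate],
    p1_candidates: Sequence[SVCandidate],
    reciprocal_overlap: float = 0.5,
) -> list[SVCandidate]:
    """Report only candidates absent from the progenitor.

    A candidate is shared when a progenitor candidate of the same type
    reciprocally overlaps it by at least ``reciprocal_overlap``.
    """
    out = []
    for cand in r1_candidates:
        shared = any(
            p.type == cand.type and _reciprocal_overlap(cand, p, reciprocal_overlap)
            for p in p1_candidates
        )
        cand = replace(cand, shared_with_progenitor=shared)
        if not shared:
            out.append(cand)
    return out


def detect_svs(
    r1_records: Iterable[AlignmentRecord],
    p1_records: Iterable[AlignmentRecord],
    min_distance: int = 750,
    min_support: int = 5,
    excluded_regions: Sequence[tuple[str, int, int]] = (),
    reciprocal_overlap: float = 0.5,
) -> list[SVCandidate]:
    """Full chain: extract -> cluster -> type -> subtract progenitor-shared."""
    r1 = type_candidates(
        cluster_pairs(
            extract_distant_pairs(r1_records, min_distance),
            min_support,
            excluded_regions,
        )
    )
    p1 = type_candidates(
        cluster_pairs(
            extract_distant_pairs(p1_records, min_distance),
            min_support,
            excluded_regions,
        )
    )
    return subtract_shared(r1, p1, reciprocal_overlap)


def write_clusters_bed(
    clusters: Iterable[DistantPairCluster], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.partner_chrom}:{c.partner_start}-{c.partner_end}\t"
                f"{c.support}\t{c.orientation}\n"
            )


def write_candidates_tsv(
    candidates: Iterable[SVCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "type\tchrom\tstart\tend\tpartner_chrom\tpartner_start\t"
            "partner_end\tsupport\tshared_with_progenitor\n"
        )
        for c in candidates:
            fh.write(
                f"{c.type}\t{c.chrom}\t{c.start}\t{c.end}\t{c.partner_chrom}\t"
                f"{c.partner_start}\t{c.partner_end}\t{c.support}\t"
                f"{str(c.shared_with_progenitor).lower()}\n"
            )
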