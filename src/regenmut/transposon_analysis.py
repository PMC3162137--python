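"""Transposon amplification scanning.

Strategy 1: per-element mean filtered coverage, normalized by each sample's
genome-wide average depth; elements whose sample/control log2 ratio exceeds
a threshold (default 0.75; a single duplicative transposition is expected to
score ~1) are flagged. Strategy 2: distant-pair clusters whose partner
footprint lands on a catalogued element, absent from the progenitor, mark
novel insertion sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .alignment_pileup import CoverageTrack
from .structural_variants import (
    DistantPair,
    SVCandidate,
    cluster_pairs,
    subtract_shared,
    type_candidates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TEElement:
    element_id: str
    family: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"zero/negative length element {self.element_id}")


def read_te_catalog(path: str | Path) -> list[TEElement]:
    """TSV catalog: element_id, family, chrom, start, end (0-based)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("element_id"):
            continue
        eid, family, chrom, start, end = line.split("\t")[:5]
        out.append(TEElement(eid, family, chrom, int(start), int(end)))
    if not out:
        raise ValueError(f"empty TE catalog: {path}")
    return out


def write_te_catalog(elements: Iterable[TEElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tfamily\tchrom\tstart\tend\n")
        for e in elements:
            fh.write(f"{e.element_id}\t{e.family}\t{e.chrom}\t{e.start}\t{e.end}\n")


def element_mean_coverage(track: CoverageTrack, element: TEElement) -> float:
    """Mean per-position depth over the element interval."""
    depth = track.depths[element.chrom]
    if element.end > depth.size:
        raise ValueError(
            f"element {element.element_id} extends past {element.chrom}"
        )
    return float(depth[element.start : element.end].mean())


@dataclass(frozen=True)
class TECoverageRecord:
    element_id: str
    family: str
    mean_coverage: float
    normalized_coverage: float
    control_normalized: float
    log2_ratio: float | None  # None: no data in the control
    flagged: bool


def _background_mean_depth(
    track: CoverageTrack, elements: Sequence[TEElement]
) -> float:
    """Masked mean depth over covered positions outside catalogued elements."""
    import numpy as np

    parts = []
    for chrom, depth in track.depths.items():
        keep = np.ones(depth.size, dtype=bool)
        for el in elements:
            if el.chrom == chrom:
                keep[el.start : min(el.end, depth.size)] = False
        d = depth[keep]
        parts.append(d[d > 0])
    stacked = np.concatenate(parts) if parts else np.array([])
    return float(stacked.mean()) if stacked.size else 0.0


def te_log2_ratios(
    sample_track: CoverageTrack,
    control_track: CoverageTrack,
    elements: Sequence[TEElement],
    threshold: float = 0.75,
    exclude_elements: bool = False,
) -> list[TECoverageRecord]:
    """Per-element normalized log2 coverage ratios, sample vs. control.

    Normalization divides by each sample's own genome-wide average depth
    (computed over covered positions; with ``exclude_elements`` the
    catalogued elements are left out of that average, so an amplified
    element cannot inflate its own normalizer). A global depth difference
    between the samples cancels. Elements without control coverage are
    reported with log2_ratio None and never flagged.
    """
    if not elements:
        raise ValueError("empty TE element list")
    if exclude_elements:
        s_avg = _background_mean_depth(sample_track, elements)
        c_avg = _background_mean_depth(control_track, elements)
    else:
        s_avg = sample_track.mean_depth(masked=True)
        c_avg = control_track.mean_depth(masked=True)
    if c_avg == 0:
        raise ValueError("control sample has zero average depth")
    if s_avg == 0:
        raise ValueError("sample has zero average depth")
    out = []
    for el in elements:
        s_norm = element_mean_coverage(sample_track, el) / s_avg
        c_norm = element_mean_coverage(control_track, el) / c_avg
        if c_norm == 0 or s_norm == 0:
            out.append(
                TECoverageRecord(
                    el.element_id, el.family, s_norm * s_avg, s_norm, c_norm,
                    None, False,
                )
            )
            continue
        ratio = math.log2(s_norm / c_norm)
        out.append(
            TECoverageRecord(
                el.element_id, el.family, s_norm * s_avg, s_norm, c_norm,
                ratio, ratio > threshold,
            )
        )
    return out


@dataclass(frozen=True)
class TEInsertionCandidate:
    element_id: str
    target_chrom: str
    target_start: int
    target_end: int
    support: int


def _partner_element(
    cand: SVCandidate, elements: Sequence[TEElement]
) -> TEElement | None:
    for el in elements:
        if (
            cand.partner_chrom == el.chrom
            and cand.partner_start < el.end
            and cand.partner_end > el.start
        ):
            return el
    return None


def detect_te_insertions(
    r1_pairs: Sequence[DistantPair],
    p1_pairs: Sequence[DistantPair],
    elements: Sequence[TEElement],
    min_support: int = 5,
) -> list[TEInsertionCandidate]:
    """Novel insertion candidates: R1 distant-pair clusters whose mates map
    onto a catalogued element, with no matching progenitor cluster.

    The cluster itself must lie outside the donor element (reads inside the
    element pointing at the element are uninformative).
    """
    if not elements:
        raise ValueError("empty TE catalog")
    r1 = type_candidates(cluster_pairs(r1_pairs, min_support))
    p1 = type_candidates(cluster_pairs(p1_pairs, min_support))
    novel = subtract_shared(r1, p1)
    out = []
    for cand in novel:
        el = _partner_element(cand, elements)
        if el is None:
            continue
        # skip clusters inside the donor element itself
        if (
            cand.chrom == el.chrom
            and cand.start < el.end
            and cand.end > el.start
        ):
            continue
        out.append(
            TEInsertionCandidate(
                el.element_id, cand.chrom, cand.start, cand.end, cand.support
            )
        )
    return out


def write_te_records(
    records: Iterable[TECoverageRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "element_id\tfamily\tmean_coverage\tnormalized_coverage\t"
            "control_normalized\tlog2_ratio\tflagged\n"
        )
        for r in records:
            ratio = "NA" if r.log2_ratio is None else f"{r.log2_ratio:.4f}"
            fh.write(
                f"{r.element_id}\t{r.family}\t{r.mean_coverage:.4f}\t"
                f"{r.normalized_coverage:.6f}\t{r.control_normalized:.6f}\t"
                f"{ratio}\t{str(r.flagged).lower()}\n"
            )
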