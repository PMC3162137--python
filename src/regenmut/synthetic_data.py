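"""Synthetic genomes, planted mutation/SV/TE truth sets and simulated reads.

Alignments are emitted by construction: every simulated read carries its true
mapping position on the reference coordinate system, so no external aligner
is involved. Haplotypes are modeled in two tiers:

* tier A — the reference sequence of each chromosome with small variants
  (SBSs, 1-2 bp indels) applied, plus a CIGAR-like alignment map back to the
  reference;
* tier B — a list of mapped pieces per haplotype chromosome describing
  large-scale rearrangements (deletions, inversions, translocations, copied
  insertions such as duplicative transposition).

Reads are drawn on the final haplotype and projected through both tiers; a
read spanning a rearrangement breakpoint is soft-clipped to its dominant
piece, which is what produces the discordant mate coordinates downstream
stages look for.
"""

from __future__ import annotations

import json
import logging
import re
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment_pileup import AlignmentRecord, write_sam
from .genome import ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation geometry and genome composition.

    Defaults follow the target setting: 76 bp paired-end reads from ~350 bp
    fragments at ~25x coverage of a 36% GC genome.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 1
    gc_content: float = 0.36
    read_length: int = 76
    fragment_mean: int = 350
    fragment_sd: int = 30
    depth: float = 25.0
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("genome_length and n_chromosomes must be > 0")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ConfigurationError("gc_content must lie in [0, 1]")
        if self.read_length > self.fragment_mean:
            raise ConfigurationError("read_length must not exceed fragment_mean")
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSBS:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str  # 'hom' | 'het'


@dataclass(frozen=True)
class PlantedIndel:
    """VCF-style anchored representation (0-based anchor position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # 'ins' | 'del'
    context: str  # 'homopolymer' | 'polydinucleotide' | 'other'
    zygosity: str


@dataclass(frozen=True)
class PlantedSV:
    type: str  # large_insertion | large_deletion | inversion | translocation
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None
    dest_pos: int | None = None


@dataclass(frozen=True)
class PlantedTEAmplification:
    element_id: str
    chrom: str
    start: int
    end: int
    multiplier: int
    dest_chrom: str
    dest_pos: int


@dataclass
class TruthSet:
    planted_sbs: list[PlantedSBS] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    planted_svs: list[PlantedSV] = field(default_factory=list)
    planted_te_amplifications: list[PlantedTEAmplification] = field(
        default_factory=list
    )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_sbs": [asdict(x) for x in self.planted_sbs],
                    "planted_indels": [asdict(x) for x in self.planted_indels],
                    "planted_svs": [asdict(x) for x in self.planted_svs],
                    "planted_te_amplifications": [
                        asdict(x) for x in self.planted_te_amplifications
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_sbs=[PlantedSBS(**x) for x in d["planted_sbs"]],
            planted_indels=[PlantedIndel(**x) for x in d["planted_indels"]],
            planted_svs=[PlantedSV(**x) for x in d["planted_svs"]],
            planted_te_amplifications=[
                PlantedTEAmplification(**x)
                for x in d["planted_te_amplifications"]
            ],
        )


# ---------------------------------------------------------------------------
# Mutation requests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SBSRequest:
    zygosity: str = "hom"
    subst_class: str | None = None  # pyrimidine-collapsed, e.g. "C>T"


@dataclass(frozen=True)
class IndelRequest:
    kind: str = "del"  # 'ins' | 'del'
    size: int = 1
    context: str = "homopolymer"  # 'homopolymer' | 'polydinucleotide' | 'other'
    zygosity: str = "hom"


@dataclass(frozen=True)
class SVRequest:
    type: str  # large_insertion | large_deletion | inversion | translocation
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None  # insertion / translocation target
    dest_pos: int | None = None


@dataclass(frozen=True)
class TEAmplificationRequest:
    element_id: str
    chrom: str
    start: int
    end: int
    extra_copies: int = 1
    dest_chrom: str | None = None
    dest_pos: int | None = None


@dataclass(frozen=True)
class MutationSpec:
    sbs: tuple[SBSRequest, ...] = ()
    indels: tuple[IndelRequest, ...] = ()
    svs: tuple[SVRequest, ...] = ()
    te_amplifications: tuple[TEAmplificationRequest, ...] = ()

    @classmethod
    def from_counts(
        cls,
        hom_sbs: int = 0,
        het_sbs: int = 0,
        hom_indels: int = 0,
        het_indels: int = 0,
        indel_context: str = "homopolymer",
        indel_kind: str = "del",
    ) -> "MutationSpec":
        size = 2 if indel_context == "polydinucleotide" else 1
        return cls(
            sbs=tuple(
                [SBSRequest(zygosity="hom")] * hom_sbs
                + [SBSRequest(zygosity="het")] * het_sbs
            ),
            indels=tuple(
                [IndelRequest(indel_kind, size, indel_context, "hom")] * hom_indels
                + [IndelRequest(indel_kind, size, indel_context, "het")] * het_indels
            ),
        )


# ---------------------------------------------------------------------------
# Tier A: small-variant alignment map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SmallIndel:
    kind: str  # 'ins' | 'del'
    pos: int  # ins: inserted bases follow ref position pos; del: first deleted
    seq: str  # inserted bases or deleted reference bases


class ChromAlignment:
    """Alignment of one mutated (tier A) chromosome back to the reference.

    Stored as a full-length op list (M/I/D); supports projecting a haplotype
    interval to (reference start, CIGAR ops) and mapping single reference
    coordinates into haplotype space.
    """

    def __init__(self, ops: list[tuple[str, int]]):
        merged: list[tuple[str, int]] = []
        for op, n in ops:
            if n <= 0:
                continue
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        self.ops = merged
        self.hap_starts: list[int] = []
        self.ref_starts: list[int] = []
        h = r = 0
        for op, n in merged:
            self.hap_starts.append(h)
            self.ref_starts.append(r)
            if op in "MI":
                h += n
            if op in "MD":
                r += n
        self.hap_len = h
        self.ref_len = r

    @classmethod
    def from_indels(
        cls, ref_len: int, indels: Sequence[_SmallIndel]
    ) -> "ChromAlignment":
        ops: list[tuple[str, int]] = []
        cur = 0
        for v in sorted(indels, key=lambda x: x.pos):
            if v.kind == "ins":
                ops.append(("M", v.pos + 1 - cur))
                ops.append(("I", len(v.seq)))
                cur = v.pos + 1
            else:
                ops.append(("M", v.pos - cur))
                ops.append(("D", len(v.seq)))
                cur = v.pos + len(v.seq)
        ops.append(("M", ref_len - cur))
        return cls(ops)

    def hap_pos(self, ref_pos: int) -> int:
        """Haplotype coordinate of a reference position (deletions collapse)."""
        if ref_pos == self.ref_len:
            return self.hap_len
        for (op, n), h0, r0 in zip(self.ops, self.hap_starts, self.ref_starts):
            if op == "M" and r0 <= ref_pos < r0 + n:
                return h0 + (ref_pos - r0)
            if op == "D" and r0 <= ref_pos < r0 + n:
                return h0
        raise ValueError(f"reference position {ref_pos} out of range")

    def project(
        self, hs: int, he: int
    ) -> tuple[int, list[tuple[str, int]]] | None:
        """Map haplotype interval [hs, he) to (ref_start, CIGAR ops).

        Haplotype bases falling inside insertions at the interval edges
        become soft clips; returns None when no base aligns (interval fully
        inside an insertion).
        """
        if not (0 <= hs < he <= self.hap_len):
            raise ValueError(f"haplotype interval [{hs}, {he}) out of range")
        i = max(bisect_right(self.hap_starts, hs) - 1, 0)
        cigar: list[tuple[str, int]] = []
        ref_at: int | None = None
        pos = hs
        while i < len(self.ops) and pos < he:
            op, n = self.ops[i]
            h0 = self.hap_starts[i]
            r0 = self.ref_starts[i]
            if op == "M":
                lo, hi = max(pos, h0), min(he, h0 + n)
                if hi > lo:
                    if ref_at is None:
                        ref_at = r0 + (lo - h0)
                    cigar.append(("M", hi - lo))
                    pos = hi
            elif op == "I":
                lo, hi = max(pos, h0), min(he, h0 + n)
                if hi > lo:
                    cigar.append(("I", hi - lo))
                    pos = hi
            elif op == "D" and cigar and pos < he:
                cigar.append(("D", n))
            i += 1
        # edge insertions -> soft clips; drop edge deletions
        while cigar and cigar[-1][0] == "D":
            cigar.pop()
        if cigar and cigar[0][0] == "I":
            cigar[0] = ("S", cigar[0][1])
        if cigar and cigar[-1][0] == "I":
            cigar[-1] = ("S", cigar[-1][1])
        if ref_at is None or not any(op == "M" for op, _ in cigar):
            return None
        return ref_at, cigar


# ---------------------------------------------------------------------------
# Tier B: rearranged haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Piece:
    """A contiguous haplotype block mapped to a tier-A chromosome interval."""

    src_chrom: str
    src_start: int  # tier-A haplotype coordinates
    src_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


class Haplotype:
    """One haplotype of one sample: mutated sequences plus reference mapping."""

    def __init__(
        self,
        tier_seqs: dict[str, str],
        alignments: dict[str, ChromAlignment],
        pieces: dict[str, list[Piece]] | None = None,
    ):
        self.tier_seqs = tier_seqs
        self.alignments = alignments
        if pieces is None:
            pieces = {
                name: [Piece(name, 0, len(seq))] for name, seq in tier_seqs.items()
            }
        self.pieces = pieces
        self.seqs: dict[str, str] = {}
        self.piece_starts: dict[str, list[int]] = {}
        for name, plist in pieces.items():
            parts = []
            starts = []
            off = 0
            for p in plist:
                starts.append(off)
                s = tier_seqs[p.src_chrom][p.src_start : p.src_end]
                parts.append(s if p.strand == "+" else revcomp(s))
                off += p.length
            self.seqs[name] = "".join(parts)
            self.piece_starts[name] = starts

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def map_read(
        self, chrom: str, hs: int, he: int
    ) -> tuple[str, int, str, list[tuple[str, int]]] | None:
        """Project a final-haplotype interval to the reference.

        Returns (ref_chrom, ref_pos, piece_strand, cigar ops in reference
        order); the cigar covers all he-hs read bases (soft clips included),
        or None when the read cannot be anchored.
        """
        plist = self.pieces[chrom]
        starts = self.piece_starts[chrom]
        i = max(bisect_right(starts, hs) - 1, 0)
        best, best_ov = None, 0
        j = i
        while j < len(plist) and starts[j] < he:
            ov = min(he, starts[j] + plist[j].length) - max(hs, starts[j])
            if ov > best_ov:
                best, best_ov = j, ov
            j += 1
        if best is None:
            return None
        p = plist[best]
        p0 = starts[best]
        lo, hi = max(hs, p0), min(he, p0 + p.length)
        clip_left = lo - hs  # read bases before the piece
        clip_right = he - hi
        if p.strand == "+":
            ts, te = p.src_start + (lo - p0), p.src_start + (hi - p0)
        else:
            ts, te = p.src_end - (hi - p0), p.src_end - (lo - p0)
        proj = self.alignments[p.src_chrom].project(ts, te)
        if proj is None:
            return None
        ref_at, cigar = proj
        # attach the outer clips in reference order
        left = clip_left if p.strand == "+" else clip_right
        right = clip_right if p.strand == "+" else clip_left
        if left:
            if cigar[0][0] == "S":
                cigar[0] = ("S", cigar[0][1] + left)
            else:
                cigar.insert(0, ("S", left))
        if right:
            if cigar[-1][0] == "S":
                cigar[-1] = ("S", cigar[-1][1] + right)
            else:
                cigar.append(("S", right))
        consumed = sum(n for op, n in cigar if op in "MIS")
        if consumed != he - hs:  # pragma: no cover - internal consistency
            raise SimulationError(
                f"cigar consumes {consumed} bases for a {he - hs} base read"
            )
        return p.src_chrom, ref_at, p.strand, cigar


@dataclass
class SampleGenome:
    """Diploid sample: two haplotypes over the same chromosome names."""

    name: str
    haplotypes: tuple[Haplotype, Haplotype]

    def write_fasta(self, path: str | Path) -> None:
        gen = ReferenceGenome(
            {
                f"{c}_hap{i}": h.seqs[c]
                for i, h in enumerate(self.haplotypes)
                for c in h.seqs
            }
        )
        gen.to_fasta(path)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Random genome at the requested GC fraction, deterministic under seed.

    Guarantees at least one homopolymer run (8 bp) and one polydinucleotide
    run (5 tandem units) per started 100 kb of each chromosome, so
    context-specific indels can always be planted.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=probs)
        seq = list(arr.tobytes().decode())
        L = config.genome_length
        for w0 in range(0, L, 100_000):
            w1 = min(w0 + 100_000, L)
            if w1 - w0 < 40:
                continue
            base = "G" if rng.random() < gc else ("A" if gc < 1 else "C")
            p = int(rng.integers(w0, w1 - 30))
            seq[p : p + 8] = base * 8
            if gc >= 1:
                unit = "GC"
            elif gc <= 0:
                unit = "AT"
            else:
                unit = "AC" if rng.random() < 0.5 else "GT"
            for _ in range(50):
                q = int(rng.integers(w0, w1 - 30))
                if abs(q - p) >= 12:
                    break
            else:
                q = min(p + 12, w1 - 30)
            seq[q : q + 10] = unit * 5
        chroms[f"chr{c + 1}"] = "".join(seq)
    return ReferenceGenome(chroms)


# ---------------------------------------------------------------------------
# Mutation planting
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 200
_PAD = 10

_COLLAPSE = {
    "A": "T", "G": "C",  # purine ref -> pyrimidine strand
}


def _find_homopolymer_runs(seq: str, min_run: int = 4) -> list[tuple[int, int, str]]:
    return [
        (m.start(), m.end(), m.group()[0])
        for m in re.finditer(r"A{%d,}|C{%d,}|G{%d,}|T{%d,}" % ((min_run,) * 4), seq)
    ]


def _find_dinuc_runs(seq: str, min_units: int = 3) -> list[tuple[int, int, str]]:
    """Maximal tandem dinucleotide repeats (unit bases differ)."""
    out = []
    i = 0
    n = len(seq)
    while i < n - 3:
        unit = seq[i : i + 2]
        if unit[0] == unit[1]:
            i += 1
            continue
        j = i + 2
        while j + 2 <= n and seq[j : j + 2] == unit:
            j += 2
        units = (j - i) // 2
        if units >= min_units:
            out.append((i, i + units * 2, unit))
            i = i + units * 2
        else:
            i += 1
    return out


class _SitePicker:
    """Tracks claimed intervals so planted events never overlap."""

    def __init__(self, genome: ReferenceGenome, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        s, e = start - _PAD, end + _PAD
        return all(e <= u0 or s >= u1 for u0, u1 in self.used[chrom])

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.used[chrom].append((start, end))

    def random_position(self, width: int = 1, tries: int = 2000):
        names = self.genome.names
        lens = np.array([self.genome.length(c) for c in names], dtype=float)
        for _ in range(tries):
            chrom = names[int(self.rng.choice(len(names), p=lens / lens.sum()))]
            L = self.genome.length(chrom)
            if L <= 2 * _EDGE_MARGIN + width:
                continue
            pos = int(self.rng.integers(_EDGE_MARGIN, L - _EDGE_MARGIN - width))
            if self.is_free(chrom, pos, pos + width):
                return chrom, pos
        raise SimulationError("could not find a free site to plant an event")


def _pick_sbs_site(picker: _SitePicker, req: SBSRequest) -> PlantedSBS:
    rng = picker.rng
    for _ in range(5000):
        chrom, pos = picker.random_position()
        ref = picker.genome.base(chrom, pos)
        if ref == "N":
            continue
        if req.subst_class is None:
            alt = rng.choice([b for b in BASES if b != ref])
        else:
            want_ref, want_alt = req.subst_class.split(">")
            if ref == want_ref:
                alt = want_alt
            elif ref == {"C": "G", "T": "A"}[want_ref]:
                alt = revcomp(want_alt)
            else:
                continue
        picker.claim(chrom, pos, pos + 1)
        return PlantedSBS(chrom, pos, ref, str(alt), req.zygosity)
    raise SimulationError(
        f"no placeable site for SBS request (class {req.subst_class})"
    )


def _pick_indel_site(
    picker: _SitePicker, req: IndelRequest
) -> tuple[PlantedIndel, _SmallIndel]:
    genome, rng = picker.genome, picker.rng
    names = list(genome.names)
    rng.shuffle(names)
    for chrom in names:
        seq = genome[chrom]
        if req.context == "homopolymer":
            runs = _find_homopolymer_runs(seq)
        elif req.context == "polydinucleotide":
            runs = _find_dinuc_runs(seq)
        else:
            runs = []
        if req.context in ("homopolymer", "polydinucleotide"):
            rng.shuffle(runs)
            for rs, re_, unit in runs:
                if rs < _EDGE_MARGIN or re_ > len(seq) - _EDGE_MARGIN:
                    continue
                if not picker.is_free(chrom, rs - 1, re_):
                    continue
                usz = len(unit)
                if req.kind == "del":
                    pos, ref_a = rs - 1, seq[rs - 1] + unit
                    alt_a = seq[rs - 1]
                    small = _SmallIndel("del", rs, unit)
                else:
                    pos, ref_a = rs - 1, seq[rs - 1]
                    alt_a = seq[rs - 1] + unit
                    small = _SmallIndel("ins", rs - 1, unit)
                picker.claim(chrom, rs - 1, re_)
                return (
                    PlantedIndel(
                        chrom, pos, ref_a, alt_a, req.kind, req.context, req.zygosity
                    ),
                    small,
                )
        else:  # context 'other': avoid any local repeat structure
            for _ in range(5000):
                c2, pos = picker.random_position(width=req.size + 2)
                s2 = genome[c2]
                lo, hi = max(pos - 6, 0), min(pos + req.size + 6, len(s2))
                window = s2[lo:hi]
                if _find_homopolymer_runs(window, 3) or _find_dinuc_runs(window, 2):
                    continue
                if req.kind == "del":
                    unit = s2[pos : pos + req.size]
                    rec = PlantedIndel(
                        c2, pos - 1, s2[pos - 1] + unit, s2[pos - 1],
                        "del", "other", req.zygosity,
                    )
                    small = _SmallIndel("del", pos, unit)
                else:
                    unit = "".join(rng.choice(list(BASES), size=req.size))
                    # inserted unit must not extend a neighbouring run
                    if unit[0] == s2[pos] or unit[-1] == s2[pos - 1]:
                        continue
                    rec = PlantedIndel(
                        c2, pos - 1, s2[pos - 1], s2[pos - 1] + unit,
                        "ins", "other", req.zygosity,
                    )
                    small = _SmallIndel("ins", pos - 1, unit)
                picker.claim(c2, pos - 1, pos + req.size)
                return rec, small
            break
    raise SimulationError(
        f"insufficient placeable sites for indel context {req.context!r}"
    )


def _build_pieces(
    genome: ReferenceGenome,
    alignments: dict[str, ChromAlignment],
    svs: Sequence[PlantedSV],
) -> dict[str, list[Piece]]:
    """Apply non-overlapping rearrangements, reference coordinates in."""
    cuts: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome.names}
    inserts: dict[str, list[tuple[int, list[Piece]]]] = {c: [] for c in genome.names}
    for sv in svs:
        aln = alignments[sv.chrom]
        if sv.type == "large_deletion":
            cuts[sv.chrom].append((sv.start, sv.end, "delete"))
        elif sv.type == "inversion":
            cuts[sv.chrom].append((sv.start, sv.end, "invert"))
        elif sv.type == "translocation":
            cuts[sv.chrom].append((sv.start, sv.end, "delete"))
            piece = Piece(sv.chrom, aln.hap_pos(sv.start), aln.hap_pos(sv.end))
            inserts[sv.dest_chrom].append((sv.dest_pos, [piece]))
        elif sv.type == "large_insertion":
            piece = Piece(sv.chrom, aln.hap_pos(sv.start), aln.hap_pos(sv.end))
            inserts[sv.dest_chrom].append((sv.dest_pos, [piece]))
        else:
            raise SimulationError(f"unknown SV type {sv.type!r}")
    pieces: dict[str, list[Piece]] = {}
    for chrom in genome.names:
        aln = alignments[chrom]
        events = sorted(
            [(s, e, kind) for s, e, kind in cuts[chrom]]
            + [(p, p, ("insert", pl)) for p, pl in inserts[chrom]],
            key=lambda t: (t[0], t[1]),
        )
        out: list[Piece] = []
        cursor = 0
        for s, e, kind in events:
            if s < cursor:
                raise SimulationError("overlapping structural variants")
            if s > cursor:
                out.append(Piece(chrom, aln.hap_pos(cursor), aln.hap_pos(s)))
            if isinstance(kind, tuple):
                out.extend(kind[1])
            elif kind == "invert":
                out.append(Piece(chrom, aln.hap_pos(s), aln.hap_pos(e), "-"))
                cursor = e
                continue
            cursor = e
        if cursor < genome.length(chrom):
            out.append(
                Piece(chrom, aln.hap_pos(cursor), aln.hap_pos(genome.length(chrom)))
            )
        pieces[chrom] = [p for p in out if p.length > 0]
    return pieces


def plant_mutations(
    genome: ReferenceGenome,
    spec: MutationSpec,
    seed: int,
    sample_name: str = "sample",
) -> tuple[SampleGenome, TruthSet]:
    """Plant the requested events and return the diploid sample plus truth.

    Homozygous events alter both haplotypes, heterozygous events haplotype 0
    only. Raises :class:`SimulationError` naming the event class when a
    request cannot be placed without overlap.
    """
    rng = np.random.default_rng([seed, 0x9E3779B9])
    picker = _SitePicker(genome, rng)
    truth = TruthSet()

    small: dict[int, dict[str, list]] = {0: {}, 1: {}}  # hap -> chrom -> events
    sbs_by_hap: dict[int, dict[str, list[PlantedSBS]]] = {0: {}, 1: {}}

    for req in spec.sbs:
        rec = _pick_sbs_site(picker, req)
        truth.planted_sbs.append(rec)
        haps = (0, 1) if req.zygosity == "hom" else (0,)
        for h in haps:
            sbs_by_hap[h].setdefault(rec.chrom, []).append(rec)
    for req in spec.indels:
        rec, sv = _pick_indel_site(picker, req)
        truth.planted_indels.append(rec)
        haps = (0, 1) if req.zygosity == "hom" else (0,)
        for h in haps:
            small[h].setdefault(rec.chrom, []).append(sv)

    svs: list[PlantedSV] = []
    for req in spec.svs:
        dest_chrom, dest_pos = req.dest_chrom, req.dest_pos
        if req.type in ("large_insertion", "translocation") and dest_pos is None:
            dest_chrom, dest_pos = picker.random_position(width=1)
        rec = PlantedSV(req.type, req.chrom, req.start, req.end, dest_chrom, dest_pos)
        picker.claim(req.chrom, req.start, req.end)
        if dest_pos is not None:
            picker.claim(dest_chrom, dest_pos, dest_pos + 1)
        svs.append(rec)
        truth.planted_svs.append(rec)
    for req in spec.te_amplifications:
        for k in range(req.extra_copies):
            dest_chrom, dest_pos = req.dest_chrom, req.dest_pos
            if dest_pos is None:
                dest_chrom, dest_pos = picker.random_position(width=1)
            else:
                dest_pos += k  # distinct adjacent sites for multi-copy requests
            svs.append(
                PlantedSV(
                    "large_insertion", req.chrom, req.start, req.end,
                    dest_chrom, dest_pos,
                )
            )
            picker.claim(dest_chrom, dest_pos, dest_pos + 1)
        truth.planted_te_amplifications.append(
            PlantedTEAmplification(
                req.element_id, req.chrom, req.start, req.end,
                req.extra_copies + 1, dest_chrom, dest_pos,
            )
        )

    haplotypes = []
    for h in (0, 1):
        tier_seqs: dict[str, str] = {}
        alignments: dict[str, ChromAlignment] = {}
        for chrom in genome.names:
            seq = list(genome[chrom])
            for rec in sbs_by_hap[h].get(chrom, []):
                seq[rec.pos] = rec.alt
            indels = small[h].get(chrom, [])
            aln = ChromAlignment.from_indels(genome.length(chrom), indels)
            parts = []
            for (op, n), h0, r0 in zip(aln.ops, aln.hap_starts, aln.ref_starts):
                if op == "M":
                    parts.append("".join(seq[r0 : r0 + n]))
                elif op == "I":
                    ins = next(
                        v for v in indels if v.kind == "ins" and v.pos + 1 == r0
                    )
                    parts.append(ins.seq)
            tier_seqs[chrom] = "".join(parts)
            alignments[chrom] = aln
        pieces = _build_pieces(genome, alignments, svs)
        haplotypes.append(Haplotype(tier_seqs, alignments, pieces))
    return SampleGenome(sample_name, (haplotypes[0], haplotypes[1])), truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def _cigar_str(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def simulate_read_pairs(
    sample: SampleGenome, config: SimulationConfig
) -> list[AlignmentRecord]:
    """Paired-end reads drawn uniformly from both haplotypes at ``depth``.

    Fragment lengths are Gaussian (truncated at read_length); mates are
    emitted convergently at fragment distance with mapq 60 and the
    uniqueness flag set. Reads spanning rearrangement breakpoints are
    soft-clipped to their dominant block, giving their pairs the discordant
    coordinates a structural variant produces.
    """
    if config.depth == 0:
        logger.warning("depth 0 requested for %s: empty read stream", sample.name)
        return []
    rng = np.random.default_rng([config.seed, _stable_hash(sample.name)])
    rl = config.read_length
    records: list[AlignmentRecord] = []
    pair_index = 0
    for hap in sample.haplotypes:
        for chrom, seq in hap.seqs.items():
            L = len(seq)
            if L < rl:
                continue
            n_pairs = int(round(L * (config.depth / 2) / (2 * rl)))
            fls = np.clip(
                rng.normal(config.fragment_mean, config.fragment_sd, n_pairs),
                rl,
                L,
            ).astype(int)
            starts = rng.integers(0, L - fls + 1)
            for fl, start in zip(fls, starts):
                fl, start = int(fl), int(start)
                iv1 = (start, start + rl)
                iv2 = (start + fl - rl, start + fl)
                m1 = hap.map_read(chrom, *iv1)
                m2 = hap.map_read(chrom, *iv2)
                if m1 is None or m2 is None:
                    continue
                pair_index += 1
                name = f"{sample.name}.{pair_index}"
                mates = []
                for (c, p, pstrand, cig), (s0, s1), drawn_rev in (
                    (m1, iv1, False),
                    (m2, iv2, True),
                ):
                    f = _apply_errors(seq[s0:s1], config.base_error_rate, rng)
                    stored = f if pstrand == "+" else revcomp(f)
                    strand = "-" if drawn_rev != (pstrand == "-") else "+"
                    mates.append((c, p, strand, _cigar_str(cig), stored))
                for k, (c, p, strand, cig, stored) in enumerate(mates):
                    oc, op_, ostrand, _, _ = mates[1 - k]
                    records.append(
                        AlignmentRecord(
                            name=name,
                            chrom=c,
                            pos=p,
                            strand=strand,
                            mapq=60,
                            unique=True,
                            mate_chrom=oc,
                            mate_pos=op_,
                            mate_strand=ostrand,
                            sequence=stored,
                            cigar=cig,
                            is_read1=(k == 0),
                        )
                    )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def _stable_hash(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(
    sample_name: str,
    records: Iterable[AlignmentRecord],
    truth: TruthSet,
    genome: ReferenceGenome,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a coordinate-sorted SAM plus a truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sam = outdir / f"{sample_name}.sam"
    truth_path = outdir / f"{sample_name}.truth.json"
    write_sam(records, genome, sam)
    truth.to_json(truth_path)
    return {"sam": sam, "truth": truth_path}


def write_fastq(
    records: Iterable[AlignmentRecord], prefix: str | Path
) -> tuple[Path, Path]:
    """Optional FASTQ export for users who want to run a real aligner."""
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rec in records:
            fh = f1 if rec.is_read1 else f2
            seq = rec.sequence if rec.strand == "+" else revcomp(rec.sequence)
            fh.write(f"@{rec.name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return p1, p2
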