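"""Reference genome container with FASTA round-trip."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Named chromosome sequences with 0-based half-open accessors."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos + 1)

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        with open(path) as handle:
            return cls(
                {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
            )

    @classmethod
    def from_string(cls, fasta_text: str) -> "ReferenceGenome":
        handle = io.StringIO(fasta_text)
        return cls(
            {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
        )
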