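"""Core genomic data model: gene structures and the annotation container.

Coordinates are 0-based, half-open throughout (BED convention). A poly(A)
site position is the coordinate of the cleaved nucleotide. For a minus-strand
gene the TSS is the right edge minus one and the 3'-most exon is the
left-most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class GeneModel:
    """A gene with its (merged-isoform) exon structure.

    ``exons`` are disjoint, genomically sorted ``(start, end)`` half-open
    intervals covering the gene span's transcribed blocks.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"gene {self.gene_id}: exons not sorted/disjoint")

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Half-open intervals between consecutive exons, genomic order."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def last_exon(self) -> tuple[int, int]:
        """The 3'-most exon with respect to transcription direction."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def tss_distance(self, position: int) -> int:
        """Signed distance from the TSS in the direction of transcription.

        Positive values are downstream (into the gene), negative upstream.
        """
        d = position - self.tss
        return d if self.strand == "+" else -d

    def intron_index(self, position: int) -> int | None:
        """1-based intron ordinal (5'->3' in transcript orientation), or None."""
        introns = self.introns
        for i, (s, e) in enumerate(introns):
            if s <= position < e:
                genomic_idx = i
                if self.strand == "+":
                    return genomic_idx + 1
                return len(introns) - genomic_idx
        return None


@dataclass
class GenomeAnnotation:
    """Container of gene models keyed by gene id."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
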