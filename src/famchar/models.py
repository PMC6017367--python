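"""Shared domain objects for the gene-family pipeline.

Coordinates are stored 1-based inclusive throughout (GFF3 convention);
conversion to 0-based half-open happens only inside the slicing helpers
defined here, so there is a single place where off-by-one errors can live.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class FamcharError(ValueError):
    """Base class for validation failures raised by this package."""


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def slice_1based(seq: str, start: int, end: int) -> str:
    """Extract the 1-based inclusive interval [start, end] from *seq*."""
    if start < 1 or end > len(seq) or end < start:
        raise FamcharError(f"interval [{start}, {end}] outside sequence of length {len(seq)}")
    return seq[start - 1:end]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon layout on a scaffold.

    ``exons`` are (start, end) pairs, 1-based inclusive, non-overlapping and
    sorted in genome order (5'->3' on the + strand of the scaffold) regardless
    of the gene's own strand; ``strand`` records orientation.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FamcharError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise FamcharError(f"{self.gene_id}: gene model needs at least one exon")
        prev_end = None
        for (s, e) in self.exons:
            if e < s:
                raise FamcharError(f"{self.gene_id}: exon end {e} < start {s}")
            if s < self.start or e > self.end:
                raise FamcharError(
                    f"{self.gene_id}: exon [{s}, {e}] outside gene span [{self.start}, {self.end}]")
            if prev_end is not None and s <= prev_end:
                raise FamcharError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def full_length_bp(self) -> int:
        return self.end - self.start + 1

    def cds(self, scaffold_seq: str) -> str:
        """Spliced coding sequence in transcript orientation."""
        parts = [slice_1based(scaffold_seq, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


@dataclass
class GenomeBundle:
    """A genome with its gene models and translated proteins."""

    scaffolds: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.scaffold_id not in self.scaffolds:
                raise FamcharError(f"{g.gene_id}: unknown scaffold {g.scaffold_id}")
            if g.end > len(self.scaffolds[g.scaffold_id]):
                raise FamcharError(f"{g.gene_id}: extends past scaffold end")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Table1Row:
    """One published family member with its printed characteristics."""

    name: str
    locus_id: str
    location: str
    orf_bp: int
    size_aa: int
    domain_span: tuple[int, int]
    pi: float
    mw_kda: float
    intron_count: int
    full_length_bp: int


@dataclass
class FamilyMember:
    """An accepted family gene carrying everything downstream stages fill in."""

    name: str
    locus_id: str
    protein: str
    orf_bp: int
    size_aa: int
    domain_span: tuple[int, int]
    pi: float
    mw_kda: float
    intron_count: int
    full_length_bp: int
    gene_model: GeneModel | None = None
    e2_class: str | None = None
    uev: bool = False
    group: str = "unplaced"

    def __post_init__(self) -> None:
        if self.orf_bp != 3 * (self.size_aa + 1):
            raise FamcharError(
                f"{self.name}: ORF {self.orf_bp} bp inconsistent with {self.size_aa} aa "
                f"(expected {3 * (self.size_aa + 1)})")
        s, e = self.domain_span
        if not (1 <= s <= e <= self.size_aa):
            raise FamcharError(f"{self.name}: domain span {self.domain_span} outside protein")
        if not (0.0 < self.pi < 14.0):
            raise FamcharError(f"{self.name}: pI {self.pi} out of range")
        if self.mw_kda <= 0:
            raise FamcharError(f"{self.name}: non-positive molecular weight")


@dataclass
class FamilySummary:
    """Family-level aggregates in the precision the published table uses."""

    n: int
    full_length_bp: tuple[float, int, int]   # mean, min, max
    orf_bp: tuple[float, int, int]
    size_aa: tuple[float, int, int]
    mw_kda: tuple[float, float, float]
    pi: tuple[float, float, float]
    intron_histogram: dict[int, int] = field(default_factory=dict)
    intronless: list[str] = field(default_factory=list)
    class_counts: dict[str, int] = field(default_factory=dict)
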