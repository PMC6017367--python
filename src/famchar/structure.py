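"""Exon/intron structure summaries for gene models."""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import FamcharError, GeneModel


@dataclass
class GeneStructure:
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    utrs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def intron_count(self) -> int:
        return len(self.introns)


def gene_structure(model: GeneModel,
                   utrs: tuple[tuple[int, int], ...] = ()) -> GeneStructure:
    """Introns as the inter-exon gaps of the model, in genome order.

    UTR spans are carried through when the annotation provides them; they are
    not inferred.
    """
    introns = []
    for (s1, e1), (s2, _e2) in zip(model.exons, model.exons[1:]):
        if s2 <= e1:
            raise FamcharError(f"{model.gene_id}: overlapping exons")
        introns.append((e1 + 1, s2 - 1))
    return GeneStructure(gene_id=model.gene_id, exons=model.exons,
                         introns=tuple(introns), utrs=tuple(utrs))


def intron_histogram(structures: list[GeneStructure]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for s in structures:
        hist[s.intron_count] = hist.get(s.intron_count, 0) + 1
    return dict(sorted(hist.items()))
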