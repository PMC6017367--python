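"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 1.5-kb regions upstream of the annotated gene start (used
as the transcription-start-site proxy), strand-aware and clipped at scaffold
bounds with an explicit truncation flag. Scanning matches IUPAC consensi on
both strands; every occurrence is reported (no greedy consumption) and ``N``
in the promoter never matches anything.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .models import FamcharError, GeneModel, GenomeBundle, reverse_complement
from .synthetic import IUPAC_DNA

CATEGORIES = {"light", "stress", "MeJA", "salicylic-acid", "gibberellin", "auxin",
              "ethylene", "circadian", "meristem", "heat", "low-temperature", "other"}

PROMOTER_LENGTH = 1500


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element: str
    category: str
    offset: int          # 0-based from the promoter 5' end (leftmost matched base)
    strand: str
    matched: str


def default_element_table() -> pd.DataFrame:
    """The bundled element table (named consensi grouped by response category)."""
    with resources.as_file(resources.files("famchar.data").joinpath("cis_elements.tsv")) as p:
        return load_element_table(p)


def load_element_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"element", "consensus", "category"}
    if not required <= set(table.columns):
        raise FamcharError(f"element table needs columns {sorted(required)}")
    if table["element"].duplicated().any():
        raise FamcharError("duplicate element names in table")
    for rec in table.itertuples(index=False):
        bad = set(rec.consensus.upper()) - set(IUPAC_DNA)
        if bad:
            raise FamcharError(f"{rec.element}: invalid IUPAC codes {sorted(bad)}")
        if rec.category not in CATEGORIES:
            raise FamcharError(f"{rec.element}: unknown category {rec.category!r}")
    return table


def extract_promoter(genome: GenomeBundle, gene: GeneModel,
                     length: int = PROMOTER_LENGTH) -> tuple[str, bool]:
    """The upstream promoter of *gene*, 5'->3' in gene orientation.

    Plus strand: bases [start - length, start - 1]; minus strand: the reverse
    complement of [end + 1, end + length]. Clipped at scaffold bounds; the
    second return value flags truncation (including the empty-promoter case).
    """
    scaffold = genome.scaffolds[gene.scaffold_id]
    if gene.strand == "+":
        lo = max(1, gene.start - length)
        hi = gene.start - 1
        seq = scaffold[lo - 1:hi] if hi >= lo else ""
    else:
        lo = gene.end + 1
        hi = min(len(scaffold), gene.end + length)
        seq = reverse_complement(scaffold[lo - 1:hi]) if hi >= lo else ""
    return seq, len(seq) < length


def _iupac_regex(consensus: str) -> re.Pattern:
    # N in the *promoter* must never match, so classes never include N.
    parts = []
    for code in consensus.upper():
        opts = IUPAC_DNA[code]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")  # lookahead: overlapping matches


def scan_elements(gene_id: str, promoter: str, table: pd.DataFrame) -> list[CisElementHit]:
    """All IUPAC matches of every table element on both promoter strands.

    Minus-strand matches are reported at the + strand offset of the site's
    leftmost base, with the matched substring as it reads on the - strand.
    """
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise FamcharError(f"{gene_id}: promoter contains non-DNA symbols {sorted(bad)}")
    hits: list[CisElementHit] = []
    rc = reverse_complement(promoter)
    n = len(promoter)
    for rec in table.itertuples(index=False):
        pat = _iupac_regex(rec.consensus)
        w = len(rec.consensus)
        for m in pat.finditer(promoter):
            hits.append(CisElementHit(gene_id, rec.element, rec.category,
                                      m.start(), "+", m.group(1)))
        for m in pat.finditer(rc):
            offset = n - m.start() - w   # leftmost base on the + strand
            hits.append(CisElementHit(gene_id, rec.element, rec.category,
                                      offset, "-", m.group(1)))
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def categorize_promoters(hits_per_gene: dict[str, list[CisElementHit]],
                         table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene category presence plus family-level counts.

    A category is present in a gene's promoter if at least one element of
    that category matched. Returns (presence matrix genes x categories,
    per-category gene counts).
    """
    categories = sorted(set(table["category"]))
    presence = pd.DataFrame(False, index=sorted(hits_per_gene), columns=categories)
    for gene_id, hits in hits_per_gene.items():
        for h in hits:
            presence.loc[gene_id, h.category] = True
    return presence, presence.sum(axis=0)


def scan_family(genome: GenomeBundle, table: pd.DataFrame | None = None,
                length: int = PROMOTER_LENGTH,
                ) -> tuple[dict[str, list[CisElementHit]], pd.DataFrame]:
    """Extract and scan every gene's promoter; convenience wrapper.

    Returns (hits per gene, promoter info table with lengths and truncation
    flags).
    """
    if table is None:
        table = default_element_table()
    hits: dict[str, list[CisElementHit]] = {}
    info_rows = []
    for gene in genome.genes:
        promoter, truncated = extract_promoter(genome, gene, length)
        hits[gene.gene_id] = scan_elements(gene.gene_id, promoter, table)
        info_rows.append(dict(gene_id=gene.gene_id, promoter_length=len(promoter),
                              truncated=truncated))
    return hits, pd.DataFrame(info_rows)


def hits_to_frame(hits_per_gene: dict[str, list[CisElementHit]]) -> pd.DataFrame:
    """BED-like table (gene, offset, end, element, category, strand, matched)."""
    rows = [dict(gene_id=h.gene_id, offset=h.offset, end=h.offset + len(h.matched),
                 element=h.element, category=h.category, strand=h.strand,
                 matched=h.matched)
            for hits in hits_per_gene.values() for h in hits]
    return pd.DataFrame(rows, columns=["gene_id", "offset", "end", "element",
                                       "category", "strand", "matched"])
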