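"""Readers and writers for the on-disk formats the pipeline touches.

FASTA goes through Bio.SeqIO with extra validation (unique ids, no empty
records). The GFF3 subset used here (gene / mRNA / exon / CDS with ID and
Parent attributes, 1-based inclusive coordinates) is parsed directly so that
malformed inputs surface as typed :class:`~famchar.models.FamcharError`
exceptions and write->read round-trips are exact.
"""

from __future__ import annotations

import os
from collections import defaultdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FamcharError, GeneModel

GAP_CHARS = "-."


def read_fasta(path: str | os.PathLike, alignment: bool = False) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Sequences are uppercased. Gap characters are preserved only when
    ``alignment`` is true; plain sequence files are degapped.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FamcharError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not alignment:
            for gap in GAP_CHARS:
                seq = seq.replace(gap, "")
        if not seq:
            raise FamcharError(f"empty FASTA record {rec.id!r} in {path}")
        records[rec.id] = seq
    if not records:
        raise FamcharError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str], width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta")
    # Bio.SeqIO wraps at 60 by default which is fine; width kept for API symmetry.


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FamcharError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    Exons are grouped under their gene via the Parent chain (exon -> mRNA ->
    gene, or exon -> gene directly); CDS features are used for genes without
    exon features. Minus-strand exon lists are stored in genome order with
    the strand recorded on the model.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    parent_of: dict[str, str] = {}
    parts: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(lambda: defaultdict(list))
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FamcharError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            scaffold, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FamcharError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FamcharError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _parse_attributes(col9)
            if ftype == "gene":
                if strand not in "+-":
                    raise FamcharError(f"{path}:{lineno}: unknown strand {strand!r}")
                gid = attrs.get("ID")
                if gid is None:
                    raise FamcharError(f"{path}:{lineno}: gene without ID")
                genes[gid] = (scaffold, start, end, strand)
                order.append(gid)
            elif ftype == "mRNA":
                fid, parent = attrs.get("ID"), attrs.get("Parent")
                if fid is None or parent is None:
                    raise FamcharError(f"{path}:{lineno}: mRNA needs ID and Parent")
                parent_of[fid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise FamcharError(f"{path}:{lineno}: {ftype} without Parent")
                parts[parent][ftype].append((start, end))

    models = []
    for gid in order:
        scaffold, start, end, strand = genes[gid]
        # collect exon/CDS features whose parent resolves to this gene
        collected: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for parent, by_type in parts.items():
            root = parent_of.get(parent, parent)
            if root == gid:
                for ftype, spans in by_type.items():
                    collected[ftype].extend(spans)
        spans = collected["exon"] or collected["CDS"]
        if not spans:
            raise FamcharError(f"gene {gid}: no exon or CDS features")
        spans = sorted(spans)
        for s, e in spans:
            if s < start or e > end:
                raise FamcharError(f"gene {gid}: exon [{s}, {e}] outside gene span")
        models.append(GeneModel(gene_id=gid, scaffold_id=scaffold, start=start,
                                end=end, strand=strand, exons=tuple(spans)))
    return models


def write_gff3(path: str | os.PathLike, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(f"{g.scaffold_id}\tfamchar\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.scaffold_id}\tfamchar\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.scaffold_id}\tfamchar\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{i};Parent={mrna}\n")
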