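"""Packaged reference tables.

``load_table1`` returns the published characteristics of the 40-member longan
ubiquitin-conjugating enzyme (UBC / E2) family — locus, scaffold location,
ORF and protein lengths, UBC-domain span, pI, molecular weight, intron count
and genomic full length — typed and validated.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .models import FamcharError, Table1Row

EXPECTED_ROWS = 40


def _data_path(name: str):
    return resources.files("famchar.data").joinpath(name)


def load_table1() -> list[Table1Row]:
    """Load the published family table (40 rows) from package data.

    Raises :class:`FamcharError` if the fixture does not have exactly 40 rows
    or violates the ORF = 3 x (aa + 1) / domain-span invariants.
    """
    with resources.as_file(_data_path("table1.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    if len(df) != EXPECTED_ROWS:
        raise FamcharError(f"family table has {len(df)} rows, expected {EXPECTED_ROWS}")
    rows = []
    for rec in df.itertuples(index=False):
        row = Table1Row(
            name=rec.name,
            locus_id=rec.locus_id,
            location=rec.location,
            orf_bp=int(rec.orf_bp),
            size_aa=int(rec.size_aa),
            domain_span=(int(rec.domain_start), int(rec.domain_end)),
            pi=float(rec.pi),
            mw_kda=float(rec.mw_kda),
            intron_count=int(rec.introns),
            full_length_bp=int(rec.full_length_bp),
        )
        if row.orf_bp != 3 * (row.size_aa + 1):
            raise FamcharError(f"{row.name}: ORF {row.orf_bp} != 3 x ({row.size_aa} + 1)")
        if row.domain_span[1] > row.size_aa:
            raise FamcharError(f"{row.name}: domain span beyond protein end")
        rows.append(row)
    return rows


def table1_dataframe() -> pd.DataFrame:
    """The same fixture as a DataFrame (one row per family member)."""
    with resources.as_file(_data_path("table1.tsv")) as path:
        return pd.read_csv(path, sep="\t")
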