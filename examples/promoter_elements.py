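"""Promoter extraction and cis-regulatory element scanning.

Implants named elements at known promoter offsets/strands (including one
gene with only 6 bp of upstream scaffold), then recovers them by IUPAC
scanning of both strands of every 1.5-kb promoter.
"""

import famchar as fc

cfg = fc.SyntheticConfig(seed=4, n_true_genes=8, n_decoys=4, n_incomplete=0,
                         n_redundant=0, n_uev=0, n_scaffolds=3)
probe = fc.generate_genome(cfg)
man = probe.manifest
plus = man[(man.strand == "+") & ~man.truncated_promoter].gene_id.iloc[0]
minus = man[man.strand == "-"].gene_id.iloc[0]
trunc = man[man.truncated_promoter].gene_id.iloc[0]
implants = [("TCA-element", plus, 700, "-"), ("HSE", plus, 100, "+"),
            ("circadian", minus, 300, "+"), ("CGTCA-motif", trunc, 1, "+")]
genome = fc.generate_genome(
    fc.SyntheticConfig(**{**cfg.__dict__, "cis_implants": implants}))

hits, info = fc.scan_family(genome.bundle)
print("implant -> recovered?")
for element, gid, offset, strand in implants:
    found = any(h.element == element and h.offset == offset and h.strand == strand
                for h in hits[gid])
    print(f"  {element:12s} {gid} @{offset}{strand}: {'yes' if found else 'NO'}")
row = info.set_index("gene_id").loc[trunc]
print(f"truncated promoter: {row.promoter_length} bp available (flagged={bool(row.truncated)})")
presence, counts = fc.categorize_promoters(hits, fc.default_element_table())
print("family-level category counts (genes with >=1 element):")
print(counts[counts > 0].to_string())
# Offsets are 0-based from the promoter 5' end; minus-strand matches are
# reported at the + strand offset of their leftmost base.
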