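"""Physicochemical characterization and the published family table.

Prints the family-level aggregates of the packaged 40-member table (full
length, ORF, protein size, molecular weight, isoelectric point, introns)
and shows the per-protein property calculators on one sequence.
"""

import famchar as fc

summary = fc.summarize_family(fc.load_table1())
print(f"members:            {summary.n}")
print(f"mean full length:   {summary.full_length_bp[0]} bp "
      f"(range {summary.full_length_bp[1]}-{summary.full_length_bp[2]})")
print(f"mean ORF:           {summary.orf_bp[0]} bp")
print(f"mean protein size:  {summary.size_aa[0]} aa")
print(f"mean MW:            {summary.mw_kda[0]} kDa")
print(f"mean pI:            {summary.pi[0]}")
print(f"intron histogram:   {summary.intron_histogram}")
print(f"intronless members: {summary.intronless}")

protein = fc.DEFAULT_CONSENSUS
print(f"\nconsensus domain protein ({len(protein)} aa):")
print(f"  MW = {fc.molecular_weight(protein):.2f} kDa, "
      f"pI = {fc.isoelectric_point(protein):.2f}")
# Architecture class I means the protein is essentially just the domain.
print("  class:", fc.classify_architecture(len(protein), (1, len(protein))))
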