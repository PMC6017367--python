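"""EM motif elicitation on sequences with a shared implanted 15-mer.

Seventeen of twenty random proteins carry the core motif HPNIYSNGSICLDIL;
the discoverer should report it as motif 1 with the correct sites.
"""

import numpy as np

import famchar as fc

implant = "HPNIYSNGSICLDIL"
rng = np.random.default_rng(22)
aa = list("ACDEFGHIKLMNPQRSTVWY")
seqs, truth = {}, {}
for i in range(20):
    length = int(rng.integers(120, 200))
    s = "".join(rng.choice(aa, size=length))
    if i < 17:
        pos = int(rng.integers(0, length - 15))
        s = s[:pos] + implant + s[pos + 15:]
        truth[f"p{i}"] = pos
    seqs[f"p{i}"] = s

motifs = fc.discover_motifs(seqs, k_max=3, w_min=6, w_max=50, mode="anr", seed=13)
top = motifs[0]
recall = sum(1 for sid, off in top.sites if truth.get(sid) == off) / len(truth)
print(f"implant:           {implant}")
print(f"motif 1 consensus: {top.consensus}  (width {top.width})")
print(f"sites found:       {len(top.sites)}  site recall: {recall:.2f}")
print(f"e-score:           {top.e_score:.1f}  (relative entropy x sites)")
presence = fc.motif_presence(motifs[:1], seqs, score_min=20.0)
print(f"sequences carrying motif 1: {int(presence[1].sum())}/20")
# A recall of 1.0 means every implanted occurrence was reported at its
# exact offset; later motifs describe whatever signal remains after erasure.
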