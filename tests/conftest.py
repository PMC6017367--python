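import numpy as np
import pytest

import famchar as fc


@pytest.fixture(scope="session")
def seed_profile():
    """Domain profile built from the synthetic seed alignment."""
    return fc.build_profile(fc.synthetic_seed_alignment(seed=3))


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome with every candidate category present."""
    cfg = fc.SyntheticConfig(seed=1, n_true_genes=6, n_decoys=8, n_incomplete=3,
                             n_redundant=2, n_uev=1, n_scaffolds=3)
    return fc.generate_genome(cfg)


@pytest.fixture(scope="session")
def implant_sequences():
    """20 random proteins, 17 carrying the exact published core 15-mer."""
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
    return seqs, truth, implant
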