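"""Seeded synthetic genomes, alignments, and count matrices.

This module emulates the study conditions the pipeline is exercised under:

* a multi-scaffold genome carrying genes whose proteins contain a full
  (possibly mutated) copy of a domain consensus, genes with truncated
  (incomplete) domain copies, near-identical redundant duplicates of true
  genes at distinct loci, decoy genes with no implant, one designated gene
  with almost no upstream sequence, and cis-element implants at stated
  promoter offsets/strands;
* negative-binomially distributed read-count matrices with specified
  log2 fold changes between two conditions;
* qPCR Ct tables with an internal reference gene.

Everything is driven by a single integer seed: the same
:class:`SyntheticConfig` produces byte-identical outputs. Ground truth for
every candidate is recorded in a manifest so recovery can be scored exactly.

The default configuration mirrors the family-mining bookkeeping of the study
this package models: 40 true members, 24 incomplete-domain candidates and
8 redundant duplicates (72 candidates total) among 60 decoys, three UEV
(active-site-less) members, and a designated gene with 6 bp of upstream
scaffold. All sequence content is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .models import FamcharError, GeneModel, GenomeBundle, reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Synthetic 150-aa domain consensus (not a natural sequence). It carries the
#: published N-terminal core motif HPNIYSNGSICLDIL at columns 31-45 and the
#: catalytic cysteine at column 86 (1-based).
DEFAULT_CONSENSUS = (
    "MSIDFCLVDYFTCKGCWTAKIACSEPQMTAHPNIYSNGSICLDILTFMCNFFRFTFKQHL"
    "CLPPAINKSMGQHIRECDLPWGVIECPHRFNCHNFYHGFQDCHVQTDCYHSSCLIQQGQI"
    "STCWDPRGDDHGFSNFSDDSMVHTFFGRHT"
)
ACTIVE_SITE_INDEX = 85  # 0-based position of the catalytic Cys in the consensus

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SyntheticConfig:
    """Everything the generators need, in one seeded record."""

    seed: int = 0
    n_scaffolds: int = 10
    n_true_genes: int = 40
    n_decoys: int = 60
    n_incomplete: int = 24
    n_redundant: int = 8
    n_uev: int = 3
    domain_consensus: str = DEFAULT_CONSENSUS
    active_site_index: int = ACTIVE_SITE_INDEX
    mutation_rate: float = 0.08
    truncated_upstream_bp: int = 6
    cis_implants: list[tuple[str, str, int, str]] = field(default_factory=list)
    # counts design: n_genes, n_replicates, dispersion, [(gene_id, lfc), ...]
    counts_n_genes: int = 40
    counts_n_replicates: int = 3
    counts_dispersion: float = 0.05
    counts_lfc: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "n_true_genes", "n_decoys", "n_incomplete",
                     "n_redundant", "n_uev", "counts_n_genes", "counts_n_replicates"):
            if getattr(self, name) < 0:
                raise FamcharError(f"{name} must be non-negative")
        if self.n_uev > self.n_true_genes:
            raise FamcharError("n_uev cannot exceed n_true_genes")
        if self.counts_dispersion <= 0:
            raise FamcharError("dispersion must be positive")
        if not set(self.domain_consensus) <= set(AMINO_ACIDS):
            raise FamcharError("domain consensus contains non-standard residues")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cis_implants"] = [tuple(x) for x in raw.get("cis_implants", [])]
        raw["counts_lfc"] = [tuple(x) for x in raw.get("counts_lfc", [])]
        return cls(**raw)


@dataclass
class SyntheticGenome:
    bundle: GenomeBundle
    manifest: pd.DataFrame       # ground truth per candidate gene
    cis_manifest: pd.DataFrame   # ground truth per implanted cis-element
    config: SyntheticConfig


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            frozen: set[int] | None = None) -> str:
    out = list(seq)
    for i in range(len(out)):
        if frozen and i in frozen:
            continue
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AMINO_ACIDS if a != out[i]])
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _split_into_exons(rng: np.random.Generator, seq: str) -> tuple[list[str], list[str]]:
    """Split a genomic coding stretch into exon pieces with random introns."""
    n_introns = int(rng.integers(0, 7))
    n_introns = min(n_introns, max(0, len(seq) // 60 - 1))
    if n_introns == 0:
        return [seq], []
    cuts = sorted(rng.choice(np.arange(30, len(seq) - 30), size=n_introns, replace=False))
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(seq[prev:int(c)])
        prev = int(c)
    pieces.append(seq[prev:])
    introns = [_random_dna(rng, int(rng.integers(60, 400))) for _ in range(n_introns)]
    return pieces, introns


def _design_proteins(rng: np.random.Generator, cfg: SyntheticConfig):
    """Return per-gene records: (gene_id, category, protein, implant_span, uev, dup_of)."""
    cons = cfg.domain_consensus
    records = []
    uev_ids = set(range(cfg.n_uev))  # first n_uev true genes lack the catalytic Cys
    true_proteins: dict[str, str] = {}
    for i in range(cfg.n_true_genes):
        gid = f"synt_true{i + 1:03d}"
        n_ext = int(rng.integers(5, 61))
        c_ext = int(rng.integers(5, 61))
        domain = _mutate(rng, cons, cfg.mutation_rate, frozen={cfg.active_site_index})
        uev = i in uev_ids
        if uev:
            domain = domain[:cfg.active_site_index] + "S" + domain[cfg.active_site_index + 1:]
        prot = _random_protein(rng, n_ext) + domain + _random_protein(rng, c_ext)
        span = (n_ext + 1, n_ext + len(cons))
        records.append((gid, "true", prot, span, uev, ""))
        true_proteins[gid] = prot
    for i in range(cfg.n_incomplete):
        gid = f"synt_part{i + 1:03d}"
        frac = rng.uniform(0.25, 0.55)          # < 60% of the consensus length
        keep = int(round(frac * len(cons)))
        piece = cons[:keep] if rng.random() < 0.5 else cons[-keep:]
        piece = _mutate(rng, piece, cfg.mutation_rate)
        n_ext = int(rng.integers(5, 41))
        prot = _random_protein(rng, n_ext) + piece + _random_protein(rng, int(rng.integers(5, 41)))
        records.append((gid, "incomplete", prot, (n_ext + 1, n_ext + keep), False, ""))
    true_ids = sorted(true_proteins)
    for i in range(cfg.n_redundant):
        gid = f"synt_dup{i + 1:03d}"
        src = true_ids[int(rng.integers(len(true_ids)))] if true_ids else None
        if src is None:
            raise FamcharError("redundant candidates require at least one true gene")
        # exact mutation count keeps identity unambiguously >= 99%
        base = list(true_proteins[src])
        k = max(1, len(base) // 200)
        for pos in rng.choice(len(base), size=k, replace=False):
            base[pos] = rng.choice([a for a in AMINO_ACIDS if a != base[pos]])
        prot = "".join(base)
        src_rec = next(r for r in records if r[0] == src)
        records.append((gid, "redundant", prot, src_rec[3], src_rec[4], src))
    for i in range(cfg.n_decoys):
        gid = f"synt_decoy{i + 1:03d}"
        prot = _random_protein(rng, int(rng.integers(120, 400)))
        records.append((gid, "decoy", prot, (0, 0), False, ""))
    return records


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Build a seeded multi-scaffold genome with implanted candidates.

    Returns the genome bundle plus a manifest that partitions every candidate
    into {true, incomplete, redundant, decoy} with its implant coordinates,
    UEV status, and (for redundant genes) the duplicated source gene; a second
    manifest records each implanted cis-element with its promoter offset and
    strand. Same config, same bytes.
    """
    rng = np.random.default_rng(config.seed)
    records = _design_proteins(rng, config)
    order = rng.permutation(len(records))

    n_scaff = max(1, config.n_scaffolds)
    scaffold_parts: list[list[str]] = [[] for _ in range(n_scaff)]
    scaffold_pos = [0] * n_scaff
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    manifest_rows = []
    designated = records[order[0]][0] if len(records) else None

    for rank, idx in enumerate(order):
        gid, category, prot, span, uev, dup_of = records[idx]
        sc = rank % n_scaff
        strand = "+" if rng.random() < 0.5 else "-"
        if gid == designated:
            strand = "+"  # keep the truncated-promoter case on the + strand
            gap = config.truncated_upstream_bp
        else:
            gap = int(rng.integers(1800, 3001))
        cds = _reverse_translate(rng, prot)
        placed = cds if strand == "+" else reverse_complement(cds)
        exon_seqs, intron_seqs = _split_into_exons(rng, placed)

        scaffold_parts[sc].append(_random_dna(rng, gap))
        scaffold_pos[sc] += gap
        gene_start = scaffold_pos[sc] + 1
        exons = []
        for j, ex in enumerate(exon_seqs):
            ex_start = scaffold_pos[sc] + 1
            scaffold_parts[sc].append(ex)
            scaffold_pos[sc] += len(ex)
            exons.append((ex_start, scaffold_pos[sc]))
            if j < len(intron_seqs):
                scaffold_parts[sc].append(intron_seqs[j])
                scaffold_pos[sc] += len(intron_seqs[j])
        gene_end = scaffold_pos[sc]
        genes.append(GeneModel(gene_id=gid, scaffold_id=f"scaffold{sc + 1}",
                               start=gene_start, end=gene_end, strand=strand,
                               exons=tuple(exons)))
        proteins[gid] = prot
        manifest_rows.append(dict(
            gene_id=gid, category=category, scaffold=f"scaffold{sc + 1}",
            start=gene_start, end=gene_end, strand=strand,
            implant_start_aa=span[0], implant_end_aa=span[1],
            uev=uev, duplicate_of=dup_of,
            truncated_promoter=(gid == designated)))

    for sc in range(n_scaff):
        # tail long enough that minus-strand genes keep a full 1.5-kb promoter
        scaffold_parts[sc].append(_random_dna(rng, int(rng.integers(1800, 2500))))
        scaffold_pos[sc] += len(scaffold_parts[sc][-1])
    scaffolds = {f"scaffold{sc + 1}": "".join(scaffold_parts[sc]) for sc in range(n_scaff)}

    gene_by_id = {g.gene_id: g for g in genes}
    cis_rows = []
    for element, gid, offset, strand in config.cis_implants:
        consensus = _element_consensus(element)
        concrete = "".join(rng.choice(list(IUPAC_DNA[c])) for c in consensus.upper())
        g = gene_by_id[gid]
        scaffold = scaffolds[g.scaffold_id]
        length = len(concrete)
        if g.strand == "+":
            avail = min(1500, g.start - 1)
            if offset + length > avail:
                raise FamcharError(
                    f"cis implant {element} at offset {offset} exceeds the "
                    f"{avail}-bp promoter of {gid}")
            pos0 = (g.start - avail - 1) + offset       # 0-based genome index
            written = concrete if strand == "+" else reverse_complement(concrete)
            scaffold = scaffold[:pos0] + written + scaffold[pos0 + length:]
        else:
            avail = min(1500, len(scaffold) - g.end)
            if offset + length > avail:
                raise FamcharError(
                    f"cis implant {element} at offset {offset} exceeds the "
                    f"{avail}-bp promoter of {gid}")
            pos0 = g.end + avail - offset - length      # 0-based genome index
            written = reverse_complement(concrete) if strand == "+" else concrete
            scaffold = scaffold[:pos0] + written + scaffold[pos0 + length:]
        scaffolds[g.scaffold_id] = scaffold
        cis_rows.append(dict(gene_id=gid, element=element, offset=offset,
                             strand=strand, sequence=concrete))

    manifest = pd.DataFrame(manifest_rows)
    cis_manifest = pd.DataFrame(
        cis_rows, columns=["gene_id", "element", "offset", "strand", "sequence"])
    bundle = GenomeBundle(scaffolds=scaffolds, genes=genes, proteins=proteins)
    return SyntheticGenome(bundle=bundle, manifest=manifest,
                           cis_manifest=cis_manifest, config=config)


def _element_consensus(element: str) -> str:
    from .promoter import default_element_table  # local import to avoid a cycle
    table = default_element_table()
    row = table[table["element"] == element]
    if row.empty:
        raise FamcharError(f"unknown cis-element {element!r}")
    return row.iloc[0]["consensus"]


def sample_nb_counts(mu: np.ndarray, lfc: np.ndarray, dispersion: float,
                     n_replicates: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """NB counts for two conditions: A at mean mu, B at mu * 2**lfc.

    Variance is ``mu + dispersion * mu**2``; zero-mean genes yield all-zero
    counts. Returns (counts_a, counts_b), each genes x replicates.
    """
    if dispersion <= 0:
        raise FamcharError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    lfc = np.asarray(lfc, dtype=float)

    def draw(means: np.ndarray) -> np.ndarray:
        out = np.zeros((len(means), n_replicates), dtype=int)
        pos = means > 0
        if pos.any():
            nb_n = 1.0 / dispersion
            p = nb_n / (nb_n + means[pos, None])
            out[pos] = rng.negative_binomial(nb_n, p, size=(int(pos.sum()), n_replicates))
        return out

    return draw(mu), draw(mu * np.power(2.0, lfc))


def generate_counts(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix for two conditions, A (control) and B.

    Counts for gene g in condition c are NB with mean ``mu_g * 2**(lfc_g)``
    in B and ``mu_g`` in A, with variance ``mu + dispersion * mu**2``. Returns
    (counts, design) where design records mu, lfc, and gene length in bp.
    """
    if config.counts_n_replicates < 2:
        raise FamcharError("need at least 2 replicates per condition")
    rng = np.random.default_rng(config.seed + 1)
    n, r = config.counts_n_genes, config.counts_n_replicates
    gene_ids = [f"gene{i + 1:04d}" for i in range(n)]
    lfc_map = dict(config.counts_lfc)
    unknown = set(lfc_map) - set(gene_ids)
    if unknown:
        raise FamcharError(f"fold-change design names unknown genes: {sorted(unknown)}")
    mu = np.round(rng.lognormal(mean=5.0, sigma=1.0, size=n))
    lengths = rng.integers(400, 4000, size=n)
    lfc = np.array([lfc_map.get(g, 0.0) for g in gene_ids])
    a, b = sample_nb_counts(mu, lfc, config.counts_dispersion, r,
                            seed=int(rng.integers(2**31)))
    counts = pd.DataFrame(
        np.hstack([a, b]), index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"A_{i + 1}" for i in range(r)] + [f"B_{i + 1}" for i in range(r)])
    design = pd.DataFrame(dict(gene_id=gene_ids, mu=mu, lfc=lfc, length_bp=lengths))
    return counts, design


def generate_ct_table(config: SyntheticConfig, genes: list[str],
                      conditions: list[str], true_log2: dict[tuple[str, str], float],
                      replicates: int = 3) -> pd.DataFrame:
    """Simulate a qPCR Ct table with an internal reference gene.

    ``true_log2[(gene, condition)]`` is the underlying log2 expression relative
    to the reference; Ct(target) = Ct(ref) - log2(rel) + noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for gene in genes:
        for cond in conditions:
            for rep in range(1, replicates + 1):
                ct_ref = 20.0 + rng.normal(0, 0.15)
                rel = true_log2.get((gene, cond), 0.0)
                ct_t = ct_ref - rel + rng.normal(0, 0.15)
                rows.append(dict(gene=gene, condition=cond, replicate=rep,
                                 ct_target=round(ct_t, 3), ct_reference=round(ct_ref, 3)))
    return pd.DataFrame(rows)


def synthetic_seed_alignment(n_sequences: int = 25, mutation_rate: float = 0.10,
                             gap_rate: float = 0.02, seed: int = 0,
                             consensus: str = DEFAULT_CONSENSUS,
                             active_site_index: int = ACTIVE_SITE_INDEX,
                             ) -> dict[str, str]:
    """A gapped seed alignment for the domain, plus its annotation row.

    The returned mapping contains ``n_sequences`` aligned sequences derived
    from the consensus by point mutation and sparse gapping, and a final
    ``#active_site`` row marking the catalytic-Cys column with ``*``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n_sequences):
        seq = list(_mutate(rng, consensus, mutation_rate, frozen={active_site_index}))
        for j in range(len(seq)):
            if j != active_site_index and rng.random() < gap_rate:
                seq[j] = "-"
        out[f"seed{i + 1:02d}"] = "".join(seq)
    ann = ["."] * len(consensus)
    ann[active_site_index] = "*"
    out["#active_site"] = "".join(ann)
    return out


def synthetic_reference_family(n_groups: int = 15, refs_per_group: int = 1,
                               members_per_group: int = 2, seed: int = 0,
                               within_rate: float = 0.03, between_rate: float = 0.35,
                               ) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Labeled reference proteins plus unlabeled members with known groups.

    Group archetypes are heavily mutated copies of the domain consensus
    (``between_rate``); references and members within a group differ from the
    archetype only lightly (``within_rate``), so clades are well separated.
    Returns (sequences, reference_labels, member_truth).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    truth: dict[str, str] = {}
    for g in range(1, n_groups + 1):
        group = f"UBC{g}"
        archetype = _mutate(rng, DEFAULT_CONSENSUS, between_rate)
        for r in range(1, refs_per_group + 1):
            rid = f"ref_{group}_{r}"
            seqs[rid] = _mutate(rng, archetype, within_rate)
            labels[rid] = group
        for m in range(1, members_per_group + 1):
            mid = f"member_{group}_{m}"
            seqs[mid] = _mutate(rng, archetype, within_rate)
            truth[mid] = group
    return seqs, labels, truth
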