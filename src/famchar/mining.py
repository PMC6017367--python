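"""Domain-based family mining.

The pipeline: build a position-specific log-odds profile from a seed
alignment of the domain, scan a proteome with affine-gap local alignment and
an empirically calibrated e-value cutoff, confirm candidates by similarity to
reference family proteins, remove incomplete-domain and redundant candidates,
and name the survivors in chromosomal order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import align
from .align import AA_INDEX, AMINO_ACIDS, encode
from .models import FamcharError, GeneModel

DEFAULT_E_CUTOFF = 0.01
DEFAULT_MIN_COVERAGE = 0.6
DEFAULT_REDUNDANCY_IDENTITY = 0.98
REDUNDANCY_MUTUAL_COVERAGE = 0.95


@dataclass
class DomainProfile:
    """Log-odds profile over match columns of a seed alignment."""

    matrix: np.ndarray           # (consensus_length, 20) log2-odds scores
    background: np.ndarray      # length-20 residue frequencies, sums to 1
    active_site_column: int     # 0-based index of the catalytic-Cys column

    @property
    def consensus_length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    score: float
    e_value: float
    target_span: tuple[int, int]    # 1-based inclusive on the protein
    profile_span: tuple[int, int]   # 1-based inclusive on the profile
    coverage: float


@dataclass
class CandidateSet:
    hits: list[DomainHit]
    removed_incomplete: list[str] = field(default_factory=list)
    removed_redundant: list[str] = field(default_factory=list)
    accepted: list[str] = field(default_factory=list)
    names: dict[str, str] = field(default_factory=dict)   # assigned name -> gene id


def build_profile(seed_alignment: dict[str, str], pseudocount: float = 1.0) -> DomainProfile:
    """Build a log-odds profile from a gapped seed alignment.

    Match columns are those with gap fraction < 50% among the aligned
    sequences; all-gap columns are dropped with a warning. Column scores are
    log2 of the pseudocount-smoothed residue frequency over the background:
    ``log2(((f + pc*bg) / (1 + pc)) / bg)`` with ``f`` the observed residue
    fraction of the column — frequency-based, so duplicated identical
    sequences leave the profile unchanged. The active-site column is read
    from an annotation row (id starting with ``#``) that marks the catalytic
    position with ``*``.
    """
    annotation = None
    seqs: dict[str, str] = {}
    for name, seq in seed_alignment.items():
        if name.startswith("#"):
            annotation = seq
        else:
            seqs[name] = seq.upper()
    if not seqs:
        raise FamcharError("seed alignment has no sequences")
    lengths = {len(s) for s in seqs.values()}
    if annotation is not None:
        lengths.add(len(annotation))
    if len(lengths) != 1:
        raise FamcharError("ragged seed alignment: sequences differ in length")
    width = lengths.pop()
    if annotation is None:
        raise FamcharError("seed alignment lacks a '#'-flagged active-site annotation row")
    rows = list(seqs.values())
    n_seqs = len(rows)

    bg_counts = np.full(20, 1e-9)
    for s in rows:
        for a in s:
            if a in AA_INDEX:
                bg_counts[AA_INDEX[a]] += 1
    background = bg_counts / bg_counts.sum()

    columns, active_col = [], None
    for j in range(width):
        col = [s[j] for s in rows]
        gaps = sum(1 for a in col if a not in AA_INDEX)
        if gaps == n_seqs:
            warnings.warn(f"seed alignment column {j + 1} is all gaps; dropped")
            continue
        if gaps / n_seqs >= 0.5:
            continue
        counts = np.zeros(20)
        for a in col:
            if a in AA_INDEX:
                counts[AA_INDEX[a]] += 1
        frac = counts / counts.sum()
        freq = (frac + pseudocount * background) / (1.0 + pseudocount)
        scores = np.log2(freq / background)
        if annotation[j] == "*":
            active_col = len(columns)
        columns.append(scores)
    if active_col is None:
        raise FamcharError("active-site column is not a match column of the profile")
    return DomainProfile(matrix=np.vstack(columns), background=background,
                         active_site_column=active_col)


def scan_proteome(profile: DomainProfile, proteins: dict[str, str],
                  e_cutoff: float = DEFAULT_E_CUTOFF, *, seed: int = 0,
                  n_shuffles: int = 1000,
                  gap_open: float = align.DEFAULT_GAP_OPEN,
                  gap_ext: float = align.DEFAULT_GAP_EXTEND) -> list[DomainHit]:
    """Scan every protein with the profile; keep hits with e-value <= cutoff.

    E-values come from a Gumbel null fitted to the scores of shuffled input
    sequences (seeded; see :func:`famchar.align.calibrate_gumbel`). Records
    with non-amino-acid symbols are skipped with a warning.
    """
    if e_cutoff <= 0:
        raise FamcharError("e-value cutoff must be positive")
    encoded: dict[str, np.ndarray] = {}
    for gene_id, seq in proteins.items():
        try:
            encoded[gene_id] = encode(seq)
        except FamcharError as exc:
            warnings.warn(f"{gene_id}: {exc}; record skipped")
    if not encoded:
        return []
    loc, scale = align.calibrate_gumbel(profile.matrix, list(encoded.values()),
                                        n_shuffles=n_shuffles, seed=seed,
                                        gap_open=gap_open, gap_ext=gap_ext)
    hits = []
    for gene_id, codes in encoded.items():
        score, tspan, pspan = align.local_align(codes, profile.matrix, gap_open, gap_ext)
        if score <= 0:
            continue
        ev = align.evalue(score, loc, scale, len(encoded))
        if ev <= e_cutoff:
            coverage = (pspan[1] - pspan[0] + 1) / profile.consensus_length
            hits.append(DomainHit(gene_id=gene_id, score=score, e_value=ev,
                                  target_span=tspan, profile_span=pspan,
                                  coverage=coverage))
    return hits


def confirm_by_similarity(hits: list[DomainHit], proteins: dict[str, str],
                          references: dict[str, str], bit_threshold: float,
                          ) -> list[DomainHit]:
    """Keep hits whose best local alignment to any reference clears a bit score.

    Uses the same affine-gap local DP as the profile scan, with the reference
    recast as BLOSUM62 score columns; BLOSUM62 is in half-bit units so the
    bit score is half the raw score.
    """
    if not references:
        raise FamcharError("reference set is empty")
    if not hits:
        return []
    ref_cols = [align.blosum62_columns(encode(seq)) for seq in references.values()]
    kept = []
    for hit in hits:
        codes = encode(proteins[hit.gene_id])
        best = max(align.local_align(codes, cols)[0] for cols in ref_cols)
        if best / 2.0 >= bit_threshold:
            kept.append(hit)
    return kept


def _identity(a: str, b: str) -> tuple[float, float]:
    """(identity over the global alignment, mutual length coverage)."""
    res = edlib.align(a, b, task="distance", mode="NW")
    alen = max(len(a), len(b))
    return 1.0 - res["editDistance"] / alen, min(len(a), len(b)) / alen


def filter_candidates(hits: list[DomainHit], proteins: dict[str, str],
                      min_coverage: float = DEFAULT_MIN_COVERAGE,
                      redundancy_identity: float = DEFAULT_REDUNDANCY_IDENTITY,
                      ) -> CandidateSet:
    """Remove incomplete-domain and redundant candidates.

    Incomplete: profile coverage below ``min_coverage``. Redundant: pairwise
    identity >= ``redundancy_identity`` over >= 95% mutual length coverage
    with an already-kept candidate; the longer protein wins, ties going to
    the lexicographically smaller id.
    """
    if not (0 < min_coverage <= 1) or not (0 < redundancy_identity <= 1):
        raise FamcharError("thresholds must lie in (0, 1]")
    result = CandidateSet(hits=list(hits))
    complete = []
    for hit in hits:
        if hit.coverage < min_coverage:
            result.removed_incomplete.append(hit.gene_id)
        else:
            complete.append(hit.gene_id)
    # longer first so the keeper is decided before its duplicates arrive
    ranked = sorted(complete, key=lambda g: (-len(proteins[g]), g))
    kept: list[str] = []
    for gid in ranked:
        dup = False
        for keeper in kept:
            ident, mutual = _identity(proteins[gid], proteins[keeper])
            if ident >= redundancy_identity and mutual >= REDUNDANCY_MUTUAL_COVERAGE:
                dup = True
                break
        if dup:
            result.removed_redundant.append(gid)
        else:
            kept.append(gid)
    order = {h.gene_id: i for i, h in enumerate(hits)}
    result.accepted = sorted(kept, key=order.__getitem__)
    return result


def _natural_key(text: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", text))


def assign_names(accepted: list[str], gene_models: dict[str, GeneModel],
                 prefix: str) -> dict[str, str]:
    """Name accepted genes prefix1..prefixN by chromosomal location.

    Ordering: scaffold id under natural numeric ordering (scaffold2 before
    scaffold10), then start coordinate. Returns name -> gene id, in order.
    """
    for gid in accepted:
        if gid not in gene_models:
            raise FamcharError(f"no gene model for accepted gene {gid}")
    ordered = sorted(accepted, key=lambda g: (_natural_key(gene_models[g].scaffold_id),
                                              gene_models[g].start))
    return {f"{prefix}{i + 1}": gid for i, gid in enumerate(ordered)}


def mine_family(profile: DomainProfile, proteins: dict[str, str],
                gene_models: dict[str, GeneModel], prefix: str = "FAM",
                e_cutoff: float = DEFAULT_E_CUTOFF,
                min_coverage: float = DEFAULT_MIN_COVERAGE,
                redundancy_identity: float = DEFAULT_REDUNDANCY_IDENTITY,
                references: dict[str, str] | None = None,
                bit_threshold: float = 0.0, seed: int = 0,
                n_shuffles: int = 1000) -> CandidateSet:
    """End-to-end mining: scan, optionally confirm, filter, and name."""
    hits = scan_proteome(profile, proteins, e_cutoff, seed=seed, n_shuffles=n_shuffles)
    if references:
        hits = confirm_by_similarity(hits, proteins, references, bit_threshold)
    candidates = filter_candidates(hits, proteins, min_coverage, redundancy_identity)
    candidates.names = assign_names(candidates.accepted, gene_models, prefix)
    return candidates
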