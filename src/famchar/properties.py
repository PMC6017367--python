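"""Physicochemical properties and E2 architecture classes.

Molecular weight is the sum of average residue masses plus one water;
isoelectric point solves Henderson-Hasselbalch net charge = 0 by bisection
with the Bjellqvist pKa set (the set behind the common web calculators).
Architecture classes follow the E2 convention: class I is the bare catalytic
domain, II adds an N-terminal extension, III a C-terminal extension, IV both.
UEVs are members whose residue at the profile's active-site column is not
cysteine.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

from . import align
from .mining import CandidateSet, DomainHit, DomainProfile
from .models import FamcharError, FamilyMember, FamilySummary, GeneModel, Table1Row

#: Average (not monoisotopic) residue masses, Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Bjellqvist pKa values: side chains plus termini.
PKA_BJELLQVIST = {
    "Nterm": 7.50, "Cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    "H": 5.98, "K": 10.00, "R": 12.00,
}

NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")
POSITIVE_GROUPS = ("Nterm", "H", "K", "R")

DEFAULT_EXTENSION_MIN = 25


def molecular_weight(protein: str) -> float:
    """Average molecular weight in kDa (unrounded; reports use 2 decimals)."""
    total = WATER_MASS
    for pos, aa in enumerate(protein, 1):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise FamcharError(f"unknown residue {aa!r} at position {pos}") from None
    return total / 1000.0


def net_charge(protein_counts: Counter, ph: float,
               pka: dict[str, float] = PKA_BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    q = 0.0
    for group in POSITIVE_GROUPS:
        n = 1 if group == "Nterm" else protein_counts.get(group, 0)
        if n:
            q += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in NEGATIVE_GROUPS:
        n = 1 if group == "Cterm" else protein_counts.get(group, 0)
        if n:
            q -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return q


def isoelectric_point(protein: str, pka: dict[str, float] = PKA_BJELLQVIST,
                      tol: float = 1e-4, max_iter: int = 200) -> float:
    """pH of zero net charge, by bisection on [0, 14] (unrounded)."""
    bad = set(protein) - set(RESIDUE_MASS)
    if bad:
        raise FamcharError(f"unknown residues {sorted(bad)}")
    missing = {"D", "E", "C", "Y", "H", "K", "R", "Nterm", "Cterm"} - set(pka)
    if missing:
        raise FamcharError(f"pKa set lacks groups {sorted(missing)}")
    counts = Counter(protein)
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = net_charge(counts, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise FamcharError("isoelectric point bisection did not converge")


def classify_architecture(size_aa: int, domain_span: tuple[int, int],
                          extension_min: int = DEFAULT_EXTENSION_MIN) -> str:
    """E2 class from the domain position within the protein."""
    start, end = domain_span
    if not (1 <= start <= end <= size_aa):
        raise FamcharError(f"domain span {domain_span} outside protein of {size_aa} aa")
    if extension_min < 1:
        raise FamcharError("extension_min must be >= 1")
    n_ext = start - 1
    c_ext = size_aa - end
    long_n = n_ext >= extension_min
    long_c = c_ext >= extension_min
    if long_n and long_c:
        return "IV"
    if long_n:
        return "II"
    if long_c:
        return "III"
    return "I"


def detect_uev(protein: str, profile: DomainProfile, hit: DomainHit) -> bool:
    """True iff the residue aligned to the active-site column is not Cys.

    If the alignment deletes the active-site column (or the hit does not
    reach it), no cysteine can sit at the catalytic position, so the member
    is flagged UEV with a warning.
    """
    qs, qe = hit.target_span
    cs, ce = hit.profile_span
    codes = align.encode(protein[qs - 1:qe])
    cols = profile.matrix[cs - 1:ce, :]
    target_col = profile.active_site_column - (cs - 1)  # 0-based within the slice
    if target_col < 0 or target_col >= cols.shape[0]:
        warnings.warn(f"hit on {hit.gene_id} does not span the active-site column")
        return True
    for i, j in align.traceback_align(codes, cols):
        if j == target_col:
            if i is None:
                warnings.warn(f"{hit.gene_id}: active-site column deleted in alignment")
                return True
            return protein[qs - 1 + i] != "C"
    warnings.warn(f"{hit.gene_id}: active-site column outside the local alignment")
    return True


def _mean(values, decimals: int | None) -> float:
    m = sum(values) / len(values)
    if decimals is None:
        return round(m)
    # published two-decimal aggregates are truncated, not rounded
    return math.floor(m * 10 ** decimals + 1e-9) / 10 ** decimals


def summarize_family(members: list[Table1Row] | list[FamilyMember]) -> FamilySummary:
    """Family aggregates at the published table's precision.

    bp/aa means are rounded to integers; kDa and pI means are truncated to
    two decimals (the convention the published aggregates follow). The
    histogram counts members per intron count; intronless members are listed
    by name.
    """
    if not members:
        raise FamcharError("cannot summarize an empty family")
    fl = [m.full_length_bp for m in members]
    orf = [m.orf_bp for m in members]
    aa = [m.size_aa for m in members]
    mw = [m.mw_kda for m in members]
    pi = [m.pi for m in members]
    introns = [m.intron_count for m in members]
    hist: dict[int, int] = {}
    for c in introns:
        hist[c] = hist.get(c, 0) + 1
    class_counts: dict[str, int] = {}
    for m in members:
        cls = getattr(m, "e2_class", None)
        if cls:
            class_counts[cls] = class_counts.get(cls, 0) + 1
    return FamilySummary(
        n=len(members),
        full_length_bp=(_mean(fl, None), min(fl), max(fl)),
        orf_bp=(_mean(orf, None), min(orf), max(orf)),
        size_aa=(_mean(aa, None), min(aa), max(aa)),
        mw_kda=(_mean(mw, 2), min(mw), max(mw)),
        pi=(_mean(pi, 2), min(pi), max(pi)),
        intron_histogram=dict(sorted(hist.items())),
        intronless=[m.name for m in members if m.intron_count == 0],
        class_counts=class_counts,
    )


def characterize_family(candidates: CandidateSet, proteins: dict[str, str],
                        gene_models: dict[str, GeneModel],
                        profile: DomainProfile | None = None,
                        extension_min: int = DEFAULT_EXTENSION_MIN,
                        ) -> list[FamilyMember]:
    """Build fully characterized members from an accepted candidate set."""
    hit_by_gene = {h.gene_id: h for h in candidates.hits}
    members = []
    for name, gid in candidates.names.items():
        prot = proteins[gid]
        hit = hit_by_gene[gid]
        model = gene_models[gid]
        member = FamilyMember(
            name=name, locus_id=gid, protein=prot,
            orf_bp=3 * (len(prot) + 1), size_aa=len(prot),
            domain_span=hit.target_span,
            pi=round(isoelectric_point(prot), 2),
            mw_kda=round(molecular_weight(prot), 2),
            intron_count=model.intron_count, full_length_bp=model.full_length_bp,
            gene_model=model,
        )
        member.e2_class = classify_architecture(member.size_aa, member.domain_span,
                                                extension_min)
        if profile is not None:
            member.uev = detect_uev(prot, profile, hit)
        members.append(member)
    return members
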