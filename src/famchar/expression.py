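"""Expression quantitation: FPKM, transforms, clustering, differential
expression, and qPCR relative quantitation.

The differential-expression caller keeps the published decision rule —
fold change at least ``fc_min`` AND (adjusted) p below ``alpha`` — but
computes p-values with a two-sided permutation test on replicate labels
(exhaustive when few permutations exist, sampled otherwise) followed by
Benjamini-Hochberg adjustment. qPCR relative expression follows the
2^(-dCt) convention with an internal reference gene, and treatment/control
ratios are classified by the two-fold rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .models import FamcharError

LOG_OFFSET = 0.01
DEFAULT_FC_MIN = 2.0
DEFAULT_ALPHA = 0.05
EXHAUSTIVE_LIMIT = 1000
SAMPLED_PERMS = 10_000


@dataclass
class ExpressionMatrix:
    """Genes x samples values with a transform-state flag."""

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        if not self.transformed and (self.values.values < 0).any():
            raise FamcharError("FPKM values must be non-negative")


@dataclass(frozen=True)
class DECall:
    gene: str
    lfc: float
    p: float
    padj: float
    call: str   # up / down / ns


def fpkm(counts, gene_length_bp, library_size):
    """FPKM = counts x 10^9 / (gene length in bp x library size)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise FamcharError("negative counts")
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if (length <= 0).any() or (lib <= 0).any():
        raise FamcharError("gene lengths and library sizes must be positive")
    return counts * 1.0e9 / (length * lib)


def fpkm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series,
                library_sizes: pd.Series | None = None,
                metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Column-wise FPKM for a genes x samples count matrix.

    Library sizes default to column sums (mapped-read totals are not
    available for a bare count matrix; the difference is documented).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise FamcharError("gene lengths missing for some genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    vals = fpkm(counts.values, lengths.values[:, None], library_sizes.values[None, :])
    return ExpressionMatrix(values=pd.DataFrame(vals, index=counts.index,
                                                columns=counts.columns),
                            metadata=metadata)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(FPKM + 0.01); refuses to transform twice."""
    if matrix.transformed:
        raise FamcharError("matrix is already log-transformed")
    return ExpressionMatrix(values=np.log10(matrix.values + LOG_OFFSET),
                            metadata=matrix.metadata, transformed=True)


def hierarchical_cluster(values: pd.DataFrame, linkage: str = "average",
                         metric: str = "euclidean") -> tuple[list, np.ndarray]:
    """Agglomerative clustering for heat-map row ordering.

    Returns (ordered row labels, scipy linkage matrix). Ties are resolved
    deterministically by row index.
    """
    if len(values) < 2:
        raise FamcharError("need at least two rows to cluster")
    if values.isna().any().any():
        raise FamcharError("matrix contains missing values")
    z = hierarchy.linkage(pdist(values.values, metric=metric), method=linkage)
    order = hierarchy.leaves_list(z)
    return [values.index[i] for i in order], z


def _cpm(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise FamcharError("a sample has zero total counts")
    return counts * 1.0e6 / lib


def call_de(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
            fc_min: float = DEFAULT_FC_MIN, alpha: float = DEFAULT_ALPHA,
            use_adjusted: bool = True, seed: int = 0) -> list[DECall]:
    """Differential-expression calls between two replicated conditions.

    Counts are library-size normalized (counts per million); the fold change
    is the ratio of condition means (0.5-CPM pseudocount). P-values come
    from a two-sided permutation test of the mean difference on the log2
    scale — exhaustive over label reassignments when there are at most 1000,
    otherwise 10,000 sampled with the given seed — then BH-adjusted. A gene
    is called up/down only when BOTH the fold-change and significance gates
    pass (``use_adjusted=False`` gates on the raw p-value instead).
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise FamcharError("each condition needs at least two replicates")
    if not counts_a.index.equals(counts_b.index):
        raise FamcharError("conditions must share the same gene index")
    ra, rb = counts_a.shape[1], counts_b.shape[1]
    combined = np.hstack([counts_a.values.astype(float), counts_b.values.astype(float)])
    cpm = _cpm(combined)
    log_cpm = np.log2(cpm + 0.5)

    mean_a = cpm[:, :ra].mean(axis=1)
    mean_b = cpm[:, ra:].mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    n_total = ra + rb
    n_comb = math.comb(n_total, ra)
    if n_comb <= EXHAUSTIVE_LIMIT:
        assignments = [np.array(c) for c in combinations(range(n_total), ra)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(n_total)[:ra] for _ in range(SAMPLED_PERMS)]

    obs = log_cpm[:, ra:].mean(axis=1) - log_cpm[:, :ra].mean(axis=1)
    count_ge = np.zeros(len(log_cpm), dtype=int)
    all_idx = np.arange(n_total)
    for a_idx in assignments:
        mask = np.zeros(n_total, dtype=bool)
        mask[a_idx] = True
        stat = log_cpm[:, ~mask].mean(axis=1) - log_cpm[:, mask].mean(axis=1)
        count_ge += np.abs(stat) >= np.abs(obs) - 1e-12
    p = count_ge / len(assignments)
    padj = multipletests(p, method="fdr_bh")[1]

    gate_p = padj if use_adjusted else p
    lfc_gate = np.abs(lfc) >= np.log2(fc_min)
    calls = []
    for i, gene in enumerate(counts_a.index):
        if lfc_gate[i] and gate_p[i] < alpha:
            call = "up" if lfc[i] > 0 else "down"
        else:
            call = "ns"
        calls.append(DECall(gene=str(gene), lfc=float(lfc[i]), p=float(p[i]),
                            padj=float(padj[i]), call=call))
    return calls


def qpcr_relative(ct_target: float, ct_reference: float) -> float:
    """Relative expression 2^(-(Ct_target - Ct_reference))."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise FamcharError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


def qpcr_classify(rel_treated: float, rel_control: float,
                  fold_min: float = DEFAULT_FC_MIN) -> str:
    """Two-fold rule on the treated/control ratio (boundary inclusive)."""
    if rel_treated <= 0 or rel_control <= 0:
        raise FamcharError("relative expression values must be positive")
    ratio = rel_treated / rel_control
    if ratio >= fold_min:
        return "up"
    if ratio <= 1.0 / fold_min:
        return "down"
    return "ns"


def expression_presence(matrix: ExpressionMatrix, fpkm_min: float = 1.0,
                        ) -> tuple[pd.DataFrame, pd.Series, float]:
    """Presence calls (FPKM >= threshold) per gene and tissue.

    Returns (boolean presence matrix, per-tissue expressed percentage,
    percentage of genes expressed in every tissue).
    """
    if matrix.transformed:
        raise FamcharError("presence is defined on raw FPKM values")
    present = matrix.values >= fpkm_min
    per_tissue = 100.0 * present.mean(axis=0)
    all_tissues = 100.0 * present.all(axis=1).mean()
    return present, per_tissue, float(all_tissues)
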