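"""Shared local-alignment machinery.

A single affine-gap Smith-Waterman core (numba-compiled) aligns a protein
against a column-scored model. The "model" is either a position-specific
log-odds profile built from a seed alignment, or a reference sequence recast
as BLOSUM62 columns — so profile scanning and similarity confirmation use
the same scoring machinery.

Score significance is calibrated empirically: scores of shuffled sequences
follow an extreme-value (Gumbel) distribution, fitted with scipy; e-values
are the fitted tail probability times the number of target sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import stats

from .models import FamcharError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


def encode(seq: str) -> np.ndarray:
    """Encode a protein as residue indices; raises on non-standard symbols."""
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:
        raise FamcharError(f"non-amino-acid symbol {exc.args[0]!r} in sequence") from None


@njit(cache=False)
def _sw_core(seq, cols, gap_open, gap_ext):  # pragma: no cover - exercised via wrapper
    n = seq.shape[0]
    m = cols.shape[0]
    neg = -1.0e30
    h_prev = np.zeros(m + 1)
    h_cur = np.zeros(m + 1)
    e_prev = np.full(m + 1, neg)   # gap in model (consume seq), by row
    # start bookkeeping: (si, sj) per state
    hs_prev = np.zeros((m + 1, 2), dtype=np.int64)
    hs_cur = np.zeros((m + 1, 2), dtype=np.int64)
    es_prev = np.zeros((m + 1, 2), dtype=np.int64)
    best = 0.0
    bi = bj = bsi = bsj = 0
    for i in range(1, n + 1):
        f = neg                     # gap in seq (consume model column), by column
        fs_i = 0
        fs_j = 0
        h_cur[0] = 0.0
        e_cur = np.full(m + 1, neg)
        es_cur = np.zeros((m + 1, 2), dtype=np.int64)
        for j in range(1, m + 1):
            # diagonal
            diag = h_prev[j - 1] + cols[j - 1, seq[i - 1]]
            if h_prev[j - 1] == 0.0:
                dsi, dsj = i, j
            else:
                dsi, dsj = hs_prev[j - 1, 0], hs_prev[j - 1, 1]
            # gap in model: extend down (seq advances)
            open_e = h_prev[j] - gap_open
            ext_e = e_prev[j] - gap_ext
            if open_e >= ext_e:
                e_val = open_e
                esi, esj = hs_prev[j, 0], hs_prev[j, 1]
            else:
                e_val = ext_e
                esi, esj = es_prev[j, 0], es_prev[j, 1]
            e_cur[j] = e_val
            es_cur[j, 0], es_cur[j, 1] = esi, esj
            # gap in seq: extend right (column advances)
            open_f = h_cur[j - 1] - gap_open
            ext_f = f - gap_ext
            if open_f >= ext_f:
                f = open_f
                fs_i, fs_j = hs_cur[j - 1, 0], hs_cur[j - 1, 1]
            else:
                f = ext_f
            h = diag
            si, sj = dsi, dsj
            if e_val > h:
                h = e_val
                si, sj = esi, esj
            if f > h:
                h = f
                si, sj = fs_i, fs_j
            if h < 0.0:
                h = 0.0
                si, sj = i, j
            h_cur[j] = h
            hs_cur[j, 0], hs_cur[j, 1] = si, sj
            if h > best:
                best = h
                bi, bj, bsi, bsj = i, j, si, sj
        h_prev, h_cur = h_cur, h_prev
        hs_prev, hs_cur = hs_cur, hs_prev
        e_prev = e_cur
        es_prev = es_cur
    return best, bsi, bi, bsj, bj


def local_align(seq_codes: np.ndarray, cols: np.ndarray,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_ext: float = DEFAULT_GAP_EXTEND):
    """Best local alignment of an encoded sequence against score columns.

    Returns (score, seq_span, col_span) with 1-based inclusive spans.
    A zero score means no positive-scoring local alignment exists.
    """
    if seq_codes.size == 0 or cols.shape[0] == 0:
        return 0.0, (0, 0), (0, 0)
    score, si, ei, sj, ej = _sw_core(seq_codes, cols, float(gap_open), float(gap_ext))
    if score <= 0.0:
        return 0.0, (0, 0), (0, 0)
    return float(score), (int(si), int(ei)), (int(sj), int(ej))


def traceback_align(seq_codes: np.ndarray, cols: np.ndarray,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_ext: float = DEFAULT_GAP_EXTEND) -> list[tuple[int | None, int | None]]:
    """Full local alignment path as (seq_pos, col) pairs, 0-based.

    ``(i, None)`` is a residue opposite a gap, ``(None, j)`` a deleted model
    column. Small dense DP with explicit traceback — used where the per-column
    residue mapping matters (e.g. reading the active-site residue), not in the
    scanning hot path.
    """
    n, m = seq_codes.size, cols.shape[0]
    neg = -1.0e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - gap_open, E[i - 1, j] - gap_ext)
            F[i, j] = max(H[i, j - 1] - gap_open, F[i, j - 1] - gap_ext)
            H[i, j] = max(0.0, H[i - 1, j - 1] + cols[j - 1, seq_codes[i - 1]],
                          E[i, j], F[i, j])
    i, j = np.unravel_index(np.argmax(H), H.shape)
    path: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            diag = H[i - 1, j - 1] + cols[j - 1, seq_codes[i - 1]]
            if np.isclose(H[i, j], diag):
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif np.isclose(H[i, j], E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            path.append((i - 1, None))
            if np.isclose(E[i, j], H[i - 1, j] - gap_open):
                state = "H"
            i -= 1
        else:
            path.append((None, j - 1))
            if np.isclose(F[i, j], H[i, j - 1] - gap_open):
                state = "H"
            j -= 1
    path.reverse()
    return path


def blosum62_columns(ref_codes: np.ndarray) -> np.ndarray:
    """Recast a reference sequence as per-column BLOSUM62 score vectors."""
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    order = blosum.alphabet
    idx = [order.index(a) for a in AMINO_ACIDS]
    mat = np.asarray(blosum)[np.ix_(idx, idx)].astype(np.float64)
    return mat[ref_codes, :]


def calibrate_gumbel(cols: np.ndarray, proteome: list[np.ndarray],
                     n_shuffles: int = 1000, seed: int = 0,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_ext: float = DEFAULT_GAP_EXTEND) -> tuple[float, float]:
    """Fit a Gumbel null to local-alignment scores of shuffled sequences.

    Shuffles cycle over the input sequences (preserving each one's length and
    composition), so the null reflects the actual target mix. Returns the
    fitted (loc, scale).
    """
    if not proteome:
        raise FamcharError("cannot calibrate against an empty proteome")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        base = proteome[k % len(proteome)]
        shuffled = rng.permutation(base)
        scores[k], _, _ = local_align(shuffled, cols, gap_open, gap_ext)
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(scale)


def evalue(score: float, loc: float, scale: float, n_targets: int) -> float:
    """Expected number of >= score hits among n_targets under the null."""
    return float(n_targets) * float(stats.gumbel_r.sf(score, loc=loc, scale=scale))
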