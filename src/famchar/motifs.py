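"""EM-based motif elicitation, in the MEME tradition.

Motifs are found sequentially: for each candidate width, expectation-
maximization fits a position-weight matrix plus occurrence prior, starting
from actual subsequences of the input; the best width is chosen by
bias-corrected relative entropy and low-information edge columns are
trimmed. Reported sites are probabilistically erased before the next motif
is sought, so successive motifs describe different signal.

Two occurrence models are supported: ``anr`` (any number of repetitions —
each window is an independent potential site) and ``zoops`` (zero or one
occurrence per sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AMINO_ACIDS, encode
from .models import FamcharError

LN2 = float(np.log(2.0))
CONVERGENCE_TOL = 1e-4
MAX_ITER = 100
EDGE_TRIM_BITS = 0.5
WIDTH_MARGIN_BITS = 0.75
SITE_POSTERIOR_MIN = 0.5


@dataclass
class Motif:
    id: int
    width: int
    pwm: np.ndarray                      # (width, 20), rows sum to 1
    sites: list[tuple[str, int]]         # (sequence id, 0-based offset)
    e_score: float                       # relative entropy (bits) x site count

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pwm.argmax(axis=1))


def _background(seq_codes: list[np.ndarray]) -> np.ndarray:
    counts = np.full(20, 1.0)  # +1 smoothing
    for codes in seq_codes:
        counts += np.bincount(codes, minlength=20)
    return counts / counts.sum()


class _Windows:
    """All width-w windows across the sequence set, with erasure weights."""

    def __init__(self, ids, seq_codes, erase, w):
        mats, owner, offsets, weights = [], [], [], []
        for k, codes in enumerate(seq_codes):
            if codes.size < w:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, w)
            mats.append(win)
            owner.append(np.full(win.shape[0], k))
            offsets.append(np.arange(win.shape[0]))
            ew = np.lib.stride_tricks.sliding_window_view(erase[k], w)
            weights.append(ew.prod(axis=1))
        if not mats:
            raise FamcharError(f"no sequence is at least {w} residues long")
        self.mat = np.vstack(mats)
        self.owner = np.concatenate(owner)
        self.offset = np.concatenate(offsets)
        self.weight = np.concatenate(weights)
        self.n_seqs = len(seq_codes)
        self.ids = ids
        self.w = w


def _seed_pwm(bg: np.ndarray, seed_window: np.ndarray) -> np.ndarray:
    """Initial PWM from one actual subsequence (0.7 on its residues)."""
    w = seed_window.shape[0]
    pwm = np.tile(bg, (w, 1)) * 0.3
    pwm[np.arange(w), seed_window] += 0.7
    return pwm / pwm.sum(axis=1, keepdims=True)


def _em(windows: _Windows, bg: np.ndarray, init_pwm: np.ndarray, mode: str,
        max_iter: int = MAX_ITER) -> tuple[np.ndarray, np.ndarray, float]:
    """Run EM from an initial PWM; returns (pwm, posteriors, log-likelihood)."""
    w = windows.w
    pwm = init_pwm
    prior = min(0.3, windows.n_seqs / windows.mat.shape[0])
    log_bg = np.log(bg)
    prev_ll = -np.inf
    z = np.zeros(windows.mat.shape[0])
    cols = np.arange(w)
    for _ in range(max_iter):
        llr = (np.log(pwm)[cols, windows.mat] - log_bg[windows.mat]).sum(axis=1)
        if mode == "anr":
            odds = prior / (1.0 - prior) * np.exp(llr)
            z = windows.weight * odds / (1.0 + odds)
            ll = float(np.sum(windows.weight * np.logaddexp(np.log1p(-prior),
                                                            np.log(prior) + llr)))
        elif mode == "zoops":
            z = np.zeros_like(llr)
            ll = 0.0
            for k in range(windows.n_seqs):
                sel = windows.owner == k
                if not sel.any():
                    continue
                m = sel.sum()
                lr = np.exp(llr[sel]) * windows.weight[sel]
                denom = (1.0 - prior) + prior / m * lr.sum()
                z[sel] = (prior / m) * lr / denom
                ll += float(np.log(denom))
        else:
            raise FamcharError(f"unknown occurrence mode {mode!r}")
        if abs(ll - prev_ll) < CONVERGENCE_TOL:
            break
        prev_ll = ll
        weights = z
        counts = np.zeros((w, 20))
        for j in range(w):
            counts[j] = np.bincount(windows.mat[:, j], weights=weights, minlength=20)
        counts += 0.01 * bg
        pwm = counts / counts.sum(axis=1, keepdims=True)
        total = weights.sum()
        if mode == "anr":
            prior = min(0.5, max(1e-6, total / windows.mat.shape[0]))
        else:
            prior = min(1.0 - 1e-6, max(1e-6, total / windows.n_seqs))
    return pwm, z, prev_ll


def _adjusted_re_per_column(pwm: np.ndarray, bg: np.ndarray, n_sites: float) -> np.ndarray:
    """Per-column relative entropy (bits) minus the small-sample bias."""
    re_col = (pwm * np.log(pwm / bg)).sum(axis=1) / LN2
    bias = (len(bg) - 1) / (2.0 * max(n_sites, 1.0) * LN2)
    return re_col - bias


def discover_motifs(proteins: dict[str, str], k_max: int = 15, w_min: int = 6,
                    w_max: int = 50, mode: str = "anr", seed: int = 0,
                    n_starts: int = 32) -> list[Motif]:
    """Greedy sequential motif elicitation.

    For each motif and each width in [w_min, w_max], up to ``n_starts``
    subsequence-seeded starting points are screened with a two-iteration EM
    and the most promising is refined to convergence; the width maximizing
    bias-corrected relative entropy (with a per-column margin, so
    uninformative flanks count against a width) wins. Its low-information
    edges are trimmed, sites (posterior > 0.5) are recorded and
    probabilistically erased, and the search repeats up to ``k_max`` motifs.
    Fully seeded: the same seed yields the same motif set.
    """
    if len(proteins) < 2:
        raise FamcharError("need at least two sequences")
    if w_min > w_max or w_min < 1:
        raise FamcharError("invalid width bounds")
    ids = list(proteins)
    seq_codes = [encode(proteins[i]) for i in ids]
    max_len = max(c.size for c in seq_codes)
    if max_len < w_min:
        raise FamcharError(f"all sequences shorter than the minimum width {w_min}")
    w_hi = min(w_max, max_len)
    bg = _background(seq_codes)
    rng = np.random.default_rng(seed)
    erase = [np.ones(c.size) for c in seq_codes]

    motifs: list[Motif] = []
    for motif_id in range(1, k_max + 1):
        best = None  # (score, w, pwm, z, windows)
        for w in range(w_min, w_hi + 1):
            windows = _Windows(ids, seq_codes, erase, w)
            usable = windows.weight > 0.5
            if usable.sum() < 2:
                continue
            pool = np.flatnonzero(usable)
            # candidate starts: windows whose exact subsequence recurs across
            # the set (ideal seeds for a shared motif), topped up at random
            sigs = {}
            for idx in pool:
                sigs.setdefault(windows.mat[idx].tobytes(), []).append(idx)
            recurring = sorted(sigs.values(), key=lambda g: (-len(g), g[0]))
            seeded = [g[0] for g in recurring[:8] if len(g) > 1]
            n_random = min(max(n_starts - len(seeded), 4), pool.size)
            randoms = rng.choice(pool, size=n_random, replace=False)
            picks = list(dict.fromkeys(seeded + list(randoms)))
            # screen starts cheaply, then refine only the most promising one
            screened = []
            for pick in picks:
                pwm, z, _ll = _em(windows, bg, _seed_pwm(bg, windows.mat[pick]),
                                  mode, max_iter=2)
                n_sites = float(z.sum())
                adj = _adjusted_re_per_column(pwm, bg, n_sites)
                screened.append((float((adj - WIDTH_MARGIN_BITS).sum() * n_sites), pwm))
            screened.sort(key=lambda t: t[0], reverse=True)
            pwm, z, _ll = _em(windows, bg, screened[0][1], mode)
            n_sites = float(z.sum())
            adj = _adjusted_re_per_column(pwm, bg, n_sites)
            score = float((adj - WIDTH_MARGIN_BITS).sum() * n_sites)
            if best is None or score > best[0]:
                best = (score, w, pwm, z, windows)
        if best is None or best[0] <= 0:
            break
        _score, w, pwm, z, windows = best
        n_sites = float(z.sum())
        adj = _adjusted_re_per_column(pwm, bg, n_sites)
        lo, hi = 0, w
        while lo < hi and adj[lo] < EDGE_TRIM_BITS:
            lo += 1
        while hi > lo and adj[hi - 1] < EDGE_TRIM_BITS:
            hi -= 1
        if hi - lo < 1:
            break
        pwm_t = pwm[lo:hi]
        site_idx = np.flatnonzero(z > SITE_POSTERIOR_MIN)
        sites = [(ids[windows.owner[i]], int(windows.offset[i]) + lo) for i in site_idx]
        e_score = float(_adjusted_re_per_column(pwm_t, bg, len(sites)).sum() * len(sites))
        motifs.append(Motif(id=motif_id, width=hi - lo, pwm=pwm_t,
                            sites=sorted(sites), e_score=e_score))
        if not sites:
            break
        for i in site_idx:  # probabilistic erasure of reported sites
            k = windows.owner[i]
            o = windows.offset[i]
            erase[k][o + lo:o + hi] *= (1.0 - z[i])
    return motifs


def motif_presence(motifs: list[Motif], proteins: dict[str, str],
                   score_min: float) -> "np.ndarray | object":
    """Gene x motif presence matrix (best log-odds window >= score_min)."""
    import pandas as pd
    if not motifs:
        raise FamcharError("no motifs given")
    ids = list(proteins)
    seq_codes = {i: encode(proteins[i]) for i in ids}
    bg = _background(list(seq_codes.values()))
    out = pd.DataFrame(False, index=ids, columns=[m.id for m in motifs])
    for m in motifs:
        lo_table = np.log2(m.pwm / bg)
        cols = np.arange(m.width)
        for i in ids:
            codes = seq_codes[i]
            if codes.size < m.width:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, m.width)
            best = float(lo_table[cols, win].sum(axis=1).max())
            out.loc[i, m.id] = best >= score_min
    return out
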