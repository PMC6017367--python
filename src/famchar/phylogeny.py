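"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap
supports, and clade-based group assignment.

Neighbor joining is the classic Saitou-Nei agglomeration: repeatedly join
the pair minimizing the Q-criterion, with branch lengths from the standard
formulas; ties are broken by the smallest (i, j) index pair so results are
deterministic. Negative branch-length estimates are clamped to zero and
flagged. Bootstrap supports are the percentage of column-resampled replicate
trees containing each original bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import FamcharError


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise FamcharError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise FamcharError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise FamcharError("distances must be non-negative with zero diagonal")


@dataclass
class PhyloTree:
    """Unrooted weighted tree with optional bipartition supports."""

    adjacency: dict[str, list[tuple[str, float]]]
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped_branches: int = 0

    def _side(self, u: str, v: str) -> frozenset:
        """Leaves reachable from v when the edge (u, v) is removed."""
        seen, stack, found = {u, v}, [v], []
        while stack:
            node = stack.pop()
            if node in self.leaf_set:
                found.append(node)
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(found)

    @property
    def leaf_set(self) -> set[str]:
        return set(self.leaves)

    def canonical(self, side: frozenset) -> frozenset:
        """Bipartition key: the side not containing the anchor leaf."""
        anchor = min(self.leaves)
        return frozenset(self.leaf_set - side) if anchor in side else side

    def bipartitions(self) -> dict[frozenset, tuple[str, str]]:
        """Non-trivial bipartitions (internal edges) -> one defining edge."""
        out = {}
        n = len(self.leaves)
        seen_edges = set()
        for u, nbrs in self.adjacency.items():
            for v, _ in nbrs:
                if (v, u) in seen_edges:
                    continue
                seen_edges.add((u, v))
                side = self._side(u, v)
                if 1 < len(side) < n - 1:
                    out[self.canonical(side)] = (u, v)
        return out

    def to_newick(self) -> str:
        """Newick string with supports as internal node labels."""
        root = self.adjacency[min(self.leaves)][0][0]   # internal nbr of anchor leaf

        def render(node: str, parent: str, length: float) -> str:
            children = [(v, w) for v, w in self.adjacency[node] if v != parent]
            if not children:
                return f"{node}:{length:.6f}"
            inner = ",".join(render(v, node, w) for v, w in children)
            label = ""
            if parent is not None:
                side = self.canonical(self._side(parent, node))
                if side in self.supports:
                    label = f"{self.supports[side]:.0f}"
            return f"({inner}){label}:{length:.6f}"

        parts = [render(v, root, w) for v, w in self.adjacency[root]]
        return f"({','.join(parts)});"


def p_distance(msa: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped positions."""
    taxa = list(msa)
    if len(taxa) < 2:
        raise FamcharError("need at least two sequences")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise FamcharError("alignment sequences differ in length")
    codes = _encode_msa(msa)
    return DistanceMatrix(taxa=taxa, d=_pdist_from_codes(taxa, codes))


def _encode_msa(msa: dict[str, str]) -> np.ndarray:
    arr = np.frombuffer("".join(msa.values()).encode(), dtype="S1")
    arr = arr.reshape(len(msa), -1)
    codes = arr.view(np.uint8).astype(np.int16)
    codes[(arr == b"-") | (arr == b".")] = -1
    return codes


def _pdist_from_codes(taxa: list[str], codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            comparable = int(ok.sum())
            if comparable == 0:
                raise FamcharError(f"no comparable positions between {taxa[i]} and {taxa[j]}")
            d[i, j] = d[j, i] = np.count_nonzero(codes[i][ok] != codes[j][ok]) / comparable
    return d


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic index-order tie-breaking."""
    n = len(dm.taxa)
    if n < 2:
        raise FamcharError("need at least two taxa")
    adjacency: dict[str, list[tuple[str, float]]] = {t: [] for t in dm.taxa}
    clamped = 0

    def add_edge(u: str, v: str, w: float) -> None:
        nonlocal clamped
        if w < 0:
            clamped += 1
            w = 0.0
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    if n == 2:
        add_edge(dm.taxa[0], dm.taxa[1], float(dm.d[0, 1]))
        return PhyloTree(adjacency=adjacency, leaves=list(dm.taxa),
                         clamped_branches=clamped)

    nodes = list(dm.taxa)
    d = dm.d.copy()
    inode = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best, bi, bj = np.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best - 1e-12:
                    best, bi, bj = q, i, j
        li = d[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        inode += 1
        new = f"_nj{inode}"
        add_edge(new, nodes[bi], li)
        add_edge(new, nodes[bj], lj)
        new_d = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[1:, 1:] = d[np.ix_(keep, keep)]
        d2[0, 1:] = d2[1:, 0] = new_d[keep]
        d = d2
        nodes = [new] + [nodes[k] for k in keep]
    # final star join of the last three nodes
    a, b, c = nodes
    inode += 1
    center = f"_nj{inode}"
    add_edge(center, a, (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0)
    add_edge(center, b, (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0)
    add_edge(center, c, (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0)
    return PhyloTree(adjacency=adjacency, leaves=list(dm.taxa), clamped_branches=clamped)


def bootstrap_support(msa: dict[str, str], n_reps: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """NJ tree from the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each original bipartition is the percentage of replicate NJ trees that
    contain it.
    """
    if n_reps < 1:
        raise FamcharError("need at least one bootstrap replicate")
    taxa = list(msa)
    codes = _encode_msa(msa)
    tree = neighbor_joining(DistanceMatrix(taxa, _pdist_from_codes(taxa, codes)))
    original = tree.bipartitions()
    counts = {bip: 0 for bip in original}
    rng = np.random.default_rng(seed)
    n_cols = codes.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_codes = codes[:, idx]
        rep_tree = neighbor_joining(
            DistanceMatrix(taxa, _pdist_from_codes(taxa, rep_codes)))
        rep_bips = set(rep_tree.bipartitions())
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    tree.supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    return tree


def assign_groups(tree: PhyloTree, reference_labels: dict[str, str],
                  support_min: float = 46.0) -> dict[str, str]:
    """Assign members to reference groups by smallest supported clades.

    For each non-reference leaf, consider every bipartition side with
    bootstrap support strictly greater than ``support_min`` that contains the
    member and at least one labeled reference; take the smallest such side.
    If all its references carry one group label, the member gets that group;
    otherwise (mixed references, or no supported clade) it is "unplaced".
    """
    missing = set(reference_labels) - tree.leaf_set
    if missing:
        raise FamcharError(f"references absent from tree: {sorted(missing)}")
    members = [leaf for leaf in tree.leaves if leaf not in reference_labels]
    sides = []
    for bip in tree.bipartitions():
        if tree.supports.get(bip, 0.0) > support_min:
            sides.append(bip)
            sides.append(frozenset(tree.leaf_set - bip))
    assignment = {}
    for member in members:
        candidates = [s for s in sides
                      if member in s and any(leaf in reference_labels for leaf in s)]
        if not candidates:
            assignment[member] = "unplaced"
            continue
        smallest = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        groups = {reference_labels[leaf] for leaf in smallest if leaf in reference_labels}
        assignment[member] = groups.pop() if len(groups) == 1 else "unplaced"
    return assignment


def align_center_star(seqs: dict[str, str]) -> dict[str, str]:
    """Rough center-star multiple alignment (convenience only).

    Aligns every sequence to the longest one with Needleman-Wunsch/BLOSUM62
    and merges gaps. This is a crude stand-in for a real aligner, intended
    for quick experiments; the phylogeny operations consume alignments from
    any source.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices
    center_id = max(seqs, key=lambda k: len(seqs[k]))
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    center = seqs[center_id]
    # column map: center position -> extra gaps inserted before it
    pre_gaps = [0] * (len(center) + 1)
    aligned: dict[str, list[tuple[str, str]]] = {}
    for name, seq in seqs.items():
        if name == center_id:
            continue
        aln = aligner.align(center, seq)[0]
        a, b = str(aln[0]), str(aln[1])
        aligned[name] = [(a, b)]
        run, cpos = 0, 0
        for ch in a:
            if ch == "-":
                run += 1
            else:
                pre_gaps[cpos] = max(pre_gaps[cpos], run)
                run, cpos = 0, cpos + 1
        pre_gaps[len(center)] = max(pre_gaps[len(center)], run)

    def expand(a: str, b: str) -> str:
        out, cpos, run = [], 0, 0
        for ch, res in zip(a, b):
            if ch == "-":
                out.append(res)
                run += 1
            else:
                out.append("-" * (pre_gaps[cpos] - run))
                out.append(res)
                run, cpos = 0, cpos + 1
        out.append("-" * (pre_gaps[len(center)] - run))
        return "".join(out)

    result = {center_id: expand(center, center)}
    for name, [(a, b)] in aligned.items():
        result[name] = expand(a, b)
    return result
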