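"""Progressive protein alignment, neighbor-joining trees with bootstrap
support, and reference-based group assignment.

The aligner is a compact Clustal-style progressive method: a UPGMA guide tree
on fractional-common-k-mer distances, then profile–profile Needleman–Wunsch
merges with BLOSUM62 and affine gaps.  Trees come from the Saitou–Nei
neighbor-joining agglomeration on p-distances (Poisson-corrected on request),
with column-resampling bootstrap supports.  Each unlabeled gene takes the
majority group among its k nearest labeled reference leaves by patristic
distance — robust when reference groups are not perfectly monophyletic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
from skbio import TreeNode

from .homology import AA_ORDER, _AA_INDEX, ScoringScheme

log = logging.getLogger(__name__)

_GAP = len(AA_ORDER)          # gap symbol index in profile space


# ---------------------------------------------------------------------- MSA

@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _kmer_set(seq: str, k: int = 3) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of common k-mers relative to the smaller sequence."""
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _upgma_order(dist: np.ndarray) -> list:
    """UPGMA agglomeration; returns a nested-tuple guide tree of leaf indices."""
    n = dist.shape[0]
    active = {i: (i,) for i in range(n)}
    nodes: dict[int, object] = {i: i for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(active) > 1:
        (i, j) = min(d, key=lambda ij: (d[ij], ij))
        new = (nodes[i], nodes[j])
        si, sj = sizes[i], sizes[j]
        for k2 in list(active):
            if k2 in (i, j):
                continue
            a, b = (min(i, k2), max(i, k2)), (min(j, k2), max(j, k2))
            val = (d[a] * si + d[b] * sj) / (si + sj)
            d[(min(k2, nxt), max(k2, nxt))] = val
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        del active[i], active[j], nodes[i], nodes[j]
        active[nxt] = True
        nodes[nxt] = new
        sizes[nxt] = si + sj
        nxt += 1
    return nodes[next(iter(active))]


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over 20 aa + X/B/Z/* + gap."""
    n_sym = len(AA_ORDER) + 1
    ncol = len(rows[0])
    prof = np.zeros((ncol, n_sym))
    for row in rows:
        for j, ch in enumerate(row):
            prof[j, _GAP if ch == "-" else _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1
    return prof / len(rows)


def _profile_nw(rows_a: list[str], rows_b: list[str],
                scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Global affine-gap DP between two profiles; returns gapped row sets."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    sub = scheme.matrix.astype(float)
    # substitution score between columns = f_a^T M f_b over residue symbols
    S = pa[:, :len(AA_ORDER)] @ sub @ pb[:, :len(AA_ORDER)].T
    go, ge = float(scheme.gap_open + scheme.gap_extend), float(scheme.gap_extend)

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)   # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), NEG)   # gap in A (consumes B)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -go - ge * (i - 1)
        ptr_x[i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = -go - ge * (j - 1)
        ptr_y[0, j] = 2
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pm, px, py = ptr_m[i], ptr_x[i], ptr_y[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            # match state
            best, arg = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, arg = Yi1[j - 1], 2
            Mi[j] = best + Si[j - 1]
            pm[j] = arg
            # gap in B: consume column of A
            ox, oe = Mi1[j] - go, Xi1[j] - ge
            if oe > ox:
                Xi[j], px[j] = oe, 1
            else:
                Xi[j], px[j] = ox, 0
            oy = Yi1[j] - go
            if oy > Xi[j]:
                Xi[j], px[j] = oy, 2
            # gap in A: consume column of B
            ox2, oe2 = Mi[j - 1] - go, Yi[j - 1] - ge
            if oe2 > ox2:
                Yi[j], py[j] = oe2, 2
            else:
                Yi[j], py[j] = ox2, 0
            ox3 = Xi[j - 1] - go
            if ox3 > Yi[j]:
                Yi[j], py[j] = ox3, 1

    # traceback from the best terminal state
    states = [M[la, lb], X[la, lb], Y[la, lb]]
    state = int(np.argmax(states))
    i, j = la, lb
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_m[i, j]
            ops.append("M"); i -= 1; j -= 1
        elif state == 1:
            prev = ptr_x[i, j]
            ops.append("X"); i -= 1
        else:
            prev = ptr_y[i, j]
            ops.append("Y"); j -= 1
        state = int(prev)
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ia += 1; ib += 1
        elif op == "X":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
    return out_a, out_b


def pairwise_global_score(a: str, b: str,
                          scheme: ScoringScheme | None = None) -> float:
    """Affine-gap global alignment score of two sequences (profile DP on
    singleton profiles — used for oracle comparisons)."""
    scheme = scheme or ScoringScheme.default()
    msa = progressive_align([a, b], ids=["a", "b"], scheme=scheme)
    return _score_msa_pair(msa.rows[0], msa.rows[1], scheme)


def _score_msa_pair(ra: str, rb: str, scheme: ScoringScheme) -> float:
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    score = 0.0
    in_gap = None
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            which = 0 if x == "-" else 1
            if in_gap == which:
                score -= ge
            else:
                score -= go
            in_gap = which
        else:
            score += scheme.score(x, y)
            in_gap = None
    return score


def progressive_align(sequences: list[str], ids: list[str] | None = None,
                      scheme: ScoringScheme | None = None, k: int = 3) -> Msa:
    """Progressive multiple alignment in guide-tree order.

    Guide tree: UPGMA on fractional-common-k-mer distances (ties broken by
    index so the result is invariant to input order up to row permutation).
    """
    scheme = scheme or ScoringScheme.default()
    ids = ids or [f"seq{i + 1}" for i in range(len(sequences))]
    if len(sequences) == 0:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return Msa(list(ids), [sequences[0]])
    n = len(sequences)
    # order-independent guide tree: sort leaves by (sequence, id)
    order = sorted(range(n), key=lambda i: (sequences[i], ids[i]))
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dist[a, b] = dist[b, a] = kmer_distance(
                sequences[order[a]], sequences[order[b]], k)
    guide = _upgma_order(dist)

    def merge(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [order[node]], [sequences[order[node]]]
        (left, right) = node
        ids_l, rows_l = merge(left)
        ids_r, rows_r = merge(right)
        rows_l, rows_r = _profile_nw(rows_l, rows_r, scheme)
        return ids_l + ids_r, rows_l + rows_r

    leaf_ids, rows = merge(guide)
    # restore the caller's row order
    pos = {leaf: r for r, leaf in enumerate(leaf_ids)}
    return Msa([ids[i] for i in range(n)], [rows[pos[i]] for i in range(n)])


# ------------------------------------------------------------- distances

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str = "p_distance"

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
            raise ValueError("distance matrix must be square and symmetric")
        if (m < 0).any():
            raise ValueError("distance matrix must be nonnegative")


def pairwise_distance(msa: Msa, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise-deletion p-distance (or its Poisson transform) from an MSA."""
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    arr = np.array([[_AA_INDEX.get(c, _AA_INDEX["X"]) if c != "-" else -1
                     for c in row] for row in msa.rows], dtype=np.int16)
    n = arr.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] >= 0) & (arr[j] >= 0)
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared non-gap sites between {msa.ids[i]} and {msa.ids[j]}")
            p = float((arr[i][shared] != arr[j][shared]).sum()) / n_shared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson distance undefined at p = 1")
                p = -math.log(1.0 - p)
            out[i, j] = out[j, i] = p
    return DistanceMatrix(list(msa.ids), out, model)


# ------------------------------------------------------------------ NJ tree

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths are clamped to
    zero (amount logged).  Returns an unrooted tree as an skbio TreeNode
    (trifurcating root)."""
    d = dm.matrix.astype(float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("invalid distance matrix")
    nodes = [TreeNode(name=name) for name in dm.ids]
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = clamp(li)
        nj.length = clamp(lj)
        parent.extend([ni, nj])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # resolve the final three nodes on an unrooted (trifurcating) root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = clamp(ln)
        root.append(nodes[idx])
    if clamped > 0:
        log.info("neighbor_joining: clamped %.4g of negative branch length", clamped)
    return root


def patristic_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------- bootstrap

def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions as the smaller-side tip-name sets."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(msa: Msa, n_reps: int = 100, seed: int = 0,
                      model: str = "p_distance",
                      ) -> tuple[TreeNode, dict[frozenset, float]]:
    """Column-resampling bootstrap: support per original internal bipartition
    as the percentage of replicate NJ trees containing it.  Supports are
    written onto the returned original tree's internal node names."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(pairwise_distance(msa, model))
    parts = _bipartitions(tree)
    counts = {p: 0 for p in parts}
    ncol = msa.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in msa.rows]
        try:
            rep_tree = neighbor_joining(pairwise_distance(Msa(list(msa.ids), rows),
                                                          model))
        except ValueError:
            continue
        rep_parts = _bipartitions(rep_tree)
        for p in parts:
            if p in rep_parts:
                counts[p] += 1
    supports = {p: 100.0 * c / n_reps for p, c in counts.items()}
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return tree, supports


# ---------------------------------------------------------- group assignment

@dataclass
class GroupAssignment:
    gene_id: str
    group: str
    support: float


def assign_groups(tree: TreeNode, reference_labels: dict[str, str],
                  k: int = 3) -> list[GroupAssignment]:
    """Assign each unlabeled leaf the majority group of its k nearest labeled
    reference leaves by patristic distance (ties: smallest summed distance)."""
    if not reference_labels:
        raise ValueError("no reference leaves provided")
    ids, mat = patristic_distances(tree)
    idx = {name: i for i, name in enumerate(ids)}
    ref_ids = [r for r in reference_labels if r in idx]
    if not ref_ids:
        raise ValueError("tree contains no reference leaves")
    out: list[GroupAssignment] = []
    for name in ids:
        if name in reference_labels:
            continue
        dists = sorted(((mat[idx[name], idx[r]], r) for r in ref_ids))
        nearest = dists[:min(k, len(dists))]
        votes: dict[str, list[float]] = {}
        for dist_value, rid in nearest:
            votes.setdefault(reference_labels[rid], []).append(dist_value)
        best = sorted(votes.items(),
                      key=lambda kv: (-len(kv[1]), sum(kv[1]), kv[0]))[0]
        out.append(GroupAssignment(name, best[0], len(best[1]) / len(nearest)))
    return out
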