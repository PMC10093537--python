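"""Progressive alignment vs a brute-force Needleman–Wunsch oracle, NJ on
additive matrices (with topology enumeration), bootstrap behavior and
tree-kNN group assignment."""

import itertools
import math
import random

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from orfamily.homology import ScoringScheme
from orfamily.phylogeny import (DistanceMatrix, Msa, assign_groups,
                                bootstrap_support, neighbor_joining,
                                pairwise_distance, pairwise_global_score,
                                patristic_distances, progressive_align,
                                tree_to_newick)

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- alignment

def brute_force_nw(a, b, scheme):
    """Independent global affine-gap DP (Gotoh) oracle."""
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    NEG = -1e18
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0
    for i in range(1, la + 1):
        X[i, 0] = -go - ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -go - ge * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = scheme.score(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
    return max(M[la, lb], X[la, lb], Y[la, lb])


def test_identical_sequences_align_without_gaps():
    msa = progressive_align(["ACDEFG", "ACDEFG"])
    assert msa.rows == ["ACDEFG", "ACDEFG"]


def test_single_gap_and_nw_score_oracle():
    scheme = ScoringScheme.default()
    msa = progressive_align(["ACDEFG", "ACEFG"])
    assert sorted(msa.rows) == ["AC-EFG", "ACDEFG"]
    assert pairwise_global_score("ACDEFG", "ACEFG") == pytest.approx(
        brute_force_nw("ACDEFG", "ACEFG", scheme))


def test_pairwise_scores_match_oracle_on_random_pairs():
    scheme = ScoringScheme.default()
    rng = random.Random(17)
    for _ in range(10):
        a = "".join(rng.choice(AAS) for _ in range(rng.randint(8, 45)))
        b = "".join(rng.choice(AAS) for _ in range(rng.randint(8, 45)))
        assert pairwise_global_score(a, b, scheme) == pytest.approx(
            brute_force_nw(a, b, scheme))


def test_alignment_order_invariance():
    seqs = ["MKVLAAGWWTR", "MKVLSAGWTR", "MECDDHHKKPY"]
    base = progressive_align(seqs, ids=["a", "b", "c"])
    perm = progressive_align([seqs[2], seqs[0], seqs[1]], ids=["c", "a", "b"])
    rows_base = dict(zip(base.ids, base.rows))
    rows_perm = dict(zip(perm.ids, perm.rows))
    assert rows_base == rows_perm


def test_msa_degapping_recovers_inputs():
    seqs = ["MKVLAAGWWTR", "MKVLSAGWTR", "MECDDHHKKPY", "MKVLAAGWWT"]
    msa = progressive_align(seqs)
    assert [msa.degapped(i) for i in range(4)] == seqs
    assert msa.n_cols >= max(len(s) for s in seqs)


def test_single_sequence_msa():
    msa = progressive_align(["MKVL"], ids=["only"])
    assert msa.rows == ["MKVL"]


# ---------------------------------------------------------------- distances

def test_p_distance_and_poisson():
    msa = Msa(["x", "y"], ["AAAAAAAAAA", "AAAAAAAACC"])
    assert pairwise_distance(msa).matrix[0, 1] == pytest.approx(0.2)
    assert pairwise_distance(msa, "poisson").matrix[0, 1] == pytest.approx(
        -math.log(0.8))
    gappy = Msa(["x", "y"], ["AA--", "--AA"])
    with pytest.raises(ValueError, match="x.*y|no shared"):
        pairwise_distance(gappy)


# --------------------------------------------------------------------- NJ

def _path_matrix(tree, ids):
    names, mat = patristic_distances(tree)
    idx = {n: i for i, n in enumerate(names)}
    return np.array([[mat[idx[a], idx[b]] for b in ids] for a in ids])


def _leaf_depths_additive(rng, n):
    """Build a random tree explicitly and return its exact path matrix."""
    nodes = {i: ("leaf", i) for i in range(n)}
    dist = {i: {i: 0.0} for i in range(n)}
    members = {i: [i] for i in range(n)}
    ids = list(range(n))
    nxt = n
    dmat = np.zeros((n, n))
    active = list(range(n))
    while len(active) > 1:
        k1, k2 = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[k1], active[k2]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        # depth of each leaf below a/b
        for x in members[a]:
            dist[a][x] = dist[a].get(x, 0.0)
        for x in members[a]:
            for y in members[b]:
                dmat[x, y] = dmat[y, x] = (dist[a][x] + la) + (dist[b][y] + lb)
        merged = nxt
        nxt += 1
        members[merged] = members[a] + members[b]
        dist[merged] = {}
        for x in members[a]:
            dist[merged][x] = dist[a][x] + la
        for y in members[b]:
            dist[merged][y] = dist[b][y] + lb
        active = [v for v in active if v not in (a, b)] + [merged]
    return dmat


def test_nj_reproduces_additive_matrices_exactly():
    for seed in range(12):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        dmat = _leaf_depths_additive(rng, n)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(ids, dmat))
        assert np.abs(_path_matrix(tree, ids) - dmat).max() < 1e-9


def test_nj_three_taxon_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_four_taxon_topology_vs_enumeration():
    """NJ recovers the unique 4-taxon topology found by least-squares fitting
    over all three unrooted topologies."""
    def quartet_split(dmat):
        # best split by the four-point condition
        sums = {("ab", "cd"): dmat[0, 1] + dmat[2, 3],
                ("ac", "bd"): dmat[0, 2] + dmat[1, 3],
                ("ad", "bc"): dmat[0, 3] + dmat[1, 2]}
        return min(sums, key=sums.get)

    for seed in range(25):
        rng = np.random.default_rng(100 + seed)
        dmat = _leaf_depths_additive(rng, 4)
        ids = list("abcd")
        want = quartet_split(dmat)
        tree = neighbor_joining(DistanceMatrix(ids, dmat))
        m = _path_matrix(tree, ids)
        got = quartet_split(m)
        assert got == want


def test_nj_matches_skbio_reference():
    rng = np.random.default_rng(5)
    dmat = _leaf_depths_additive(rng, 6)
    ids = [f"t{i}" for i in range(6)]
    mine = neighbor_joining(DistanceMatrix(ids, dmat))
    ref = skbio_nj(SkbioDM(dmat, ids))
    ref_mat = ref.tip_tip_distances(ids).data
    mine_mat = _path_matrix(mine, ids)
    order = [list(ref.tip_tip_distances(ids).ids).index(i) for i in ids]
    assert np.allclose(mine_mat, ref_mat[np.ix_(order, order)], atol=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_nj_ultrametric_matches_upgma_topology():
    # perfectly ultrametric distances: two clean clades
    d = np.array([
        [0, 2, 8, 8],
        [2, 0, 8, 8],
        [8, 8, 0, 2],
        [8, 8, 2, 0]], float)
    tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
    m = _path_matrix(tree, list("abcd"))
    assert m[0, 1] < m[0, 2] and m[2, 3] < m[0, 2]   # (a,b) and (c,d) clades


# ---------------------------------------------------------------- bootstrap

def _toy_msa():
    return progressive_align(
        ["AAAAAAAAAACCCCCCCCCC", "AAAAAAAAAWCCCCCCCCCW",
         "WWWWWWWWWWGGGGGGGGGG", "WWWWWWWWWVGGGGGGGGGV"],
        ids=list("abcd"))


def test_bootstrap_separated_clades():
    tree, supports = bootstrap_support(_toy_msa(), n_reps=100, seed=1)
    assert supports and all(s >= 95 for s in supports.values())
    assert all(0 <= s <= 100 for s in supports.values())


def test_bootstrap_single_rep_and_determinism():
    _, s1 = bootstrap_support(_toy_msa(), n_reps=1, seed=3)
    assert set(s1.values()) <= {0.0, 100.0}
    _, a = bootstrap_support(_toy_msa(), n_reps=20, seed=5)
    _, b = bootstrap_support(_toy_msa(), n_reps=20, seed=5)
    assert a == b


def test_bootstrap_newick_roundtrip(tmp_path):
    tree, _ = bootstrap_support(_toy_msa(), n_reps=10, seed=2)
    from skbio import TreeNode
    text = tree_to_newick(tree)
    back = TreeNode.read([text])
    assert {t.name for t in back.tips()} == set("abcd")


# ------------------------------------------------------------- assignment

def test_assign_groups_trivial_and_boundary():
    from skbio import TreeNode
    tree = TreeNode.read(["((q:0.0,ref1:0.0):1.0,(ref2:1.0,ref3:1.0):1.0);"])
    labels = {"ref1": "delta", "ref2": "eta", "ref3": "eta"}
    out = {a.gene_id: a for a in assign_groups(tree, labels, k=1)}
    assert out["q"].group == "delta" and out["q"].support == 1.0
    # k larger than the number of references: all references vote
    out = {a.gene_id: a for a in assign_groups(tree, labels, k=10)}
    assert out["q"].group == "eta"            # 2 eta votes beat 1 delta
    with pytest.raises(ValueError):
        assign_groups(tree, {})


def test_group_truth_recovery_on_synthetic(small_dataset):
    """Genes built from group templates are assigned back to their groups."""
    ds = small_dataset
    genes = {t.gene_id: ds.proteins[t.gene_id] for t in ds.truth
             if t.category == "intact"}
    seqs = {**genes, **ds.references}
    ids = list(seqs)
    msa = progressive_align([seqs[i] for i in ids], ids=ids)
    tree = neighbor_joining(pairwise_distance(msa))
    truth = {t.gene_id: t.group for t in ds.truth}
    hits = 0
    assignments = assign_groups(tree, ds.reference_labels)
    for a in assignments:
        hits += truth[a.gene_id] == a.group
    assert hits / len(assignments) >= 0.95
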