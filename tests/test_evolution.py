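"""Nei–Gojobori estimator against an exhaustive enumeration oracle, plus
duplicate-pair screening, tandem-cluster calling and the selection summary."""

import itertools
import math
import random

import numpy as np
import pytest

from orfamily.codons import BASES, CODON_TABLE
from orfamily.evolution import (SaturationError, codon_aware_align,
                                detect_clusters, find_duplicate_pairs,
                                ng86_kaks, selection_summary)


# ---------------------------------------------------------------- oracle

def oracle_sites(codon):
    """Independent site count: fraction of non-stop single-nt changes at each
    position that are synonymous."""
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in BASES
                if b != codon[pos]]
        alts = [c for c in alts if CODON_TABLE[c] != "*"]
        if alts:
            s += sum(CODON_TABLE[c] == CODON_TABLE[codon] for c in alts) / len(alts)
    return s, 3.0 - s


def oracle_diffs(c1, c2):
    """Average (Sd, Nd) over all orderings of the differing positions,
    discarding pathways through stops (fall back to all orderings)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def count(order, allow_stop):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and not allow_stop:
                return None
            sd += CODON_TABLE[nxt] == CODON_TABLE[cur]
            nd += CODON_TABLE[nxt] != CODON_TABLE[cur]
            cur = nxt
        return sd, nd

    paths = [c for c in (count(o, False) for o in itertools.permutations(diff)) if c]
    if not paths:
        paths = [count(o, True) for o in itertools.permutations(diff)]
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_kaks(cds_a, cds_b):
    s = n = sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if CODON_TABLE.get(ca, "*") == "*" or CODON_TABLE.get(cb, "*") == "*":
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        s += (sa + sb) / 2
        n += (na + nb) / 2
        dsd, dnd = oracle_diffs(ca, cb)
        sd += dsd
        nd += dnd
    return n, s, nd, sd


def random_cds(rng, n_codons):
    sense = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    return "".join(rng.choice(sense) for _ in range(n_codons))


def test_ng86_counts_match_enumeration_oracle():
    rng = random.Random(42)
    for _ in range(120):
        n = rng.randint(1, 10)
        a = random_cds(rng, n)
        b = list(a)
        for i in range(len(b)):                    # sprinkle divergence
            if rng.random() < 0.15:
                b[i] = rng.choice("ACGT")
        b = "".join(b)
        n_o, s_o, nd_o, sd_o = oracle_kaks(a, b)
        try:
            r = ng86_kaks(a, b)
        except (SaturationError, ValueError):
            continue
        assert r.n_sites == pytest.approx(n_o, abs=1e-12)
        assert r.s_sites == pytest.approx(s_o, abs=1e-12)
        assert r.nd == pytest.approx(nd_o, abs=1e-12)
        assert r.sd == pytest.approx(sd_o, abs=1e-12)


def test_ng86_site_conservation_and_symmetry():
    rng = random.Random(1)
    for _ in range(40):
        a = random_cds(rng, rng.randint(2, 12))
        b = list(a)
        for i in range(len(b)):
            if rng.random() < 0.1:
                b[i] = rng.choice("ACGT")
        b = "".join(b)
        try:
            r_ab = ng86_kaks(a, b)
            r_ba = ng86_kaks(b, a)
        except (SaturationError, ValueError):
            continue
        assert r_ab.n_sites + r_ab.s_sites == pytest.approx(
            3 * r_ab.codons_compared)
        assert r_ab.ka == pytest.approx(r_ba.ka)
        assert r_ab.ks == pytest.approx(r_ba.ks)


def test_ng86_phe_wobble_is_purely_synonymous():
    # TTT->TTC is Phe->Phe; context codons keep the pair out of saturation
    r = ng86_kaks("TTTGGAGGA", "TTCGGAGGA")
    assert r.nd == 0.0
    assert r.sd == 1.0
    assert r.ka == 0.0
    assert r.ks > 0.0


def test_ng86_identity_and_saturation():
    r = ng86_kaks("ATGAAATTT", "ATGAAATTT")
    assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None
    with pytest.raises(SaturationError):
        ng86_kaks("TTT", "TTC")        # one codon: pS = 3 >= 3/4
    with pytest.raises(ValueError):
        ng86_kaks("ATGAAA", "ATG")


def test_ng86_against_biopython_reference():
    """Independent cross-check: Biopython's NG86 (slightly different stop
    handling) should agree within a few percent on realistic pairs."""
    import warnings
    warnings.filterwarnings("ignore")
    from Bio.Align import PairwiseAligner, analysis
    from orfamily.synthetic import make_or_template, mutate_duplicate

    rng = np.random.default_rng(3)
    _, cds = make_or_template("beta", 280, rng)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    for seed, (ks_t, ka_t) in enumerate([(0.2, 0.05), (0.3, 0.1)]):
        child = mutate_duplicate(cds, ks_t, ka_t, np.random.default_rng(seed))
        aln = aligner.align(cds[:-3], child[:-3])[0]
        dn, ds = analysis.calculate_dn_ds(aln, method="NG86")
        r = ng86_kaks(cds, child)
        assert r.ka == pytest.approx(dn, rel=0.05, abs=0.005)
        assert r.ks == pytest.approx(ds, rel=0.05, abs=0.005)


def test_codon_aware_align_handles_unequal_lengths():
    a = "ATGAAATTTGGGCCCTAA"
    b = "ATGAAAGGGCCCTAA"                      # one codon deleted
    aln_a, aln_b = codon_aware_align(a, b)
    assert len(aln_a) == len(aln_b)
    assert aln_a.replace("-", "") == a
    assert aln_b.replace("-", "") == b
    r = ng86_kaks(aln_a, aln_b)
    assert r.codons_skipped == 1               # the gap codon


# ------------------------------------------------------------- duplicates

def test_duplicate_pair_screen(rng):
    from orfamily.synthetic import make_or_template, mutate_duplicate
    _, cds = make_or_template("delta", 300, rng)
    identical = {"a": cds, "b": cds}
    pairs = find_duplicate_pairs(identical)
    assert len(pairs) == 1
    assert pairs[0].coverage == pytest.approx(1.0)
    assert pairs[0].identity == pytest.approx(1.0)

    low = mutate_duplicate(cds, 0.6, 0.6, np.random.default_rng(1))
    assert not find_duplicate_pairs({"a": cds, "b": low})      # saturating rates

    close = mutate_duplicate(cds, 0.1, 0.05, np.random.default_rng(2))
    kept = find_duplicate_pairs({"a": cds, "b": close})
    assert len(kept) == 1 and kept[0].identity >= 0.75


# ---------------------------------------------------------------- clusters

def test_cluster_rules():
    coords = [("g1", "chr1", 0, 1000), ("g2", "chr1", 500_000, 501_000),
              ("g3", "chr1", 2_000_000, 2_001_000)]
    clusters = detect_clusters(coords)
    assert len(clusters) == 1
    assert clusters[0].members == ["g1", "g2"]

    chain = [("a", "c", 0, 1000), ("b", "c", 900_000, 901_000),
             ("c", "c", 1_800_000, 1_801_000)]
    (cl,) = detect_clusters(chain)
    assert cl.members == ["a", "b", "c"]       # transitive chaining

    split = [("x", "chr1", 0, 1000), ("y", "chr2", 1000, 2000)]
    assert detect_clusters(split) == []        # never across chromosomes


def test_cluster_gap_mode():
    coords = [("g1", "c", 0, 950_000), ("g2", "c", 990_000, 991_000)]
    assert len(detect_clusters(coords, mode="start")) == 1
    # end-to-start distance is only 40 kb: still one cluster
    assert len(detect_clusters(coords, mode="gap")) == 1
    far = [("g1", "c", 0, 10_000), ("g2", "c", 1_050_000, 1_060_000)]
    assert detect_clusters(far, mode="start") == []


# ---------------------------------------------------------------- summary

class _R:
    def __init__(self, ratio):
        self.ratio = ratio


def test_selection_summary_counts_and_rounding():
    s = selection_summary([_R(0.3), _R(0.5), _R(1.2)])
    assert s.n_positive == 1 and s.pct_positive == "33.3"
    assert s.n_purifying == 2 and s.pct_purifying == "66.7"

    # published proportions re-derived from their printed counts
    ratios = [1.5] * 12 + [0.3] * 209 + [0.7] * 18
    s = selection_summary([_R(r) for r in ratios])
    assert s.n_pairs == 239
    assert s.pct_positive == "5"
    assert s.pct_purifying == "95"
    assert s.n_02_06 == 209 and s.pct_02_06 == "87.4"
    assert sum(s.histogram.values()) == 239


def test_selection_summary_all_undefined():
    assert selection_summary([_R(None), _R(None)]) is None
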