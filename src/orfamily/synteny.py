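"""Collinearity between two annotated gene sets (simplified MCScanX stage).

Reciprocal-best protein homologs anchor the comparison; within each
chromosome pair, anchors are chained into collinear blocks as longest
strictly monotone runs of gene ranks (increasing = same orientation,
decreasing = inverted) with bounded rank gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .homology import ScoringScheme, evalue

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    score: float
    reciprocal_best: bool


@dataclass
class SyntenyBlock:
    chromosome_a: str
    chromosome_b: str
    anchors: list[tuple[str, str]]     # ordered (gene_a, gene_b) pairs
    orientation: str                   # "same" | "inverted"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _protein_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = scheme.bio_matrix
    a.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    a.extend_gap_score = -scheme.gap_extend
    return a


def _shared_kmers(a: str, b: str, k: int = 5) -> bool:
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def reciprocal_homologs(proteome_a: dict[str, str], proteome_b: dict[str, str],
                        scheme: ScoringScheme | None = None,
                        evalue_cutoff: float = 1e-10,
                        ) -> list[HomologPair]:
    """All-against-all local alignment between two proteomes; pairs that are
    each other's best hit (and pass the E-value floor) are reciprocal-best.

    A shared-5-mer prefilter skips hopeless pairs before alignment.  The
    floor is deliberately strict: ungapped Karlin–Altschul statistics ignore
    composition bias, and low-complexity decoys reach E ~ 1e-5; genuine
    orthologs sit many orders of magnitude below 1e-10.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scheme = scheme or ScoringScheme.default()
    aligner = _protein_aligner(scheme)
    scores: dict[tuple[str, str], float] = {}
    for ida, pa in proteome_a.items():
        for idb, pb in proteome_b.items():
            if not _shared_kmers(pa, pb):
                continue
            score = float(aligner.score(pa, pb))
            ev = evalue(score, len(pa), len(pb), scheme)
            if ev <= evalue_cutoff:
                scores[(ida, idb)] = score
    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    for (ida, idb), s in scores.items():
        if ida not in best_a or (s, idb) > best_a[ida]:
            best_a[ida] = (s, idb)
        if idb not in best_b or (s, ida) > best_b[idb]:
            best_b[idb] = (s, ida)
    out = []
    for (ida, idb), s in sorted(scores.items()):
        rb = best_a.get(ida, (None, None))[1] == idb and \
             best_b.get(idb, (None, None))[1] == ida
        out.append(HomologPair(ida, idb, s, rb))
    return out


def chain_collinear_blocks(pairs: list[HomologPair],
                           gene_orders_a: dict[str, list[str]],
                           gene_orders_b: dict[str, list[str]],
                           max_gap_genes: int = 25, min_block: int = 5,
                           reciprocal_only: bool = True,
                           ) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Longest strictly monotone chains of rank-in-B (increasing or decreasing)
    over anchors sorted by rank-in-A, with both rank gaps <= max_gap_genes,
    found by quadratic DP; chains are extracted best-first from the remaining
    anchors and reported when they carry >= min_block anchors.
    """
    rank_a = {g: (chrom, i) for chrom, order in gene_orders_a.items()
              for i, g in enumerate(order)}
    rank_b = {g: (chrom, i) for chrom, order in gene_orders_b.items()
              for i, g in enumerate(order)}
    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for p in pairs:
        if reciprocal_only and not p.reciprocal_best:
            continue
        if p.gene_a not in rank_a or p.gene_b not in rank_b:
            continue
        ca, ra = rank_a[p.gene_a]
        cb, rb = rank_b[p.gene_b]
        by_pair.setdefault((ca, cb), []).append((ra, rb, p.gene_a, p.gene_b))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), anchors in sorted(by_pair.items()):
        remaining = sorted(anchors)
        while True:
            best_chain, best_dir = _best_monotone_chain(remaining, max_gap_genes)
            if best_chain is None or len(best_chain) < min_block:
                break
            blocks.append(SyntenyBlock(
                ca, cb, [(ga, gb) for _, _, ga, gb in best_chain],
                "same" if best_dir > 0 else "inverted"))
            used = set(best_chain)
            remaining = [a for a in remaining if a not in used]
    return blocks


def _best_monotone_chain(anchors, max_gap):
    """Longest strictly monotone (in rank-B) chain over rank-A-sorted anchors
    with rank gaps <= max_gap in both genomes; O(n^2) DP."""
    n = len(anchors)
    if n == 0:
        return None, 0
    best_overall = None
    best_dir = 0
    for direction in (1, -1):
        length = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if anchors[j][0] >= anchors[i][0]:
                    continue
                if anchors[i][0] - anchors[j][0] > max_gap:
                    continue
                db = (anchors[i][1] - anchors[j][1]) * direction
                if db <= 0 or db > max_gap:
                    continue
                if length[j] + 1 > length[i]:
                    length[i] = length[j] + 1
                    prev[i] = j
        end = max(range(n), key=lambda i: length[i])
        chain = []
        i = end
        while i >= 0:
            chain.append(anchors[i])
            i = prev[i]
        chain.reverse()
        if best_overall is None or len(chain) > len(best_overall):
            best_overall, best_dir = chain, direction
    return best_overall, best_dir


def highlight_family_pairs(blocks: list[SyntenyBlock],
                           family_ids: set[str]) -> list[tuple[str, str, int]]:
    """Anchor pairs inside blocks whose both members belong to the family,
    with their block index as context."""
    out = []
    for bi, block in enumerate(blocks):
        for ga, gb in block.anchors:
            if ga in family_ids and gb in family_ids:
                out.append((ga, gb, bi))
    return out
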