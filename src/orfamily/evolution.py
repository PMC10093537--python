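"""Duplicate-pair detection, tandem clusters and Nei–Gojobori (1986) selection analysis.

The NG86 estimator counts synonymous (S) and non-synonymous (N) *sites* by the
fraction of single-nucleotide changes at each codon position that preserve the
amino acid, and synonymous/non-synonymous *differences* (Sd, Nd) by averaging
over all minimal mutational pathways between a codon pair.  Proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4)·ln(1 - (4/3)p).  Ka/Ks > 1 indicates positive selection,
< 1 purifying selection.

Duplicated gene pairs follow the classic screen: all-vs-all local nucleotide
alignment (match +2 / mismatch -3, affine gaps), keep pairs whose alignment
covers >= 75% of the longer CDS at >= 75% identity with E <= 1e-20.  Tandem
clusters chain genes on one chromosome whose neighbors lie closer than 1 Mb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio import Align

from ._util import format_percent
from .codons import CODON_TABLE, BASES

log = logging.getLogger(__name__)

__all__ = [
    "KaKsResult", "DupPair", "GeneCluster", "SaturationError",
    "ng86_sites", "ng86_kaks", "find_duplicate_pairs", "detect_clusters",
    "selection_summary",
]


class SaturationError(ValueError):
    """Raised when pS or pN >= 3/4 and the Jukes–Cantor correction diverges."""


# ------------------------------------------------------------------ NG86 core

@lru_cache(maxsize=64)
def _codon_site_split(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon; sums to 3.

    At each position the three alternative bases are classified; changes to
    stop codons are excluded from the denominator so every position still
    contributes exactly one site.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = considered = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == "*":
                continue
            considered += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        if considered:
            s += syn / considered
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if every ordering is
    blocked the average falls back to all orderings with stop steps counted as
    non-synonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stop):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and not allow_stop:
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [p for p in (walk(o, False) for o in permutations(diff)) if p]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class KaKsResult:
    """NG86 estimate for one aligned CDS pair."""

    gene_a: str
    gene_b: str
    n_sites: float      # N: non-synonymous sites (pair average)
    s_sites: float      # S: synonymous sites
    nd: float           # Nd: non-synonymous differences
    sd: float           # Sd: synonymous differences
    pn: float
    ps: float
    ka: float
    ks: float
    ratio: float | None         # None when Ks == 0 (undefined)
    codons_compared: int
    codons_skipped: int

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: Jukes–Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_sites(cds: str) -> tuple[float, float]:
    """(S, N) site totals of a single CDS (stop/ambiguous codons skipped)."""
    s_tot = n_tot = 0.0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if codon not in CODON_TABLE or CODON_TABLE[codon] == "*":
            continue
        s, n = _codon_site_split(codon)
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def ng86_kaks(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KaKsResult:
    """Nei–Gojobori Ka/Ks for two pre-aligned, equal-length, in-frame CDS.

    Codon pairs containing gaps, ambiguity codes or stop codons are skipped
    (count reported); a shared terminal stop codon is trimmed silently.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS pair must be equal length after codon-aware alignment")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned CDS length must be a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if CODON_TABLE.get(cds_a[-3:]) == "*" and CODON_TABLE.get(cds_b[-3:]) == "*":
        cds_a, cds_b = cds_a[:-3], cds_b[:-3]

    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    compared = skipped = 0
    for i in range(0, len(cds_a) - 2, 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if (ca not in CODON_TABLE or cb not in CODON_TABLE
                or CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*"):
            skipped += 1
            continue
        compared += 1
        sa, na = _codon_site_split(ca)
        sb, nb = _codon_site_split(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        dsd, dnd = _pathway_diffs(ca, cb)
        sd += dsd; nd += dnd
    if skipped:
        log.debug("ng86_kaks(%s,%s): skipped %d codon pairs", gene_a, gene_b, skipped)
    if compared == 0:
        raise ValueError("no comparable codons")

    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(gene_a, gene_b, n_sites, s_sites, nd, sd, pn, ps,
                      ka, ks, ratio, compared, skipped)


def codon_aware_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: align the translations globally
    (BLOSUM62, affine gaps) and project gaps back onto codons ('---').

    Inputs must be in frame (length divisible by 3, no internal stops); a
    terminal stop codon is carried through.  The output pair is equal-length
    and ready for ng86_kaks, which skips gap codons.
    """
    from Bio.Align import substitution_matrices

    def split(cds: str) -> tuple[list[str], str | None]:
        if len(cds) % 3:
            raise ValueError("CDS length must be a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        stop = codons.pop() if codons and CODON_TABLE.get(codons[-1]) == "*" else None
        return codons, stop

    codons_a, stop_a = split(cds_a.upper())
    codons_b, stop_b = split(cds_b.upper())
    prot_a = "".join(CODON_TABLE.get(c, "X") for c in codons_a)
    prot_b = "".join(CODON_TABLE.get(c, "X") for c in codons_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        out_a.append("---" if x == "-" else codons_a[ia])
        out_b.append("---" if y == "-" else codons_b[ib])
        ia += x != "-"
        ib += y != "-"
    if stop_a and stop_b:
        out_a.append(stop_a)
        out_b.append(stop_b)
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------- duplicate pairs

@dataclass(frozen=True)
class DupPair:
    """An unordered duplicated gene pair passing the coverage/identity screen."""

    gene_a: str
    gene_b: str
    aligned_length: int
    coverage: float
    identity: float
    e_value: float
    score: float


def _dna_aligner(match: float = 2.0, mismatch: float = -3.0,
                 gap_open: float = 5.0, gap_extend: float = 2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _ungapped_lambda(match: float = 2.0, mismatch: float = -3.0) -> float:
    """Karlin–Altschul lambda for the nucleotide scheme at uniform composition."""
    from scipy.optimize import brentq
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    return brentq(f, 1e-6, 5.0)


_NT_LAMBDA = None
_NT_K = 0.3  # calibration constant; only the score ranking matters for the cutoff


def nucleotide_evalue(score: float, m: int, n: int) -> float:
    global _NT_LAMBDA
    if _NT_LAMBDA is None:
        _NT_LAMBDA = _ungapped_lambda()
    return _NT_K * m * n * math.exp(-_NT_LAMBDA * score)


def _shared_kmers(a: str, b: str, k: int = 12) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i:i + k] for i in range(0, len(a) - k + 1, 4)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def find_duplicate_pairs(cds_set: dict[str, str], min_cov: float = 0.75,
                         min_id: float = 0.75, evalue_cutoff: float = 1e-20,
                         ) -> list[DupPair]:
    """Screen all unordered CDS pairs for duplicates (>=75% coverage of the
    longer gene, >=75% identity in the aligned region, E <= 1e-20).

    A shared-12-mer prefilter skips clearly unrelated pairs before the local
    alignment; a pair sharing no 12-mer cannot reach 75% identity over 75%
    of a >=250-codon CDS.
    """
    aligner = _dna_aligner()
    out: list[DupPair] = []
    for (ida, a), (idb, b) in combinations(cds_set.items(), 2):
        if not _shared_kmers(a, b):
            continue
        alns = aligner.align(a, b)
        if len(alns) == 0:
            continue
        aln = alns[0]
        score = aln.score
        ev = nucleotide_evalue(score, len(a), len(b))
        if ev > evalue_cutoff:
            continue
        # columns of the local alignment, counting gap columns
        ta, tb = str(aln[0]), str(aln[1])
        aligned_length = len(ta)
        matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
        identity = matches / aligned_length if aligned_length else 0.0
        longer = max(len(a), len(b))
        if len(a) >= len(b):
            span = aln.aligned[0]
        else:
            span = aln.aligned[1]
        covered = int(sum(e - s for s, e in span))
        coverage = covered / longer
        if coverage >= min_cov and identity >= min_id:
            out.append(DupPair(ida, idb, aligned_length, coverage, identity, ev, score))
    return out


# ---------------------------------------------------------------- clusters

@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: list[str]
    span: tuple[int, int]


def detect_clusters(gene_coords, max_gap: int = 1_000_000,
                    mode: str = "start") -> list[GeneCluster]:
    """Single-linkage tandem clusters: per chromosome, sort by start and link
    consecutive genes closer than max_gap; emit components with >= 2 members.

    gene_coords: iterable of (gene_id, chromosome, start, end); mode "start"
    measures start-to-start distance, "gap" end-to-start.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id, chrom, start, end in gene_coords:
        by_chrom.setdefault(chrom, []).append((int(start), int(end), gene_id))
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom])
        run: list[tuple[int, int, str]] = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            dist = cur[0] - prev[0] if mode == "start" else cur[0] - prev[1]
            if dist < max_gap:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run, len(clusters)))
                run = [cur]
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run, len(clusters)))
    return clusters


def _make_cluster(chrom, run, idx) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster{idx + 1}",
        chromosome=chrom,
        members=[g for _, _, g in run],
        span=(run[0][0], max(e for _, e, _ in run)),
    )


# ---------------------------------------------------------- selection summary

@dataclass
class SelectionSummary:
    n_pairs: int                 # pairs with a defined ratio
    n_undefined: int
    n_positive: int              # ratio > 1
    n_purifying: int             # ratio < 1
    n_neutral: int               # ratio == 1
    pct_positive: str
    pct_purifying: str
    n_02_06: int                 # ratio in [0.2, 0.6]
    pct_02_06: str
    histogram: dict[str, int] = field(default_factory=dict)   # 0.2-wide bins


def selection_summary(results, bin_width: float = 0.2,
                      max_bin: float = 2.0) -> SelectionSummary | None:
    """Counts/percentages of positive vs purifying selection plus a 0.2-wide
    ratio histogram.  Undefined ratios (Ks = 0) are excluded from denominators.
    Percentages use the one-decimal-or-integer rounding of the report."""
    results = list(results)
    ratios = [r.ratio for r in results if getattr(r, "ratio", None) is not None]
    n_undef = len(results) - len(ratios)
    if not ratios:
        log.warning("selection_summary: all %d ratios undefined", n_undef)
        return None
    n = len(ratios)
    n_pos = sum(1 for r in ratios if r > 1.0)
    n_pur = sum(1 for r in ratios if r < 1.0)
    n_mid = sum(1 for r in ratios if 0.2 <= r <= 0.6)
    hist: dict[str, int] = {}
    nbins = int(round(max_bin / bin_width))
    for i in range(nbins):
        lo, hi = i * bin_width, (i + 1) * bin_width
        hist[f"[{lo:.1f},{hi:.1f})"] = sum(1 for r in ratios if lo <= r < hi)
    hist[f">={max_bin:.1f}"] = sum(1 for r in ratios if r >= max_bin)
    return SelectionSummary(
        n_pairs=n, n_undefined=n_undef, n_positive=n_pos, n_purifying=n_pur,
        n_neutral=n - n_pos - n_pur,
        pct_positive=format_percent(n_pos, n),
        pct_purifying=format_percent(n_pur, n),
        n_02_06=n_mid, pct_02_06=format_percent(n_mid, n),
        histogram=hist,
    )
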