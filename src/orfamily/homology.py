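"""Translated homology search: protein queries against all six frames of a genome.

A TBLASTN-style pipeline at desk scale: exact amino-acid k-mer seeds between
each query and each translated frame, ungapped X-drop extension on the seed
diagonal, then an exact local (Smith–Waterman) refinement on a window around
the extended segment.  Significance uses the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with published ungapped BLOSUM62 parameters; hits with
E below the cutoff are reported in genomic forward coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._util import revcomp

log = logging.getLogger(__name__)

AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


# ------------------------------------------------------------------ scoring

@dataclass
class ScoringScheme:
    """Substitution matrix plus gap and Karlin–Altschul parameters.

    Defaults: BLOSUM62 with 'X' (and '*') scoring 0 against everything,
    affine gaps 11/1, and the published ungapped BLOSUM62 constants
    lambda ~ 0.318, K ~ 0.13 treated as fixed calibration values.
    """

    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.318
    kappa: float = 0.13
    bio_matrix: object = field(default=None, repr=False)

    @classmethod
    def default(cls) -> "ScoringScheme":
        m = substitution_matrices.load("BLOSUM62")
        arr = np.zeros((len(AA_ORDER), len(AA_ORDER)), dtype=np.int32)
        for a in AA_ORDER:
            for b in AA_ORDER:
                if a in "X*" or b in "X*":
                    arr[_AA_INDEX[a], _AA_INDEX[b]] = 0
                else:
                    arr[_AA_INDEX[a], _AA_INDEX[b]] = int(m[a, b])
        bio = substitution_matrices.Array(alphabet=AA_ORDER, dims=2)
        for a in AA_ORDER:
            for b in AA_ORDER:
                bio[a, b] = arr[_AA_INDEX[a], _AA_INDEX[b]]
        return cls(matrix=arr, bio_matrix=bio)

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_AA_INDEX.get(a, _AA_INDEX["X"]),
                               _AA_INDEX.get(b, _AA_INDEX["X"])])


def evalue(score: float, query_length: int, database_length: int,
           scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation for a local alignment score."""
    if query_length <= 0 or database_length <= 0:
        raise ValueError("sequence lengths must be positive")
    return scheme.kappa * query_length * database_length * math.exp(-scheme.lam * score)


# ------------------------------------------------------ six-frame translation

_CODON_CODE = np.full(125, _AA_INDEX["X"], dtype=np.int8)


def _init_codon_code() -> None:
    from .codons import CODON_TABLE
    base = {"A": 0, "C": 1, "G": 2, "T": 3}
    for codon, aa in CODON_TABLE.items():
        i = base[codon[0]] * 25 + base[codon[1]] * 5 + base[codon[2]]
        _CODON_CODE[i] = _AA_INDEX[aa]


_init_codon_code()

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _b, _v in zip("ACGT", range(4)):
    _BASE_CODE[ord(_b)] = _v
    _BASE_CODE[ord(_b.lower())] = _v


def _translate_frame(codes: np.ndarray, frame: int) -> str:
    """Translate base codes (0-3, 4=N) from a frame offset; N codons -> X."""
    usable = (len(codes) - frame) // 3
    if usable <= 0:
        return ""
    c = codes[frame:frame + 3 * usable].reshape(-1, 3).astype(np.int32)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    aa_codes = _CODON_CODE[idx]
    return "".join(AA_ORDER[i] for i in aa_codes)


def _frame_codes(codes: np.ndarray, frame: int) -> np.ndarray:
    usable = (len(codes) - frame) // 3
    c = codes[frame:frame + 3 * usable].reshape(-1, 3).astype(np.int32)
    return _CODON_CODE[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]].astype(np.int8)


def six_frame_translate(dna: str) -> list[tuple[str, int, str]]:
    """All six translations of a DNA string as (strand, frame, protein).

    Stops are '*', codons containing N are 'X'.  Reverse-strand frames are
    computed on the reverse complement.
    """
    out = []
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for frame in range(3):
            out.append((strand, frame, _translate_frame(codes, frame)))
    return out


# ------------------------------------------------------------------- search

@dataclass
class TranslatedHit:
    query_id: str
    chromosome: str
    strand: str
    frame: int
    start: int            # genomic forward coordinates, 0-based half-open
    end: int
    score: float
    e_value: float
    identity: float
    aln_length: int


@dataclass
class CandidateLocus:
    chromosome: str
    strand: str
    span: tuple[int, int]
    hit_ids: list[int]
    best_e_value: float


def _encode_protein(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in protein],
                    dtype=np.int8)


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-32 hash of every k-mer (length n-k+1)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        h = h * 32 + codes[j:n - k + 1 + j]
    return h


def _ungapped_extend(qcodes, scodes, qpos, spos, k, matrix, x_drop):
    """Extend an exact k-mer seed on its diagonal until the score drops by
    x_drop; returns (best score, qstart, qend) with the subject implied."""
    score = int(matrix[qcodes[qpos:qpos + k], scodes[spos:spos + k]].sum())
    best = score
    qi, si = qpos + k, spos + k
    best_qend = qi
    while qi < len(qcodes) and si < len(scodes):
        score += int(matrix[qcodes[qi], scodes[si]])
        if score > best:
            best, best_qend = score, qi + 1
        if best - score > x_drop:
            break
        qi += 1; si += 1
    score = best
    qi, si = qpos - 1, spos - 1
    best_qstart = qpos
    while qi >= 0 and si >= 0:
        score += int(matrix[qcodes[qi], scodes[si]])
        if score > best:
            best, best_qstart = score, qi
        if best - score > x_drop:
            break
        qi -= 1; si -= 1
    return best, best_qstart, best_qend


def _make_local_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.bio_matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def seeded_translated_search(queries: dict[str, str], genome: dict[str, str],
                             scheme: ScoringScheme | None = None,
                             evalue_cutoff: float = 1e-5,
                             k: int = 4, x_drop: int = 20, band: int = 16,
                             gapped_trigger: int = 40,
                             ) -> list[TranslatedHit]:
    """Search protein queries against all six reading frames of a genome.

    Returns hits with E <= evalue_cutoff sorted by (chromosome, start).  A
    query region present verbatim in the genome always seeds and survives the
    cutoff at desk scale.  Queries shorter than the seed length are skipped
    with a warning.
    """
    scheme = scheme or ScoringScheme.default()
    aligner = _make_local_aligner(scheme)
    db_length = sum(len(s) for s in genome.values()) * 2  # both strands, aa-equivalent /3*6

    enc_queries: dict[str, np.ndarray] = {}
    seed_index: dict[int, list[tuple[str, int]]] = {}
    for qid, qseq in queries.items():
        if len(qseq) < k:
            log.warning("query %s shorter than seed length %d: skipped", qid, k)
            continue
        qc = _encode_protein(qseq)
        enc_queries[qid] = qc
        for h_val, qpos in zip(_kmer_hashes(qc, k), range(len(qc) - k + 1)):
            # seeds containing X or * never match standard-residue frames usefully
            seed_index.setdefault(int(h_val), []).append((qid, qpos))
    if not enc_queries:
        return []
    seed_hash_arr = np.fromiter(seed_index.keys(), dtype=np.int64,
                                count=len(seed_index))
    seed_hash_arr.sort()

    hits: list[TranslatedHit] = []
    for chrom, seq in genome.items():
        fcodes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        rcodes = _BASE_CODE[np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)]
        for strand, codes in (("+", fcodes), ("-", rcodes)):
            for frame in range(3):
                prot_codes = _frame_codes(codes, frame)
                if len(prot_codes) < k:
                    continue
                sub_hashes = _kmer_hashes(prot_codes, k)
                mask = np.isin(sub_hashes, seed_hash_arr)
                positions = np.flatnonzero(mask)
                covered: dict[tuple[str, int], int] = {}
                prot_str = None
                for spos in positions:
                    for qid, qpos in seed_index.get(int(sub_hashes[spos]), ()):
                        diag = int(spos) - qpos
                        key = (qid, diag)
                        if covered.get(key, -1) >= spos:
                            continue
                        qc = enc_queries[qid]
                        score, qs, qe = _ungapped_extend(
                            qc, prot_codes, qpos, int(spos), k,
                            scheme.matrix, x_drop)
                        covered[key] = int(spos) + (qe - qpos)
                        if score < gapped_trigger:
                            continue
                        if prot_str is None:
                            prot_str = "".join(AA_ORDER[i] for i in prot_codes)
                        hit = _gapped_hit(qid, queries[qid], prot_str, qs, qe,
                                          diag, band, aligner, scheme,
                                          db_length, chrom, strand, frame,
                                          len(seq))
                        if hit is not None and hit.e_value <= evalue_cutoff:
                            hits.append(hit)
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand, h.frame))
    return hits


def _gapped_hit(qid, qseq, prot_str, qs, qe, diag, band, aligner, scheme,
                db_length, chrom, strand, frame, chrom_len):
    """Exact local DP on a window around the ungapped segment."""
    ss, se = qs + diag, qe + diag
    pad = 2 * band + 8
    w0, w1 = max(0, ss - pad - len(qseq)), min(len(prot_str), se + pad + len(qseq))
    window = prot_str[w0:w1]
    alns = aligner.align(qseq, window)
    if len(alns) == 0:
        return None
    aln = alns[0]
    score = float(aln.score)
    sub_blocks = aln.aligned[1]
    if len(sub_blocks) == 0:
        return None
    sub_start = int(sub_blocks[0][0]) + w0
    sub_end = int(sub_blocks[-1][1]) + w0
    ta, tb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    identity = matches / len(ta) if len(ta) else 0.0
    # aa coordinates on this frame's translation -> genomic forward coords
    nt_start = frame + 3 * sub_start
    nt_end = frame + 3 * sub_end
    if strand == "+":
        g_start, g_end = nt_start, nt_end
    else:
        g_start, g_end = chrom_len - nt_end, chrom_len - nt_start
    ev = evalue(score, len(qseq), db_length, scheme)
    return TranslatedHit(qid, chrom, strand, frame, g_start, g_end,
                         score, ev, identity, len(ta))


def _dedupe_hits(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Collapse identical (query, location) hits kept from different seeds."""
    best: dict[tuple, TranslatedHit] = {}
    for h in hits:
        key = (h.query_id, h.chromosome, h.strand, h.frame, h.start, h.end)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return list(best.values())


# ------------------------------------------------------------------- merging

def merge_hits_to_loci(hits: list[TranslatedHit],
                       max_gap: int = 2000) -> list[CandidateLocus]:
    """Merge hits on one chromosome and strand whose spans lie within max_gap
    of each other; loci are maximal under this rule (order-independent)."""
    by_key: dict[tuple[str, str], list[tuple[int, TranslatedHit]]] = {}
    for i, h in enumerate(hits):
        by_key.setdefault((h.chromosome, h.strand), []).append((i, h))
    loci: list[CandidateLocus] = []
    for (chrom, strand), items in sorted(by_key.items()):
        items.sort(key=lambda ih: (ih[1].start, ih[1].end))
        cur_ids: list[int] = []
        cur_span: list[int] = []
        cur_best = math.inf
        for i, h in items:
            if cur_ids and h.start - cur_span[1] <= max_gap:
                cur_span[1] = max(cur_span[1], h.end)
                cur_ids.append(i)
                cur_best = min(cur_best, h.e_value)
            else:
                if cur_ids:
                    loci.append(CandidateLocus(chrom, strand,
                                               (cur_span[0], cur_span[1]),
                                               cur_ids, cur_best))
                cur_ids = [i]
                cur_span = [h.start, h.end]
                cur_best = h.e_value
        if cur_ids:
            loci.append(CandidateLocus(chrom, strand,
                                       (cur_span[0], cur_span[1]),
                                       cur_ids, cur_best))
    loci.sort(key=lambda l: (l.chromosome, l.span[0]))
    return loci


def hits_table(hits: list[TranslatedHit]) -> pd.DataFrame:
    """BLAST-tabular-style hit table."""
    rows = [{
        "qseqid": h.query_id, "sseqid": h.chromosome,
        "pident": round(100.0 * h.identity, 2), "length": h.aln_length,
        "evalue": h.e_value, "bitscore": h.score,
        "sstart": h.start + 1, "send": h.end,
        "sstrand": "plus" if h.strand == "+" else "minus", "frame": h.frame,
    } for h in hits]
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length",
                                       "evalue", "bitscore", "sstart", "send",
                                       "sstrand", "frame"])
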