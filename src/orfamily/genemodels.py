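"""Gene models and their classification as intact / truncated / pseudogene.

An olfactory-receptor candidate is *intact* when its CDS has a start codon, a
terminal stop, encodes >= 250 residues with no frameshift or premature stop,
and the protein can form seven transmembrane helices (predicted here by
Kyte–Doolittle hydropathy segmentation).  A candidate with any disruption is a
*pseudogene*; one lacking start and/or stop but still well matched to a known
OR query is *truncated*.  Protein physicochemical properties (molecular
weight, isoelectric point, instability index) follow the classic ProtParam
definitions, and the five canonical OR motifs are scanned as degenerate
patterns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import IsoelectricPoint as _IP
from Bio.SeqUtils.ProtParamData import DIWV, kd as KD_SCALE

from ._util import revcomp
from .codons import CODON_TABLE, translate_cds

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
WATER_MW = 18.0153

#: the five canonical OR motifs as degenerate patterns (X = any residue,
#: brackets = alternatives).  Motif 5 is the conserved extracellular-loop
#: cysteine, scanned in a Ser/Thr-flanked context.
MOTIF_PATTERNS: dict[int, str] = {
    1: "MA[FY][DE]RYVAIC",
    2: "NX[TS]X",
    3: "PMLNPFIY",
    4: "KAFSTCXSH",
    5: "[ST]C[ST]",
}


def _motif_regex(pattern: str) -> re.Pattern:
    return re.compile(pattern.replace("X", "."))


_MOTIF_RE = {mid: _motif_regex(p) for mid, p in MOTIF_PATTERNS.items()}


# ---------------------------------------------------------------- data types

@dataclass
class GeneModel:
    """A candidate gene locus with exon structure and spliced CDS."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]      # 0-based half-open, sorted, non-overlapping
    cds: str

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class Disruption:
    kind: str            # "premature_stop" | "frameshift"
    cds_offset: int      # nucleotide offset within the CDS


@dataclass
class ProteinRecord:
    sequence: str
    length: int
    molecular_weight: float
    pi: float
    instability_index: float
    tm_segments: list[tuple[int, int]]
    motif_hits: list[tuple[int, tuple[int, int]]]

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)


@dataclass
class ClassifiedGene:
    model: GeneModel
    category: str                    # intact | truncated | pseudogene | rejected
    protein: ProteinRecord | None
    tm_count: int
    disruptions: list[Disruption] = field(default_factory=list)
    query_identity: float | None = None


# --------------------------------------------------------- model extraction

def _orfs_in_frame(dna: str):
    """Yield (start, end) of ATG..stop ORFs in frame of the given string."""
    i, n = 0, len(dna)
    while i + 2 < n:
        if dna[i:i + 3] == "ATG":
            j = i
            while j + 2 < n:
                if CODON_TABLE.get(dna[j:j + 3]) == "*":
                    yield i, j + 3
                    break
                j += 3
            else:
                pass
            i = j + 3
        else:
            i += 3


def longest_orf(dna: str) -> tuple[int, int, str] | None:
    """Longest ATG..stop ORF over both strands; returns (start, end, strand)
    in forward coordinates, or None."""
    best = None
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        for frame in range(3):
            for s, e in _orfs_in_frame(seq[frame:]):
                s, e = s + frame, e + frame
                if best is None or e - s > best[1] - best[0]:
                    if strand == "+":
                        best = (s, e, "+")
                    else:
                        best = (len(dna) - e, len(dna) - s, "-")
    return best


def extract_gene_model(locus, genome: dict[str, str], annotation=None,
                       min_orf: int = 150) -> GeneModel | None:
    """Build a gene model for a candidate locus.

    If an annotated gene (fileio.GffGene) overlaps the locus its exon
    structure is adopted; otherwise the longest ORF in the locus becomes a
    single-exon model.  Loci with no annotation and no ORF >= min_orf nt are
    discarded (None, reason logged).
    """
    chrom, start, end = locus.chromosome, locus.span[0], locus.span[1]
    if annotation:
        overlapping = [
            g for g in annotation
            if g.chrom == chrom and g.start < end and g.end > start
        ]
        if overlapping:
            g = max(overlapping, key=lambda g: min(g.end, end) - max(g.start, start))
            return GeneModel(
                gene_id=g.gene_id, chromosome=chrom, strand=g.strand,
                exons=sorted(g.exons), cds=g.spliced_cds(genome),
            )
    slice_ = genome[chrom][start:end]
    orf = longest_orf(slice_)
    if orf is None or orf[1] - orf[0] < min_orf:
        log.info("locus %s:%d-%d discarded: no annotation and no ORF >= %d nt",
                 chrom, start, end, min_orf)
        return None
    s, e, strand = orf
    exon = (start + s, start + e)
    cds = genome[chrom][exon[0]:exon[1]]
    if strand == "-":
        cds = revcomp(cds)
    gene_id = f"{chrom}:{exon[0]}-{exon[1]}"
    return GeneModel(gene_id=gene_id, chromosome=chrom, strand=strand,
                     exons=[exon], cds=cds)


# ------------------------------------------------------------- disruptions

def detect_disruptions(cds: str, hit_frames=None) -> list[Disruption]:
    """Premature stops (in-frame '*' before the last codon) and frameshifts
    (CDS length not a multiple of 3, or supporting homology hits jumping
    between reading frames on one strand)."""
    out: list[Disruption] = []
    n = len(cds)
    n_codons = n // 3
    for i in range(n_codons - 1):
        if CODON_TABLE.get(cds[3 * i:3 * i + 3]) == "*":
            out.append(Disruption("premature_stop", 3 * i))
    if n % 3 != 0:
        out.append(Disruption("frameshift", 3 * n_codons))
    elif hit_frames is not None and len(set(hit_frames)) > 1:
        out.append(Disruption("frameshift", 0))
    return out


# --------------------------------------------------------- TM segmentation

def predict_tm_segments(protein: str, window: int = 19,
                        threshold: float = 1.6, merge_gap: int = 5,
                        min_len: int = 15) -> list[tuple[int, int]]:
    """Transmembrane helix spans by Kyte–Doolittle sliding-window hydropathy.

    Windows (odd length) whose mean hydropathy exceeds the threshold are
    merged into runs; runs separated by < merge_gap residues are joined and
    runs shorter than min_len residues dropped.  Returns residue spans
    (0-based half-open).
    """
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    n = len(protein)
    if n < window:
        return []
    values = np.array([KD_SCALE.get(aa, 0.0) for aa in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = np.flatnonzero(means > threshold)  # index i covers residues [i, i+window)
    spans: list[list[int]] = []
    for i in above:                            # runs of consecutive window indices
        if spans and i == spans[-1][1] - window + 1:
            spans[-1][1] = int(i) + window
        else:
            spans.append([int(i), int(i) + window])
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_len]


# ------------------------------------------------------- protein properties

def _validate_protein(sequence: str) -> None:
    bad = set(sequence) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue(s) in sequence: {sorted(bad)}")


def molecular_weight(sequence: str) -> float:
    """Average-mass molecular weight: residue masses minus one water per bond."""
    _validate_protein(sequence)
    total = sum(protein_weights[aa] for aa in sequence)
    return total - (len(sequence) - 1) * WATER_MW


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a pH, Bjellqvist pKa set
    (termini + D, E, C, Y, H, K, R)."""
    pos_pks = dict(_IP.positive_pKs)
    neg_pks = dict(_IP.negative_pKs)
    pos_pks["Nterm"] = _IP.pKnterminal.get(sequence[0], pos_pks["Nterm"])
    neg_pks["Cterm"] = _IP.pKcterminal.get(sequence[-1], neg_pks["Cterm"])
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    charge = 0.0
    for group, pk in pos_pks.items():
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n * 10 ** pk / (10 ** pk + 10 ** ph)
    for group, pk in neg_pks.items():
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n * 10 ** ph / (10 ** pk + 10 ** ph)
    return charge


def isoelectric_point(sequence: str, tol: float = 0.01) -> float:
    """pI by bisection of the net-charge curve on pH 0..14."""
    _validate_protein(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide DIWV weights."""
    _validate_protein(sequence)
    if len(sequence) < 2:
        return 0.0
    total = sum(DIWV[a][b] for a, b in zip(sequence, sequence[1:]))
    return 10.0 / len(sequence) * total


def protein_properties(sequence: str) -> tuple[float, float, float]:
    """(molecular weight Da, pI, instability index) of a standard-residue protein."""
    return (molecular_weight(sequence), isoelectric_point(sequence),
            instability_index(sequence))


# ------------------------------------------------------------- motif scan

def scan_conserved_motifs(protein: str) -> list[tuple[int, tuple[int, int]]]:
    """Non-overlapping occurrences of the five canonical OR motifs."""
    hits = []
    for mid, rx in _MOTIF_RE.items():
        for m in rx.finditer(protein):
            hits.append((mid, (m.start(), m.end())))
    return hits


# ----------------------------------------------------------- classification

_PROT_ALIGNER: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _PROT_ALIGNER = a
    return _PROT_ALIGNER


def best_query_identity(protein: str, queries: dict[str, str],
                        min_match_len: int = 100) -> float:
    """Best local-alignment identity to any query over >= min_match_len columns."""
    best = 0.0
    aligner = _protein_aligner()
    for q in queries.values():
        alns = aligner.align(protein, q)
        if len(alns) == 0:
            continue
        aln = alns[0]
        ta, tb = str(aln[0]), str(aln[1])
        if len(ta) < min_match_len:
            continue
        matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
        best = max(best, matches / len(ta))
    return best


def classify_gene(model: GeneModel, tm_predictor=predict_tm_segments,
                  min_len: int = 250, min_tm: int = 7,
                  queries: dict[str, str] | None = None,
                  query_identity: float | None = None,
                  homology_floor: float = 0.40, min_match_len: int = 100,
                  hit_frames=None, with_properties: bool = True,
                  ) -> ClassifiedGene:
    """Classify one gene model.

    Precedence: any disruption => pseudogene; else start + stop + length +
    7 TM => intact; else homology to a known OR >= homology_floor =>
    truncated; else rejected non-OR.
    """
    cds = model.cds.upper()
    disruptions = detect_disruptions(cds, hit_frames=hit_frames)
    if disruptions:
        return ClassifiedGene(model, "pseudogene", None, 0, disruptions)

    protein_seq = translate_cds(cds)
    has_start = cds.startswith("ATG")
    has_stop = CODON_TABLE.get(cds[-3:]) == "*"
    tm = tm_predictor(protein_seq)
    tm_count = len(tm)

    identity = query_identity
    if identity is None and queries:
        identity = best_query_identity(protein_seq, queries, min_match_len)

    def record() -> ProteinRecord:
        clean = all(aa in STANDARD_AA for aa in protein_seq)
        mw, pi, ii = protein_properties(protein_seq) if (with_properties and clean) \
            else (float("nan"),) * 3
        return ProteinRecord(
            sequence=protein_seq, length=len(protein_seq),
            molecular_weight=mw, pi=pi, instability_index=ii,
            tm_segments=tm, motif_hits=scan_conserved_motifs(protein_seq),
        )

    if has_start and has_stop and len(protein_seq) >= min_len and tm_count >= min_tm:
        return ClassifiedGene(model, "intact", record(), tm_count, [], identity)
    if identity is not None and identity >= homology_floor:
        return ClassifiedGene(model, "truncated", record(), tm_count, [], identity)
    log.info("gene %s rejected as non-OR (start=%s stop=%s len=%d tm=%d id=%s)",
             model.gene_id, has_start, has_stop, len(protein_seq), tm_count, identity)
    return ClassifiedGene(model, "rejected", None, tm_count, [], identity)
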