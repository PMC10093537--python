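"""Gene-model classification, TM-helix hydropathy prediction, ProtParam-style
protein properties (with a charge-grid pI oracle) and motif scanning."""

import random

import numpy as np
import pytest

from orfamily.fileio import GffGene
from orfamily.genemodels import (GeneModel, classify_gene, detect_disruptions,
                                 extract_gene_model, instability_index,
                                 isoelectric_point, molecular_weight, net_charge,
                                 predict_tm_segments, protein_properties,
                                 scan_conserved_motifs)
from orfamily.homology import CandidateLocus
from orfamily._util import revcomp


# --------------------------------------------------------------- TM helices

def test_tm_constructed_extremes():
    protein = "D" * 20 + "L" * 30 + "D" * 20
    assert len(predict_tm_segments(protein)) == 1
    assert predict_tm_segments("D" * 100) == []
    assert predict_tm_segments("LLL") == []          # shorter than window


def test_tm_on_generator_template(rng):
    from orfamily.synthetic import make_or_template
    protein, _ = make_or_template("delta", 310, rng)
    assert len(predict_tm_segments(protein)) >= 7


def test_tm_window_validation():
    with pytest.raises(ValueError):
        predict_tm_segments("L" * 50, window=18)


# ------------------------------------------------------------- disruptions

def test_disruption_rules():
    dis = detect_disruptions("ATGTAAAAATGA")
    assert [(d.kind, d.cds_offset) for d in dis] == [("premature_stop", 3)]
    dis = detect_disruptions("A" * 301)
    assert [d.kind for d in dis] == ["frameshift"]
    assert detect_disruptions("ATGAAATTTTGA") == []
    # frame jump among supporting hits implies a frameshift
    dis = detect_disruptions("ATGAAATTTTGA", hit_frames=[0, 2])
    assert [d.kind for d in dis] == ["frameshift"]


# ------------------------------------------------------------- properties

def test_single_glycine_mass():
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)


def test_mw_additivity():
    water = 18.0153
    a, b = "ACDEFG", "KLMNP"
    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - water, abs=1e-6)


def test_pi_charge_signs():
    assert isoelectric_point("KKKKK") > 9
    assert isoelectric_point("DDDDD") < 5


def grid_scan_pi(seq, step=1e-4):
    """Independent oracle: brute-force scan of |net charge| over pH 0-14."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.abs([net_charge(seq, ph) for ph in grid])
    return float(grid[int(np.argmin(charges))])


def test_pi_bisection_matches_grid_scan():
    rng = random.Random(5)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(8):
        pep = "".join(rng.choice(aas) for _ in range(20))
        assert isoelectric_point(pep) == pytest.approx(grid_scan_pi(pep), abs=0.02)


def test_properties_against_biopython_protparam():
    """Cross-check against the established ProtParam implementation."""
    from Bio.SeqUtils.ProtParam import ProteinAnalysis
    rng = random.Random(11)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(5):
        pep = "".join(rng.choice(aas) for _ in range(40))
        pa = ProteinAnalysis(pep)
        mw, pi, instab = protein_properties(pep)
        assert mw == pytest.approx(pa.molecular_weight(), abs=0.01)
        assert pi == pytest.approx(pa.isoelectric_point(), abs=0.05)
        assert instab == pytest.approx(pa.instability_index(), abs=0.01)


def test_invalid_residue_is_named():
    with pytest.raises(ValueError, match="X"):
        protein_properties("ACDX")


# ------------------------------------------------------------------ motifs

@pytest.mark.parametrize("seq,motif", [
    ("GGGMAYDRYVAICGGG", 1),
    ("GGGMAFERYVAICGGG", 1),
    ("GGGKAFSTCVSHGGG", 4),
    ("GGGPMLNPFIYGGG", 3),
    ("GGGNGTSGGG", 2),
    ("GGGSCSGGG", 5),
])
def test_motif_patterns(seq, motif):
    assert motif in {m for m, _ in scan_conserved_motifs(seq)}


def test_no_motifs_in_poly_ala():
    assert scan_conserved_motifs("AAAA") == []


# ------------------------------------------------------------ classification

def _clean_cds(n_codons=251):
    from orfamily.synthetic import make_or_template
    _, cds = make_or_template("delta", n_codons, np.random.default_rng(1))
    return cds


def _model(cds, gene_id="g", chrom="chr1", strand="+"):
    return GeneModel(gene_id, chrom, strand, [(0, len(cds))], cds)


def test_classify_intact_pseudo_truncated():
    cds = _clean_cds()
    assert classify_gene(_model(cds)).category == "intact"

    broken = cds[:300] + "TAA" + cds[303:]
    c = classify_gene(_model(broken))
    assert c.category == "pseudogene"
    assert c.disruptions[0].kind == "premature_stop"

    no_start = "CTG" + cds[3:]
    c = classify_gene(_model(no_start), query_identity=0.8)
    assert c.category == "truncated"

    c = classify_gene(_model(no_start), query_identity=0.1)
    assert c.category == "rejected"


def test_classify_pseudogene_takes_precedence():
    cds = _clean_cds()
    broken = cds[:300] + "TAA" + cds[303:]
    # even with perfect homology, a disruption is disqualifying
    assert classify_gene(_model(broken), query_identity=1.0).category == "pseudogene"


def test_classified_protein_record():
    c = classify_gene(_model(_clean_cds()))
    p = c.protein
    assert p.length >= 250
    assert 0 < p.pi < 14
    assert p.molecular_weight > 0
    assert p.tm_count >= 7


# ------------------------------------------------------------- extraction

def test_extract_adopts_annotation_and_orf_fallback(small_dataset):
    ds = small_dataset
    multi = next(t for t in ds.truth if t.n_exons >= 2)
    locus = CandidateLocus(multi.chromosome, multi.strand,
                           (multi.start, multi.end), [], 1e-30)
    model = extract_gene_model(locus, ds.genome, ds.gff_genes)
    assert model.n_exons == multi.n_exons
    assert model.cds == ds.cds[multi.gene_id]

    single = next(t for t in ds.truth
                  if t.n_exons == 1 and t.category == "intact")
    locus = CandidateLocus(single.chromosome, single.strand,
                           (max(0, single.start - 50), single.end + 50),
                           [], 1e-30)
    model = extract_gene_model(locus, ds.genome, annotation=None)
    assert model.cds == ds.cds[single.gene_id]   # longest ORF == planted CDS


def test_extract_minus_strand_convention():
    cds = _clean_cds()
    genome = {"c": "ACGT" * 200 + revcomp(cds) + "ACGT" * 200}
    start = 800
    gene = GffGene("g", "c", start, start + len(cds), "-",
                   [(start, start + len(cds))])
    locus = CandidateLocus("c", "-", (start, start + len(cds)), [], 1e-30)
    model = extract_gene_model(locus, genome, [gene])
    assert model.cds == cds


def test_extract_discards_orfless_locus():
    genome = {"c": "CCCCCC" * 200}               # no ATG anywhere
    locus = CandidateLocus("c", "+", (0, 1200), [], 1e-10)
    assert extract_gene_model(locus, genome, annotation=None) is None
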