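"""Generator contracts: template structure, degradation, divergence planting,
dataset geometry/ground truth, format round-trips and determinism."""

import numpy as np
import pytest

from orfamily.codons import CODON_TABLE, translate_cds
from orfamily.evolution import detect_clusters, ng86_kaks
from orfamily.fileio import read_gff3, write_gff3
from orfamily.genemodels import detect_disruptions, predict_tm_segments
from orfamily.synthetic import (InvalidConfigError, SynthConfig, TISSUES,
                                build_dataset, degrade, make_or_template,
                                mutate_duplicate)
from tests.conftest import SMALL_SYNTH


# ---------------------------------------------------------------- templates

def test_template_examples():
    protein, _ = make_or_template("delta", 310, np.random.default_rng(1))
    assert len(protein) == 310
    assert len(predict_tm_segments(protein)) >= 7

    _, cds = make_or_template("eta", 250, np.random.default_rng(2))
    assert len(cds) == 753                      # 251 codons incl. the stop
    assert cds.startswith("ATG")
    assert CODON_TABLE[cds[-3:]] == "*"
    assert "*" not in translate_cds(cds)


def test_template_determinism_and_validation():
    a = make_or_template("zeta", 280, np.random.default_rng(5))
    b = make_or_template("zeta", 280, np.random.default_rng(5))
    assert a == b
    with pytest.raises(InvalidConfigError):
        make_or_template("delta", 249, np.random.default_rng(0))


def test_group_templates_carry_their_motifs():
    from orfamily.genemodels import scan_conserved_motifs
    p_type1, _ = make_or_template("delta", 300, np.random.default_rng(3))
    p_type2, _ = make_or_template("eta", 300, np.random.default_rng(3))
    assert {1, 2, 3, 4, 5} <= {m for m, _ in scan_conserved_motifs(p_type1)}
    hits2 = {m for m, _ in scan_conserved_motifs(p_type2)}
    assert {1, 2, 3, 4} <= hits2                # type II retains 1-4 ...
    assert 5 not in hits2                       # ... but lacks the motif-5 Cys


# ------------------------------------------------------------------ degrade

def test_degrade_pseudogenize_and_truncate(rng):
    _, cds = make_or_template("beta", 300, rng)
    for seed in range(6):
        variant, info = degrade(cds, "pseudogenize", np.random.default_rng(seed))
        assert len(detect_disruptions(variant)) >= 1
    for seed in range(6):
        variant, info = degrade(cds, "truncate", np.random.default_rng(seed))
        assert detect_disruptions(variant) == []           # clean interior
        missing_start = not variant.startswith("ATG")
        missing_stop = CODON_TABLE.get(variant[-3:]) != "*"
        assert missing_start or missing_stop
    a = degrade(cds, "pseudogenize", np.random.default_rng(3))
    b = degrade(cds, "pseudogenize", np.random.default_rng(3))
    assert a == b
    with pytest.raises(ValueError):
        degrade(cds, "mangle", rng)


# --------------------------------------------------------- planted divergence

def test_mutate_duplicate_degenerate_cases(rng):
    _, cds = make_or_template("epsilon", 300, rng)
    assert mutate_duplicate(cds, 0.0, 0.0, np.random.default_rng(0)) == cds
    syn_only = mutate_duplicate(cds, 0.3, 0.0, np.random.default_rng(0))
    assert syn_only != cds
    assert translate_cds(syn_only) == translate_cds(cds)
    assert len(syn_only) == len(cds)
    with pytest.raises(InvalidConfigError):
        mutate_duplicate(cds, 0.7, 0.1, rng)


def test_mutate_duplicate_rate_recovery(rng):
    """Planted (Ks, Ka) = (0.3, 0.1) recovered by the estimator within the
    generator's contract tolerances, averaged over 20 seeds."""
    _, cds = make_or_template("delta", 300, rng)
    kas, kss = [], []
    for seed in range(20):
        child = mutate_duplicate(cds, 0.3, 0.1, np.random.default_rng(seed))
        r = ng86_kaks(cds, child)
        kas.append(r.ka)
        kss.append(r.ks)
    assert np.mean(kss) == pytest.approx(0.3, abs=0.08)
    assert np.mean(kas) == pytest.approx(0.1, abs=0.05)


# ------------------------------------------------------------------ dataset

def test_dataset_counts_and_truth(small_dataset):
    ds = small_dataset
    counts = {c: sum(1 for t in ds.truth if t.category == c)
              for c in ("intact", "truncated", "pseudogene")}
    assert counts == {"intact": 20, "truncated": 5, "pseudogene": 2}
    assert len(ds.truth) == 27

    for t in ds.truth:
        assert 0 <= t.start < t.end <= ds.config.chrom_length
        if t.category == "intact":
            assert t.tm_count >= 7
            assert len(ds.cds[t.gene_id]) >= 750
            assert detect_disruptions(ds.cds[t.gene_id]) == []
        if t.category == "pseudogene":
            assert len(detect_disruptions(ds.cds[t.gene_id])) >= 1
    # no overlapping spans on the same strand
    by_strand = {}
    for t in ds.truth:
        by_strand.setdefault((t.chromosome, t.strand), []).append((t.start, t.end))
    for spans in by_strand.values():
        spans.sort()
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_dataset_cluster_truth(small_dataset):
    ds = small_dataset
    found = detect_clusters(
        [(t.gene_id, t.chromosome, t.start, t.end) for t in ds.truth])
    planted = {}
    for t in ds.truth:
        if t.cluster_id:
            planted.setdefault(t.cluster_id, set()).add(t.gene_id)
    assert len(found) == ds.config.n_clusters == len(planted)
    assert {frozenset(c.members) for c in found} == set(
        map(frozenset, planted.values()))


def test_dataset_gff_roundtrip(small_dataset, tmp_path):
    ds = small_dataset
    path = tmp_path / "truth.gff3"
    write_gff3(ds.gff_genes, path)
    back = read_gff3(path)
    assert len(back) == len(ds.gff_genes)
    for g in back:
        assert g.spliced_cds(ds.genome) == ds.cds[g.gene_id]


def test_dataset_determinism(tmp_path):
    cfg = SynthConfig(seed=11, **SMALL_SYNTH)
    d1 = build_dataset(cfg)
    d2 = build_dataset(cfg)
    assert d1.genome == d2.genome
    assert d1.counts.equals(d2.counts)
    p1 = d1.write(tmp_path / "a")
    p2 = d2.write(tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_dataset_expression_design(small_dataset):
    ds = small_dataset
    expressed = [t for t in ds.truth if t.category != "pseudogene"]
    assert set(ds.lengths.index) >= {t.gene_id for t in expressed}
    n_cond = len(set(ds.sample_sheet["condition"]))
    assert n_cond == 3                       # control, hypoxia, re-oxygenation
    assert set(ds.sample_sheet["tissue"]) == set(TISSUES)
    n_de = sum(any(t.planted_de.values()) for t in expressed)
    assert n_de == round(ds.config.de_fraction * len(expressed))


def test_config_validation():
    with pytest.raises(InvalidConfigError):
        SynthConfig(n_intact=0).validate()
    with pytest.raises(InvalidConfigError):
        SynthConfig(dup_events=[(0, 0.8, 0.1)]).validate()
    with pytest.raises(InvalidConfigError):
        SynthConfig(cluster_span=10_000_000, chrom_length=1_000_000).validate()
    with pytest.raises(InvalidConfigError):
        SynthConfig(groups=("delta", "omega")).validate()


def test_geometry_infeasible():
    cfg = SynthConfig(seed=0, n_chromosomes=1, chrom_length=600_000,
                      n_intact=30, n_truncated=0, n_pseudo=0, n_clusters=2,
                      cluster_span=200_000, dup_events=[])
    with pytest.raises(InvalidConfigError, match="infeasible"):
        build_dataset(cfg)
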