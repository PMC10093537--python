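"""Pipeline orchestration: one config, all stages, one summary report.

Stages run in dependency order — simulate/load, translated search, gene-model
classification, phylogeny + group assignment, duplication/selection analysis,
collinearity, expression — each writing its artifacts under the output
directory together with a manifest of parameters and input checksums.  A
single seed fans out to per-stage generators, so toggling one stage never
shifts another's randomness, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import format_percent, sha256_file, stage_rng
from . import evolution, expression, genemodels, homology, phylogeny, synteny
from .fileio import GffGene, read_fasta, read_gff3, read_tsv, write_fasta, \
    write_gff3, write_tsv
from .synthetic import SynthConfig, SynthDataset, build_dataset

log = logging.getLogger(__name__)

GROUP_ORDER = ("beta", "gamma", "delta", "zeta", "epsilon", "eta")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ------------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one pipeline run."""

    outdir: str = "orfamily_out"
    seed: int = 0
    # inputs; when simulate is true they are generated instead
    simulate: bool = True
    genome: str | None = None
    annotation: str | None = None
    queries: str | None = None
    references: str | None = None
    reference_labels: str | None = None   # TSV (id, group) when not encoded in ids
    counts: str | None = None
    samples: str | None = None
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    # stage toggles
    run_search: bool = True
    run_classify: bool = True
    run_phylogeny: bool = True
    run_evolution: bool = True
    run_synteny: bool = True
    run_expression: bool = True
    # homology search
    evalue_cutoff: float = 1e-5
    seed_k: int = 4
    x_drop: int = 20
    band: int = 16
    merge_gap: int = 2000
    # classification
    min_len: int = 250
    min_tm: int = 7
    tm_window: int = 19
    tm_threshold: float = 1.6
    homology_floor: float = 0.40
    # phylogeny
    distance_model: str = "p_distance"
    bootstrap_reps: int = 100
    knn_k: int = 3
    # evolution
    dup_min_cov: float = 0.75
    dup_min_id: float = 0.75
    dup_evalue: float = 1e-20
    cluster_max_gap: int = 1_000_000
    cluster_mode: str = "start"
    major_cluster_size: int = 5
    # synteny
    min_block: int = 5
    max_gap_genes: int = 25
    # expression
    de_threshold: float = 1.0
    de_pseudo: float = 1.0
    control_condition: str = "control"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def validate(self) -> None:
        if not self.simulate:
            for key in ("genome", "queries"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"config requires {key!r} when simulate is off")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{key} file not found: {value}")


# ------------------------------------------------------------------- report

@dataclass
class SummaryReport:
    n_intact: int = 0
    n_truncated: int = 0
    n_pseudo: int = 0
    n_rejected: int = 0
    group_counts: dict = field(default_factory=dict)       # group -> n classified
    group_expanded: dict = field(default_factory=dict)     # group -> n expanded
    chromosome_counts: dict = field(default_factory=dict)
    n_multi_exon: int = 0
    pct_multi_exon: str = "0"
    clusters: list = field(default_factory=list)           # (id, chrom, size)
    n_major_clusters: int = 0
    n_duplicate_pairs: int = 0
    n_expanded: int = 0
    pct_expanded: str = "0"
    selection: dict = field(default_factory=dict)
    n_de: int = 0
    pct_de: str = "0"
    de_per_tissue: dict = field(default_factory=dict)
    skipped_stages: list = field(default_factory=list)
    warnings: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_intact + self.n_truncated + self.n_pseudo

    @property
    def n_classified(self) -> int:
        return self.n_intact + self.n_truncated

    def check_consistency(self) -> None:
        """Every printed percentage must recompute from its numerator and
        denominator, and category/group counts must add up."""
        def pct_ok(pct, num, den, style):
            if pct == "0" and num == 0:          # stage skipped / nothing seen
                return True
            return den > 0 and pct == format_percent(num, den, style)

        assert self.n_total == self.n_intact + self.n_truncated + self.n_pseudo
        if self.group_counts:
            assert sum(self.group_counts.values()) == self.n_classified, \
                "group counts (incl. non_or) must sum to classified genes"
        assert pct_ok(self.pct_expanded, self.n_expanded,
                      self.n_classified, "two_decimal")
        assert pct_ok(self.pct_multi_exon, self.n_multi_exon,
                      self.n_classified, "int")
        assert pct_ok(self.pct_de, self.n_de, self.n_classified, "two_decimal")
        sel = self.selection
        if sel and sel.get("n_pairs"):
            assert sel["pct_positive"] == format_percent(
                sel["n_positive"], sel["n_pairs"])
            assert sel["pct_purifying"] == format_percent(
                sel["n_purifying"], sel["n_pairs"])
            assert sel["pct_02_06"] == format_percent(
                sel["n_02_06"], sel["n_pairs"])


def render_summary(report: SummaryReport) -> tuple[str, pd.DataFrame, dict]:
    """Human-readable table plus machine-readable TSV/JSON forms carrying the
    same numbers (expanded counts in parentheses in the text table)."""
    report.check_consistency()
    cols = {}
    for group in GROUP_ORDER:
        n = report.group_counts.get(group, 0)
        ex = report.group_expanded.get(group, 0)
        cols[group] = f"{n} ({ex})" if ex else str(n)
    cols["non_or"] = str(report.group_counts.get("non_or", 0))
    cols["functional"] = str(report.n_intact)
    cols["truncated"] = str(report.n_truncated)
    cols["pseudo"] = str(report.n_pseudo)
    cols["total"] = str(report.n_total)
    header = "  ".join(f"{k:>10}" for k in cols)
    values = "  ".join(f"{v:>10}" for v in cols.values())
    lines = ["OR gene family summary", header, values, ""]
    lines.append(f"multi-exon genes: {report.n_multi_exon} ({report.pct_multi_exon}%)")
    lines.append(f"major tandem clusters: {len(report.clusters)}")
    for cid, chrom, size in report.clusters:
        lines.append(f"  {cid}: {chrom}, {size} genes")
    lines.append(f"duplicate pairs: {report.n_duplicate_pairs}; expanded genes: "
                 f"{report.n_expanded} ({report.pct_expanded}%)")
    sel = report.selection
    if sel and sel.get("n_pairs"):
        lines.append(
            f"selection: {sel['n_positive']} pairs ({sel['pct_positive']}%) with "
            f"Ka/Ks > 1; {sel['n_purifying']} pairs ({sel['pct_purifying']}%) "
            f"below 1; {sel['n_02_06']} pairs ({sel['pct_02_06']}%) in [0.2, 0.6]")
    if report.n_de or report.pct_de != "0":
        per_tissue = ", ".join(f"{t}: {n}" for t, n in
                               sorted(report.de_per_tissue.items()))
        lines.append(f"differentially expressed: {report.n_de} "
                     f"({report.pct_de}%) [{per_tissue}]")
    if report.skipped_stages:
        lines.append("skipped stages: " + ", ".join(report.skipped_stages))
    text = "\n".join(lines) + "\n"

    flat = {"n_intact": report.n_intact, "n_truncated": report.n_truncated,
            "n_pseudo": report.n_pseudo, "n_total": report.n_total,
            "n_classified": report.n_classified,
            "n_multi_exon": report.n_multi_exon,
            "pct_multi_exon": report.pct_multi_exon,
            "n_clusters": len(report.clusters),
            "n_major_clusters": report.n_major_clusters,
            "n_duplicate_pairs": report.n_duplicate_pairs,
            "n_expanded": report.n_expanded, "pct_expanded": report.pct_expanded,
            "n_de": report.n_de, "pct_de": report.pct_de}
    for group in GROUP_ORDER:
        flat[f"group_{group}"] = report.group_counts.get(group, 0)
    flat["group_non_or"] = report.group_counts.get("non_or", 0)
    for key, value in (report.selection or {}).items():
        if key != "histogram":
            flat[f"selection_{key}"] = value
    df = pd.DataFrame([flat])
    as_json = {**flat,
               "chromosome_counts": report.chromosome_counts,
               "clusters": [list(c) for c in report.clusters],
               "de_per_tissue": report.de_per_tissue,
               "selection_histogram": (report.selection or {}).get("histogram", {}),
               "skipped_stages": report.skipped_stages,
               "warnings": report.warnings}
    return text, df, as_json


# ------------------------------------------------------------------ stages

def _load_reference_labels(config: PipelineConfig,
                           references: dict[str, str]) -> dict[str, str]:
    if config.reference_labels:
        df = read_tsv(config.reference_labels)
        return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    labels = {}
    for rid in references:
        parts = rid.split("_")
        if len(parts) >= 2:
            labels[rid] = parts[1]
    return labels


def run_pipeline(config: PipelineConfig) -> tuple[SummaryReport, dict]:
    """Run all enabled stages; returns (report, artifact paths)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = SummaryReport()
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        # ---------------- inputs ------------------------------------------
        stage = "simulate" if config.simulate else "load"
        dataset: SynthDataset | None = None
        if config.simulate:
            synth_cfg = SynthConfig(seed=config.seed, **config.synth)
            dataset = build_dataset(synth_cfg)
            data_dir = outdir / "data"
            paths = dataset.write(data_dir)
            artifacts.update({k: str(v) for k, v in paths.items()})
            genome = dataset.genome
            annotation = dataset.gff_genes
            queries = dataset.queries
            references = dataset.references
            reference_labels = dataset.reference_labels
            counts_df, lengths, samples = (dataset.counts, dataset.lengths,
                                           dataset.sample_sheet)
        else:
            genome = read_fasta(config.genome)
            annotation = read_gff3(config.annotation) if config.annotation else None
            queries = read_fasta(config.queries)
            references = read_fasta(config.references) if config.references else {}
            reference_labels = _load_reference_labels(config, references)
            counts_df = lengths = samples = None
            if config.counts:
                raw = read_tsv(config.counts).set_index("gene")
                lengths = raw.pop("length")
                counts_df = raw
                samples = read_tsv(config.samples)

        scheme = homology.ScoringScheme.default()

        # ---------------- search ------------------------------------------
        classified: list[genemodels.ClassifiedGene] = []
        loci = []
        hits = []
        if config.run_search:
            stage = "search"
            hits = homology.seeded_translated_search(
                queries, genome, scheme, evalue_cutoff=config.evalue_cutoff,
                k=config.seed_k, x_drop=config.x_drop, band=config.band)
            loci = homology.merge_hits_to_loci(hits, max_gap=config.merge_gap)
            hits_path = outdir / "hits.tsv"
            write_tsv(homology.hits_table(hits), hits_path)
            artifacts["hits"] = str(hits_path)
        else:
            report.skipped_stages.append("search")

        # ---------------- classification ----------------------------------
        if config.run_classify and config.run_search:
            stage = "classify"
            def tm_predictor(protein):
                return genemodels.predict_tm_segments(
                    protein, window=config.tm_window,
                    threshold=config.tm_threshold)

            # several loci (e.g. a weak opposite-strand hit) can resolve to
            # the same gene model: keep the best-supported locus per gene
            by_gene: dict[str, tuple] = {}
            for locus in loci:
                model = genemodels.extract_gene_model(locus, genome, annotation)
                if model is None:
                    continue
                best_id = max((hits[i].identity for i in locus.hit_ids),
                              default=0.0)
                prev = by_gene.get(model.gene_id)
                if prev is None or best_id > prev[2]:
                    by_gene[model.gene_id] = (model, locus, best_id)
            for model, locus, best_id in by_gene.values():
                hit_frames = None
                if model.n_exons == 1:
                    # frame-jump evidence only from well-matched hits, so a
                    # stray weak off-frame hit cannot fake a frameshift
                    hit_frames = [hits[i].frame for i in locus.hit_ids
                                  if hits[i].identity >= config.homology_floor]
                classified.append(genemodels.classify_gene(
                    model, tm_predictor=tm_predictor, min_len=config.min_len,
                    min_tm=config.min_tm, queries=None, query_identity=best_id,
                    homology_floor=config.homology_floor,
                    hit_frames=hit_frames))
            _write_classified(classified, outdir, artifacts)
            _fill_category_counts(report, classified)
        elif config.run_classify:
            report.skipped_stages.append("classify")
        else:
            report.skipped_stages.append("classify")

        kept = [c for c in classified if c.category in ("intact", "truncated")]
        proteins = {c.model.gene_id: c.protein.sequence for c in kept
                    if c.protein is not None}
        cds_map = {c.model.gene_id: c.model.cds for c in kept}

        # ---------------- phylogeny ----------------------------------------
        group_of: dict[str, str] = {}
        if config.run_phylogeny and kept and references:
            stage = "phylogeny"
            seqs = {**proteins, **references}
            ids = list(seqs)
            msa = phylogeny.progressive_align([seqs[i] for i in ids], ids=ids,
                                              scheme=scheme)
            boot_seed = int(stage_rng(config.seed, "bootstrap").integers(2**31))
            tree, supports = phylogeny.bootstrap_support(
                msa, n_reps=config.bootstrap_reps, seed=boot_seed,
                model=config.distance_model)
            assignments = phylogeny.assign_groups(tree, reference_labels,
                                                  k=config.knn_k)
            group_of = {a.gene_id: a.group for a in assignments}
            newick_path = outdir / "tree.nwk"
            newick_path.write_text(phylogeny.tree_to_newick(tree) + "\n")
            aln_path = outdir / "aligned.fasta"
            write_fasta(dict(zip(msa.ids, msa.rows)), aln_path)
            groups_path = outdir / "groups.tsv"
            write_tsv(pd.DataFrame(
                [{"gene": a.gene_id, "group": a.group, "support": a.support}
                 for a in assignments]), groups_path)
            artifacts.update({"tree": str(newick_path), "alignment": str(aln_path),
                              "groups": str(groups_path)})
            counts: dict[str, int] = {}
            for c in kept:
                grp = group_of.get(c.model.gene_id, "non_or")
                counts[grp] = counts.get(grp, 0) + 1
            report.group_counts = counts
        else:
            report.skipped_stages.append("phylogeny")

        # ---------------- evolution ----------------------------------------
        expanded_ids: set[str] = set()
        if config.run_evolution and kept:
            stage = "evolution"
            pairs = evolution.find_duplicate_pairs(
                cds_map, min_cov=config.dup_min_cov, min_id=config.dup_min_id,
                evalue_cutoff=config.dup_evalue)
            kaks_results = []
            n_saturated = 0
            for p in pairs:
                try:
                    aln_a, aln_b = evolution.codon_aware_align(
                        cds_map[p.gene_a], cds_map[p.gene_b])
                    kaks_results.append(evolution.ng86_kaks(
                        aln_a, aln_b, p.gene_a, p.gene_b))
                except (evolution.SaturationError, ValueError) as exc:
                    n_saturated += 1
                    log.info("Ka/Ks skipped for %s/%s: %s",
                             p.gene_a, p.gene_b, exc)
            summary = evolution.selection_summary(kaks_results)
            coords = [(c.model.gene_id, c.model.chromosome, c.model.start,
                       c.model.end) for c in classified]
            clusters = evolution.detect_clusters(
                coords, max_gap=config.cluster_max_gap, mode=config.cluster_mode)
            expanded_ids = {g for p in pairs for g in (p.gene_a, p.gene_b)}
            _write_evolution(pairs, kaks_results, clusters, outdir, artifacts)
            report.n_duplicate_pairs = len(pairs)
            report.n_expanded = len(expanded_ids)
            report.pct_expanded = format_percent(
                len(expanded_ids), len(kept), "two_decimal") if kept else "0"
            if summary is not None:
                report.selection = dataclasses.asdict(summary)
            if n_saturated:
                report.warnings["kaks_saturated_pairs"] = n_saturated
            report.clusters = [(c.cluster_id, c.chromosome, len(c.members))
                               for c in clusters
                               if len(c.members) >= config.major_cluster_size]
            report.n_major_clusters = len(report.clusters)
            for c in kept:
                grp = group_of.get(c.model.gene_id)
                if grp and c.model.gene_id in expanded_ids:
                    report.group_expanded[grp] = report.group_expanded.get(grp, 0) + 1
        else:
            report.skipped_stages.append("evolution")

        # ---------------- synteny ------------------------------------------
        if config.run_synteny and proteins:
            stage = "synteny"
            partner, orders_b, inverted = _make_partner(
                classified, proteins, stage_rng(config.seed, "partner"))
            orders_a = _gene_orders(classified)
            homs = synteny.reciprocal_homologs(proteins, partner, scheme)
            blocks = synteny.chain_collinear_blocks(
                homs, orders_a, orders_b, max_gap_genes=config.max_gap_genes,
                min_block=config.min_block)
            family_pairs = synteny.highlight_family_pairs(
                blocks, set(proteins) | set(partner))
            _write_synteny(homs, blocks, outdir, artifacts)
            report.warnings["synteny_blocks"] = len(blocks)
            report.warnings["synteny_family_anchor_pairs"] = len(family_pairs)
        else:
            report.skipped_stages.append("synteny")

        # ---------------- expression ----------------------------------------
        if config.run_expression and counts_df is not None:
            stage = "expression"
            fpkm_df = expression.fpkm(counts_df, lengths)
            fc = expression.log2fc(fpkm_df, samples,
                                   control_condition=config.control_condition,
                                   pseudo=config.de_pseudo)
            de = expression.de_flags(fc, threshold=config.de_threshold)
            family = set(cds_map) if cds_map else set(counts_df.index)
            per_gene = expression.de_gene_flags(de)
            fam_flags = per_gene[per_gene.index.isin(family)]
            report.n_de = int(fam_flags.sum())
            denom = len(kept) if kept else len(fam_flags)
            report.pct_de = format_percent(report.n_de, denom, "two_decimal")
            tissue_flags = expression.de_tissue_flags(de)
            fam_tissue = tissue_flags[tissue_flags.index.isin(family)]
            report.de_per_tissue = {t: int(fam_tissue[t].sum())
                                    for t in fam_tissue.columns}
            fpkm_path = outdir / "fpkm.tsv"
            write_tsv(fpkm_df.rename_axis("gene").reset_index(), fpkm_path)
            fc_flat = fc.copy()
            fc_flat.columns = [f"{t}_{c}" for t, c in fc.columns]
            fc_path = outdir / "log2fc.tsv"
            write_tsv(fc_flat.rename_axis("gene").reset_index(), fc_path)
            de_path = outdir / "de_flags.tsv"
            write_tsv(de.table, de_path)
            artifacts.update({"fpkm": str(fpkm_path), "log2fc": str(fc_path),
                              "de": str(de_path)})
        else:
            report.skipped_stages.append("expression")

        # ---------------- multi-exon + chromosomes -------------------------
        report.n_multi_exon = sum(1 for c in kept if c.model.n_exons > 1)
        report.pct_multi_exon = format_percent(
            report.n_multi_exon, len(kept), "int") if kept else "0"
        chrom_counts: dict[str, int] = {}
        for c in classified:
            if c.category in ("intact", "truncated", "pseudogene"):
                chrom_counts[c.model.chromosome] = \
                    chrom_counts.get(c.model.chromosome, 0) + 1
        report.chromosome_counts = dict(sorted(chrom_counts.items()))

        # ---------------- report + manifest --------------------------------
        stage = "report"
        text, df, as_json = render_summary(report)
        (outdir / "report.txt").write_text(text)
        write_tsv(df, outdir / "report.tsv")
        (outdir / "report.json").write_text(
            json.dumps(as_json, indent=2, sort_keys=True) + "\n")
        artifacts.update({"report_txt": str(outdir / "report.txt"),
                          "report_tsv": str(outdir / "report.tsv"),
                          "report_json": str(outdir / "report.json")})
        manifest = {
            "parameters": dataclasses.asdict(config),
            "artifacts": sorted(artifacts),
            "input_checksums": {
                name: sha256_file(path) for name, path in sorted(artifacts.items())
                if Path(path).suffix in (".fasta", ".gff3") and Path(path).exists()
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = str(outdir / "manifest.json")
        return report, artifacts
    except StageError:
        raise
    except Exception as exc:                      # noqa: BLE001
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc


# ------------------------------------------------------------- stage helpers

def _fill_category_counts(report: SummaryReport, classified) -> None:
    for c in classified:
        if c.category == "intact":
            report.n_intact += 1
        elif c.category == "truncated":
            report.n_truncated += 1
        elif c.category == "pseudogene":
            report.n_pseudo += 1
        else:
            report.n_rejected += 1


def _write_classified(classified, outdir: Path, artifacts: dict) -> None:
    genes = []
    rows = []
    for c in classified:
        m = c.model
        genes.append(GffGene(m.gene_id, m.chromosome, m.start, m.end, m.strand,
                             list(m.exons), {"category": c.category}))
        row = {"gene": m.gene_id, "category": c.category, "n_exons": m.n_exons,
               "tm_count": c.tm_count,
               "query_identity": (round(c.query_identity, 4)
                                  if c.query_identity is not None else "")}
        if c.protein is not None:
            row.update(length=c.protein.length,
                       molecular_weight=round(c.protein.molecular_weight, 2),
                       pi=round(c.protein.pi, 2),
                       instability=round(c.protein.instability_index, 2),
                       motifs=";".join(str(mid) for mid in
                                       sorted({m for m, _ in
                                               c.protein.motif_hits})))
        rows.append(row)
    gff_path = outdir / "classified.gff3"
    write_gff3(genes, gff_path)
    props_path = outdir / "properties.tsv"
    write_tsv(pd.DataFrame(rows), props_path)
    artifacts.update({"classified_gff": str(gff_path),
                      "properties": str(props_path)})


def _write_evolution(pairs, kaks_results, clusters, outdir: Path,
                     artifacts: dict) -> None:
    pairs_path = outdir / "duplicate_pairs.tsv"
    write_tsv(pd.DataFrame(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b,
          "aligned_length": p.aligned_length,
          "coverage": round(p.coverage, 4), "identity": round(p.identity, 4),
          "e_value": p.e_value} for p in pairs]), pairs_path)
    kaks_path = outdir / "kaks.tsv"
    write_tsv(pd.DataFrame(
        [{"gene_a": r.gene_a, "gene_b": r.gene_b, "N": round(r.n_sites, 2),
          "S": round(r.s_sites, 2), "Nd": round(r.nd, 2), "Sd": round(r.sd, 2),
          "Ka": round(r.ka, 4), "Ks": round(r.ks, 4),
          "ratio": (round(r.ratio, 4) if r.ratio is not None else "NA")}
         for r in kaks_results]), kaks_path)
    clusters_path = outdir / "clusters.tsv"
    write_tsv(pd.DataFrame(
        [{"cluster": c.cluster_id, "chromosome": c.chromosome,
          "n_members": len(c.members), "start": c.span[0], "end": c.span[1],
          "members": ",".join(c.members)} for c in clusters]), clusters_path)
    artifacts.update({"duplicate_pairs": str(pairs_path), "kaks": str(kaks_path),
                      "clusters": str(clusters_path)})


def _write_synteny(homs, blocks, outdir: Path, artifacts: dict) -> None:
    homs_path = outdir / "homologs.tsv"
    write_tsv(pd.DataFrame(
        [{"gene_a": h.gene_a, "gene_b": h.gene_b, "score": h.score,
          "reciprocal_best": h.reciprocal_best} for h in homs]), homs_path)
    blocks_path = outdir / "synteny_blocks.tsv"
    write_tsv(pd.DataFrame(
        [{"block": i + 1, "chromosome_a": b.chromosome_a,
          "chromosome_b": b.chromosome_b, "orientation": b.orientation,
          "n_anchors": b.n_anchors,
          "anchors": ";".join(f"{a}|{c}" for a, c in b.anchors)}
         for i, b in enumerate(blocks)]), blocks_path)
    artifacts.update({"homologs": str(homs_path),
                      "synteny_blocks": str(blocks_path)})


def _gene_orders(classified) -> dict[str, list[str]]:
    by_chrom: dict[str, list] = {}
    for c in classified:
        if c.category in ("intact", "truncated"):
            by_chrom.setdefault(c.model.chromosome, []).append(
                (c.model.start, c.model.gene_id))
    return {chrom: [g for _, g in sorted(items)]
            for chrom, items in by_chrom.items()}


def _make_partner(classified, proteins, rng):
    """Deterministic partner gene set for collinearity: same per-chromosome
    order with one inverted middle segment per chromosome, proteins lightly
    perturbed (a stand-in related genome, synthetic by construction)."""
    orders_a = _gene_orders(classified)
    partner: dict[str, str] = {}
    orders_b: dict[str, list[str]] = {}
    inverted: dict[str, tuple[int, int]] = {}
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for chrom, order in sorted(orders_a.items()):
        ids_b = [f"P_{g}" for g in order]
        n = len(ids_b)
        if n >= 6:
            lo, hi = n // 3, 2 * n // 3
            ids_b[lo:hi] = ids_b[lo:hi][::-1]
            inverted[chrom] = (lo, hi)
        orders_b[f"{chrom}_b"] = ids_b
        for g in order:
            seq = list(proteins[g])
            for i in range(len(seq)):
                if rng.random() < 0.02:
                    seq[i] = aas[int(rng.integers(len(aas)))]
            partner[f"P_{g}"] = "".join(seq)
    return partner, orders_b, inverted
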