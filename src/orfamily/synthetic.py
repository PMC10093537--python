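"""Synthetic genomes with planted olfactory-receptor gene families.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-chromosome genome carrying OR-like genes in tandem clusters
(inter-gene distance far below 1 Mb, clusters and singletons separated by
well over 1 Mb), with planted intact genes (>= 250 codons, seven hydrophobic
transmembrane blocks, canonical motifs), truncated genes (start and/or stop
codon removed), pseudogenes (premature stop or 1-2 nt frameshift), duplicate
pairs with controlled synonymous / non-synonymous divergence, and an
overdispersed 3-tissue x hypoxia-stage expression design with planted
fold-changes.  Every random draw flows from the config seed, so identical
seeds give byte-identical FASTA/GFF3/TSV outputs.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp, stage_rng
from .codons import (AA_TO_CODONS, CODON_TABLE, STOP_CODONS, translate_cds,
                     synonymous_neighbors, nonsynonymous_neighbors)
from .fileio import GffGene, write_fasta, write_gff3, write_tsv
from .genemodels import predict_tm_segments
from Bio.SeqUtils.ProtParamData import kd as _KD

log = logging.getLogger(__name__)

GROUPS = ("beta", "gamma", "delta", "epsilon", "zeta", "eta")
TYPE_II_GROUPS = frozenset({"eta"})

TISSUES = ("gill", "heart", "liver")
CONDITIONS = ("control", "hypoxia", "reoxygenation")

# hydrophobic alphabet for TM blocks and strongly polar alphabet for loops:
# keeps Kyte-Doolittle window means well separated around the 1.6 threshold
# (worst-case all-Ala block mean 1.8 still clears it; loops average -3.7 so
# boundary windows fall below it within a few residues)
_HYDRO = "LVFMA"
_POLAR = "DENQKR"

#: hydropathy classes for class-preserving non-synonymous mutations: keeps
#: duplicated copies' TM blocks hydrophobic and their loops strongly polar
_HYDRO_CLASS = frozenset("ACFILMV")
_STRONG_POLAR = frozenset("DENQKRH")


def _aa_class(aa: str) -> int:
    if aa in _HYDRO_CLASS:
        return 0
    if aa in _STRONG_POLAR:
        return 1
    return 2


class InvalidConfigError(ValueError):
    pass


def _default_dup_events() -> list[tuple[int, float, float]]:
    """Default duplication history: mostly purifying pairs (Ka/Ks ~ 0.3-0.5)
    with a minority under positive selection, echoing the published pattern."""
    events: list[tuple[int, float, float]] = []
    purifying = [(0.30, 0.12), (0.25, 0.10), (0.35, 0.12), (0.28, 0.09),
                 (0.32, 0.14), (0.26, 0.11), (0.30, 0.10), (0.34, 0.13),
                 (0.24, 0.08), (0.29, 0.12), (0.31, 0.11), (0.27, 0.13),
                 (0.33, 0.10), (0.25, 0.12), (0.30, 0.14)]
    positive = [(0.10, 0.25), (0.12, 0.28), (0.08, 0.22)]
    for i, (ks, ka) in enumerate(purifying + positive):
        events.append((i, ks, ka))
    return events


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the package's standard study
    conditions (60/15/5 genes on 4 chromosomes, 7 tandem clusters)."""

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    n_intact: int = 60
    n_truncated: int = 15
    n_pseudo: int = 5
    n_clusters: int = 7
    cluster_span: int = 400_000
    multi_exon_fraction: float = 0.2
    dup_events: list = field(default_factory=_default_dup_events)
    de_fraction: float = 0.44
    groups: tuple = ("beta", "delta", "epsilon", "zeta", "eta")
    # expression design
    n_replicates: int = 3
    dispersion: float = 0.1
    de_fold: float = 4.0
    n_background_genes: int = 200   # stable non-OR transcriptome component
                                    # so library totals do not track OR DE
    # geometry
    singleton_gap: int = 1_500_000      # > 1 Mb so singletons never co-cluster
    min_codons: int = 250
    max_codons: int = 340

    def validate(self) -> None:
        if self.n_intact < 1:
            raise InvalidConfigError("n_intact must be >= 1")
        if len(self.dup_events) >= self.n_intact:
            raise InvalidConfigError("more duplicate children than intact genes")
        n_founders = self.n_intact - len(self.dup_events)
        for parent, ks, ka in self.dup_events:
            if not (0 <= ks < 0.7 and 0 <= ka < 0.7):
                raise InvalidConfigError("dup_events rates must lie in [0, 0.7)")
            if not (0 <= parent < n_founders):
                raise InvalidConfigError(f"dup parent index {parent} out of range")
        if self.cluster_span >= self.chrom_length:
            raise InvalidConfigError("cluster_span must be smaller than chrom_length")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise InvalidConfigError(f"unknown group labels: {sorted(unknown)}")
        if not (0 <= self.de_fraction <= 1 and 0 <= self.multi_exon_fraction <= 1):
            raise InvalidConfigError("fractions must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one planted gene."""

    gene_id: str
    category: str                  # intact | truncated | pseudogene
    group: str
    chromosome: str
    start: int                     # 0-based half-open genomic span
    end: int
    strand: str
    n_exons: int
    tm_count: int
    cluster_id: str | None
    parent_id: str | None
    planted_de: dict = field(default_factory=dict)   # tissue -> bool


# --------------------------------------------------------------- templates

def _group_rng(group: str) -> np.random.Generator:
    h = hashlib.sha256(f"orfamily-group:{group}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def _pick(rng, letters: str) -> str:
    return letters[int(rng.integers(len(letters)))]


def _group_architecture(group: str) -> list[tuple[str, str]]:
    """Ancestral segment list for one group: (segment kind, residues).

    Kinds: 'tm' (hydrophobic block), 'linker' (polar), 'motif' (fixed).
    Type II groups (eta) omit the motif-5 cysteine context; all groups carry
    motifs 1-4 at their canonical positions.
    """
    rng = _group_rng(group)

    def tm(n=19):
        return ("tm", "".join(_pick(rng, _HYDRO) for _ in range(n)))

    def linker(n):
        return ("linker", "".join(_pick(rng, _POLAR) for _ in range(n)))

    motif2 = "N" + _pick(rng, _POLAR) + _pick(rng, "TS") + _pick(rng, _POLAR)
    motif1 = "MA" + _pick(rng, "FY") + _pick(rng, "DE") + "RYVAIC"
    motif5 = _pick(rng, "ST") + "C" + _pick(rng, "ST")
    motif4 = "KAFSTC" + _pick(rng, "VIA") + "SH"
    motif3 = "PMLNPFIY"

    arch: list[tuple[str, str]] = [("motif", "M")]     # start codon residue
    arch += [linker(5), ("motif", motif2), linker(5)]  # N-terminus, glycosylation
    arch += [tm(), linker(14), tm(), linker(14), tm()]
    arch += [linker(4), ("motif", motif1), linker(4)]  # ICL2: MAYDRYVAIC-like
    arch += [tm()]
    if group in TYPE_II_GROUPS:
        arch += [linker(13)]                           # type II lacks motif 5
    else:
        arch += [linker(5), ("motif", motif5), linker(5)]
    arch += [tm(), linker(4), ("motif", motif4), linker(4), tm(), linker(14), tm()]
    arch += [linker(3), ("motif", motif3), linker(1)]  # C-terminus
    return arch


def _architecture_length(arch) -> int:
    return sum(len(seg) for _, seg in arch)


def back_translate(protein: str, rng) -> str:
    """CDS for a protein, codons drawn uniformly among synonymous choices,
    with a uniformly chosen stop codon appended."""
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
            continue
        choices = AA_TO_CODONS[aa]
        codons.append(choices[int(rng.integers(len(choices)))])
    stops = sorted(STOP_CODONS)
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


#: per-branch divergence of every group member from its group ancestor;
#: pairwise, two founders then sit just below the 75%-identity duplicate
#: screen while staying well inside one phylogenetic group
FOUNDER_KS = 0.35
FOUNDER_KA = 0.12

from functools import lru_cache


@lru_cache(maxsize=16)
def _group_ancestor(group: str):
    """Ancestral codon sequence and padding pools for one group.

    Returns (body codons incl leading ATG, nt-pad codons, ct-pad codons,
    stop codon, motif base-positions)."""
    arch = _group_architecture(group)
    rng = _group_rng(group + ":codons")
    body_protein = "".join(seg for _, seg in arch)
    motif_pos = set()
    offset = 0
    for kind, seg in arch:
        if kind == "motif":
            motif_pos.update(range(offset, offset + len(seg)))
        offset += len(seg)
    pad_rng = _group_rng(group + ":pad")
    nt_pool = "".join(_pick(pad_rng, _POLAR) for _ in range(200))
    ct_pool = "".join(_pick(pad_rng, _POLAR) for _ in range(200))

    def codons_for(protein: str) -> list[str]:
        return [AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))]
                if not (aa == "M") else "ATG" for aa in protein]

    body_codons = codons_for(body_protein)
    nt_codons = codons_for(nt_pool)
    ct_codons = codons_for(ct_pool)
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    return body_codons, nt_codons, ct_codons, stop, frozenset(motif_pos)


def make_or_template(group: str, n_codons: int, rng, max_tries: int = 100,
                     founder_ks: float = FOUNDER_KS,
                     founder_ka: float = FOUNDER_KA) -> tuple[str, str]:
    """Generate one OR-like (protein, CDS) pair for a phylogenetic group.

    Every member descends from the group's ancestral CDS (seven hydrophobic
    19-residue blocks separated by polar linkers, canonical motifs embedded)
    by synonymous/non-synonymous substitutions at per-branch rates, so group
    members share codon-level ancestry and within-group pairs have realistic,
    unsaturated nucleotide divergence.  Motif codons are restored after
    mutation and candidates are resampled until the hydropathy predictor
    confirms >= 7 TM segments, so the planted structure is true under the
    package's own predictor.  The CDS starts with ATG, ends with one stop
    codon and has no internal stops.
    """
    if n_codons < 250:
        raise InvalidConfigError("n_codons must be >= 250 for an intact OR template")
    body_codons, nt_codons, ct_codons, stop, motif_pos = _group_ancestor(group)
    base_len = len(body_codons)
    if n_codons < base_len:
        raise InvalidConfigError(
            f"n_codons {n_codons} below architecture length {base_len}")
    extra = n_codons - base_len
    npl, cpl = extra // 2, extra - extra // 2
    codons0 = ([body_codons[0]] + nt_codons[:npl] + body_codons[1:]
               + ct_codons[:cpl] + [stop])
    anc_cds = "".join(codons0)
    # motif positions after inserting the N-terminal pad (position 0 is M)
    abs_motifs = {p + npl if p > 0 else p for p in motif_pos}

    for _ in range(max_tries):
        cds = mutate_duplicate(anc_cds, founder_ks, founder_ka, rng)
        chars = list(cds)
        for p in abs_motifs:          # motifs stay intact in every member
            chars[3 * p:3 * p + 3] = codons0[p]
        cds = "".join(chars)
        protein = translate_cds(cds)
        if len(predict_tm_segments(protein)) >= 7:
            return protein, cds
    raise RuntimeError(f"could not realize a 7-TM template for group {group}")


# ----------------------------------------------------------------- degrade

def degrade(cds: str, mode: str, rng) -> tuple[str, dict]:
    """Derive a pseudogene or truncated variant from an intact CDS.

    pseudogenize: insert a premature stop codon OR a 1-2 nt frameshift at a
    recorded position.  truncate: remove the start codon and/or the terminal
    stop codon without any internal disruption.  Returns (variant, info).
    """
    if mode == "pseudogenize":
        n_codons = len(cds) // 3
        if rng.random() < 0.5:
            idx = int(rng.integers(5, n_codons - 5))
            stop = sorted(STOP_CODONS)[int(rng.integers(3))]
            variant = cds[: 3 * idx] + stop + cds[3 * idx + 3:]
            return variant, {"kind": "premature_stop", "position": 3 * idx}
        pos = int(rng.integers(15, len(cds) - 15))
        if rng.random() < 0.5:
            k = int(rng.integers(1, 3))
            ins = "".join(_pick(rng, "ACGT") for _ in range(k))
            variant = cds[:pos] + ins + cds[pos:]
            return variant, {"kind": "frameshift", "position": pos, "indel": +k}
        variant = cds[:pos] + cds[pos + 1:]
        return variant, {"kind": "frameshift", "position": pos, "indel": -1}

    if mode == "truncate":
        what = ("start", "stop", "both")[int(rng.integers(3))]
        variant = cds
        if what in ("start", "both"):
            variant = "CTG" + variant[3:]             # ATG -> Leu, no start
        if what in ("stop", "both"):
            sense = AA_TO_CODONS["Y"][0]              # terminal stop -> Tyr
            variant = variant[:-3] + sense
        return variant, {"kind": "truncate", "removed": what}

    raise ValueError(f"unknown degrade mode: {mode!r}")


# --------------------------------------------------------- duplicate mutator

def mutate_duplicate(cds: str, syn_rate: float, nonsyn_rate: float, rng) -> str:
    """Place substitutions on a copy of a CDS so that its realized per-site
    synonymous and non-synonymous divergence matches the requested rates.

    Each event resamples one codon among its single-nucleotide synonymous (or
    non-synonymous, stop-avoiding) neighbors; multiple hits on one codon are
    allowed.  Because multiple hits and mixed-pathway codons erode observed
    differences, events are added until the NG86-counted difference
    proportions reach the Jukes-Cantor-inverted targets
    p* = (3/4)(1 - exp(-4 rate / 3)), so the downstream JC correction
    recovers the planted rates.  Non-synonymous replacements prefer the
    residue's own hydropathy class (TM blocks stay hydrophobic, loops stay
    polar) and avoid revisiting the parent's amino acid.  Length preserved;
    the start codon and terminal stop are never touched.
    """
    if not (0 <= syn_rate < 0.7 and 0 <= nonsyn_rate < 0.7):
        raise InvalidConfigError("mutation rates must lie in [0, 0.7)")
    from .evolution import _codon_site_split, _pathway_diffs

    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    originals = list(codons)
    body = [i for i in range(1, len(codons) - 1) if CODON_TABLE[codons[i]] != "*"]

    ps_target = 0.75 * (1.0 - math.exp(-4.0 * syn_rate / 3.0))
    pn_target = 0.75 * (1.0 - math.exp(-4.0 * nonsyn_rate / 3.0))

    # running NG86 pair state, updated incrementally as codons change;
    # site totals cover every codon the estimator will compare (the start
    # codon contributes sites even though it is never mutated)
    counted = [i for i in range(len(codons) - 1) if CODON_TABLE[codons[i]] != "*"]
    s_par = n_par = 0.0
    per_codon: dict[int, tuple[float, float, float, float]] = {}
    s_chi = n_chi = sd_tot = nd_tot = 0.0
    for i in counted:
        sp, np_ = _codon_site_split(originals[i])
        s_par += sp; n_par += np_
        per_codon[i] = (sp, np_, 0.0, 0.0)
        s_chi += sp; n_chi += np_

    def set_codon(idx: int, new: str) -> None:
        nonlocal s_chi, n_chi, sd_tot, nd_tot
        sc_old, nc_old, sd_old, nd_old = per_codon[idx]
        codons[idx] = new
        sc, nc = _codon_site_split(new)
        dsd, dnd = _pathway_diffs(originals[idx], new)
        per_codon[idx] = (sc, nc, dsd, dnd)
        s_chi += sc - sc_old; n_chi += nc - nc_old
        sd_tot += dsd - sd_old; nd_tot += dnd - nd_old

    def pair_state():
        return (s_par + s_chi) / 2, (n_par + n_chi) / 2, sd_tot, nd_tot

    def nonsyn_choices(idx: int) -> list[str]:
        codon = codons[idx]
        options = nonsynonymous_neighbors(codon)
        parent_aa = CODON_TABLE[originals[idx]]
        cls = _aa_class(CODON_TABLE[codon])

        def ok(c: str) -> bool:
            aa = CODON_TABLE[c]
            # stay in class; in TM blocks also cap hydropathy (no I/V creep
            # that would bridge loops in the window predictor)
            return _aa_class(aa) == cls and (cls != 0 or _KD[aa] <= 3.85)

        fresh = [c for c in options if CODON_TABLE[c] != parent_aa]
        for tier in ([c for c in fresh if ok(c)],
                     [c for c in options if ok(c)],
                     fresh, options):
            if tier:
                return tier
        return []

    def syn_choices(idx: int) -> list[str]:
        options = synonymous_neighbors(codons[idx])
        forward = [c for c in options if c != originals[idx]]
        return forward or options

    def current(which: str) -> float:
        s_sites, n_sites, sd, nd = pair_state()
        if which == "syn":
            return sd / s_sites if s_sites else 0.0
        return nd / n_sites if n_sites else 0.0

    def candidates(idx: int, which: str, above: bool) -> list[str]:
        if which == "syn":
            if above:
                return synonymous_neighbors(codons[idx])   # reverts allowed
            return syn_choices(idx)
        if above:                                          # walk back toward parent
            options = nonsynonymous_neighbors(codons[idx])
            parent_aa = CODON_TABLE[originals[idx]]
            back = [c for c in options if CODON_TABLE[c] == parent_aa]
            return back or options
        return nonsyn_choices(idx)

    def fill(p_target: float, which: str) -> None:
        if p_target <= 0:
            return
        guard = 0
        limit = 40 * len(body) + 200
        sites_idx = 0 if which == "syn" else 1
        # dither the target by up to half an event step so the discrete
        # stopping grid is centred on the requested proportion
        dither = None
        while guard < limit:
            guard += 1
            state = pair_state()
            step = 1.0 / max(state[sites_idx], 1.0)
            if dither is None:
                dither = (rng.random() - 0.5) * step
                p_target = p_target + dither
            cur = current(which)
            if abs(cur - p_target) <= 0.5 * step:          # converged
                return
            idx = body[int(rng.integers(len(body)))]
            options = candidates(idx, which, cur > p_target)
            if not options:
                continue
            old = codons[idx]
            set_codon(idx, options[int(rng.integers(len(options)))])
            # revert events that move realized divergence away from the target
            if abs(current(which) - p_target) >= abs(cur - p_target):
                set_codon(idx, old)

    # alternating fills: each phase shifts the other's pathway attribution
    # slightly, so both proportions are re-trimmed before finishing
    for _ in range(2):
        fill(pn_target, "nonsyn")
        fill(ps_target, "syn")
    fill(pn_target, "nonsyn")
    return "".join(codons)


# ------------------------------------------------------------ gene assembly

def _make_introns(cds: str, n_exons: int, rng) -> tuple[str, list[tuple[int, int]]]:
    """Split a CDS into n_exons with canonical GT..AG introns (80-2000 nt).

    Returns (genomic gene sequence in CDS orientation, exon spans relative to
    the gene sequence)."""
    if n_exons < 2:
        return cds, [(0, len(cds))]
    cuts = sorted(rng.choice(np.arange(1, len(cds) // 3), size=n_exons - 1,
                             replace=False) * 3)
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(cds[prev:c])
        prev = c
    pieces.append(cds[prev:])
    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    offset = 0
    for i, piece in enumerate(pieces):
        exons.append((offset, offset + len(piece)))
        seq_parts.append(piece)
        offset += len(piece)
        if i < len(pieces) - 1:
            ilen = int(rng.integers(80, 2001))
            intron = "GT" + "".join(_pick(rng, "ACGT") for _ in range(ilen - 4)) + "AG"
            seq_parts.append(intron)
            offset += ilen
    return "".join(seq_parts), exons


@dataclass
class SynthDataset:
    """In-memory result of build_dataset, with writers for every artifact."""

    config: SynthConfig
    genome: dict
    truth: list
    gff_genes: list
    cds: dict                 # gene_id -> planted CDS (spliced, gene orientation)
    proteins: dict            # gene_id -> planted protein (intact genes)
    queries: dict             # query_id -> protein
    references: dict          # ref_id -> protein
    reference_labels: dict    # ref_id -> group
    counts: pd.DataFrame      # genes x samples
    lengths: pd.Series        # transcript length per expressed gene
    sample_sheet: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {k: v for k, v in asdict(t).items() if k != "planted_de"}
            for tissue in TISSUES:
                row[f"de_{tissue}"] = bool(t.planted_de.get(tissue, False))
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "annotation": outdir / "truth.gff3",
            "truth": outdir / "truth.tsv",
            "queries": outdir / "queries.fasta",
            "references": outdir / "references.fasta",
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "config": outdir / "config.yaml",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.gff_genes, paths["annotation"])
        write_tsv(self.truth_frame(), paths["truth"])
        write_fasta(self.queries, paths["queries"])
        write_fasta(self.references, paths["references"])
        counts = self.counts.copy()
        counts.insert(0, "length", self.lengths)
        counts.index.name = "gene"
        write_tsv(counts.reset_index(), paths["counts"])
        write_tsv(self.sample_sheet, paths["samples"])
        cfg = asdict(self.config)
        cfg["groups"] = list(cfg["groups"])
        cfg["dup_events"] = [list(e) for e in cfg["dup_events"]]
        paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
        return paths


def build_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Generate the full synthetic study: genome, truth annotation, query and
    reference proteins, and the hypoxia expression count matrix."""
    config = config or SynthConfig()
    config.validate()
    rng = stage_rng(config.seed, "genome")

    groups = list(config.groups)
    n_children = len(config.dup_events)
    n_founders = config.n_intact - n_children

    # ---- gene specifications ------------------------------------------
    specs: list[dict] = []     # placement order; children directly after parent
    founders: list[dict] = []
    for i in range(n_founders):
        founders.append({
            "category": "intact",
            "group": groups[i % len(groups)],
            "n_codons": int(rng.integers(config.min_codons, config.max_codons + 1)),
            "children": [],
        })
    for parent_idx, ks, ka in config.dup_events:
        founders[parent_idx]["children"].append((ks, ka))
    for f in founders:
        specs.append(f)
        for ks, ka in f["children"]:
            specs.append({"category": "intact", "group": f["group"],
                          "parent_spec": f, "rates": (ks, ka)})
    for j in range(config.n_truncated):
        specs.append({"category": "truncated", "group": groups[j % len(groups)],
                      "n_codons": int(rng.integers(config.min_codons,
                                                   config.max_codons + 1))})
    for j in range(config.n_pseudo):
        specs.append({"category": "pseudogene", "group": groups[j % len(groups)],
                      "n_codons": int(rng.integers(config.min_codons,
                                                   config.max_codons + 1))})

    # ---- sequences ----------------------------------------------------
    for idx, spec in enumerate(specs):
        spec["gene_id"] = f"SSOR{idx + 1:04d}"
    for spec in specs:
        if "parent_spec" in spec:
            continue
        protein, cds = make_or_template(spec["group"], spec["n_codons"], rng)
        spec["protein"], spec["cds"] = protein, cds
        spec["tm_count"] = len(predict_tm_segments(protein))
    for spec in specs:
        if "parent_spec" in spec:
            parent = spec["parent_spec"]
            ks, ka = spec["rates"]
            for _ in range(50):   # child must stay a 7-TM intact gene
                cds_child = mutate_duplicate(parent["cds"], ks, ka, rng)
                prot_child = translate_cds(cds_child)
                tm_child = len(predict_tm_segments(prot_child))
                if tm_child >= 7:
                    break
            else:
                raise RuntimeError("duplicate child lost its 7-TM architecture")
            spec["cds"], spec["protein"] = cds_child, prot_child
            spec["tm_count"] = tm_child
            spec["parent_id"] = parent["gene_id"]
    for spec in specs:
        if spec["category"] == "truncated":
            spec["cds"], spec["info"] = degrade(spec["cds"], "truncate", rng)
        elif spec["category"] == "pseudogene":
            spec["cds"], spec["info"] = degrade(spec["cds"], "pseudogenize", rng)

    # ---- exon structure ----------------------------------------------
    for spec in specs:
        multi = (spec["category"] != "pseudogene"
                 and rng.random() < config.multi_exon_fraction)
        n_exons = int(rng.integers(2, 6)) if multi else 1
        spec["gene_seq"], spec["rel_exons"] = _make_introns(spec["cds"], n_exons, rng)
        spec["strand"] = "+" if rng.random() < 0.5 else "-"

    # ---- placement -----------------------------------------------------
    n_genes = len(specs)
    n_singletons = min(2 * config.n_chromosomes,
                       max(0, n_genes - 2 * config.n_clusters))
    n_clustered = n_genes - n_singletons
    if n_clustered < 2 * config.n_clusters:
        raise InvalidConfigError("not enough genes to fill every cluster with 2 members")

    sizes = [n_clustered // config.n_clusters] * config.n_clusters
    for i in range(n_clustered % config.n_clusters):
        sizes[i] += 1
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 100_000 for c in chrom_names}

    def place(spec, chrom, at):
        glen = len(spec["gene_seq"])
        spec["chrom"], spec["start"], spec["end"] = chrom, at, at + glen
        return at + glen

    pos = 0
    for ci, size in enumerate(sizes):
        chrom = chrom_names[ci % config.n_chromosomes]
        at = cursors[chrom]
        first = at
        for k in range(size):
            spec = specs[pos]
            spec["cluster_id"] = f"cluster{ci + 1}"
            end = place(spec, chrom, at)
            at = end + int(rng.integers(5_000, 30_000))
            pos += 1
        if at - first > config.cluster_span:
            log.warning("cluster %d span %d exceeds configured cluster_span",
                        ci + 1, at - first)
        cursors[chrom] = at + config.singleton_gap
    for k in range(n_singletons):
        spec = specs[pos]
        chrom = chrom_names[k % config.n_chromosomes]
        spec["cluster_id"] = None
        end = place(spec, chrom, cursors[chrom])
        cursors[chrom] = end + config.singleton_gap
        pos += 1
    for chrom, cur in cursors.items():
        if cur - config.singleton_gap > config.chrom_length:
            raise InvalidConfigError(
                f"geometry infeasible: {chrom} needs {cur - config.singleton_gap} bases "
                f"but chrom_length is {config.chrom_length}")

    # ---- assemble chromosomes -----------------------------------------
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    genome: dict[str, str] = {}
    for chrom in chrom_names:
        arr = base_arr[rng.integers(0, 4, size=config.chrom_length)]
        for spec in specs:
            if spec["chrom"] != chrom:
                continue
            seq = spec["gene_seq"]
            if spec["strand"] == "-":
                seq = revcomp(seq)
            arr[spec["start"]:spec["end"]] = np.frombuffer(seq.encode(), dtype="S1")
        genome[chrom] = arr.tobytes().decode()

    # ---- truth + annotation --------------------------------------------
    truth: list[TruthRecord] = []
    gff_genes: list[GffGene] = []
    cds_map: dict[str, str] = {}
    protein_map: dict[str, str] = {}
    for spec in specs:
        start, end, strand = spec["start"], spec["end"], spec["strand"]
        glen = end - start
        if strand == "+":
            exons = [(start + s, start + e) for s, e in spec["rel_exons"]]
        else:
            exons = sorted((end - e, end - s) for s, e in spec["rel_exons"])
        truth.append(TruthRecord(
            gene_id=spec["gene_id"], category=spec["category"],
            group=spec["group"], chromosome=spec["chrom"],
            start=start, end=end, strand=strand,
            n_exons=len(exons), tm_count=spec["tm_count"],
            cluster_id=spec["cluster_id"], parent_id=spec.get("parent_id"),
        ))
        attrs = {"category": spec["category"], "group": spec["group"]}
        if spec["cluster_id"]:
            attrs["cluster"] = spec["cluster_id"]
        if spec.get("parent_id"):
            attrs["parent"] = spec["parent_id"]
        gff_genes.append(GffGene(spec["gene_id"], spec["chrom"], start, end,
                                 strand, exons, attrs))
        cds_map[spec["gene_id"]] = spec["cds"]
        protein_map[spec["gene_id"]] = spec.get("protein", "")

    # ---- queries and labeled references ---------------------------------
    qrng = stage_rng(config.seed, "queries")
    queries: dict[str, str] = {}
    references: dict[str, str] = {}
    reference_labels: dict[str, str] = {}
    for group in groups:
        for qi in range(2):
            p, _ = make_or_template(group, 300, qrng)
            queries[f"QRY_{group}_{qi + 1}"] = p
        for ri in range(3):
            p, _ = make_or_template(group, 300, qrng)
            rid = f"REF_{group}_{ri + 1}"
            references[rid] = p
            reference_labels[rid] = group

    # ---- expression counts ----------------------------------------------
    counts, lengths, sample_sheet = _expression_counts(config, specs, truth)

    return SynthDataset(config, genome, truth, gff_genes, cds_map, protein_map,
                        queries, references, reference_labels,
                        counts, lengths, sample_sheet)


def _expression_counts(config: SynthConfig, specs, truth):
    """Negative-binomial counts for classified (intact + truncated) genes over
    3 tissues x (control, hypoxia, reoxygenation) x replicates, with planted
    fold-changes for DE genes (up and down balanced)."""
    rng = stage_rng(config.seed, "expression")
    expressed = [s for s in specs if s["category"] in ("intact", "truncated")]
    gene_ids = [s["gene_id"] for s in expressed]
    lengths = pd.Series({s["gene_id"]: len(s["cds"]) for s in expressed})
    truth_by_id = {t.gene_id: t for t in truth}

    n_de = int(round(config.de_fraction * len(expressed)))
    de_idx = rng.choice(len(expressed), size=n_de, replace=False)
    plans: dict[str, dict] = {}
    for rank, gi in enumerate(sorted(de_idx)):
        gid = gene_ids[gi]
        tissue = TISSUES[int(rng.integers(len(TISSUES)))]
        direction = 1 if rank % 2 == 0 else -1          # balance up/down
        conds = (["hypoxia", "reoxygenation"] if rng.random() < 0.5
                 else [CONDITIONS[1 + int(rng.integers(2))]])
        plans[gid] = {"tissue": tissue, "direction": direction, "conditions": conds}
        truth_by_id[gid].planted_de = {t: (t == tissue) for t in TISSUES}
    for t in truth:
        if not t.planted_de:
            t.planted_de = {tis: False for tis in TISSUES}

    n_bg = config.n_background_genes
    bg_ids = [f"BG{i + 1:04d}" for i in range(n_bg)]
    bg_lengths = pd.Series(rng.integers(600, 3000, size=n_bg), index=bg_ids)
    lengths = pd.concat([lengths, bg_lengths])

    base = rng.lognormal(mean=math.log(300.0), sigma=0.7, size=len(expressed))
    bg_base = rng.lognormal(mean=math.log(400.0), sigma=0.9, size=n_bg)
    samples = []
    nb_n = 1.0 / config.dispersion
    data = {}
    for tissue in TISSUES:
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                name = f"{tissue}_{cond}_r{rep}"
                samples.append({"sample": name, "tissue": tissue,
                                "condition": cond, "replicate": rep})
                depth = rng.uniform(0.8, 1.2)
                mu = base.copy()
                for gi, gid in enumerate(gene_ids):
                    plan = plans.get(gid)
                    if plan and plan["tissue"] == tissue and cond in plan["conditions"]:
                        mu[gi] = (mu[gi] * config.de_fold if plan["direction"] > 0
                                  else mu[gi] / config.de_fold)
                mu = np.concatenate([mu, bg_base]) * depth
                col = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
                data[name] = col
    counts = pd.DataFrame(data, index=gene_ids + bg_ids)
    sample_sheet = pd.DataFrame(samples)
    return counts, lengths, sample_sheet
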