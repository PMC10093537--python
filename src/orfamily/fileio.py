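"""File-format plumbing: FASTA, GFF3 and TSV readers/writers.

Coordinates are 0-based half-open in memory and 1-based closed on disk
(GFF3 convention).  FASTA goes through Biopython's SeqIO; tables through
pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3

@dataclass
class GffGene:
    """One gene feature with its exon children."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open span of the whole gene
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def spliced_cds(self, genome: dict[str, str]) -> str:
        """Concatenate exon sequence in genomic order; reverse-complement on minus."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s:e] for s, e in sorted(self.exons)]
        cds = "".join(parts)
        return revcomp(cds) if self.strand == "-" else cds


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) or "."


def _parse_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_gff3(genes: Iterable[GffGene], path, source: str = "orfamily") -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = {"ID": g.gene_id, **g.attributes}
        lines.append(
            "\t".join(
                [g.chrom, source, "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", _fmt_attrs(attrs)]
            )
        )
        for i, (s, e) in enumerate(sorted(g.exons), 1):
            ex_attrs = {"ID": f"{g.gene_id}.exon{i}", "Parent": g.gene_id}
            lines.append(
                "\t".join(
                    [g.chrom, source, "exon", str(s + 1), str(e), ".",
                     g.strand, ".", _fmt_attrs(ex_attrs)]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GffGene]:
    genes: list[GffGene] = []
    by_id: dict[str, GffGene] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
        attrs = _parse_attrs(attr_text)
        if ftype == "gene":
            g = GffGene(
                gene_id=attrs.pop("ID"),
                chrom=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                attributes=attrs,
            )
            genes.append(g)
            by_id[g.gene_id] = g
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent in by_id:
                by_id[parent].exons.append((int(start) - 1, int(end)))
    for g in genes:
        g.exons.sort()
    return genes


# ---------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
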