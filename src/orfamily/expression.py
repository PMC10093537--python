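"""FPKM expression, hypoxia fold changes and differential-expression flags.

FPKM = count x 1e9 / (library total x transcript length).  Per tissue, each
hypoxia/re-oxygenation condition is compared against that tissue's control:
log2((FPKM + pseudo) / (control FPKM + pseudo)), replicates averaged within
a condition first.  A gene is flagged differentially expressed when
|log2FC| >= threshold in at least one non-control condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import format_percent

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Counts (genes x samples) with transcript lengths and sample labels."""

    counts: pd.DataFrame           # integer counts, index = gene ids
    lengths: pd.Series             # bases, index = gene ids
    samples: pd.DataFrame          # columns: sample, tissue, condition[, replicate]

    def __post_init__(self):
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.samples["sample"]) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples missing from count matrix: {sorted(missing)}")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments."""
    totals = counts.sum(axis=0) if totals is None else totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library total in sample(s): {list(zero.index)}")
    return counts * 1e9 / (totals.to_numpy()[None, :] *
                           lengths.to_numpy()[:, None])


def condition_means(fpkm_df: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average FPKM over replicates; columns become (tissue, condition)."""
    groups = samples.groupby(["tissue", "condition"])["sample"].apply(list)
    out = {}
    for (tissue, cond), cols in groups.items():
        out[(tissue, cond)] = fpkm_df[cols].mean(axis=1)
    result = pd.DataFrame(out)
    result.columns = pd.MultiIndex.from_tuples(result.columns,
                                               names=["tissue", "condition"])
    return result


def log2fc(fpkm_df: pd.DataFrame, samples: pd.DataFrame,
           control_condition: str = "control", pseudo: float = 1.0,
           ) -> pd.DataFrame:
    """log2 fold change of every non-control condition against its tissue's
    control, with a pseudo-count guarding small values."""
    means = condition_means(fpkm_df, samples)
    tissues = means.columns.get_level_values("tissue").unique()
    out = {}
    for tissue in tissues:
        sub = means[tissue]
        if control_condition not in sub.columns:
            raise ValueError(f"tissue {tissue!r} has no {control_condition!r} sample")
        ctrl = sub[control_condition]
        for cond in sub.columns:
            if cond == control_condition:
                continue
            out[(tissue, cond)] = np.log2((sub[cond] + pseudo) / (ctrl + pseudo))
    result = pd.DataFrame(out)
    result.columns = pd.MultiIndex.from_tuples(result.columns,
                                               names=["tissue", "condition"])
    return result


@dataclass
class DeSummary:
    table: pd.DataFrame            # gene, tissue, condition, log2fc, de_flag
    n_genes: int
    n_de: int
    pct_de: str                    # two-decimal style, as printed in reports
    per_tissue: dict


def de_flags(fc: pd.DataFrame, threshold: float = 1.0) -> DeSummary:
    """Flag genes with |log2FC| >= threshold in >= 1 non-control condition."""
    rows = []
    for gene in fc.index:
        for (tissue, cond) in fc.columns:
            val = float(fc.loc[gene, (tissue, cond)])
            rows.append({"gene": gene, "tissue": tissue, "condition": cond,
                         "log2fc": val, "de_flag": abs(val) >= threshold})
    table = pd.DataFrame(rows)
    by_gene = table.groupby("gene")["de_flag"].any()
    per_tissue = {
        tissue: int(sub.groupby("gene")["de_flag"].any().sum())
        for tissue, sub in table.groupby("tissue")
    }
    n_genes = len(by_gene)
    n_de = int(by_gene.sum())
    return DeSummary(table=table, n_genes=n_genes, n_de=n_de,
                     pct_de=format_percent(n_de, n_genes, "two_decimal"),
                     per_tissue=per_tissue)


def de_gene_flags(summary: DeSummary) -> pd.Series:
    """Per-gene overall DE flag."""
    return summary.table.groupby("gene")["de_flag"].any()


def de_tissue_flags(summary: DeSummary) -> pd.DataFrame:
    """Per-gene, per-tissue DE flag matrix."""
    return (summary.table.groupby(["gene", "tissue"])["de_flag"].any()
            .unstack("tissue"))
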