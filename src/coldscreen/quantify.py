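"""RPKM quantification, gene-level aggregation, fold changes and expression filters.

Expression is measured in RPKM (reads per kilobase of transcript per million
mapped reads): ``RPKM = 1e9 * c / (N * L)`` for ``c`` reads on a transcript of
length ``L`` nucleotides in a library of ``N`` mapped reads. A gene's
expression is the sum of its transcripts' RPKM, and its cold/control fold
change is the ratio of that sum accumulated over all cold samples to the same
sum over all control samples.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from coldscreen.model import (
    COLD,
    CONTROL,
    CountMatrix,
    DataFormatError,
    ExpressionMatrix,
    SampleSheet,
)


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcript-level RPKM from counts, lengths and library sizes.

    Library sizes come from the sample sheet when declared, otherwise from the
    column sums of the count matrix. A zero library size is a fatal error for
    that sample. RPKM is zero exactly where the count is zero.
    """
    n = counts.library_sizes()
    zero = n[n == 0]
    if len(zero):
        raise DataFormatError(f"zero library size for samples: {list(zero.index)}")
    lengths = counts.annotation.lengths.loc[counts.values.index].to_numpy(dtype=np.float64)
    scale = 1e9 / (lengths[:, None] * n.to_numpy(dtype=np.float64)[None, :])
    values = pd.DataFrame(
        counts.values.to_numpy(dtype=np.float64) * scale,
        index=counts.values.index,
        columns=counts.values.columns,
    )
    return ExpressionMatrix(values=values, annotation=counts.annotation, samples=counts.samples)


@dataclasses.dataclass(frozen=True)
class GeneExpressionTable:
    """Gene x sample summed RPKM and summed read counts, with condition sums.

    ``rpkm`` and ``counts`` share the same gene index and sample columns.
    Condition sums accumulate the summed RPKM over all transcripts *and* all
    samples of a condition; with equal group sizes their ratio equals the
    ratio of per-condition means.
    """

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    samples: SampleSheet

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    def condition_sum(self, condition: str) -> pd.Series:
        ids = self.samples.table.index[self.samples.table["condition"] == condition]
        return self.rpkm[list(ids)].sum(axis=1)

    @property
    def s_control(self) -> pd.Series:
        return self.condition_sum(CONTROL)

    @property
    def s_cold(self) -> pd.Series:
        return self.condition_sum(COLD)


def build_gene_table(counts: CountMatrix, rpkm: ExpressionMatrix) -> GeneExpressionTable:
    """Aggregate transcript counts and RPKM to genes (sum over transcripts)."""
    return GeneExpressionTable(
        rpkm=rpkm.gene_rpkm(), counts=counts.gene_counts(), samples=counts.samples
    )


def gene_fold_change(s_cold: float, s_ctrl: float, pseudocount: float = 0.0) -> float:
    """Cold/control fold change of summed RPKM.

    Returns ``+inf`` when the control sum is zero but the cold sum is positive,
    and ``nan`` when both are zero (the gene is unranked). A pseudocount (in
    RPKM units, added to both sums) yields finite ratios for users who prefer
    finite ranks; the default keeps the ratio exact.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    s_cold = s_cold + pseudocount
    s_ctrl = s_ctrl + pseudocount
    if s_ctrl == 0.0:
        return math.inf if s_cold > 0.0 else math.nan
    return s_cold / s_ctrl


def fold_changes(table: GeneExpressionTable, pseudocount: float = 0.0) -> pd.Series:
    """Per-gene fold change (see :func:`gene_fold_change`), indexed by gene."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    s_cold = table.s_cold.to_numpy() + pseudocount
    s_ctrl = table.s_control.to_numpy() + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = s_cold / s_ctrl
    fc[(s_ctrl == 0.0) & (s_cold > 0.0)] = np.inf
    fc[(s_ctrl == 0.0) & (s_cold == 0.0)] = np.nan
    return pd.Series(fc, index=table.gene_ids, name="fold_change")


def expressed_filter(table: GeneExpressionTable) -> tuple[pd.Index, pd.Index]:
    """Split genes into (expressed, expressed-in-all-samples) index sets.

    A gene is *expressed* when its summed RPKM is positive in at least one
    sample, and *expressed in all samples* when positive in every sample; the
    second set is nested in the first.
    """
    positive = table.rpkm > 0
    expressed = table.gene_ids[positive.any(axis=1)]
    expressed_all = table.gene_ids[positive.all(axis=1)]
    return expressed, expressed_all


def genes_detected_per_sample(table: GeneExpressionTable) -> pd.Series:
    """Number of genes with positive summed RPKM in each individual sample."""
    return (table.rpkm > 0).sum(axis=0).rename("n_genes_detected")
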