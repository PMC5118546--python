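"""The gene-calling engine: exact tests, FDR correction, and the consistency vote.

For each gene, every cold sample is tested separately against the control
condition with a two-sided Fisher exact test on the 2x2 table

    [reads on the gene in the cold sample,  reads on all other genes in it]
    [reads on the gene in the controls,     reads on all other genes in them]

p-values are Benjamini-Hochberg corrected (by default across all expressed
genes within each cold sample's family), and a gene is called modified only if
the corrected value falls below ``alpha`` in the same direction in at least
``min_consistent`` of the cold samples with no significant change in the
opposite direction. Candidate ranking takes the top fraction of upregulated
genes by fold change.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from coldscreen.model import (
    COLD,
    CONTROL,
    DOWN,
    FLAT,
    UNCHANGED,
    UP,
    ColdscreenError,
    CountMatrix,
    GeneCall,
    SampleSheet,
    ScreenSummary,
)
from coldscreen.quantify import build_gene_table, compute_rpkm, expressed_filter, fold_changes

log = logging.getLogger("coldscreen")

BH_FAMILIES = ("per_sample_genomewide", "per_gene_across_samples")
PAIRINGS = ("vs_pooled_control", "paired_by_index")


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the screen.

    alpha
        Significance threshold on the BH-corrected p-value (default 0.05).
    min_consistent
        Minimum number of cold samples that must change significantly in the
        same direction (default 3 of 4).
    n_cold_samples
        Expected number of cold samples; checked against the sample sheet.
    bh_family
        ``per_sample_genomewide`` adjusts across all tested genes within each
        cold sample's family (the conservative genome-wide standard);
        ``per_gene_across_samples`` adjusts each gene's per-sample p-values as
        a family of ``n_cold_samples`` tests.
    pairing
        ``vs_pooled_control`` tests each cold sample against the summed
        control condition; ``paired_by_index`` pairs cold and control samples
        by their order in the sample sheet.
    top_fraction
        Fraction of upregulated genes returned by :func:`top_induced`
        (default 0.10, the top decile).
    """

    alpha: float = 0.05
    min_consistent: int = 3
    n_cold_samples: int = 4
    bh_family: str = "per_sample_genomewide"
    pairing: str = "vs_pooled_control"
    top_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ColdscreenError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 1 <= self.min_consistent <= self.n_cold_samples:
            raise ColdscreenError(
                f"min_consistent must be in [1, n_cold_samples], got {self.min_consistent}"
            )
        if self.bh_family not in BH_FAMILIES:
            raise ColdscreenError(f"bh_family must be one of {BH_FAMILIES}")
        if self.pairing not in PAIRINGS:
            raise ColdscreenError(f"pairing must be one of {PAIRINGS}")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ColdscreenError(f"top_fraction must be in (0, 1], got {self.top_fraction}")

    def to_text(self) -> str:
        """Flat ``key = value`` serialization (field order fixed)."""
        return "".join(
            f"{f.name} = {getattr(self, f.name)}\n" for f in dataclasses.fields(self)
        )

    @classmethod
    def from_text(cls, text: str) -> "CallerConfig":
        kwargs: dict = {}
        casts = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ColdscreenError(f"unknown config key {key!r}")
            if key in ("alpha", "top_fraction"):
                kwargs[key] = float(value)
            elif key in ("min_consistent", "n_cold_samples"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def fisher_gene_test(
    gene_reads_a: int, other_reads_a: int, gene_reads_b: int, other_reads_b: int
) -> float:
    """Two-sided Fisher exact p-value for a gene-vs-rest 2x2 count table.

    Uses the classical minimum-likelihood definition: the sum of hypergeometric
    point probabilities no greater than that of the observed table (with a
    small relative tolerance for floating-point ties). A table with a zero row
    or column margin carries no information and returns 1.0 by convention.
    """
    cells = (gene_reads_a, other_reads_a, gene_reads_b, other_reads_b)
    for c in cells:
        if c < 0 or c != int(c):
            raise ColdscreenError(f"contingency cells must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1. Output satisfies
    q >= p elementwise and is monotone nondecreasing along the sorted order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ColdscreenError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_direction_counts(
    per_sample_q: Sequence[float], per_sample_direction: Sequence[str], config: CallerConfig
) -> tuple[int, int]:
    """(number significant & up, number significant & down) at q < alpha."""
    if len(per_sample_q) != len(per_sample_direction):
        raise ColdscreenError("q and direction vectors differ in length")
    n_up = sum(1 for q, d in zip(per_sample_q, per_sample_direction) if q < config.alpha and d == UP)
    n_down = sum(
        1 for q, d in zip(per_sample_q, per_sample_direction) if q < config.alpha and d == DOWN
    )
    return n_up, n_down


def call_modified(
    per_sample_q: Sequence[float], per_sample_direction: Sequence[str], config: CallerConfig
) -> str:
    """The consistency vote: 'up', 'down' or 'unchanged'.

    A gene is called in a direction only when at least ``min_consistent`` cold
    samples change significantly (corrected q < alpha) in that direction and
    *no* cold sample changes significantly in the opposite direction. A 'flat'
    direction (exactly equal proportions) never counts as significant change
    in either direction.
    """
    if len(per_sample_q) != config.n_cold_samples:
        raise ColdscreenError(
            f"expected {config.n_cold_samples} per-sample entries, got {len(per_sample_q)}"
        )
    n_up, n_down = significant_direction_counts(per_sample_q, per_sample_direction, config)
    if n_up >= config.min_consistent and n_down == 0:
        return UP
    if n_down >= config.min_consistent and n_up == 0:
        return DOWN
    return UNCHANGED


def _direction(gene_a: int, total_a: int, gene_b: int, total_b: int) -> str:
    # integer cross-multiplication: exact tie detection, no float rounding
    lhs = int(gene_a) * int(total_b)
    rhs = int(gene_b) * int(total_a)
    if lhs > rhs:
        return UP
    if lhs < rhs:
        return DOWN
    return FLAT


def per_sample_tests(
    gene_reads: pd.Series,
    library_sizes: pd.Series,
    samples: SampleSheet,
    config: CallerConfig,
) -> tuple[list[float], list[str], float]:
    """Per-cold-sample Fisher tests for one gene, plus the pooled test.

    ``gene_reads`` holds the gene's summed transcript counts per sample and
    ``library_sizes`` the total mapped reads per sample (reads on all other
    genes = total - gene). Under ``vs_pooled_control`` every cold sample is
    tested against the summed control condition; under ``paired_by_index``
    cold sample k is tested against control sample k in sheet order. The
    direction compares the gene's read proportion in the cold sample with the
    control-side proportion ('flat' on exact equality). The pooled p-value
    tests summed cold against summed control counts.

    Returns (per-sample p-values, per-sample directions, pooled p), cold
    samples in sample-sheet order.
    """
    cold_ids = samples.cold_ids
    ctrl_ids = samples.control_ids
    if config.pairing == "paired_by_index" and len(cold_ids) != len(ctrl_ids):
        raise ColdscreenError(
            f"paired_by_index needs equal group sizes, got {len(cold_ids)} cold "
            f"vs {len(ctrl_ids)} control"
        )

    gene_ctrl_pool = int(gene_reads[ctrl_ids].sum())
    total_ctrl_pool = int(library_sizes[ctrl_ids].sum())
    p_values: list[float] = []
    directions: list[str] = []
    for k, sid in enumerate(cold_ids):
        g_cold = int(gene_reads[sid])
        n_cold = int(library_sizes[sid])
        if config.pairing == "vs_pooled_control":
            g_ctrl, n_ctrl = gene_ctrl_pool, total_ctrl_pool
        else:
            g_ctrl = int(gene_reads[ctrl_ids[k]])
            n_ctrl = int(library_sizes[ctrl_ids[k]])
        p_values.append(fisher_gene_test(g_cold, n_cold - g_cold, g_ctrl, n_ctrl - g_ctrl))
        directions.append(_direction(g_cold, n_cold, g_ctrl, n_ctrl))

    gene_cold_pool = int(gene_reads[cold_ids].sum())
    total_cold_pool = int(library_sizes[cold_ids].sum())
    pooled_p = fisher_gene_test(
        gene_cold_pool,
        total_cold_pool - gene_cold_pool,
        gene_ctrl_pool,
        total_ctrl_pool - gene_ctrl_pool,
    )
    return p_values, directions, pooled_p


def _fc_rank_key(call: GeneCall) -> tuple:
    fc = call.fold_change
    fc_class = 0 if math.isinf(fc) else (2 if math.isnan(fc) else 1)
    fc_desc = 0.0 if fc_class != 1 else -fc
    return (fc_class, fc_desc, call.pooled_p, call.gene_id)


def top_induced(calls: Sequence[GeneCall], config: CallerConfig) -> list[str]:
    """Top-fraction most cold-induced genes among those called up.

    Ranked by fold change descending (+inf first), ties broken by ascending
    pooled p-value then gene_id; returns the first
    ``ceil(top_fraction * n_up)`` gene ids.
    """
    up_calls = sorted((c for c in calls if c.call == UP), key=_fc_rank_key)
    n_keep = math.ceil(config.top_fraction * len(up_calls))
    return [c.gene_id for c in up_calls[:n_keep]]


def run_screen(
    counts: CountMatrix, config: CallerConfig | None = None
) -> tuple[list[GeneCall], ScreenSummary]:
    """Run the full screen on a validated count matrix.

    Computes RPKM, aggregates to genes, restricts to expressed genes
    (summed RPKM > 0 in at least one sample), runs the per-sample Fisher
    tests, BH-corrects within the configured family, applies the consistency
    vote and the fold change, and tallies the cohort summary. Returns calls
    sorted by gene_id together with the :class:`ScreenSummary`.
    """
    from coldscreen.report import summarize

    config = config or CallerConfig()
    samples = counts.samples
    cold_ids = samples.cold_ids
    if len(cold_ids) != config.n_cold_samples:
        raise ColdscreenError(
            f"sample sheet has {len(cold_ids)} cold samples but config expects "
            f"{config.n_cold_samples}"
        )

    rpkm = compute_rpkm(counts)
    table = build_gene_table(counts, rpkm)
    expressed, expressed_all = expressed_filter(table)
    log.info(
        "screen: %d genes, %d expressed, %d expressed in all samples",
        len(table.gene_ids),
        len(expressed),
        len(expressed_all),
    )
    fc = fold_changes(table)
    sizes = counts.library_sizes()
    gene_counts = table.counts.loc[expressed]

    p_rows: list[list[float]] = []
    dir_rows: list[list[str]] = []
    pooled: list[float] = []
    for gid in expressed:
        p_i, d_i, pool_p = per_sample_tests(gene_counts.loc[gid], sizes, samples, config)
        p_rows.append(p_i)
        dir_rows.append(d_i)
        pooled.append(pool_p)

    p_matrix = np.asarray(p_rows, dtype=np.float64).reshape(len(expressed), len(cold_ids))
    if config.bh_family == "per_sample_genomewide":
        q_matrix = np.column_stack(
            [bh_adjust(p_matrix[:, j]) for j in range(p_matrix.shape[1])]
        ) if len(expressed) else p_matrix
    else:  # per_gene_across_samples
        q_matrix = np.vstack([bh_adjust(row) for row in p_matrix]) if len(expressed) else p_matrix

    calls: list[GeneCall] = []
    for i, gid in enumerate(expressed):
        q_i = q_matrix[i, :].tolist()
        d_i = dir_rows[i]
        n_up, n_down = significant_direction_counts(q_i, d_i, config)
        calls.append(
            GeneCall(
                gene_id=str(gid),
                fold_change=float(fc[gid]),
                pooled_p=pooled[i],
                per_sample_p=tuple(p_rows[i]),
                per_sample_q=tuple(q_i),
                per_sample_direction=tuple(d_i),
                n_significant_up=n_up,
                n_significant_down=n_down,
                call=call_modified(q_i, d_i, config),
            )
        )
    calls.sort(key=lambda c: c.gene_id)
    summary = summarize(calls, len(expressed), len(expressed_all))
    return calls, summary
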