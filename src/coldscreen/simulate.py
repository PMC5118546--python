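"""Synthetic cold-exposure experiments with known ground truth.

The generator emulates the statistical structure the caller assumes: a 4-vs-4
control/cold design, gene-wise negative-binomial read counts with per-gene
baseline expression drawn on a log scale, multi-transcript genes whose reads
are split by fixed per-gene proportions, library sizes jittered around an
average of 45 million mapped reads, and a configurable set of truly
cold-induced or -repressed genes with stated fold changes. A single integer
seed determines every draw; each gene uses an independent substream, so
enlarging the gene set does not perturb the counts of existing genes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coldscreen.model import (
    COLD,
    CONTROL,
    DOWN,
    FLAT,
    UP,
    ColdscreenError,
    CountMatrix,
    SampleSheet,
    TranscriptAnnotation,
)


#: nominal sequencing depth the baseline means refer to: a gene with baseline
#: m yields on average m reads in a library of this size, scaled as N_i / N_ref
REFERENCE_LIBRARY_SIZE = 45e6


def _as_pairs(value, field: str) -> tuple[tuple[int, float], ...]:
    if isinstance(value, Mapping):
        items = value.items()
    else:
        items = tuple(tuple(pair) for pair in value)
    out = []
    for pair in items:
        if len(pair) != 2:
            raise ColdscreenError(f"{field}: entries must be (gene index, value) pairs")
        idx, v = pair
        out.append((int(idx), float(v)))
    return tuple(sorted(out))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic experiment.

    Defaults encode the emulated study conditions: four animals per group,
    libraries of 45 million reads +-10%, per-gene baseline expression
    log10-normal around 100 reads (sd 0.8 decades), negative-binomial
    dispersion 0.1 (variance = m + 0.1 m^2), one to four transcripts per gene
    with lengths uniform on 500-5,000 nt. ``effects`` lists
    (gene index, true fold change) pairs; all other genes are nulls (fold 1).
    ``baseline_overrides`` pins selected genes' baseline mean reads, e.g. to
    place an effect gene at a stated expression level.
    """

    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (1, 4)
    n_control: int = 4
    n_cold: int = 4
    baseline_log10_mean: float = 2.0
    baseline_log10_sd: float = 0.8
    nb_dispersion: float = 0.1
    library_size_mean: float = 45e6
    library_size_jitter: float = 0.10
    effects: tuple[tuple[int, float], ...] = ()
    baseline_overrides: tuple[tuple[int, float], ...] = ()
    transcript_length_range: tuple[int, int] = (500, 5000)
    dirichlet_concentration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", _as_pairs(self.effects, "effects"))
        object.__setattr__(
            self, "baseline_overrides", _as_pairs(self.baseline_overrides, "baseline_overrides")
        )
        for field in ("n_genes", "n_control", "n_cold"):
            if getattr(self, field) < 1:
                raise ColdscreenError(f"{field}: must be >= 1")
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ColdscreenError("transcripts_per_gene: need 1 <= low <= high")
        if self.nb_dispersion < 0:
            raise ColdscreenError("nb_dispersion: must be >= 0")
        if self.baseline_log10_sd < 0:
            raise ColdscreenError("baseline_log10_sd: must be >= 0")
        if self.library_size_mean <= 0:
            raise ColdscreenError("library_size_mean: must be > 0")
        if not 0 <= self.library_size_jitter < 1:
            raise ColdscreenError("library_size_jitter: must be in [0, 1)")
        llo, lhi = self.transcript_length_range
        if not 1 <= llo <= lhi:
            raise ColdscreenError("transcript_length_range: need 1 <= low <= high")
        if self.dirichlet_concentration <= 0:
            raise ColdscreenError("dirichlet_concentration: must be > 0")
        for idx, f in self.effects:
            if not 0 <= idx < self.n_genes:
                raise ColdscreenError(f"effects: gene index {idx} outside [0, n_genes)")
            if f <= 0:
                raise ColdscreenError(f"effects: fold change must be > 0, got {f}")
        for idx, m in self.baseline_overrides:
            if not 0 <= idx < self.n_genes:
                raise ColdscreenError(f"baseline_overrides: gene index {idx} outside [0, n_genes)")
            if m <= 0:
                raise ColdscreenError(f"baseline_overrides: mean must be > 0, got {m}")


@dataclasses.dataclass(frozen=True)
class SimulationTruth:
    """Ground truth per simulated gene: true fold change, direction, baseline mean."""

    table: pd.DataFrame  # index gene_id; true_fold_change, direction, baseline_mean_reads

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def true_fold_change(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "true_fold_change"])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\ttrue_fold_change\tdirection\tbaseline_mean_reads\n")
            for gid, row in self.table.iterrows():
                fh.write(
                    f"{gid}\t{row['true_fold_change']:.6g}\t{row['direction']}\t"
                    f"{row['baseline_mean_reads']:.6g}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimulationTruth":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
        return cls(table=frame)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion == 0.0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, TranscriptAnnotation, SampleSheet, SimulationTruth]:
    """Draw one synthetic experiment.

    Per gene g and sample i, gene-level reads follow
    NB(mean = m_g * f_g^[i is cold] * N_i / N_ref, dispersion) where N_i is the
    sample's library size and N_ref the configured average; reads are then
    partitioned among the gene's transcripts by per-gene proportions drawn
    once from a symmetric Dirichlet. Fully reproducible from ``config.seed``.
    """
    n_samples = config.n_control + config.n_cold
    sample_ids = [f"ctrl_{k + 1}" for k in range(config.n_control)] + [
        f"cold_{k + 1}" for k in range(config.n_cold)
    ]
    is_cold = np.array([False] * config.n_control + [True] * config.n_cold)

    # sample-level substream: library sizes only, independent of n_genes
    rng_samples = np.random.default_rng((config.seed, 0))
    jitter = config.library_size_jitter
    sizes = rng_samples.uniform(
        config.library_size_mean * (1 - jitter), config.library_size_mean * (1 + jitter), n_samples
    ).astype(np.int64)

    effect_of = dict(config.effects)
    override_of = dict(config.baseline_overrides)
    width = max(4, len(str(config.n_genes)))

    tx_rows: dict[str, tuple[str, int]] = {}
    count_rows: dict[str, np.ndarray] = {}
    truth_rows = []
    lo_t, hi_t = config.transcripts_per_gene
    lo_l, hi_l = config.transcript_length_range
    size_factor = sizes.astype(np.float64) / REFERENCE_LIBRARY_SIZE
    for g in range(config.n_genes):
        gid = f"G{g + 1:0{width}d}"
        rng = np.random.default_rng((config.seed, 1, g))
        n_tx = int(rng.integers(lo_t, hi_t + 1))
        lengths = rng.integers(lo_l, hi_l + 1, n_tx)
        props = rng.dirichlet(np.full(n_tx, config.dirichlet_concentration))
        baseline = float(10 ** rng.normal(config.baseline_log10_mean, config.baseline_log10_sd))
        baseline = override_of.get(g, baseline)
        fold = effect_of.get(g, 1.0)

        mean = baseline * size_factor * np.where(is_cold, fold, 1.0)
        gene_reads = _nb_counts(rng, mean, config.nb_dispersion)
        tx_counts = np.vstack([rng.multinomial(r, props) for r in gene_reads]).T  # tx x sample

        for t in range(n_tx):
            tid = f"{gid}.T{t + 1}"
            tx_rows[tid] = (gid, int(lengths[t]))
            count_rows[tid] = tx_counts[t]
        truth_rows.append(
            (gid, fold, UP if fold > 1 else (DOWN if fold < 1 else FLAT), baseline)
        )

    annotation = TranscriptAnnotation(
        table=pd.DataFrame.from_dict(tx_rows, orient="index", columns=["gene_id", "length_nt"])
        .rename_axis("transcript_id")
        .astype({"length_nt": np.int64})
    )
    samples = SampleSheet(
        table=pd.DataFrame(
            {
                "condition": np.where(is_cold, COLD, CONTROL),
                "library_size": pd.array(sizes, dtype="Int64"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    counts = CountMatrix(
        values=pd.DataFrame.from_dict(count_rows, orient="index", columns=sample_ids).astype(
            np.int64
        ),
        annotation=annotation,
        samples=samples,
    )
    truth = SimulationTruth(
        table=pd.DataFrame(
            truth_rows, columns=["gene_id", "true_fold_change", "direction", "baseline_mean_reads"]
        ).set_index("gene_id")
    )
    return counts, annotation, samples, truth


#: printed cold inductions of five thermogenic marker genes
#: (PGC-1a 3.3x, UCP1 4.5x, Dio2 4.8x, glycerokinase 5.4x, Elovl3 9.9x)
FIXTURE_FOLDS = (3.3, 4.5, 4.8, 5.4, 9.9)
FIXTURE_SEED = 1234


def fixture_config() -> SimulationConfig:
    """Configuration of the bundled toy dataset (see :func:`fixture_small`)."""
    return SimulationConfig(
        n_genes=50,
        effects=tuple((g, f) for g, f in enumerate(FIXTURE_FOLDS)),
        baseline_overrides=tuple((g, 1000.0) for g in range(len(FIXTURE_FOLDS))),
        seed=FIXTURE_SEED,
    )


def fixture_small() -> tuple[CountMatrix, TranscriptAnnotation, SampleSheet, SimulationTruth]:
    """Deterministic 50-gene, 8-sample toy experiment.

    Genes G0001-G0005 are cold-induced at the fold changes of five classic
    thermogenic markers (PGC-1a, UCP1, Dio2, glycerokinase, Elovl3: 3.3, 4.5,
    4.8, 5.4 and 9.9), each at a baseline of 1,000 reads; the remaining 45
    genes are nulls. The seed is fixed, so counts, annotation and truth are
    identical on every call and across platforms.
    """
    return simulate_counts(fixture_config())
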