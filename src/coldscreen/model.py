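"""Domain types and plain-text I/O for the screen.

All tables travel as a fixed TSV dialect: tab-separated, UTF-8, ``.`` decimal
point, no quoting, ``\\n`` line endings. Writers are deterministic (sorted rows,
fixed column order, fixed number formatting) so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("coldscreen")

CONTROL = "control"
COLD = "cold"
CONDITIONS = (CONTROL, COLD)

UP = "up"
DOWN = "down"
FLAT = "flat"
DIRECTIONS = (UP, DOWN, FLAT)

UNCHANGED = "unchanged"
CALLS = (UP, DOWN, UNCHANGED)
#: sort rank used by :func:`write_calls`: upregulated first, then down, then unchanged
CALL_RANK = {UP: 0, DOWN: 1, UNCHANGED: 2}


class ColdscreenError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(ColdscreenError):
    """A malformed or inconsistent input table."""


# ---------------------------------------------------------------------------
# annotation


@dataclasses.dataclass(frozen=True)
class TranscriptAnnotation:
    """Transcript -> gene map with effective transcript lengths.

    ``table`` is indexed by ``transcript_id`` and carries ``gene_id`` (string)
    and ``length_nt`` (positive integer, nucleotides). Every transcript maps to
    exactly one gene; transcript ids are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"gene_id", "length_nt"} - set(t.columns)
        if missing:
            raise DataFormatError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][:5].tolist()
            raise DataFormatError(f"duplicate transcript_id in annotation: {dup}")
        lengths = t["length_nt"]
        if not np.issubdtype(lengths.dtype, np.integer):
            raise DataFormatError("annotation length_nt must be integer nucleotides")
        if (lengths < 1).any():
            bad = t.index[lengths < 1][:5].tolist()
            raise DataFormatError(f"non-positive transcript length for: {bad}")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.table.index

    @property
    def gene_ids(self) -> pd.Series:
        """gene_id per transcript, indexed by transcript_id."""
        return self.table["gene_id"]

    @property
    def lengths(self) -> pd.Series:
        """Effective transcript length in nucleotides, indexed by transcript_id."""
        return self.table["length_nt"]

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.table["gene_id"].unique()))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TranscriptAnnotation":
        """Build from a frame with columns transcript_id, gene_id, length_nt."""
        t = frame.copy()
        if "transcript_id" in t.columns:
            t = t.set_index("transcript_id")
        t["length_nt"] = _parse_int_column(t["length_nt"], "length_nt", minimum=1)
        return cls(table=t[["gene_id", "length_nt"]])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TranscriptAnnotation":
        frame = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
        for col in ("transcript_id", "gene_id", "length_nt"):
            if col not in frame.columns:
                raise DataFormatError(f"{path}: annotation TSV missing column {col!r}")
        return cls.from_frame(frame)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.sort_index()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("transcript_id\tgene_id\tlength_nt\n")
            for tid, row in out.iterrows():
                fh.write(f"{tid}\t{row['gene_id']}\t{int(row['length_nt'])}\n")


def transcript_lengths_from_gtf(path: str | Path) -> TranscriptAnnotation:
    """Exon-union transcript lengths from a standard 9-column GTF.

    Effective length is the number of genomic bases covered by the union of a
    transcript's exon intervals (GTF coordinates are 1-based, inclusive), so
    overlapping exon records are not double counted. Transcripts annotated
    without any exon feature are excluded with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    gene_of: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        if feat.end < feat.start:
            raise DataFormatError(
                f"{path}: exon with end < start ({feat.start}-{feat.end}) "
                f"for transcript {feat.attributes.get('transcript_id', ['?'])[0]}"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        prev = gene_of.setdefault(tid, gid)
        if prev != gid:
            raise DataFormatError(f"{path}: transcript {tid} assigned to genes {prev} and {gid}")
        exons.setdefault(tid, []).append((feat.start, feat.end))

    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        if tid not in exons:
            log.warning("transcript %s has no exon features; excluded from annotation", tid)

    if not exons:
        raise DataFormatError(f"{path}: no exon features found")
    rows = {
        tid: (gene_of[tid], interval_union_length(ivs)) for tid, ivs in sorted(exons.items())
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["gene_id", "length_nt"])
    frame.index.name = "transcript_id"
    frame["length_nt"] = frame["length_nt"].astype(np.int64)
    return TranscriptAnnotation(table=frame)


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by a union of 1-based inclusive intervals."""
    merged_end = None
    merged_start = None
    total = 0
    for start, end in sorted(intervals):
        if merged_end is None:
            merged_start, merged_end = start, end
        elif start <= merged_end + 1:
            merged_end = max(merged_end, end)
        else:
            total += merged_end - merged_start + 1
            merged_start, merged_end = start, end
    if merged_end is not None:
        total += merged_end - merged_start + 1
    return total


# ---------------------------------------------------------------------------
# samples


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: condition and (optionally) total mapped reads.

    ``table`` is indexed by ``sample_id`` with columns ``condition`` (one of
    ``control``/``cold``) and ``library_size`` (positive integer or <NA>; when
    absent the library size is taken as the sample's column sum of counts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][:5].tolist()
            raise DataFormatError(f"duplicate sample_id: {dup}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise DataFormatError(
                f"unknown condition values {sorted(bad)}; expected one of {CONDITIONS}"
            )
        for cond in CONDITIONS:
            if not (t["condition"] == cond).any():
                raise DataFormatError(f"sample sheet has no {cond!r} sample")
        if "library_size" in t.columns:
            ls = t["library_size"]
            if (ls.dropna() <= 0).any():
                raise DataFormatError("library_size must be a positive read count")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def control_ids(self) -> list[str]:
        return list(self.table.index[self.table["condition"] == CONTROL])

    @property
    def cold_ids(self) -> list[str]:
        return list(self.table.index[self.table["condition"] == COLD])

    def declared_library_sizes(self) -> pd.Series:
        """library_size column as nullable Int64 (all-<NA> if never declared)."""
        if "library_size" in self.table.columns:
            return self.table["library_size"].astype("Int64")
        return pd.Series(pd.NA, index=self.table.index, dtype="Int64", name="library_size")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        t = frame.copy()
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        if "condition" not in t.columns:
            raise DataFormatError("sample sheet missing column 'condition'")
        if "library_size" in t.columns:
            t["library_size"] = _parse_int_column(
                t["library_size"], "library_size", minimum=1, nullable=True
            )
            t = t[["condition", "library_size"]]
        else:
            t = t[["condition"]]
        return cls(table=t)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
        if "sample_id" not in frame.columns:
            raise DataFormatError(f"{path}: sample sheet missing column 'sample_id'")
        return cls.from_frame(frame)

    def write_tsv(self, path: str | Path) -> None:
        ls = self.declared_library_sizes()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample_id\tcondition\tlibrary_size\n")
            for sid in self.table.index:
                size = ls.loc[sid]
                size_txt = "" if pd.isna(size) else str(int(size))
                fh.write(f"{sid}\t{self.table.at[sid, 'condition']}\t{size_txt}\n")


# ---------------------------------------------------------------------------
# matrices


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Transcript x sample integer read counts bound to annotation and samples.

    Rows are a subset of the annotation's transcripts; columns are exactly the
    sample sheet's samples, in sheet order.
    """

    values: pd.DataFrame
    annotation: TranscriptAnnotation
    samples: SampleSheet

    def __post_init__(self) -> None:
        v = self.values
        if not all(np.issubdtype(dt, np.integer) for dt in v.dtypes):
            raise DataFormatError("counts must be integers")
        if (v.to_numpy() < 0).any():
            raise DataFormatError("counts must be nonnegative")
        unknown = v.index.difference(self.annotation.transcript_ids)
        if len(unknown):
            raise DataFormatError(
                f"transcripts absent from annotation: {unknown[:5].tolist()}"
            )
        if list(v.columns) != list(self.samples.sample_ids):
            raise DataFormatError(
                f"count columns {list(v.columns)} do not match sample sheet "
                f"{list(self.samples.sample_ids)}"
            )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Series:
        """gene_id per row, aligned to the count matrix index."""
        return self.annotation.gene_ids.loc[self.values.index]

    def library_sizes(self) -> pd.Series:
        """Total mapped reads per sample: declared sizes, else column sums."""
        declared = self.samples.declared_library_sizes()
        sums = self.values.sum(axis=0)
        out = declared.astype("float64")
        out[declared.isna()] = sums[declared.isna()]
        return out.astype(np.int64).rename("library_size")

    def gene_counts(self) -> pd.DataFrame:
        """Gene x sample counts: sum of each gene's transcript rows."""
        return self.values.groupby(self.gene_ids, sort=True).sum()


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Transcript x sample RPKM, same shape and keys as the source counts."""

    values: pd.DataFrame
    annotation: TranscriptAnnotation
    samples: SampleSheet

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isfinite(v).all():
            raise DataFormatError("RPKM values must be finite")
        if (v < 0).any():
            raise DataFormatError("RPKM values must be nonnegative")

    def gene_rpkm(self) -> pd.DataFrame:
        """Gene x sample summed RPKM over each gene's transcripts."""
        gene_ids = self.annotation.gene_ids.loc[self.values.index]
        return self.values.groupby(gene_ids, sort=True).sum()


def read_counts(
    path: str | Path, annotation: TranscriptAnnotation, samples: SampleSheet
) -> CountMatrix:
    """Read and validate a counts TSV (transcript_id, gene_id, one column per sample).

    Raises :class:`DataFormatError` naming the offending cell on a negative or
    non-integer count, the offending transcript when absent from the
    annotation, and the offending columns on any mismatch with the sample
    sheet. The gene_id column is cross-checked against the annotation.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "gene_id"):
        if col not in frame.columns:
            raise DataFormatError(f"{path}: counts TSV missing column {col!r}")
    count_cols = [c for c in frame.columns if c not in ("transcript_id", "gene_id")]
    sheet_ids = list(samples.sample_ids)
    extra = sorted(set(count_cols) - set(sheet_ids))
    missing = sorted(set(sheet_ids) - set(count_cols))
    if extra:
        raise DataFormatError(f"{path}: sample columns not in sample sheet: {extra}")
    if missing:
        raise DataFormatError(f"{path}: sample sheet samples missing from counts: {missing}")

    frame = frame.set_index("transcript_id")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][:5].tolist()
        raise DataFormatError(f"{path}: duplicate transcript rows: {dup}")

    parsed = {}
    for col in sheet_ids:
        raw = frame[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() | (values != values.round()) | (values < 0)
        if bad.any():
            tid = frame.index[bad][0]
            raise DataFormatError(
                f"{path}: invalid count {raw[bad].iloc[0]!r} at transcript {tid!r}, "
                f"sample {col!r} (must be a nonnegative integer)"
            )
        parsed[col] = values.astype(np.int64)
    values = pd.DataFrame(parsed, index=frame.index)

    unknown = values.index.difference(annotation.transcript_ids)
    if len(unknown):
        raise DataFormatError(
            f"{path}: transcripts absent from annotation: {unknown[:5].tolist()}"
        )
    claimed = frame["gene_id"]
    expected = annotation.gene_ids.loc[values.index]
    wrong = claimed != expected
    if wrong.any():
        tid = values.index[wrong][0]
        raise DataFormatError(
            f"{path}: gene_id mismatch for transcript {tid!r}: file says "
            f"{claimed[tid]!r}, annotation says {expected[tid]!r}"
        )
    return CountMatrix(values=values, annotation=annotation, samples=samples)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a counts TSV in the format :func:`read_counts` accepts (rows sorted)."""
    gene_ids = counts.gene_ids
    sample_ids = list(counts.samples.sample_ids)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("transcript_id\tgene_id\t" + "\t".join(sample_ids) + "\n")
        for tid in sorted(counts.values.index):
            row = counts.values.loc[tid]
            fh.write(
                f"{tid}\t{gene_ids[tid]}\t" + "\t".join(str(int(row[s])) for s in sample_ids) + "\n"
            )


# ---------------------------------------------------------------------------
# results


@dataclasses.dataclass(frozen=True)
class GeneCall:
    """Per-gene screen result.

    ``fold_change`` is the cold/control ratio of summed transcript RPKM; it is
    ``+inf`` when the control sum is zero but the cold sum is not, and ``nan``
    when both sums are zero (such genes fail the expressed filter and never
    reach the caller in the normal pipeline). Per-sample vectors have one entry
    per cold sample, in sample-sheet order.
    """

    gene_id: str
    fold_change: float
    pooled_p: float
    per_sample_p: tuple[float, ...]
    per_sample_q: tuple[float, ...]
    per_sample_direction: tuple[str, ...]
    n_significant_up: int
    n_significant_down: int
    call: str

    def __post_init__(self) -> None:
        k = len(self.per_sample_p)
        if len(self.per_sample_q) != k or len(self.per_sample_direction) != k:
            raise ColdscreenError(f"{self.gene_id}: per-sample vectors differ in length")
        for p, q in zip(self.per_sample_p, self.per_sample_q):
            if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
                raise ColdscreenError(f"{self.gene_id}: p/q outside [0, 1]")
            if q < p - 1e-12:
                raise ColdscreenError(f"{self.gene_id}: adjusted q below raw p")
        if any(d not in DIRECTIONS for d in self.per_sample_direction):
            raise ColdscreenError(f"{self.gene_id}: invalid direction")
        if self.call not in CALLS:
            raise ColdscreenError(f"{self.gene_id}: invalid call {self.call!r}")


@dataclasses.dataclass(frozen=True)
class ScreenSummary:
    """Cohort-level tallies of the screen."""

    n_expressed: int
    n_expressed_all_samples: int
    n_modified: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.n_modified != self.n_up + self.n_down:
            raise ColdscreenError("n_modified must equal n_up + n_down")
        if self.n_modified > self.n_expressed:
            raise ColdscreenError("n_modified cannot exceed n_expressed")
        if self.n_expressed_all_samples > self.n_expressed:
            raise ColdscreenError("expressed-in-all cannot exceed expressed")

    @property
    def pct_modified(self) -> float:
        """100 * n_modified / n_expressed (0 when nothing is expressed)."""
        if self.n_expressed == 0:
            return 0.0
        return 100.0 * self.n_modified / self.n_expressed


def _fmt_number(x: float) -> str:
    """6 significant digits; '+inf' for infinity, 'NA' for undefined."""
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "+inf" if x > 0 else "-inf"
    return format(x, ".6g")


def _parse_number(text: str) -> float:
    if text == "NA":
        return math.nan
    if text == "+inf":
        return math.inf
    return float(text)


def _call_sort_key(call: GeneCall) -> tuple:
    fc = call.fold_change
    if math.isinf(fc):
        fc_class, fc_desc = 0, 0.0
    elif math.isnan(fc):
        fc_class, fc_desc = 2, 0.0
    else:
        fc_class, fc_desc = 1, -fc
    return (CALL_RANK[call.call], fc_class, fc_desc, call.gene_id)


def write_calls(
    calls: Sequence[GeneCall],
    summary: ScreenSummary,
    out_prefix: str | Path,
    cold_sample_ids: Sequence[str],
    expressed_in_all: Iterable[str] = (),
    config_text: str = "",
) -> tuple[Path, Path]:
    """Write ``<prefix>.calls.tsv`` and ``<prefix>.summary.txt``.

    The calls table is sorted by (call rank, descending fold change with +inf
    first and NA last, gene_id); numbers use 6 significant digits. Output is
    byte-identical across runs on identical input. The summary is key = value
    text and echoes the caller configuration when ``config_text`` is given.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    calls_path = out_prefix.with_name(out_prefix.name + ".calls.tsv")
    summary_path = out_prefix.with_name(out_prefix.name + ".summary.txt")
    in_all = set(expressed_in_all)

    cols = ["gene_id", "call", "fold_change", "pooled_p"]
    cols += [f"p_{s}" for s in cold_sample_ids]
    cols += [f"q_{s}" for s in cold_sample_ids]
    cols += [f"dir_{s}" for s in cold_sample_ids]
    cols += ["n_significant_up", "n_significant_down", "in_all_samples"]
    with open(calls_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for call in sorted(calls, key=_call_sort_key):
            if len(call.per_sample_p) != len(cold_sample_ids):
                raise ColdscreenError(
                    f"{call.gene_id}: {len(call.per_sample_p)} per-sample entries for "
                    f"{len(cold_sample_ids)} cold samples"
                )
            row = [call.gene_id, call.call, _fmt_number(call.fold_change), _fmt_number(call.pooled_p)]
            row += [_fmt_number(p) for p in call.per_sample_p]
            row += [_fmt_number(q) for q in call.per_sample_q]
            row += list(call.per_sample_direction)
            row += [
                str(call.n_significant_up),
                str(call.n_significant_down),
                "1" if call.gene_id in in_all else "0",
            ]
            fh.write("\t".join(row) + "\n")

    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(summary_text(summary, config_text))
    return calls_path, summary_path


def summary_text(summary: ScreenSummary, config_text: str = "") -> str:
    from coldscreen.report import format_pct  # local import: report depends on model

    lines = [
        f"n_expressed = {summary.n_expressed}",
        f"n_expressed_all_samples = {summary.n_expressed_all_samples}",
        f"n_modified = {summary.n_modified}",
        f"n_up = {summary.n_up}",
        f"n_down = {summary.n_down}",
        f"pct_modified = {format_pct(summary.pct_modified)}",
    ]
    for cfg_line in config_text.splitlines():
        if cfg_line.strip():
            lines.append(f"config.{cfg_line.strip()}")
    return "\n".join(lines) + "\n"


def read_calls(path: str | Path) -> tuple[list[GeneCall], list[str], set[str]]:
    """Read a calls TSV back: (calls, cold_sample_ids, expressed_in_all gene ids)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    p_cols = [c for c in frame.columns if c.startswith("p_")]
    cold_ids = [c[2:] for c in p_cols]
    calls: list[GeneCall] = []
    in_all: set[str] = set()
    for _, row in frame.iterrows():
        gid = row["gene_id"]
        if row["in_all_samples"] == "1":
            in_all.add(gid)
        calls.append(
            GeneCall(
                gene_id=gid,
                fold_change=_parse_number(row["fold_change"]),
                pooled_p=_parse_number(row["pooled_p"]),
                per_sample_p=tuple(_parse_number(row[f"p_{s}"]) for s in cold_ids),
                per_sample_q=tuple(_parse_number(row[f"q_{s}"]) for s in cold_ids),
                per_sample_direction=tuple(row[f"dir_{s}"] for s in cold_ids),
                n_significant_up=int(row["n_significant_up"]),
                n_significant_down=int(row["n_significant_down"]),
                call=row["call"],
            )
        )
    return calls, cold_ids, in_all


def read_summary(path: str | Path) -> dict[str, str]:
    """Parse a key = value summary file into a flat dict."""
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        m = re.match(r"([^=]+?)\s*=\s*(.*)", line)
        if not m:
            raise DataFormatError(f"{path}: malformed summary line {line!r}")
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def _parse_int_column(
    series: pd.Series, name: str, minimum: int, nullable: bool = False
) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    missing = values.isna()
    if nullable:
        src_missing = series.isna() | (series.astype(str).str.strip() == "")
        bad = (missing & ~src_missing) | (~missing & ((values != values.round()) | (values < minimum)))
    else:
        bad = missing | (values != values.round()) | (values < minimum)
    if bad.any():
        raise DataFormatError(
            f"column {name!r}: invalid value {series[bad].iloc[0]!r} "
            f"(need integer >= {minimum})"
        )
    if nullable:
        return values.astype("Int64")
    return values.astype(np.int64)
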