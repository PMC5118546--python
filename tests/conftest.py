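"""Shared builders for small in-memory datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coldscreen.model import CountMatrix, SampleSheet, TranscriptAnnotation


def make_annotation(entries: dict[str, tuple[str, int]]) -> TranscriptAnnotation:
    """entries: transcript_id -> (gene_id, length_nt)."""
    frame = pd.DataFrame.from_dict(entries, orient="index", columns=["gene_id", "length_nt"])
    frame.index.name = "transcript_id"
    return TranscriptAnnotation(table=frame.astype({"length_nt": np.int64}))


def make_samples(
    conditions: dict[str, str], library_sizes: dict[str, int] | None = None
) -> SampleSheet:
    frame = pd.DataFrame(
        {"condition": pd.Series(conditions)}, index=pd.Index(conditions, name="sample_id")
    )
    if library_sizes is not None:
        frame["library_size"] = pd.array(
            [library_sizes.get(s) for s in frame.index], dtype="Int64"
        )
    return SampleSheet(table=frame)


def make_counts(
    annotation: TranscriptAnnotation,
    samples: SampleSheet,
    rows: dict[str, list[int]],
) -> CountMatrix:
    """rows: transcript_id -> counts in sample-sheet order."""
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(samples.sample_ids)
    ).astype(np.int64)
    values.index.name = "transcript_id"
    return CountMatrix(values=values, annotation=annotation, samples=samples)


@pytest.fixture
def four_v_four() -> SampleSheet:
    """4 control + 4 cold samples with equal declared library sizes of 1e6."""
    ids = [f"ctrl_{i}" for i in range(1, 5)] + [f"cold_{i}" for i in range(1, 5)]
    return make_samples(
        {s: ("control" if s.startswith("ctrl") else "cold") for s in ids},
        {s: 1_000_000 for s in ids},
    )


@pytest.fixture
def tiny_dataset(four_v_four):
    """3 transcripts / 2 genes x 8 samples with simple integer counts."""
    annotation = make_annotation(
        {"t1": ("gA", 1000), "t2": ("gA", 2000), "t3": ("gB", 500)}
    )
    counts = make_counts(
        annotation,
        four_v_four,
        {
            "t1": [10, 12, 11, 9, 40, 44, 38, 42],
            "t2": [5, 6, 5, 4, 20, 21, 19, 22],
            "t3": [100, 110, 90, 100, 100, 110, 90, 100],
        },
    )
    return counts, annotation, four_v_four
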