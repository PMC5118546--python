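"""Cohort summaries and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from coldscreen.model import DOWN, UP, GeneCall, ScreenSummary

log = logging.getLogger("coldscreen")


def format_pct(value: float) -> str:
    """Percentage to one decimal, ties rounded half away from zero (16.22 -> '16.2')."""
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(calls: Sequence[GeneCall], n_expressed: int, n_expressed_all_samples: int) -> ScreenSummary:
    """Tally calls made on the expressed gene set into a :class:`ScreenSummary`.

    ``n_expressed`` and ``n_expressed_all_samples`` are the sizes of the
    nested expression filters the calls were computed on. With nothing
    expressed the percentage is reported as 0 with a warning.
    """
    n_up = sum(1 for c in calls if c.call == UP)
    n_down = sum(1 for c in calls if c.call == DOWN)
    if n_expressed == 0:
        log.warning("no expressed genes: percent modified reported as 0")
    return ScreenSummary(
        n_expressed=n_expressed,
        n_expressed_all_samples=n_expressed_all_samples,
        n_modified=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
    )


def file_checksum(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every run's outputs.

    Captures the package version, the exact command, the configuration text,
    the seed (for simulated runs), and checksums of all inputs and outputs —
    enough to rerun the deterministic stages bit-identically.
    """

    version: str
    command: str
    config_text: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    seed: int | None = None
    created_utc: str = ""

    def to_json(self) -> str:
        record = dataclasses.asdict(self)
        return json.dumps(record, indent=2, sort_keys=True) + "\n"

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        record = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**record)


def build_manifest(
    command: str,
    config_text: str,
    inputs: dict[str, str | Path],
    outputs: dict[str, str | Path],
    seed: int | None = None,
) -> RunManifest:
    from coldscreen import __version__

    return RunManifest(
        version=__version__,
        command=command,
        config_text=config_text,
        inputs={name: file_checksum(p) for name, p in inputs.items()},
        outputs={name: file_checksum(p) for name, p in outputs.items()},
        seed=seed,
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
    )
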