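"""Sample sheets: the mapping from tag pairs to scats and their metadata."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["SampleSheetRow", "read_sample_sheet", "write_sample_sheet"]

_COLUMNS = [
    "run_id", "scat_id", "fwd_tag", "rev_tag",
    "location", "year", "phase", "population_id", "sex",
]


@dataclass(frozen=True)
class SampleSheetRow:
    run_id: str
    scat_id: str
    fwd_tag: str
    rev_tag: str
    location: str = ""
    year: str = ""
    phase: str = ""
    population_id: str = ""
    sex: str = "unknown"


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    return [SampleSheetRow(**{c: row[c] for c in _COLUMNS}) for _, row in df.iterrows()]


def write_sample_sheet(rows: Iterable[SampleSheetRow], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in rows], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
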