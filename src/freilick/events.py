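"""Timestamped event series (licks, TTLs) and their CSV formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class LickEventSeries:
    """Ordered lick timestamps with a provenance label.

    ``source`` records where the events came from: ``ground_truth``,
    ``offline``, ``online`` or a free-form label.
    """

    times_s: np.ndarray
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float).ravel()
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise DataError("lick times must be sorted non-decreasing")

    def __len__(self) -> int:
        return self.times_s.size

    def __iter__(self):
        return iter(self.times_s)


def write_events(events: LickEventSeries, path: str | Path) -> None:
    """Write events as CSV with header ``time_s,label``."""
    pd.DataFrame({"time_s": events.times_s, "label": events.source}).to_csv(
        path, index=False
    )


def read_events(path: str | Path, source: str | None = None) -> LickEventSeries:
    """Read an event CSV; accepts either ``time_s,label`` or bare ``time_s``."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise DataError(f"{path}: expected a 'time_s' column")
    if source is None:
        source = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else "unknown"
    return LickEventSeries(times_s=np.sort(df["time_s"].to_numpy(float)), source=source)
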