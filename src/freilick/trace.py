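"""Analog trace container and its on-disk format.

A trace is stored as raw little-endian float32 samples next to a JSON
sidecar holding the sampling rate, units, start time and channel label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError


@dataclass
class SGTrace:
    """Uniformly sampled analog signal (e.g. the amplified strain-gauge voltage).

    Parameters
    ----------
    samples : ndarray
        Signal values, volts.
    fs_hz : float
        Sampling rate, Hz. Must be positive.
    t0_s : float
        Time of the first sample, seconds.
    units : str
        Physical units of the samples.
    channel : str
        Free-form channel label.
    """

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    units: str = "V"
    channel: str = "SG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ParameterError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.samples.ndim != 1:
            raise DataError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0_s + np.arange(self.n) / self.fs_hz


def write_trace(trace: SGTrace, data_path: str | Path) -> None:
    """Write raw float32 samples plus a ``.json`` sidecar next to them."""
    data_path = Path(data_path)
    trace.samples.astype("<f4").tofile(data_path)
    sidecar = {
        "sampling_rate_hz": trace.fs_hz,
        "units": trace.units,
        "t0_s": trace.t0_s,
        "channel": trace.channel,
    }
    data_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(data_path: str | Path, meta_path: str | Path | None = None) -> SGTrace:
    """Read a raw float32 trace and its JSON sidecar."""
    data_path = Path(data_path)
    if meta_path is None:
        meta_path = data_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    samples = np.fromfile(data_path, dtype="<f4").astype(float)
    return SGTrace(
        samples=samples,
        fs_hz=float(meta["sampling_rate_hz"]),
        t0_s=float(meta.get("t0_s", 0.0)),
        units=str(meta.get("units", "V")),
        channel=str(meta.get("channel", "SG")),
    )
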