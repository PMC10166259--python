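"""Event-aligned analysis of denoised calcium traces.

Behavioral events are aligned to the nearest imaging frame, each unit's
denoised trace is robustly normalized by its median absolute deviation
(MAD, without the Gaussian consistency constant), and event-triggered
averages are computed per unit. A unit is *modulated* when its averaged
waveform peaks at or above 3x MAD; modulated units are classed as
initiation, licking or postlick neurons according to whether the maximal
peak occurs in the nose-poke- (walking delay), head-entry- (licking
response) or reward-aligned (reward anticipation) average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateTraceError, ParameterError
from .task import SessionLog

CLASSES = ("initiation", "licking", "postlick", "unmodulated")

#: alignment event -> task period it probes -> class name
ALIGNMENT_CLASS = {"nose_poke": "initiation", "head_entry": "licking",
                   "reward": "postlick"}


@dataclass
class CalciumTraceSet:
    """Units x frames matrix of denoised traces with frame timestamps."""

    traces: np.ndarray
    frame_ts: np.ndarray
    unit_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.frame_ts = np.asarray(self.frame_ts, dtype=float)
        if np.any(np.diff(self.frame_ts) <= 0):
            raise DataError("frame timestamps must be strictly increasing")
        if self.traces.shape[1] != self.frame_ts.size:
            raise DataError("trace columns must match the number of frame timestamps")
        if self.unit_ids is None:
            self.unit_ids = list(range(self.traces.shape[0]))

    @property
    def n_units(self) -> int:
        return self.traces.shape[0]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_ts)))


@dataclass
class EventAlignedAverage:
    """Per-unit event-triggered averages of MAD-normalized traces."""

    average: np.ndarray  # units x window (NaN rows for excluded units)
    lags_s: np.ndarray
    n_events: int
    n_skipped: int
    excluded_units: list  # MAD = 0


@dataclass
class ModulationResult:
    table: pd.DataFrame  # unit_id, class, peak_mad, peak_alignment, peak_lag_s
    threshold: float
    averages: dict[str, EventAlignedAverage]
    skipped_alignments: list[str]


def align_events_to_frames(event_ts, frame_ts) -> tuple[np.ndarray, np.ndarray]:
    """Map each event to the nearest frame index; ties go to the earlier frame.

    Returns ``(indices, in_span)`` where ``in_span`` is False for events
    before the first or after the last frame timestamp.
    """
    frame_ts = np.asarray(frame_ts, dtype=float)
    if frame_ts.size == 0:
        raise ParameterError("frame_ts must be non-empty")
    event_ts = np.atleast_1d(np.asarray(event_ts, dtype=float))
    pos = np.searchsorted(frame_ts, event_ts)
    left = np.clip(pos - 1, 0, frame_ts.size - 1)
    right = np.clip(pos, 0, frame_ts.size - 1)
    # earlier frame wins on exact ties
    idx = np.where(
        np.abs(event_ts - frame_ts[left]) <= np.abs(frame_ts[right] - event_ts),
        left, right,
    )
    in_span = (event_ts >= frame_ts[0]) & (event_ts <= frame_ts[-1])
    return idx, in_span


def mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency constant)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def mad_normalize(trace: np.ndarray) -> np.ndarray:
    """Robust z-score: ``(x - median) / MAD``. Scale-invariant under positive
    affine transforms. Raises :class:`DegenerateTraceError` when MAD = 0."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ParameterError("trace must hold at least 2 samples")
    m = mad(trace)
    if m == 0:
        raise DegenerateTraceError("trace has zero MAD; unit excluded")
    return (trace - np.median(trace)) / m


def event_triggered_average(
    traces: CalciumTraceSet,
    event_frame_idx: Sequence[int] | np.ndarray,
    pre_frames: int,
    post_frames: int,
) -> EventAlignedAverage:
    """Average MAD-normalized trace segments around event frames.

    Events whose window would leave the recording are skipped (counted in
    ``n_skipped``); zero usable events is an error. Units with MAD = 0 are
    excluded and reported, their rows left NaN.
    """
    idx = np.asarray(event_frame_idx, dtype=int)
    n_frames = traces.frame_ts.size
    usable = idx[(idx - pre_frames >= 0) & (idx + post_frames < n_frames)]
    n_skipped = idx.size - usable.size
    if usable.size == 0:
        raise DataError("no event windows fit inside the recording")
    window = pre_frames + post_frames + 1
    avg = np.full((traces.n_units, window), np.nan)
    excluded = []
    for u in range(traces.n_units):
        try:
            norm = mad_normalize(traces.traces[u])
        except DegenerateTraceError:
            excluded.append(traces.unit_ids[u])
            continue
        segs = np.stack([norm[i - pre_frames:i + post_frames + 1] for i in usable])
        avg[u] = segs.mean(axis=0)
    period = float(np.median(np.diff(traces.frame_ts)))
    lags = (np.arange(window) - pre_frames) * period
    return EventAlignedAverage(average=avg, lags_s=lags, n_events=int(usable.size),
                               n_skipped=int(n_skipped), excluded_units=excluded)


def _alignment_event_times(log: SessionLog, alignment: str) -> np.ndarray:
    if alignment == "nose_poke":
        t = [tr.t_nose_poke for tr in log.trials]
    elif alignment == "head_entry":
        t = [tr.t_head_entry for tr in log.trials]
    elif alignment == "reward":
        # reward times on rewarded trials; cue onset of hits as fallback
        t = [tr.t_reward for tr in log.trials if tr.t_reward is not None]
        if not t:
            t = [tr.t_cue for tr in log.trials if tr.outcome == "hit"]
    else:
        raise ParameterError(f"unknown alignment {alignment!r}")
    return np.asarray([x for x in t if x is not None], dtype=float)


def classify_modulation(
    traces: CalciumTraceSet,
    log: SessionLog,
    threshold: float = 3.0,
    window_pre_s: float = 1.0,
    window_post_s: float = 2.0,
) -> ModulationResult:
    """Call modulated units at the 3x-MAD threshold and class them by period.

    Three event-triggered averages are computed per unit (nose poke, head
    entry, reward). The unit's peak is the maximum of each average over
    non-negative lags; it is modulated when any alignment's peak reaches
    ``threshold``, and its class is the period of the maximal peak:
    initiation (walking delay), licking (licking response) or postlick
    (reward anticipation). Alignments with no events are skipped and noted.
    """
    period = float(np.median(np.diff(traces.frame_ts)))
    pre = int(round(window_pre_s / period))
    post = int(round(window_post_s / period))
    averages: dict[str, EventAlignedAverage] = {}
    skipped: list[str] = []
    for alignment in ALIGNMENT_CLASS:
        ev = _alignment_event_times(log, alignment)
        if ev.size == 0:
            skipped.append(alignment)
            continue
        idx, in_span = align_events_to_frames(ev, traces.frame_ts)
        if not in_span.any():
            skipped.append(alignment)
            continue
        averages[alignment] = event_triggered_average(traces, idx[in_span], pre, post)
    if not averages:
        raise DataError("no alignment has events inside the recording")
    rows = []
    for u, uid in enumerate(traces.unit_ids):
        peaks = {}
        for alignment, eta in averages.items():
            row = eta.average[u]
            if np.all(np.isnan(row)):
                continue
            post_part = row[eta.lags_s >= 0]
            peaks[alignment] = float(np.nanmax(post_part))
        if not peaks:  # degenerate unit
            rows.append({"unit_id": uid, "class": "unmodulated", "peak_mad": np.nan,
                         "peak_alignment": None, "peak_lag_s": np.nan,
                         "excluded": True})
            continue
        best = max(peaks, key=peaks.get)
        peak = peaks[best]
        modulated = peak >= threshold
        eta = averages[best]
        row = eta.average[u]
        lag = float(eta.lags_s[eta.lags_s >= 0][int(np.nanargmax(row[eta.lags_s >= 0]))])
        rows.append({
            "unit_id": uid,
            "class": ALIGNMENT_CLASS[best] if modulated else "unmodulated",
            "peak_mad": peak,
            "peak_alignment": best,
            "peak_lag_s": lag,
            "excluded": False,
        })
    table = pd.DataFrame(rows)
    return ModulationResult(table=table, threshold=threshold, averages=averages,
                            skipped_alignments=skipped)


def split_by_trial_type(
    traces: CalciumTraceSet,
    log: SessionLog,
    align: str = "head_entry",
    window_pre_s: float = 1.0,
    window_post_s: float = 2.0,
) -> dict[str, np.ndarray]:
    """Group event-aligned trace segments by trial outcome.

    Returns ``{outcome: units x trials x time}`` for hit, error and miss
    trials aligned to the chosen event. Trials whose window leaves the
    recording are dropped; each usable trial lands in exactly one group.
    """
    attr = {"head_entry": "t_head_entry", "nose_poke": "t_nose_poke",
            "cue": "t_cue"}.get(align)
    if attr is None:
        raise ParameterError(f"unsupported alignment {align!r}")
    period = float(np.median(np.diff(traces.frame_ts)))
    pre = int(round(window_pre_s / period))
    post = int(round(window_post_s / period))
    n_frames = traces.frame_ts.size
    norm = np.full_like(traces.traces, np.nan)
    for u in range(traces.n_units):
        try:
            norm[u] = mad_normalize(traces.traces[u])
        except DegenerateTraceError:
            pass
    out: dict[str, list[np.ndarray]] = {"hit": [], "error": [], "miss": []}
    for tr in log.trials:
        t_ev = getattr(tr, attr)
        if t_ev is None:
            continue
        idx, in_span = align_events_to_frames([t_ev], traces.frame_ts)
        i = int(idx[0])
        if not in_span[0] or i - pre < 0 or i + post >= n_frames:
            continue
        out[tr.outcome].append(norm[:, i - pre:i + post + 1])
    return {
        k: (np.stack(v, axis=1) if v else np.empty((traces.n_units, 0, pre + post + 1)))
        for k, v in out.items()
    }


def compute_frame_loss(frame_ts, nominal_rate_hz: float) -> float:
    """Percentage of frames lost, inferred from timestamp gaps.

    Each gap contributes ``round(gap / nominal_period) - 1`` lost frames;
    the percentage is ``100 * lost / (observed + lost)``.
    """
    frame_ts = np.asarray(frame_ts, dtype=float)
    if frame_ts.size < 2:
        raise ParameterError("need at least 2 frame timestamps")
    gaps = np.diff(frame_ts)
    if np.any(gaps <= 0):
        raise DataError("frame timestamps must be strictly increasing")
    period = 1.0 / nominal_rate_hz
    lost = int(np.sum(np.maximum(np.round(gaps / period).astype(int) - 1, 0)))
    return 100.0 * lost / (frame_ts.size + lost)


# --------------------------------------------------------------------------
# On-disk format: raw float32 matrix + JSON sidecar, frame clock as CSV
# --------------------------------------------------------------------------

def write_traceset(ts: CalciumTraceSet, data_path: str | Path) -> None:
    data_path = Path(data_path)
    ts.traces.astype("<f4").tofile(data_path)
    frames_csv = data_path.with_suffix(".frames.csv")
    pd.DataFrame({"frame": np.arange(ts.frame_ts.size), "time_s": ts.frame_ts}
                 ).to_csv(frames_csv, index=False)
    sidecar = {"n_units": ts.n_units, "n_frames": int(ts.frame_ts.size),
               "frame_timestamps_file": frames_csv.name,
               "unit_ids": list(map(str, ts.unit_ids))}
    data_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_traceset(data_path: str | Path, meta_path: str | Path | None = None) -> CalciumTraceSet:
    data_path = Path(data_path)
    if meta_path is None:
        meta_path = data_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    frames = pd.read_csv(data_path.parent / meta["frame_timestamps_file"])
    mat = np.fromfile(data_path, dtype="<f4").astype(float)
    mat = mat.reshape(meta["n_units"], meta["n_frames"])
    return CalciumTraceSet(traces=mat, frame_ts=frames["time_s"].to_numpy(float),
                           unit_ids=list(meta.get("unit_ids") or range(meta["n_units"])))
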