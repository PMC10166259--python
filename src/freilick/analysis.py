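"""Behavioral performance metrics over session logs.

Block performance is a trailing moving average of the 0/1 hit sequence
(window 5 by default, matching the plotted learning curves); the learning
criterion is 70% correct over a full sliding window of five trials. Misses
count as incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .task import Outcome, SessionLog

#: sentinel for a block that never reaches the learning criterion
NOT_REACHED = -1


@dataclass
class PerformanceCurve:
    """Trailing hit-fraction curve over one block of trials."""

    trial: np.ndarray  # 1-based within-block trial indices
    hit_fraction: np.ndarray
    window: int


def _hits(outcomes) -> np.ndarray:
    return np.array([1.0 if o == "hit" else 0.0 for o in outcomes])


def block_performance(outcomes, window: int = 5) -> PerformanceCurve:
    """Moving-average hit fraction; partial windows at the block start use
    all trials seen so far (the plotting convention)."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    h = _hits(outcomes)
    n = h.size
    if n == 0:
        return PerformanceCurve(trial=np.empty(0, int), hit_fraction=np.empty(0), window=window)
    csum = np.concatenate(([0.0], np.cumsum(h)))
    idx = np.arange(1, n + 1)
    lo = np.maximum(0, idx - window)
    frac = (csum[idx] - csum[lo]) / (idx - lo)
    return PerformanceCurve(trial=idx, hit_fraction=frac, window=window)


def trials_to_criterion(outcomes, criterion: float = 0.70, window: int = 5) -> int:
    """Smallest trial index whose *full* trailing window reaches the criterion.

    Returns ``NOT_REACHED`` (-1) when no full window ever does. Unlike the
    displayed curve, partial windows never satisfy the criterion.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    h = _hits(outcomes)
    for t in range(window, h.size + 1):
        if h[t - window:t].mean() >= criterion:
            return t
    return NOT_REACHED


def reversal_summary(log: SessionLog, criterion: float = 0.70, window: int = 5) -> pd.DataFrame:
    """Per-block table: length, trials to criterion, outcome counts."""
    rows = []
    for block in range(1, log.n_blocks_entered + 1):
        outcomes = [t.outcome for t in log.trials if t.block == block]
        counts = {o: outcomes.count(o) for o in ("hit", "error", "miss")}
        rows.append({
            "block": block,
            "length": len(outcomes),
            "trials_to_criterion": trials_to_criterion(outcomes, criterion, window),
            "hits": counts["hit"], "errors": counts["error"], "misses": counts["miss"],
        })
    return pd.DataFrame(rows, columns=["block", "length", "trials_to_criterion",
                                       "hits", "errors", "misses"])
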