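"""Discrete-event engine for the directional-licking reversal task.

A trial proceeds nose poke -> gate opening -> walking delay -> head entry
into the licking chamber -> a 2 s licking-response (LR) window that decides
the outcome: a lick on the rewarded spout is a *hit*, a lick on the other
spout an *error*, no lick a *miss*. At the end of the LR an auditory cue is
played — a pure 5 kHz tone after hits, white noise after errors and misses.
Hits are followed by a 1 s reward-anticipation (RA) period, water delivery
and a 4 s post-reward interval; errors and misses close the gate immediately
after the cue.

The rewarded spout reverses (serial reversal learning) once the current
block has both (1) at least ``block_min_len`` trials and (2) a hit fraction
of at least ``criterion`` over the trailing ``criterion_window`` trials.
The criterion window never spans a reversal: block outcome history resets at
each flip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, ProtocolError

Outcome = Literal["hit", "error", "miss"]
Side = Literal["left", "right"]

CUE_HIT = "tone_5khz"
CUE_FAIL = "white_noise"

#: stages 1-3 present a single spout, so errors are impossible
SINGLE_SPOUT_STAGES = {"1", "2", "3"}


@dataclass
class TaskConfig:
    """Task parameters; defaults are the standard intrasession-reversal setup."""

    n_blocks: int = 2
    block_min_len: int = 15
    criterion: float = 0.70
    criterion_window: int = 15
    lr_duration_s: float = 2.0
    ra_duration_s: float = 1.0
    post_reward_s: float = 4.0
    reward_prob: float = 1.0
    first_rewarded_spout: Side = "left"
    immediate_feedback: bool = False
    stage: str = "final"  # "1".."5" or "final"
    walk_timeout_s: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_min_len < 1:
            raise ParameterError("n_blocks and block_min_len must be >= 1")
        if not (0 < self.criterion <= 1):
            raise ParameterError("criterion must lie in (0, 1]")
        if self.criterion_window < 1:
            raise ParameterError("criterion_window must be >= 1")
        if min(self.lr_duration_s, self.ra_duration_s, self.post_reward_s) <= 0:
            raise ParameterError("durations must be positive")
        if not (0 <= self.reward_prob <= 1):
            raise ParameterError("reward_prob must lie in [0, 1]")
        if self.first_rewarded_spout not in ("left", "right"):
            raise ParameterError("first_rewarded_spout must be 'left' or 'right'")

    @property
    def single_spout(self) -> bool:
        return str(self.stage) in SINGLE_SPOUT_STAGES


@dataclass
class TrialRecord:
    """One completed trial; timestamps in simulated seconds, 1-based indices."""

    index: int
    block: int
    rewarded_spout: Side
    outcome: Outcome
    cue_type: str
    t_nose_poke: float
    t_gate_open: float
    t_head_entry: float
    first_lick_side: Optional[Side]
    t_first_lick: Optional[float]
    t_cue: float
    t_reward: Optional[float]
    t_gate_close: float
    t_trial_end: float
    rewarded: bool = False


@dataclass
class SessionLog:
    """Ordered trial records plus config, seed and reversal bookkeeping."""

    config: TaskConfig
    trials: list[TrialRecord]
    reversal_trials: list[int]  # 1-based trial indices at which the flip occurred
    seed: int

    @property
    def n_blocks_entered(self) -> int:
        return max((t.block for t in self.trials), default=0)


@dataclass
class ReversalDecision:
    reverse: bool
    window_perf: float


def classify_outcome(
    first_lick_side: Optional[Side],
    first_lick_latency_s: Optional[float],
    rewarded_spout: Side,
    config: TaskConfig,
) -> Outcome:
    """Classify a trial from its first lick inside the LR window.

    No lick, or a first lick after the LR window, is a miss; a first lick on
    the rewarded spout is a hit; any other lick is an error. Later licks are
    ignored.
    """
    if first_lick_side is None or first_lick_latency_s is None:
        return "miss"
    if first_lick_latency_s < 0:
        raise ParameterError("lick latency must be non-negative")
    if first_lick_latency_s >= config.lr_duration_s:
        return "miss"
    return "hit" if first_lick_side == rewarded_spout else "error"


def schedule_trial_events(
    outcome: Outcome,
    head_entry_t: float,
    config: TaskConfig,
    wrong_lick_t: Optional[float] = None,
) -> dict[str, Optional[float]]:
    """Timestamps of cue, reward, gate closing and trial end for an outcome.

    Hits: cue at HE + LR, reward at cue + RA, end after the post-reward
    interval. Errors and misses: cue at the end of the LR (or at the wrong
    lick under immediate feedback), gate closes with the cue, no reward.
    """
    if outcome not in ("hit", "error", "miss"):
        raise ParameterError(f"unknown outcome {outcome!r}")
    cue = head_entry_t + config.lr_duration_s
    if outcome == "hit":
        reward = cue + config.ra_duration_s
        end = reward + config.post_reward_s
        return {"cue": cue, "reward": reward, "gate_close": end, "trial_end": end}
    if outcome == "error" and config.immediate_feedback and wrong_lick_t is not None:
        cue = wrong_lick_t
    return {"cue": cue, "reward": None, "gate_close": cue, "trial_end": cue}


def update_reversal(block_outcomes: list[Outcome], config: TaskConfig) -> ReversalDecision:
    """Evaluate the two reversal conditions on the current block only.

    Reverses iff the block holds at least ``block_min_len`` trials and the
    hit fraction over the trailing ``criterion_window`` trials (the whole
    block when shorter) reaches ``criterion``. Misses count as non-hits.
    """
    n = len(block_outcomes)
    if n == 0:
        return ReversalDecision(reverse=False, window_perf=float("nan"))
    window = block_outcomes[-min(n, config.criterion_window):]
    perf = sum(1 for o in window if o == "hit") / len(window)
    return ReversalDecision(reverse=(n >= config.block_min_len and perf >= config.criterion), window_perf=perf)


def _other(side: Side) -> Side:
    return "right" if side == "left" else "left"


def run_session(config: TaskConfig, agent, max_trials: int = 200) -> SessionLog:
    """Simulate a full session driven by an agent policy.

    The agent is called once per trial opportunity with an
    :class:`~freilick.agents.Observation`; a ``no_entry`` action consumes
    the opportunity without producing a trial. Contingency flips when the
    reversal criterion fires and unfinished blocks remain. Reward on hits is
    delivered with probability ``reward_prob`` (outcome labels unaffected).
    Fully reproducible given (config, agent, seed).
    """
    from .agents import Observation  # local import to avoid a cycle

    if max_trials < 1:
        raise ParameterError("max_trials must be >= 1")
    rng = np.random.default_rng(config.seed)
    rewarded: Side = config.first_rewarded_spout
    trials: list[TrialRecord] = []
    reversals: list[int] = []
    block = 1
    block_outcomes: list[Outcome] = []
    t = 0.0
    prev: Optional[TrialRecord] = None
    for _ in range(max_trials):
        obs = Observation(
            trial_index=len(trials) + 1,
            block=block,
            prev_outcome=prev.outcome if prev else None,
            prev_cue=prev.cue_type if prev else None,
            prev_rewarded=prev.rewarded if prev else False,
            prev_side=prev.first_lick_side if prev else None,
            rewarded_spout=rewarded,
        )
        action = agent.act(obs)
        _validate_action(action, obs.trial_index)
        if action.kind == "no_entry":
            t += 1.0 + action.nose_poke_latency_s
            continue
        t_np = t + action.nose_poke_latency_s
        t_gate = t_np  # gate opens on the nose poke (stages 1-2: already open)
        if config.walk_timeout_s is not None and action.walk_s > config.walk_timeout_s:
            t += 1.0 + action.nose_poke_latency_s
            continue
        t_he = t_np + action.walk_s

        if action.kind == "lick":
            side: Optional[Side] = action.side
            if config.single_spout:
                side = rewarded  # only one spout is mounted
            latency: Optional[float] = action.lick_latency_s
        else:  # enter_no_lick
            side, latency = None, None
        outcome = classify_outcome(side, latency, rewarded, config)
        lick_t = t_he + latency if latency is not None else None
        wrong_lick_t = lick_t if outcome == "error" else None
        sched = schedule_trial_events(outcome, t_he, config, wrong_lick_t)
        got_reward = outcome == "hit" and bool(rng.random() < config.reward_prob)
        rec = TrialRecord(
            index=len(trials) + 1,
            block=block,
            rewarded_spout=rewarded,
            outcome=outcome,
            cue_type=CUE_HIT if outcome == "hit" else CUE_FAIL,
            t_nose_poke=t_np,
            t_gate_open=t_gate,
            t_head_entry=t_he,
            first_lick_side=side if latency is not None and latency < config.lr_duration_s else None,
            t_first_lick=lick_t if latency is not None and latency < config.lr_duration_s else None,
            t_cue=sched["cue"],
            t_reward=sched["reward"] if got_reward else None,
            t_gate_close=sched["gate_close"],
            t_trial_end=sched["trial_end"],
            rewarded=got_reward,
        )
        trials.append(rec)
        agent.learn(rec)
        block_outcomes.append(outcome)
        decision = update_reversal(block_outcomes, config)
        if decision.reverse and block < config.n_blocks:
            reversals.append(rec.index)
            rewarded = _other(rewarded)
            block += 1
            block_outcomes = []
        t = rec.t_trial_end
        prev = rec
    return SessionLog(config=config, trials=trials, reversal_trials=reversals, seed=config.seed)


def _validate_action(action, trial_index: int) -> None:
    kind = getattr(action, "kind", None)
    if kind not in ("lick", "enter_no_lick", "no_entry"):
        raise ProtocolError(f"trial {trial_index}: malformed action kind {kind!r}")
    for name in ("nose_poke_latency_s", "walk_s", "lick_latency_s"):
        v = getattr(action, name, None)
        if v is not None and v < 0:
            raise ProtocolError(f"trial {trial_index}: negative {name}")
    if kind == "lick" and getattr(action, "side", None) not in ("left", "right"):
        raise ProtocolError(f"trial {trial_index}: lick action without a valid side")


# --------------------------------------------------------------------------
# TTL export and session (de)serialization
# --------------------------------------------------------------------------

def export_ttl_map(log: SessionLog) -> pd.DataFrame:
    """Flatten a session into one timestamped row per physical event.

    Channels mirror the rig's TTL map: nose poke, gate, head entry, per-spout
    lick lines, cue, water. Rows are sorted by time.
    """
    rows: list[dict] = []

    def add(trial: int, block: int, channel: str, time_s: Optional[float], detail: str = "") -> None:
        if time_s is not None:
            rows.append({"trial": trial, "block": block, "event": channel,
                         "time_s": round(time_s, 3), "detail": detail})

    for tr in log.trials:
        add(tr.index, tr.block, "nose_poke", tr.t_nose_poke)
        add(tr.index, tr.block, "gate_open", tr.t_gate_open)
        add(tr.index, tr.block, "head_entry", tr.t_head_entry)
        if tr.t_first_lick is not None:
            add(tr.index, tr.block, f"lick_{tr.first_lick_side}", tr.t_first_lick)
        add(tr.index, tr.block, "cue", tr.t_cue, tr.cue_type)
        add(tr.index, tr.block, "water", tr.t_reward)
        add(tr.index, tr.block, "gate_close", tr.t_gate_close)
    df = pd.DataFrame(rows, columns=["trial", "block", "event", "time_s", "detail"])
    return df.sort_values(["time_s", "trial"], kind="stable").reset_index(drop=True)


def trials_frame(log: SessionLog) -> pd.DataFrame:
    """One row per trial with outcome, spout and all timestamps."""
    return pd.DataFrame([asdict(t) for t in log.trials])


def write_session(log: SessionLog, outdir: str | Path) -> None:
    """Write events.csv, trials.csv, config.json and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_ttl_map(log).to_csv(outdir / "events.csv", index=False)
    tf = trials_frame(log)
    for col in tf.columns:
        if col.startswith("t_"):
            tf[col] = tf[col].round(3)
    tf.to_csv(outdir / "trials.csv", index=False)
    (outdir / "config.json").write_text(json.dumps(asdict(log.config), indent=2))
    counts = {o: sum(1 for t in log.trials if t.outcome == o) for o in ("hit", "error", "miss")}
    summary = {"n_trials": len(log.trials), "outcomes": counts,
               "reversal_trials": log.reversal_trials, "seed": log.seed,
               "n_blocks_entered": log.n_blocks_entered}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def read_session(indir: str | Path) -> SessionLog:
    """Reconstruct a SessionLog from a directory written by write_session."""
    indir = Path(indir)
    config = TaskConfig(**json.loads((indir / "config.json").read_text()))
    summary = json.loads((indir / "summary.json").read_text())
    tf = pd.read_csv(indir / "trials.csv")
    trials = []
    for _, row in tf.iterrows():
        d = row.to_dict()
        for k, v in list(d.items()):
            if pd.isna(v):
                d[k] = None
        d["index"] = int(d["index"])
        d["block"] = int(d["block"])
        d["rewarded"] = bool(d["rewarded"])
        trials.append(TrialRecord(**d))
    return SessionLog(config=config, trials=trials,
                      reversal_trials=[int(i) for i in summary["reversal_trials"]],
                      seed=int(summary["seed"]))
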