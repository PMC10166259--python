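"""Agent policies standing in for the animal.

An agent receives an :class:`Observation` describing what the animal could
know (its previous choice, cue and reward — plus, for oracle agents used in
testing, the currently rewarded spout) and returns an :class:`AgentAction`.
All stochastic agents are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .task import Side, TrialRecord


@dataclass
class Observation:
    trial_index: int
    block: int
    prev_outcome: Optional[str]
    prev_cue: Optional[str]
    prev_rewarded: bool
    prev_side: Optional[Side]
    rewarded_spout: Side  # ground truth; only oracle agents may read this


@dataclass
class AgentAction:
    kind: str  # "lick" | "enter_no_lick" | "no_entry"
    side: Optional[Side] = None
    nose_poke_latency_s: float = 0.5
    walk_s: float = 0.5
    lick_latency_s: float = 0.3


class AgentPolicy:
    """Base policy; subclasses override :meth:`act` (and optionally learn)."""

    def act(self, obs: Observation) -> AgentAction:  # pragma: no cover - abstract
        raise NotImplementedError

    def learn(self, trial: TrialRecord) -> None:
        """Feedback hook called by the engine after each completed trial."""


def _draw_latencies(rng: np.random.Generator) -> dict[str, float]:
    """Trial-to-trial variable latencies: walking delays and lick latencies
    vary widely in real sessions, which is what lets event-aligned analyses
    tell the nose-poke, head-entry and reward periods apart."""
    return {
        "nose_poke_latency_s": float(rng.uniform(0.2, 1.0)),
        "walk_s": float(rng.uniform(0.3, 1.5)),
        "lick_latency_s": float(rng.uniform(0.1, 1.0)),
    }


class PerfectAgent(AgentPolicy):
    """Oracle agent: always licks the currently rewarded spout."""

    def __init__(self, seed: int = 0, **_: object) -> None:
        self._rng = np.random.default_rng(seed)

    def act(self, obs: Observation) -> AgentAction:
        return AgentAction(kind="lick", side=obs.rewarded_spout,
                           **_draw_latencies(self._rng))


class SideBiasedAgent(AgentPolicy):
    """Always licks one fixed spout regardless of feedback."""

    def __init__(self, side: Side = "left", seed: int = 0, **_: object) -> None:
        if side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        self.side = side
        self._rng = np.random.default_rng(seed)

    def act(self, obs: Observation) -> AgentAction:
        return AgentAction(kind="lick", side=self.side,
                           **_draw_latencies(self._rng))


class EpsilonRandomAgent(AgentPolicy):
    """Random explorer with optional no-entry / no-lick lapses.

    With probability ``epsilon`` the side is uniform random, otherwise the
    agent repeats its last rewarded side (falling back to uniform). With
    probabilities ``p_no_entry`` / ``p_no_lick`` the agent skips the trial
    opportunity or enters without licking, exercising miss outcomes.
    """

    def __init__(self, epsilon: float = 1.0, p_no_entry: float = 0.0,
                 p_no_lick: float = 0.0, seed: int = 0, **_: object) -> None:
        if not (0 <= epsilon <= 1):
            raise ParameterError("epsilon must lie in [0, 1]")
        self.epsilon = epsilon
        self.p_no_entry = p_no_entry
        self.p_no_lick = p_no_lick
        self._rng = np.random.default_rng(seed)
        self._last_rewarded_side: Optional[Side] = None

    def act(self, obs: Observation) -> AgentAction:
        u = self._rng.random()
        if u < self.p_no_entry:
            return AgentAction(kind="no_entry")
        if u < self.p_no_entry + self.p_no_lick:
            return AgentAction(kind="enter_no_lick")
        if self._rng.random() < self.epsilon or self._last_rewarded_side is None:
            side: Side = "left" if self._rng.random() < 0.5 else "right"
        else:
            side = self._last_rewarded_side
        return AgentAction(kind="lick", side=side, **_draw_latencies(self._rng))

    def learn(self, trial: TrialRecord) -> None:
        if trial.rewarded and trial.first_lick_side is not None:
            self._last_rewarded_side = trial.first_lick_side


class WSLSQLearner(AgentPolicy):
    """Win-stay/lose-shift flavored Q-learner over the two spouts.

    Side values are updated from reward feedback with learning rate
    ``alpha``: ``Q[side] += alpha * (r - Q[side])``. Action is greedy over Q
    with an ``epsilon`` exploration floor; ties break by seeded coin flip.
    A high alpha makes the agent switch within a few post-reversal errors.
    """

    def __init__(self, alpha: float = 0.5, epsilon: float = 0.05,
                 seed: int = 0, **_: object) -> None:
        if not (0 < alpha <= 1):
            raise ParameterError("alpha must lie in (0, 1]")
        self.alpha = alpha
        self.epsilon = epsilon
        self.q: dict[Side, float] = {"left": 0.5, "right": 0.5}
        self._rng = np.random.default_rng(seed)

    def act(self, obs: Observation) -> AgentAction:
        if self._rng.random() < self.epsilon:
            side: Side = "left" if self._rng.random() < 0.5 else "right"
        elif self.q["left"] == self.q["right"]:
            side = "left" if self._rng.random() < 0.5 else "right"
        else:
            side = "left" if self.q["left"] > self.q["right"] else "right"
        return AgentAction(kind="lick", side=side, **_draw_latencies(self._rng))

    def learn(self, trial: TrialRecord) -> None:
        side = trial.first_lick_side
        if side is None:
            return
        r = 1.0 if trial.rewarded else 0.0
        self.q[side] += self.alpha * (r - self.q[side])


_KINDS = {
    "perfect": PerfectAgent,
    "side_biased": SideBiasedAgent,
    "epsilon_random": EpsilonRandomAgent,
    "wsls_qlearner": WSLSQLearner,
}


def make_agent(kind: str, params: dict | None = None, seed: int = 0) -> AgentPolicy:
    """Construct one of the built-in policies by name."""
    if kind not in _KINDS:
        raise ParameterError(f"unknown agent kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](seed=seed, **(params or {}))
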