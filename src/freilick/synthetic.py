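"""Synthetic signal generators with known ground truth.

Every downstream module can be exercised without hardware: lick trains are
drawn from a refractory renewal process, strain-gauge traces superimpose
raised-cosine transients on a noisy drifting baseline, calcium traces place
difference-of-exponential transients locked to behavioral events, and frame
clocks emulate an imaging frame grid with dropped frames.

Defaults emulate the regime of the real rig: licking at ~10 Hz so that the
interlick interval distribution peaks near 100 ms, transient peaks of a few
hundred millivolts on the amplified strain-gauge channel, and a 20 Hz
miniscope frame clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .events import LickEventSeries
from .trace import SGTrace


@dataclass
class LickTrainSpec:
    """Parameters of the renewal-process lick train.

    Interlick intervals are ``refractory_s`` plus a Gamma-distributed
    residual (shape ``residual_shape``, mean chosen so the overall rate is
    ``rate_hz``). The peaked residual puts the interval mode above the
    refractory bound: at 10 Hz with a 60 ms refractory and shape 4 the mode
    sits near 100 ms, matching the empirical interlick-interval distribution
    of licking mice. ``residual_shape = 1`` recovers the memoryless
    refractory-plus-exponential process.
    """

    rate_hz: float = 10.0
    refractory_s: float = 0.06
    duration_s: float = 30.0
    amplitude_V: float = 0.3
    amplitude_cv: float = 0.2
    width_s: float = 0.12  # full support of the raised-cosine transient
    residual_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refractory_s <= 0:
            raise ParameterError("refractory_s must be positive")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.amplitude_V <= 0:
            raise ParameterError("amplitude_V must be positive")
        if self.rate_hz < 0:
            raise ParameterError("rate_hz must be non-negative")
        if self.residual_shape <= 0:
            raise ParameterError("residual_shape must be positive")
        if self.rate_hz > 0 and self.rate_hz * self.refractory_s >= 1.0:
            raise ParameterError(
                "rate_hz too high for the refractory period: "
                f"need rate_hz < 1/refractory_s = {1.0 / self.refractory_s:.3f} Hz"
            )


@dataclass
class NoiseSpec:
    """Additive Gaussian noise plus a linear baseline drift.

    The noise is band-limited at ``bandwidth_hz`` (the analog front end of a
    strain-gauge amplifier is not white out to arbitrary sampling rates);
    ``sigma_V`` is the standard deviation *after* band-limiting, so threshold
    crossing statistics do not depend on the simulation sampling rate. Set
    ``bandwidth_hz`` to ``None`` for white noise.
    """

    sigma_V: float = 0.01
    drift_V_per_s: float = 0.0
    baseline_V: float = 0.0
    bandwidth_hz: float | None = 500.0

    def __post_init__(self) -> None:
        if self.sigma_V < 0:
            raise ParameterError("sigma_V must be non-negative")
        if self.bandwidth_hz is not None and self.bandwidth_hz <= 0:
            raise ParameterError("bandwidth_hz must be positive or None")


@dataclass
class CalciumKernel:
    """Difference-of-exponentials indicator response.

    ``k(t) = peak_df * (exp(-t/decay_s) - exp(-t/rise_s)) / max`` for t >= 0.
    Rise must be faster than decay so the kernel is a unimodal transient.
    """

    rise_s: float = 0.1
    decay_s: float = 1.0
    peak_df: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_s <= 0:
            raise ParameterError("rise_s must be positive")
        if self.decay_s <= self.rise_s:
            raise ParameterError("decay_s must exceed rise_s")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel sampled at times ``t`` (seconds relative to event onset)."""
        t = np.asarray(t, dtype=float)
        raw = np.zeros_like(t)
        pos = t >= 0
        raw[pos] = np.exp(-t[pos] / self.decay_s) - np.exp(-t[pos] / self.rise_s)
        # analytic peak location of the double exponential
        t_peak = (
            self.rise_s
            * self.decay_s
            / (self.decay_s - self.rise_s)
            * np.log(self.decay_s / self.rise_s)
        )
        peak = np.exp(-t_peak / self.decay_s) - np.exp(-t_peak / self.rise_s)
        return self.peak_df * raw / peak


def interval_moments(spec: LickTrainSpec) -> tuple[float, float]:
    """Mean and variance of one interlick interval of the renewal process."""
    mean = 1.0 / spec.rate_hz
    resid = mean - spec.refractory_s
    return mean, resid**2 / spec.residual_shape


def gen_lick_train(spec: LickTrainSpec) -> LickEventSeries:
    """Draw a lick train from the refractory renewal process.

    Returns strictly increasing times in ``[0, duration_s]`` whose successive
    differences are all >= ``refractory_s``. Deterministic given ``spec.seed``.
    """
    if spec.rate_hz == 0:
        return LickEventSeries(times_s=np.empty(0), source="ground_truth")
    rng = np.random.default_rng(spec.seed)
    mean_resid = 1.0 / spec.rate_hz - spec.refractory_s
    k = spec.residual_shape
    theta = mean_resid / k

    def residual() -> float:
        return float(rng.gamma(k, theta))

    times: list[float] = []
    t = residual()  # first event needs no refractory wait
    while t <= spec.duration_s:
        times.append(t)
        t += spec.refractory_s + residual()
    return LickEventSeries(times_s=np.array(times), source="ground_truth")


def raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unimodal raised-cosine bump of unit peak and full support ``width``."""
    tau = np.asarray(t, dtype=float) - center
    out = np.zeros_like(tau)
    mask = np.abs(tau) <= width / 2
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * tau[mask] / width))
    return out


def gen_sg_trace(
    licks: LickEventSeries,
    kernel_width_s: float = 0.12,
    amplitude_V: float = 0.3,
    noise: NoiseSpec | None = None,
    fs_hz: float = 10_000.0,
    duration_s: float | None = None,
    amplitude_cv: float = 0.0,
    seed: int = 0,
) -> SGTrace:
    """Render a strain-gauge voltage trace from a lick train.

    Each lick contributes one raised-cosine transient centered at its time;
    per-lick peak heights are Gamma-distributed with mean ``amplitude_V`` and
    coefficient of variation ``amplitude_cv``. Gaussian noise, baseline offset
    and linear drift come from ``noise``.
    """
    if noise is None:
        noise = NoiseSpec()
    if fs_hz <= 2.0 / kernel_width_s:
        raise ParameterError(
            f"fs_hz={fs_hz} too low to resolve transients of width {kernel_width_s}s"
        )
    if duration_s is None:
        last = licks.times_s[-1] if len(licks) else 0.0
        duration_s = last + kernel_width_s + 1.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    sig = np.full(n, noise.baseline_V, dtype=float)
    sig += noise.drift_V_per_s * t
    if amplitude_cv > 0:
        shape = 1.0 / amplitude_cv**2
        amps = rng.gamma(shape, amplitude_V / shape, size=len(licks))
    else:
        amps = np.full(len(licks), amplitude_V)
    half = kernel_width_s / 2
    for t_lick, amp in zip(licks.times_s, amps):
        lo = max(0, int(np.floor((t_lick - half) * fs_hz)))
        hi = min(n, int(np.ceil((t_lick + half) * fs_hz)) + 1)
        sig[lo:hi] += amp * raised_cosine(t[lo:hi], t_lick, kernel_width_s)
    if noise.sigma_V > 0:
        eps = rng.normal(0.0, 1.0, size=n)
        if noise.bandwidth_hz is not None and noise.bandwidth_hz < fs_hz / 2:
            from scipy import signal as _signal

            sos = _signal.butter(4, noise.bandwidth_hz, fs=fs_hz, output="sos")
            eps = _signal.sosfiltfilt(sos, eps)
            eps = eps / eps.std()  # sigma_V is the post-filter scale
        sig += noise.sigma_V * eps
    return SGTrace(samples=sig, fs_hz=fs_hz, t0_s=0.0)


def gen_validation_scene(
    n_licks: int = 200,
    rate_hz: float = 5.0,
    refractory_s: float = 0.15,
    amplitude_V: float = 0.3,
    amplitude_cv: float = 0.2,
    noise_sigma_V: float = 0.03,
    lead_in_s: float = 2.0,
    fs_hz: float = 10_000.0,
    seed: int = 0,
) -> tuple[LickEventSeries, SGTrace]:
    """Standard detector-validation fixture: a lick train plus its trace.

    Defaults give well-separated licks (>= 150 ms spacing) at a peak
    signal-to-noise ratio of 10, preceded by ``lead_in_s`` of lick-free
    baseline so the online comparator can estimate its reference level from
    quiet signal — as on the rig, where thresholds are set while the animal
    is not licking.
    """
    duration = n_licks / rate_hz * 1.3 + 2.0
    spec = LickTrainSpec(rate_hz=rate_hz, refractory_s=refractory_s,
                         duration_s=duration, amplitude_V=amplitude_V,
                         amplitude_cv=amplitude_cv, seed=seed)
    licks = gen_lick_train(spec)
    times = licks.times_s[:n_licks] + lead_in_s
    licks = LickEventSeries(times_s=times, source="ground_truth")
    trace = gen_sg_trace(licks, kernel_width_s=spec.width_s,
                         amplitude_V=amplitude_V,
                         noise=NoiseSpec(sigma_V=noise_sigma_V),
                         fs_hz=fs_hz, amplitude_cv=amplitude_cv, seed=seed + 1)
    return licks, trace


@dataclass
class SyntheticCalcium:
    """Generated trace matrix plus its ground truth.

    ``locked`` flags which units carry event-locked transients; ``unit_events``
    gives each locked unit's assigned event times.
    """

    traces: np.ndarray  # units x frames
    frame_ts: np.ndarray
    locked: np.ndarray  # bool per unit
    unit_events: list[np.ndarray]


def gen_calcium_traces(
    events: Sequence[float] | np.ndarray,
    kernel: CalciumKernel,
    locked_fraction: float = 0.3,
    noise_sigma: float = 1.0,
    frame_ts: np.ndarray | None = None,
    n_units: int = 20,
    jitter_s: float = 0.0,
    seed: int = 0,
) -> SyntheticCalcium:
    """Generate a units x frames denoised-trace matrix with known locking.

    The first ``round(locked_fraction * n_units)`` units carry one kernel
    transient per event (optionally jittered); the rest are pure Gaussian
    noise. Ground-truth labels are returned alongside the matrix.
    """
    if frame_ts is None:
        raise ParameterError("frame_ts is required")
    frame_ts = np.asarray(frame_ts, dtype=float)
    if frame_ts.size == 0:
        raise ParameterError("frame_ts must be non-empty")
    if np.any(np.diff(frame_ts) <= 0):
        raise ParameterError("frame_ts must be strictly increasing")
    events = np.asarray(events, dtype=float)
    rng = np.random.default_rng(seed)
    n_locked = int(round(locked_fraction * n_units))
    traces = rng.normal(0.0, noise_sigma, size=(n_units, frame_ts.size)) if noise_sigma > 0 else np.zeros((n_units, frame_ts.size))
    locked = np.zeros(n_units, dtype=bool)
    locked[:n_locked] = True
    unit_events: list[np.ndarray] = []
    for u in range(n_units):
        if not locked[u]:
            unit_events.append(np.empty(0))
            continue
        ev = events.copy()
        if jitter_s > 0:
            ev = ev + rng.normal(0.0, jitter_s, size=ev.size)
        unit_events.append(ev)
        for e in ev:
            traces[u] += kernel.evaluate(frame_ts - e)
    return SyntheticCalcium(
        traces=traces, frame_ts=frame_ts, locked=locked, unit_events=unit_events
    )


def gen_modulation_scene(
    n_units: int = 30,
    locked_fraction: float = 0.3,
    peak_over_noise: float = 8.0,
    n_trials: int = 40,
    frame_rate_hz: float = 20.0,
    noise_sigma: float = 1.0,
    jitter_s: float = 0.05,
    seed: int = 0,
):
    """Simulated session plus calcium traces with known modulation labels.

    Runs the task with the oracle agent so every trial carries nose-poke,
    head-entry and reward events, then builds a trace matrix in which the
    locked units split evenly among the three classes — transients at the
    nose poke (initiation), head entry (licking) or reward (postlick) — and
    the remaining units are pure noise.

    Returns ``(log, trace_set, labels)`` where labels are the ground-truth
    class per unit.
    """
    from .agents import make_agent
    from .modulation import CalciumTraceSet
    from .task import TaskConfig, run_session

    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_blocks=1, seed=seed)
    log = run_session(cfg, make_agent("perfect", seed=seed), max_trials=n_trials)
    event_times = {
        "initiation": np.array([t.t_nose_poke for t in log.trials]),
        "licking": np.array([t.t_head_entry for t in log.trials]),
        "postlick": np.array([t.t_reward for t in log.trials if t.t_reward is not None]),
    }
    duration = log.trials[-1].t_trial_end + 5.0
    frame_ts = gen_frame_clock(frame_rate_hz, int(duration * frame_rate_hz))
    kernel = CalciumKernel(rise_s=0.1, decay_s=0.6,
                           peak_df=peak_over_noise * max(noise_sigma, 1e-12))
    n_locked = int(round(locked_fraction * n_units))
    labels = []
    traces = rng.normal(0.0, noise_sigma, size=(n_units, frame_ts.size))
    class_cycle = ("initiation", "licking", "postlick")
    for u in range(n_units):
        if u >= n_locked:
            labels.append("unmodulated")
            continue
        lab = class_cycle[u % 3]
        labels.append(lab)
        ev = event_times[lab]
        if jitter_s > 0:
            ev = ev + rng.normal(0.0, jitter_s, size=ev.size)
        for e in ev:
            traces[u] += kernel.evaluate(frame_ts - e)
    return log, CalciumTraceSet(traces=traces, frame_ts=frame_ts), labels


def gen_frame_clock(
    nominal_rate_hz: float, n_frames: int, dropped_idx: Iterable[int] = ()
) -> np.ndarray:
    """Nominal frame-time grid with the listed frame indices removed."""
    dropped = set(int(i) for i in dropped_idx)
    if any(i < 0 or i >= n_frames for i in dropped):
        raise ParameterError("dropped_idx must lie in [0, n_frames)")
    grid = np.arange(n_frames) / nominal_rate_hz
    keep = np.array([i not in dropped for i in range(n_frames)])
    return grid[keep]
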