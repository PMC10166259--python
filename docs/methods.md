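# Methods

## Synthetic signal models

**Lick trains** are drawn from a refractory renewal process: each interlick
interval is `refractory_s` (default 60 ms) plus a Gamma-distributed residual
with shape 4 and mean set so the overall rate equals `rate_hz`. A peaked
residual was chosen over an exponential one because an exponential puts the
interval mode exactly at the refractory bound, whereas real interlick
intervals peak near 100 ms at ~10 Hz licking; shape 4 reproduces that mode
while keeping a two-parameter process (shape 1 recovers the memoryless
variant). The analytic mean/variance of the interval distribution gives a
closed-form counting oracle used in the tests.

**Strain-gauge transients** are raised-cosine bumps (unimodal, compact
support, analytic peak) of full width 120 ms (60 ms at half height — above
the detector's 50 ms width floor, as the mechanical response of a sprung
spout outlasts tongue contact). Per-lick peak heights are Gamma-distributed
with mean `amplitude_V` (default 0.3 V) and a configurable coefficient of
variation; no measured amplitude distribution is available for real licks,
so these defaults are placeholders exposed in the spec of every generator
call. Additive Gaussian noise is band-limited at 500 Hz before scaling so
that `sigma_V` is the delivered noise standard deviation and comparator
threshold-crossing statistics do not depend on the simulation sampling
rate; white noise at an arbitrary `fs` would make online-detector behavior
an artifact of the discretization. A linear drift term and baseline offset
are available.

**Calcium transients** use a difference-of-exponentials kernel (rise
100 ms, decay 600 ms by default), the standard minimal indicator model,
normalized to a specified peak. Event-locked units receive one transient
per assigned behavioral event with optional Gaussian timing jitter (50 ms in
the standard scene); unlocked units are pure Gaussian noise. The generator
does not model spike-to-fluorescence nonlinearity, neuropil, or correlated
noise, so passing recovery tests demonstrates the correctness of the
alignment/averaging/thresholding logic, not performance on real imaging
data.

**Frame clocks** are uniform grids with listed indices removed, the ground
truth for the frame-loss estimator.

**Standard scenes.** `gen_validation_scene` (200 licks at >= 150 ms
spacing, peak SNR 10, 2 s lick-free lead-in so the comparator can estimate
baseline from quiet signal) and `gen_modulation_scene` (30 units, 30%
locked, peaks 8x the noise scale, 40 oracle-agent trials at a 20 Hz frame
clock) fix the conditions used by the acceptance checks.

## Lick detection

Offline: polyphase FIR resampling to 1 kHz with line-extension padding
(zero-phase, so peak times are unbiased and constant baselines survive the
edges), then a forward-backward 4th-order Butterworth at 64 Hz, then
`scipy.signal.find_peaks` with distance 60 ms, prominence 0.015 (treated as
volts of the amplified signal and exposed in config) and width 50 ms at
half prominence.

Online: baseline is the median of the leading 2 s window; the comparator
fires on upward crossings of baseline + threshold (default 100 mV) and
re-arms when the signal falls below baseline + threshold/2. The hysteresis
fraction is a design choice — the original analog circuit's re-arm behavior
is not documented — and with realistic noise the emulator double-fires on
transient flanks at low thresholds, which is exactly the regime where the
hardware's PPV degrades.

**Matching** is optimal one-to-one matching (maximum cardinality, then
minimum total delay) via the rectangular assignment problem, with a pair
feasible when its delay is strictly below the 60 ms tolerance. A greedy
closest-pair-first matcher was considered and rejected: it is not
cardinality-optimal (detected {0, 0.5} vs truth {0.4, 1.4} at tolerance 1.0
yields one greedy pair but two optimal ones), and the tests compare against
an exhaustive search oracle. Undefined sensitivity/PPV (zero denominator)
is reported as NaN, never 0.

## Task engine

Outcomes follow the first lick inside the licking-response window; later
licks are ignored (multi-lick trials are not otherwise distinguished).
Misses count as non-hits in the criterion window. The reversal criterion is
evaluated over the current block only and the window resets at each flip,
so pre-reversal hits can never satisfy the post-reversal criterion; when
the block is shorter than the 15-trial window the whole block is used, but
the 15-trial length gate still applies. With probabilistic reward only
water delivery is stochastic — outcome labels and cues are unchanged — and
`reward_prob = 1` reproduces the deterministic task bit-for-bit at the same
seed. Training stages 1–3 mount a single spout (errors impossible); stage 4
introduces both spouts with optional immediate error feedback. Walking
delay has no timeout unless configured. Time is continuous float seconds;
logs serialize at millisecond precision with 1-based trial and block
indices. Agent latencies (nose-poke, walking, lick) are drawn per trial
from uniform distributions (0.2–1.0, 0.3–1.5, 0.1–1.0 s): variable walking
delays are what make the three event alignments separable downstream, as
they are in real sessions.

## Session analysis

The displayed performance curve uses trailing windows truncated at the
block start (plotting convention); `trials_to_criterion` requires a full
5-trial window, so a block shorter than the window reports the not-reached
sentinel (−1). Both behaviors are deliberate and documented because they
answer different questions (what the curve shows vs when learning is
declared).

## Modulation analysis

The normalize-then-average reading is used: each unit's full trace is
converted to a robust z-score `(x − median)/MAD` (raw MAD, no 0.6745
consistency constant) before event-triggered averaging, which makes the
"3x MAD" threshold well-defined on the averaged waveform. Units with zero
MAD are excluded, not imputed. Because the walking-delay duration varies
per trial, classes are assigned by peak competition across three fixed
alignments (nose poke, head entry, reward) instead of time-warping; the
peak is taken over non-negative lags of the default −1 s to +2 s window,
and the class is the period of the maximal peak. Events are snapped to the
nearest frame with ties to the earlier frame; events outside the frame
span, and windows that leave the recording, are skipped and counted.
Averaging n events shrinks the noise floor by ~sqrt(n), so with >= 40
events a 3x-MAD threshold sits far above the noise peak distribution —
the false-positive control the tests verify by Monte Carlo.

Frame loss counts, per inter-frame gap, `round(gap/period) − 1` missing
frames and reports `100 * lost / (observed + lost)`.

## Commutator

The sensor response is an idealized bipolar Hall output, `cos(angle −
position_i)`; the transfer function of the physical sensors is not
documented, and any monotone odd periodic response decodes identically
after the phasor combination `sum_i r_i · e^{i phi_i} = (3/2) e^{i theta}`.
Sector boundaries sit at 60-degree multiples; the decision matrix is the
shortest-signed-displacement rule quantized to one sector per update
(entries reconstructed from that principle, not transcribed from a
schematic), with an indeterminate decode holding the motor. Motor dynamics
are idealized as instantaneous. Per-step rotations of 60 degrees or more
alias and are flagged in the log. Noise on the readings perturbs the
decoded phasor angle but the loop is self-correcting because decoding acts
on the absolute relative angle: a spurious sector step shifts the relative
angle by one sector, which the next decode undoes.

## Problem sizes and numerical choices

Test and acceptance runs use 40–200 licks, 30–45-trial sessions, 30-unit
trace matrices at 20 Hz, 500 randomized sessions for the invariant sweep,
1,000 random matching instances for the oracle comparison, and 4,000-step
commutator trajectories — sizes at which every analytic or brute-force
oracle is exact and the full suite runs in a few seconds. Filtering edge
regions are excluded from amplitude assertions; matching feasibility is a
strict inequality; assignment infeasibility uses a cost large enough that
cardinality always dominates total delay.

## Known limitations

Animal-derived figures (detector sensitivity/PPV on video-annotated
recordings, per-mouse trials to criterion, hardware frame-loss and latency
measurements) require the original recordings or hardware and are outside
what synthetic validation can establish. The generators are deliberately
minimal: no tongue kinematics, no electrode/mechanical artifacts, no
correlated imaging noise, symbolic audio cues, and no real-time execution
or serial-port control.
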