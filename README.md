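# freilick

A hardware-free Python toolbox for the computational core of a low-cost
freely-moving mouse behavioral platform built around a strain-gauge (SG)
lickometer: lick detection and detector validation, a directional-licking
discriminative/serial-reversal task engine, session performance analysis,
event-aligned calcium-trace modulation classification, and a simulator of
the Hall-sensor ring commutator that keeps the animal's tether cable
untwisted. Every input the pipelines need can be generated synthetically
with known ground truth, so the whole stack is testable on a desk.

It is aimed at behavioral neurophysiologists who run (or build) operant
licking rigs and want the analysis and control logic as an importable,
tested library rather than firmware and one-off scripts.

## What it computes

**Lick detection.** The amplified SG voltage is antialias-downsampled to
1 kHz and zero-phase low-pass filtered at 64 Hz; individual licks are
extracted as peaks with a minimal peak distance of 60 ms, minimal prominence
of 0.015 V and minimal width of 50 ms at half prominence. An online
comparator emulation raises one TTL onset per upward crossing of a
threshold set 100 mV above baseline (with hysteresis re-arm at half the
threshold). Detected licks are matched one-to-one against ground truth with
a 60 ms tolerance, giving TP/FP/FN counts and

    Sensitivity = TP / (TP + FN),     PPV = TP / (TP + FP).

A threshold sweep reproduces the sensitivity/PPV trade-off of lowering the
comparator reference voltage.

**Task engine.** A discrete-event finite-state machine of the two-spout
directional licking task: nose poke opens the gate, the animal walks to the
licking chamber, and its first lick within the 2 s licking-response window
decides the outcome (hit / error / miss). Hits earn a 5 kHz tone, a 1 s
reward-anticipation period, water, and a 4 s post-reward interval; errors
and misses earn white noise and gate closure. The rewarded spout reverses
when the current block has at least 15 trials *and* at least 70% hits over
the trailing 15-trial window; block count and reward probability are
configurable (serial and probabilistic reversal). Sessions are driven by
pluggable agent policies (oracle, side-biased, epsilon-random, Q-learner).

**Session analysis.** Moving-average (window 5) block performance curves,
trials-to-criterion at 70% correct over a full 5-trial sliding window, and
per-block reversal summaries.

**Neural modulation.** Behavioral events are aligned to the nearest imaging
frame; denoised calcium traces are normalized by their raw median absolute
deviation (MAD); per-unit event-triggered averages are computed for three
alignments (nose poke, head entry, reward). A unit is *modulated* when an
averaged peak reaches 3x MAD and is classed as an initiation, licking or
postlick neuron by the period of its maximal peak. Frame loss is quantified
from frame-clock gaps.

**Commutator.** Three Hall sensors 120 degrees apart read a magnet on the
tether cable; combining the three cosine direction fields decodes the
magnet orientation among 6 radial positions, and a shortest-displacement
decision matrix commands a stepper motor one sector at a time, bounding
cable twist to ~60 degrees.

## Worked example

```python
import numpy as np
from freilick import (gen_validation_scene, detect_licks_offline, match_licks,
                      confusion_metrics, TaskConfig, run_session, make_agent,
                      reversal_summary)

# 200 synthetic licks (>=150 ms apart) on a noisy strain-gauge trace, SNR 10
licks, trace = gen_validation_scene(n_licks=200, seed=0)
det = detect_licks_offline(trace)
m = match_licks(det, licks)
print(f"detected {len(det)} of {len(licks)} licks: TP={m.tp} FP={m.fp} FN={m.fn}")
print({k: round(v, 3) for k, v in confusion_metrics(m).items()})

# a learning agent working through a 3-block serial-reversal session
log = run_session(TaskConfig(n_blocks=3, seed=0),
                  make_agent("wsls_qlearner", {"alpha": 0.7}, seed=0),
                  max_trials=120)
print("reversals at trials:", log.reversal_trials)
print(reversal_summary(log).to_string(index=False))
```

prints

```
detected 201 of 200 licks: TP=200 FP=1 FN=0
{'sensitivity': 1.0, 'ppv': 0.995}
reversals at trials: [15, 30]
 block  length  trials_to_criterion  hits  errors  misses
     1      15                    5    14       1       0
     2      15                    6    13       2       0
     3      90                    6    87       3       0
```

The offline pipeline recovers all 200 constructed licks with a single false
positive (sensitivity 1.0, PPV 0.995). The Q-learning agent reaches the
70%-of-15 criterion at the earliest possible trial in each block, so the
contingency flips at trials 15 and 30; `trials_to_criterion` is the
5-trial-window learning measure per block.

The same operations are available from a shell: `freilick detect`,
`validate`, `sweep`, `simulate`, `analyze`, `modulation`, `commutator`
(see `freilick --help`).

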