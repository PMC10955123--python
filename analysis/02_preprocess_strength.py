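#!/usr/bin/env python
"""Preprocess the simulated strength trial and summarize torque.

Reads the raw trial written by 01_simulate_trials.py, applies the 6 Hz
zero-lag Butterworth filter, cuts repetitions by movement direction,
extracts each repetition's isokinetic phase (|v| within 10% of 30 deg/s),
and reports peak/mean torque (absolute and per kg) plus the 101-node
normalized curve, written to results/.
"""

from pathlib import Path

import numpy as np

from ecctrain import io
from ecctrain.isokin import (
    extract_isokinetic_phase,
    filter_trial,
    segment_repetitions,
    to_normalized_curve,
)
from ecctrain.strength import aggregate_repetitions, torque_summary

OUT = Path("results")
trial = io.read_trial_csv(OUT / "trials" / "S001_ecc30_pre.csv")
mass = trial.meta["body_mass"]

filtered = filter_trial(trial)
segments = [s for s in segment_repetitions(filtered) if s.direction == "external"]
print(f"{len(segments)} external-rotation repetitions")

summaries, curves = [], []
for k, seg in enumerate(segments):
    phase = extract_isokinetic_phase(seg, target_speed=30.0)
    peak, mean = torque_summary(phase)
    summaries.append((peak, mean))
    print(f"  rep {k + 1}: isokinetic phase {len(phase)} samples at "
          f"{phase.achieved_speed:.1f} deg/s, peak {peak:.2f} Nm, "
          f"mean {mean:.2f} Nm")
    curve = to_normalized_curve(phase, 101, body_mass=mass)
    curve.meta.update(subject="S001", group="intervention", time="pre",
                      mode="eccentric", speed=30)
    curves.append(curve)

peak, mean = aggregate_repetitions(summaries)
print(f"subject summary: peak {peak:.2f} Nm ({peak / mass:.4f} Nm/kg), "
      f"mean {mean:.2f} Nm ({mean / mass:.4f} Nm/kg)")
io.write_curves_tsv(curves, OUT / "S001_ecc30_pre_curves.tsv")
print(f"wrote {len(curves)} normalized 101-node curves")
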