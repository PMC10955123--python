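#!/usr/bin/env python
"""Simulate one subject's dynamometer session and write the raw trials.

Generates an eccentric strength trial (3 repetitions, 30 deg/s, 150 deg
amplitude) and a passive internal-rotation ROM test (10 stretch cycles at
10 deg/s with the 9 Nm reversal rule), then writes both as CSV under
results/trials/. Prints the ground truth the later stages should recover.
"""

from pathlib import Path

from ecctrain import io
from ecctrain.synth import TrialSpec, simulate_active_trial, simulate_passive_trial

OUT = Path("results/trials")
OUT.mkdir(parents=True, exist_ok=True)

active_spec = TrialSpec(
    mode="eccentric", direction="external", target_speed=30.0,
    rom_start=-60.0, rom_end=90.0, accel_time=0.2,
    noise_sd_torque=0.5, seed=42,
)
trial, truth = simulate_active_trial(
    active_spec, peak_torque=39.6, optimum_angle=20.0, n_reps=3
)
trial.meta.update(subject="S001", body_mass=84.8)
io.write_trial_csv(trial, OUT / "S001_ecc30_pre.csv")
print(f"active trial: {len(trial)} samples, "
      f"plateau {truth['plateau_duration_s']:.3f} s per repetition, "
      f"true peak {truth['peak_torque']} Nm at {truth['optimum_angle']} deg")

passive_spec = TrialSpec(
    mode="passive", direction="internal", target_speed=10.0,
    rom_start=0.0, rom_end=100.0, noise_sd_torque=0.1, seed=43,
)
ptrial, ptruth = simulate_passive_trial(
    passive_spec, stiffness_params=(0.5, 0.05, 0.0), n_cycles=10
)
ptrial.meta.update(subject="S001", body_mass=84.8)
io.write_trial_csv(ptrial, OUT / "S001_passive_pre.csv")
print(f"passive trial: {ptruth['n_cycles']} cycles, "
      f"true reversal at {ptruth['reversal_angle']:.2f} deg "
      f"(9 Nm criterion)")
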