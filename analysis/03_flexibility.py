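#!/usr/bin/env python
"""Passive flexibility analysis of the simulated ROM test.

Averages the stretch phases of the passive trial, fits the three-parameter
exponential T(theta) = a*exp(b*theta) + c, and derives maximal ROM (9 Nm
criterion, 100 deg cap) and submaximal ROM (4.5 Nm). Compares against the
generator's analytic reversal angle. Writes results/passive_fit.json.
"""

from pathlib import Path

from ecctrain import io
from ecctrain.flex import average_passive_trials, fit_efunction, with_rom
from ecctrain.isokin import filter_trial, segment_repetitions

OUT = Path("results")
trial = io.read_trial_csv(OUT / "trials" / "S001_passive_pre.csv")

stretches = [
    (s.angle, s.torque)
    for s in segment_repetitions(filter_trial(trial))
    if s.direction == "external"          # the stretch (loading) limbs
]
print(f"{len(stretches)} stretch phases averaged")
angle, torque = average_passive_trials(stretches, n_expected=5)

fit = with_rom(fit_efunction(angle, torque), threshold=9.0,
               sub_threshold=4.5, angle_cap=100.0)
print(f"fit: a={fit.a:.4f} Nm, b={fit.b:.5f} 1/deg, c={fit.c:.4f} Nm, "
      f"rmse={fit.rmse:.4f} Nm (converged={fit.converged})")
print(f"maximal ROM (9 Nm): {fit.rom_max:.2f} deg   "
      f"submaximal ROM (4.5 Nm): {fit.rom_sub:.2f} deg")

io.dump_json(
    {"a": fit.a, "b": fit.b, "c": fit.c, "rmse": fit.rmse,
     "rom_max_deg": fit.rom_max, "rom_sub_deg": fit.rom_sub},
    OUT / "passive_fit.json",
)
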