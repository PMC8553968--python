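"""Sensor noise and prior width both reshape the adaptation time course.

Part 1 sweeps the sensor-noise power during a gentle roll-tilt transition:
noisier sensors yield weaker per-sample evidence (the filter's reliability
weighting tracks the noise), delaying adaptation onset.

Part 2 compares a direct 1.2 -> 0.5 g transition against the same transition
after oscillating "training" gravity levels that widen the posterior:
the trained system starts adapting immediately but takes longer to converge.
"""

import vestadapt as va
from vestadapt.scenarios import NOISE_SWEEP_POWERS

print("-- sensor noise (roll tilt 15 deg, 0.125 Hz; 1 -> 0.5 g) --")
print(f"{'noise power':>12} {'initiation (s)':>15}")
for power in NOISE_SWEEP_POWERS:
    name = f"fig7_p{power:.0e}".replace("e-0", "e-")
    summary = va.run(va.SimulationConfig(scenario=name, seed=1)).summary
    print(f"{power:>12.0e} {summary['initiation_time']:>15.1f}")

print("\n-- prior width (roll tilt 30 deg, 0.25 Hz; ... -> 0.5 g) --")
print(f"{'scenario':>12} {'initiation (s)':>15} {'convergence (s)':>16}")
for name in ("fig6_direct", "fig6_learned"):
    summary = va.run(va.SimulationConfig(scenario=name, seed=1)).summary
    label = name.split("_")[1]
    print(
        f"{label:>12} {summary['initiation_time_nominal']:>15.1f} "
        f"{summary['convergence_time']:>16.1f}"
    )

print(
    "\nHigher noise powers slow adaptation initiation monotonically."
    "\nThe learned scenario's widened posterior keeps its estimate off the"
    "\ntrained 1.2 g level, so it departs immediately (initiation 0) yet"
    "\nconverges later than the direct transition -- early start, slow finish."
)
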