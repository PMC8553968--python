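"""A full gravity-transition experiment: 1 g to 0.5 g under roll tilt.

Runs the canonical preset (sinusoidal head-centred roll tilt, 30 deg at
0.25 Hz; twenty gravity hypotheses 0.1-2.0 g; sensor-noise power 1e-8) and
prints how the central (MMSE) gravity estimate and tilt perception evolve.
"""

import numpy as np

import vestadapt as va

result = va.run(va.SimulationConfig(scenario="fig3", seed=1))
s = result.summary
t_tr = s["transition_time"]

print(f"gravity drops 1 g -> 0.5 g at t = {t_tr:.0f} s")
print(f"{'t (s)':>7} {'true g':>7} {'MMSE g':>7} {'top hypothesis':>15}")
for t_query in (t_tr - 50, t_tr + 30, t_tr + 100, t_tr + 250, result.t[-1] - 1):
    k = int(np.argmin(np.abs(result.t - t_query)))
    top = result.hypotheses[np.argmax(result.posterior[k])]
    print(
        f"{result.t[k]:>7.0f} {result.g_level_true[k]:>7.2f} "
        f"{result.mmse[k]:>7.3f} {top:>13.1f} g"
    )

print(f"\ninitiation {s['initiation_time']:.1f} s after the transition")
print(f"convergence {s['convergence_time']:.1f} s after the transition")
print(f"plateau estimate {s['plateau_mmse']:.3f} g (true 0.5 g)")

amp = np.deg2rad(30)
pre = va.perception_error(result, "tilt", (t_tr - 44, t_tr - 4))
mid = va.perception_error(result, "tilt", (t_tr + 80, t_tr + 120))
post = va.perception_error(result, "tilt", (result.t[-1] - 40, result.t[-1]))
print(
    f"\ntilt RMS error: pre {100*pre/amp:.1f}%  mid-adaptation "
    f"{100*mid/amp:.1f}%  post {100*post/amp:.1f}% of the 30 deg amplitude"
)
print(
    "\nThe estimate departs sigmoidally, the posterior passes through a"
    "\nbimodal shape, and tilt is misperceived only while the internal"
    "\nmagnitude of gravity is in transit between the two levels."
)
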