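"""Static roll-tilt perception of a single vestibular observer.

Builds one observer whose internal gravity magnitude is held at 1 g, exposes
it to a static 30-degree roll in hypo-, normal and hyper-gravity, and prints
the perceived tilt once the estimator has settled.
"""

import numpy as np
from scipy.spatial.transform import Rotation

import vestadapt as va

params = va.ObserverParams()
print(f"utricular-plane otolith weight w = {params.w_util}")
print(f"{'true g-level':>12} {'true tilt':>10} {'perceived':>10}")

for g_level in (0.5, 1.0, 1.5):
    g_head = Rotation.from_euler("x", 30, degrees=True).apply([0, 0, g_level * va.G0])
    afference = va.Afference(alpha_oto=g_head, alpha_scc=np.zeros(3))
    state = va.ObserverState.initial(np.asarray(1.0))  # internal magnitude: 1 g
    for _ in range(6000):  # 300 s, well past every observer time constant
        state, _ = va.observer_step(state, afference, params, dt=0.05)
    tilt = np.degrees(va.perceived_tilt(state))
    print(f"{g_level:>10.1f} g {30.0:>9.1f}° {tilt:>9.1f}°")

print(
    "\nWith the internal gravity magnitude stuck at 1 g, tilt is perceived"
    "\nveridically in 1 g, overestimated in hyper-gravity and underestimated"
    "\nin hypo-gravity -- the misperception pattern reported in altered-"
    "\ngravity psychophysics, produced by the utricular/saccular weighting."
)
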