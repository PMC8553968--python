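"""Summary metrics for adaptation traces and perception errors.

Operationalises "when does adaptation start" and "when has it converged" for
a central-estimate trace, and the RMS perception error of a percept channel
over a time window.  Defaults: half a grid step (0.05 g) for both the
initiation departure and the convergence band, since 0.1 g is the natural
resolution of the default hypothesis grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: sentinel returned when a trace never initiates/converges (distinct from an
#: error: the computation succeeded, the event just never happened)
NOT_CONVERGED = math.inf


@dataclass
class AdaptationTrace:
    """Central gravity-estimate trace, optionally with posterior history."""

    times: np.ndarray               # (N,) s, strictly increasing
    mmse: np.ndarray                # (N,) g units
    posterior_history: np.ndarray | None = None  # (N, m)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mmse = np.asarray(self.mmse, dtype=float)
        if len(self.times) != len(self.mmse):
            raise ValueError("times and mmse must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def convergence_time(
    trace: AdaptationTrace,
    transition_time: float,
    target: float,
    tol: float = 0.05,
    hold: float = 0.0,
) -> float:
    """Time (relative to the transition) to settle within ``tol`` of ``target``.

    The first post-transition time after which ``|mmse - target| < tol``
    holds continuously for ``hold`` seconds.  Returns :data:`NOT_CONVERGED`
    if no such time exists within the trace (the hold window must fit).
    """
    t = trace.times
    if len(t) == 0 or t[-1] < transition_time:
        raise ValueError("trace must span past the transition time")
    sel = t >= transition_time
    ts = t[sel]
    within = np.abs(trace.mmse[sel] - target) < tol
    return _first_sustained(ts, within, hold) - transition_time if np.any(within) else NOT_CONVERGED


def _first_sustained(ts: np.ndarray, ok: np.ndarray, hold: float) -> float:
    """Start of the first maximal True run lasting at least ``hold`` seconds;
    inf when no such run exists."""
    n = len(ok)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if ts[j] - ts[i] >= hold:
            return float(ts[i])
        i = j + 1
    return NOT_CONVERGED


def initiation_time(
    trace: AdaptationTrace,
    transition_time: float,
    start_level: float,
    delta: float = 0.05,
) -> float:
    """Time (relative to the transition) of first departure from the
    pre-transition level by at least ``delta``; :data:`NOT_CONVERGED` if the
    trace never departs."""
    t = trace.times
    if len(t) == 0 or t[-1] < transition_time:
        raise ValueError("trace must span past the transition time")
    sel = t >= transition_time
    departed = np.abs(trace.mmse[sel] - start_level) >= delta
    if not np.any(departed):
        return NOT_CONVERGED
    return float(t[sel][np.argmax(departed)] - transition_time)


_CHANNELS = ("tilt", "accel_y", "accel_z", "omega_x")


def perception_error(sim, channel: str, window: tuple[float, float]) -> float:
    """RMS of (perceived - true) for one percept channel over a time window.

    ``sim`` is a :class:`vestadapt.simulate.SimResult`; ``channel`` is one of
    ``tilt`` (rad), ``accel_y``/``accel_z`` (m/s^2) or ``omega_x`` (rad/s).
    """
    if channel not in _CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; choose from {_CHANNELS}")
    t0, t1 = window
    sel = (sim.t >= t0) & (sim.t <= t1)
    if not np.any(sel):
        raise ValueError(f"window {window} contains no samples")
    if channel == "tilt":
        err = sim.tilt_perceived[sel] - sim.tilt_true[sel]
    elif channel == "accel_y":
        err = sim.a_perceived[sel, 1] - sim.a_true[sel, 1]
    elif channel == "accel_z":
        err = sim.a_perceived[sel, 2] - sim.a_true[sel, 2]
    else:
        err = sim.omega_perceived[sel, 0] - sim.omega_true[sel, 0]
    return float(np.sqrt(np.mean(err * err)))
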