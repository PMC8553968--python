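"""Passive-motion profiles, gravity schedules and sensor noise.

These are the inputs to every simulated experiment: a sinusoidal motion
profile (roll tilt, lateral translation, upright yaw, or none), a
piecewise-constant gravity-level schedule with instantaneous transitions, and
additive white measurement noise specified by the height of its power
spectral density.

Frame/kinematics convention (see :mod:`vestadapt.observer`): head-frame
vectors, world z up.  A profile angle ``theta(t)`` about axis ``n`` means the
world-to-head quaternion is the rotation by ``theta`` about ``n``; the
head-frame angular velocity consistent with ``dv_head/dt = -omega x v_head``
is then ``omega = -theta_dot * n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .observer import G0, Afference, MotionSample

PROFILE_KINDS = ("roll_tilt", "lateral_translation", "upright_yaw", "none")


@dataclass
class GravitySchedule:
    """Piecewise-constant gravity level: ordered ``(start_time, g_level)``.

    Transitions are instantaneous at each segment start.
    """

    segments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(level < 0 for _, level in self.segments):
            raise ValueError("gravity levels must be >= 0")

    def level_at(self, t: np.ndarray | float) -> np.ndarray | float:
        starts = np.array([s for s, _ in self.segments])
        levels = np.array([lv for _, lv in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(levels) - 1)
        return levels[idx]

    @property
    def transition_times(self) -> list[float]:
        return [s for s, _ in self.segments[1:]]

    @classmethod
    def step(cls, pre: float, post: float, at: float) -> "GravitySchedule":
        """A single instantaneous transition ``pre -> post`` at time ``at``."""
        return cls([(0.0, pre), (at, post)])


@dataclass
class ProfileSpec:
    """Sinusoidal passive-motion profile.

    ``amplitude`` is in degrees for the rotational kinds and in m/s^2 for
    lateral translation.  ``kind='none'`` is a motionless upright head.
    """

    kind: str
    amplitude: float = 0.0
    frequency: float = 0.0
    duration: float = 100.0
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}; choose from {PROFILE_KINDS}")
        if self.kind != "none" and self.frequency <= 0:
            raise ValueError("frequency must be > 0 for periodic profiles")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency if self.frequency > 0 else np.inf


@dataclass
class NoiseSpec:
    """Additive white measurement noise.

    ``power`` is the height of the (two-sided) power spectral density of the
    white noise added independently to each of the six afferent channels,
    units^2 * s; at step ``dt`` the per-sample variance is ``power / dt``.
    """

    power: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("noise power must be >= 0")

    def per_sample_std(self, dt: float) -> float:
        return float(np.sqrt(self.power / dt))


@dataclass
class MotionTrace:
    """Time-sampled true motion: arrays over N samples."""

    t: np.ndarray          # (N,)
    omega: np.ndarray      # (N, 3) rad/s, head frame
    accel: np.ndarray      # (N, 3) m/s^2, head frame
    g_level: np.ndarray    # (N,) g units
    quat: np.ndarray       # (N, 4) world->head, scalar-last
    g_head: np.ndarray     # (N, 3) m/s^2, head frame

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, k: int) -> MotionSample:
        return MotionSample(
            t=float(self.t[k]),
            omega=self.omega[k],
            accel=self.accel[k],
            g_level=float(self.g_level[k]),
            orientation=self.quat[k],
            g_head=self.g_head[k],
        )

    def __iter__(self) -> Iterator[MotionSample]:
        return (self.sample(k) for k in range(len(self)))

    def to_frame(self):
        """Export as a pandas DataFrame (t, omega, accel, g_level, quaternion)."""
        import pandas as pd

        data = {"t": self.t}
        for i, ax in enumerate("xyz"):
            data[f"omega_{ax}"] = self.omega[:, i]
        for i, ax in enumerate("xyz"):
            data[f"accel_{ax}"] = self.accel[:, i]
        data["g_level"] = self.g_level
        for i, comp in enumerate(["qx", "qy", "qz", "qw"]):
            data[comp] = self.quat[:, i]
        return pd.DataFrame(data)


def make_motion_trace(profile: ProfileSpec, gravity: GravitySchedule) -> MotionTrace:
    """Sample a motion profile against a gravity schedule.

    Head-centred roll tilt rotates about head x with zero linear acceleration
    (the rotation axis passes through the head; centripetal terms are
    neglected).  Lateral translation and upright yaw leave the head-frame
    gravity direction constant.
    """
    n = int(round(profile.duration / profile.dt))
    t = np.arange(n) * profile.dt
    omega = np.zeros((n, 3))
    accel = np.zeros((n, 3))
    angle = np.zeros(n)
    axis_idx: int | None = None

    if profile.kind in ("roll_tilt", "upright_yaw"):
        amp = np.deg2rad(profile.amplitude)
        two_pi_f = 2.0 * np.pi * profile.frequency
        angle = amp * np.sin(two_pi_f * t)
        rate = amp * two_pi_f * np.cos(two_pi_f * t)
        axis_idx = 0 if profile.kind == "roll_tilt" else 2
        omega[:, axis_idx] = -rate  # consistency with v_head = R(angle) v_world
    elif profile.kind == "lateral_translation":
        two_pi_f = 2.0 * np.pi * profile.frequency
        accel[:, 1] = profile.amplitude * np.sin(two_pi_f * t)

    g_level = np.asarray(gravity.level_at(t), dtype=float)
    if n == 0:
        g_level = np.zeros(0)

    if axis_idx is not None:
        rotvec = np.zeros((n, 3))
        rotvec[:, axis_idx] = angle
        rot = Rotation.from_rotvec(rotvec)
        quat = rot.as_quat()
        g_head = rot.apply(np.array([0.0, 0.0, G0])) * g_level[:, None]
    else:
        quat = np.tile(np.array([0.0, 0.0, 0.0, 1.0]), (n, 1))
        g_head = np.zeros((n, 3))
        g_head[:, 2] = g_level * G0

    return MotionTrace(t=t, omega=omega, accel=accel, g_level=g_level, quat=quat, g_head=g_head)


def add_sensor_noise(
    afference: Afference, noise: NoiseSpec, dt: float, rng: np.random.Generator
) -> Afference:
    """Add zero-mean Gaussian noise of variance ``power/dt`` per channel."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if noise.power == 0:
        return afference
    std = noise.per_sample_std(dt)
    return Afference(
        alpha_oto=afference.alpha_oto + rng.normal(0.0, std, 3),
        alpha_scc=afference.alpha_scc + rng.normal(0.0, std, 3),
    )


# ---------------------------------------------------------------------------
# Named figure presets
# ---------------------------------------------------------------------------

#: baseline noise power used by every preset except the noise sweep
BASELINE_NOISE_POWER = 1e-8

#: committed noise-power sweep for the noise-dependence experiment; the
#: levels are spaced so that the predicted reliability inflation of the
#: conflict variances (see filterbank.reliability_scaled) is well separated
#: across levels (factors ~1.0, 1.1, 2.0, 4.1 on the acceleration channel);
#: below ~1e-4 units^2*s the model predicts no measurable effect
NOISE_SWEEP_POWERS = (1e-8, 1e-3, 1e-2, 3e-2)

#: fraction of the run spent at the pre-transition level so the posterior
#: concentrates there before the transition
BURN_IN_FRACTION = 0.25


def _single_transition(
    pre: float,
    post: float,
    duration: float,
    profile_kind: str = "roll_tilt",
    amplitude: float = 30.0,
    frequency: float = 0.25,
    power: float = BASELINE_NOISE_POWER,
    dt: float = 0.02,
) -> tuple[ProfileSpec, GravitySchedule, NoiseSpec]:
    profile = ProfileSpec(
        kind=profile_kind, amplitude=amplitude, frequency=frequency, duration=duration, dt=dt
    )
    schedule = GravitySchedule.step(pre, post, BURN_IN_FRACTION * duration)
    return profile, schedule, NoiseSpec(power=power)


def _learned_schedule(final_start: float) -> GravitySchedule:
    # oscillating "training" levels that widen the posterior, ending with a
    # hold at the same 1.2 g level the direct scenario starts from (long
    # enough for the central estimate to settle there, short enough that the
    # posterior remains wider than the direct scenario's), then 0.5 g
    levels = [1.0, 0.8, 1.2, 0.8, 1.2, 0.5]
    hold = 350.0  # final hold at 1.2 g: long enough to settle, short enough
    seg = (final_start - hold) / 4.0  # to keep the posterior widened
    starts = [0.0, seg, 2 * seg, 3 * seg, final_start - hold, final_start]
    return GravitySchedule([(float(s), lv) for s, lv in zip(starts, levels)])


_STD_DURATION = 700.0      # gravity-transition runs (criterion: asymptotes)
_STATIC_DURATION = 1400.0  # motion-comparison runs (shared transition time)
_FIG6_TRANSITION = 850.0
_FIG6_DURATION = 1500.0
_NOISE_DURATION = 2000.0   # long burn-in so noisy runs still concentrate


def _presets() -> dict[str, tuple[ProfileSpec, GravitySchedule, NoiseSpec]]:
    p: dict[str, tuple[ProfileSpec, GravitySchedule, NoiseSpec]] = {}
    p["fig3"] = _single_transition(1.0, 0.5, _STD_DURATION)
    p["fig4a"] = _single_transition(1.0, 0.5, _STD_DURATION)
    p["fig4b"] = _single_transition(1.0, 0.2, _STD_DURATION)
    p["fig4c"] = _single_transition(1.0, 1.5, _STD_DURATION)
    # motion dependence: 1 -> 0.5 g under varied profiles; all fig5 presets
    # share one duration (hence one transition time) so their adaptation
    # times are directly comparable
    p["fig5_roll_a30"] = _single_transition(1.0, 0.5, _STATIC_DURATION)
    p["fig5_roll_a15"] = _single_transition(1.0, 0.5, _STATIC_DURATION, amplitude=15.0)
    p["fig5_roll_a45"] = _single_transition(1.0, 0.5, _STATIC_DURATION, amplitude=45.0)
    p["fig5_roll_f0125"] = _single_transition(1.0, 0.5, _STATIC_DURATION, frequency=0.125)
    p["fig5_roll_f05"] = _single_transition(1.0, 0.5, _STATIC_DURATION, frequency=0.5)
    p["fig5_none"] = _single_transition(
        1.0, 0.5, _STATIC_DURATION, profile_kind="none", amplitude=0.0, frequency=0.0
    )
    p["fig5_trans_a0125"] = _single_transition(
        1.0, 0.5, _STATIC_DURATION, profile_kind="lateral_translation", amplitude=0.125
    )
    p["fig5_trans_a025_f05"] = _single_transition(
        1.0,
        0.5,
        _STATIC_DURATION,
        profile_kind="lateral_translation",
        amplitude=0.25,
        frequency=0.5,
    )
    p["fig5_yaw_a30"] = _single_transition(1.0, 0.5, _STATIC_DURATION, profile_kind="upright_yaw")
    p["fig5_yaw_a60_f05"] = _single_transition(
        1.0, 0.5, _STATIC_DURATION, profile_kind="upright_yaw", amplitude=60.0, frequency=0.5
    )
    # prior-width dependence: direct vs learned adaptation to 0.5 g
    prof = ProfileSpec(kind="roll_tilt", amplitude=30.0, frequency=0.25, duration=_FIG6_DURATION)
    p["fig6_direct"] = (
        prof,
        GravitySchedule.step(1.2, 0.5, _FIG6_TRANSITION),
        NoiseSpec(power=BASELINE_NOISE_POWER),
    )
    p["fig6_learned"] = (
        prof,
        _learned_schedule(_FIG6_TRANSITION),
        NoiseSpec(power=BASELINE_NOISE_POWER),
    )
    # noise dependence: gentler roll tilt, swept noise power
    for power in NOISE_SWEEP_POWERS:
        name = f"fig7_p{power:.0e}".replace("e-0", "e-")
        p[name] = _single_transition(
            1.0, 0.5, _NOISE_DURATION, amplitude=15.0, frequency=0.125, power=power
        )
    return p


def scenario_names() -> list[str]:
    """Names of all built-in figure presets."""
    return sorted(_presets())


def figure_scenario(name: str) -> tuple[ProfileSpec, GravitySchedule, NoiseSpec]:
    """Return the committed ``(profile, schedule, noise)`` for a named preset."""
    presets = _presets()
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; known: {', '.join(sorted(presets))}")
    return presets[name]
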