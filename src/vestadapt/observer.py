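"""Single-hypothesis vestibular observer.

The observer is an internal-model state estimator for passive self-motion:
noisy otolith and semicircular-canal (SCC) afference is compared against the
afference *expected* from the current internal estimates of gravity ``g_hat``,
linear acceleration ``a_hat`` and angular velocity ``omega_hat``.  The
differences -- the sensory conflicts ``e_a`` (acceleration), ``e_f``
(gravito-inertial direction) and ``e_omega`` (rotation) -- are fed back
through fixed gains to steer the internal states.

Each observer carries a fixed hypothesis for the *magnitude* of gravity: after
every integration step ``|g_hat|`` is re-pinned to ``g_mag_hypothesis * g0``
(direction preserved), so a bank of observers can entertain alternative
gravity magnitudes in parallel while sharing identical afference.

All vector quantities live in a head-fixed right-handed frame: x out the
nose, y out the left ear, z out the crown.  The otolith afference for an
upright, static head in 1 g is ``[0, 0, +9.81]`` m/s^2 (reaction convention).

State arrays may carry a leading batch dimension ``(m, 3)``; every operation
broadcasts, which is how the hypothesis bank steps all observers at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G0 = 9.81
"""Standard gravity magnitude (m/s^2) corresponding to a g-level of 1."""

#: otolith vectors shorter than this (m/s^2) have no usable direction, so the
#: direction conflict e_f is forced to zero (guards near free-fall).
EF_DIRECTION_GUARD = 0.1


@dataclass
class ObserverParams:
    """Feedback gains, time constants and otolith weighting of one observer.

    Parameters
    ----------
    k_a:
        Gain from the acceleration conflict ``e_a`` onto the internal
        acceleration estimate (dimensionless, canonically negative: excess
        sensed gravito-inertial force is attributed to acceleration of the
        head *opposite* the excess).
    k_f_omega:
        Gain from the gravito-inertial direction conflict ``e_f`` onto the
        *perceived* angular velocity (rad/s per unit conflict).
    k_omega_f:
        Gain steering the internal gravity vector toward the sensed
        gravito-inertial direction, via ``e_f x g_hat`` (1/s).
    k_omega:
        Gain from the rotation conflict ``e_omega`` onto the angular velocity
        estimate; produces the classic velocity-storage lengthening of the
        canal time constant to roughly ``(1 + k_omega) * tau_scc``.
    tau_scc:
        Torsion-pendulum (high-pass) time constant of the canals, seconds.
    tau_a:
        Leak time constant of the acceleration estimate, seconds.
    w_util:
        Relative weight, in (0, 1], of the two utricular-plane components
        (head x and y) of the otolith vectors when forming the conflicts; the
        perpendicular (saccular, head z) component keeps weight 1.  Values
        below 1 reproduce roll-tilt overestimation in hyper-gravity and
        underestimation in hypo-gravity while leaving perception veridical
        once the internal gravity magnitude matches the true one.
    g0:
        Gravity magnitude of one g-level, m/s^2.
    """

    k_a: float = -4.0
    k_f_omega: float = 8.0
    k_omega_f: float = 4.0
    k_omega: float = 8.0
    tau_scc: float = 5.7
    tau_a: float = 1.0
    w_util: float = 0.5
    g0: float = G0

    def __post_init__(self) -> None:
        if self.tau_scc <= 0:
            raise ValueError(f"tau_scc must be > 0, got {self.tau_scc}")
        if self.tau_a <= 0:
            raise ValueError(f"tau_a must be > 0, got {self.tau_a}")
        if not 0.0 < self.w_util <= 1.0:
            raise ValueError(f"w_util must be in (0, 1], got {self.w_util}")
        if self.g0 <= 0:
            raise ValueError(f"g0 must be > 0, got {self.g0}")

    @property
    def otolith_weights(self) -> np.ndarray:
        """Diagonal of the otolith weighting matrix, ``[w, w, 1]``."""
        return np.array([self.w_util, self.w_util, 1.0])


@dataclass
class MotionSample:
    """True self-motion at one instant, expressed in the head frame.

    ``orientation`` is a unit quaternion ``(x, y, z, w)`` whose rotation maps
    world-frame vectors into the head frame; ``g_head`` caches the head-frame
    gravity vector (reaction convention, upright = ``[0, 0, +g]``).
    """

    t: float
    omega: np.ndarray
    accel: np.ndarray
    g_level: float
    orientation: np.ndarray
    g_head: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.g_level < 0:
            raise ValueError("g_level must be >= 0")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be unit norm")
        if self.g_head is None:
            from scipy.spatial.transform import Rotation

            g_world = np.array([0.0, 0.0, self.g_level * G0])
            self.g_head = Rotation.from_quat(self.orientation).apply(g_world)
        else:
            self.g_head = np.asarray(self.g_head, dtype=float)


@dataclass
class Afference:
    """Noisy vestibular measurements at one time step (head frame)."""

    alpha_oto: np.ndarray  # otolith, m/s^2
    alpha_scc: np.ndarray  # canals, rad/s

    def __post_init__(self) -> None:
        self.alpha_oto = np.asarray(self.alpha_oto, dtype=float)
        self.alpha_scc = np.asarray(self.alpha_scc, dtype=float)
        if not (np.all(np.isfinite(self.alpha_oto)) and np.all(np.isfinite(self.alpha_scc))):
            raise ValueError("afference components must be finite")


@dataclass
class ConflictSignals:
    """The three sensory conflicts of one observer (or a batch of them)."""

    e_a: np.ndarray      # m/s^2
    e_f: np.ndarray      # dimensionless, |e_f| = sine of direction mismatch
    e_omega: np.ndarray  # rad/s

    def norms(self) -> np.ndarray:
        """Stack of the three conflict norms, shape ``(..., 3)``."""
        return np.stack(
            [
                np.linalg.norm(self.e_a, axis=-1),
                np.linalg.norm(self.e_f, axis=-1),
                np.linalg.norm(self.e_omega, axis=-1),
            ],
            axis=-1,
        )


@dataclass
class ObserverState:
    """Internal states of one observer (or a batch, with leading dim m)."""

    g_hat: np.ndarray
    a_hat: np.ndarray
    omega_hat: np.ndarray
    scc_sensor_state: np.ndarray
    scc_internal_state: np.ndarray
    g_mag_hypothesis: float | np.ndarray

    @classmethod
    def initial(
        cls,
        g_mag_hypothesis: float | np.ndarray,
        g0: float = G0,
        direction: np.ndarray | None = None,
    ) -> "ObserverState":
        """A converged-at-rest state: gravity along ``direction`` (default
        upright, +z), zero acceleration/rotation estimates and filter states.
        """
        mags = np.asarray(g_mag_hypothesis, dtype=float)
        if direction is None:
            direction = np.array([0.0, 0.0, 1.0])
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        g_hat = mags[..., None] * g0 * direction
        zeros = np.zeros_like(g_hat)
        return cls(
            g_hat=g_hat,
            a_hat=zeros.copy(),
            omega_hat=zeros.copy(),
            scc_sensor_state=zeros.copy(),
            scc_internal_state=zeros.copy(),
            g_mag_hypothesis=mags,
        )

    def copy(self) -> "ObserverState":
        return ObserverState(
            g_hat=self.g_hat.copy(),
            a_hat=self.a_hat.copy(),
            omega_hat=self.omega_hat.copy(),
            scc_sensor_state=self.scc_sensor_state.copy(),
            scc_internal_state=self.scc_internal_state.copy(),
            g_mag_hypothesis=np.copy(self.g_mag_hypothesis),
        )


def scc_transduce(
    omega: np.ndarray, sensor_state: np.ndarray, dt: float, tau_scc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Semicircular-canal transduction: per-axis first-order high-pass.

    Torsion-pendulum dynamics ``tau*s / (tau*s + 1)`` realised as the state
    equation ``dx/dt = (omega - x)/tau`` with output ``alpha = omega - x``.
    The state advance uses the exact zero-order-hold discretisation, so the
    sampled output matches the continuous-time response to machine precision
    for piecewise-constant input.

    Returns the afference at the *current* sample and the advanced state.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if tau_scc <= 0:
        raise ValueError(f"tau_scc must be > 0, got {tau_scc}")
    omega = np.asarray(omega, dtype=float)
    alpha_scc = omega - sensor_state
    new_state = omega + (sensor_state - omega) * np.exp(-dt / tau_scc)
    return alpha_scc, new_state


def oto_transduce(g_head: np.ndarray, accel: np.ndarray) -> np.ndarray:
    """Otolith transduction: gravito-inertial force ``g_head - accel``.

    Otolith dynamics are treated as identity over the frequencies of
    interest; in free fall (``accel == g_head``) the afference vanishes.
    """
    g_head = np.asarray(g_head, dtype=float)
    accel = np.asarray(accel, dtype=float)
    return g_head - accel


def _direction_conflict(
    expected_g: np.ndarray, resolved_g: np.ndarray, params: ObserverParams
) -> np.ndarray:
    """e_f = unit(W g_hat) x unit(W (alpha_oto + a_hat)); zero when either
    weighted vector is shorter than the guard threshold.

    The measured side is the *gravito-inertially resolved* gravity vector:
    the otolith afference (g - a) corrected by the current acceleration
    estimate.  Comparing directions after resolution keeps the conflict
    insensitive to translation that the observer already accounts for.
    """
    w = params.otolith_weights
    we = expected_g * w
    wm = resolved_g * w
    ne = np.linalg.norm(we, axis=-1, keepdims=True)
    nm = np.linalg.norm(wm, axis=-1, keepdims=True)
    ok = (ne > EF_DIRECTION_GUARD) & (nm > EF_DIRECTION_GUARD)
    # avoid 0/0 where guarded; the result there is masked to zero anyway
    ne = np.where(ne > 0, ne, 1.0)
    nm = np.where(nm > 0, nm, 1.0)
    e_f = np.cross(we / ne, wm / nm)
    return np.where(ok, e_f, 0.0)


def _conflicts_from_arrays(
    g_hat: np.ndarray,
    a_hat: np.ndarray,
    scc_internal_state: np.ndarray,
    alpha_oto: np.ndarray,
    params: ObserverParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conflicts as a function of the instantaneous internal states.

    The rotation conflict follows from the self-consistent loop
    ``omega_hat = alpha_scc + k_omega*e_omega + k_f_omega*e_f`` with
    ``alpha_scc_hat`` the internal high-pass of ``omega_hat``:

        e_omega = (x_int - k_f_omega * e_f) / (1 + k_omega)

    which is the closed-form solution of the algebraic feedback loop (the
    measured ``alpha_scc`` cancels identically).
    """
    w = params.otolith_weights
    expected_oto = g_hat - a_hat
    e_a = (alpha_oto - expected_oto) * w
    e_f = _direction_conflict(g_hat, alpha_oto + a_hat, params)
    e_omega = (scc_internal_state - params.k_f_omega * e_f) / (1.0 + params.k_omega)
    return e_a, e_f, e_omega


def conflict_signals(
    afference: Afference,
    state: ObserverState,
    params: ObserverParams,
    dt: float | None = None,
) -> ConflictSignals:
    """Sensory conflicts of ``state`` against the incoming ``afference``.

    ``dt`` is accepted for interface symmetry with :func:`observer_step` but
    the conflicts are instantaneous and do not depend on it.
    """
    e_a, e_f, e_omega = _conflicts_from_arrays(
        state.g_hat, state.a_hat, state.scc_internal_state, afference.alpha_oto, params
    )
    return ConflictSignals(e_a=e_a, e_f=e_f, e_omega=e_omega)


def _derivatives(
    g_hat: np.ndarray,
    a_hat: np.ndarray,
    x_int: np.ndarray,
    alpha_scc: np.ndarray,
    alpha_oto: np.ndarray,
    params: ObserverParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e_a, e_f, e_omega = _conflicts_from_arrays(g_hat, a_hat, x_int, alpha_oto, params)
    omega_hat = alpha_scc + params.k_omega * e_omega + params.k_f_omega * e_f
    # the internal gravity vector is rotated by the canal-based rate estimate;
    # the e_f component of the rotation percept does not spin g_hat, it only
    # appears in the perceived angular velocity (see docs/methods.md)
    omega_int = omega_hat - params.k_f_omega * e_f
    dg = -np.cross(omega_int, g_hat) + params.k_omega_f * np.cross(e_f, g_hat)
    da = (params.k_a * e_a - a_hat) / params.tau_a
    dx = (omega_hat - x_int) / params.tau_scc
    return dg, da, dx


def observer_step(
    state: ObserverState,
    afference: Afference,
    params: ObserverParams,
    dt: float,
) -> tuple[ObserverState, ConflictSignals]:
    """Advance one observer (or a batch) by ``dt`` with fixed-step RK4.

    The afference is held constant over the step (zero-order hold).  After
    integration ``|g_hat|`` is re-pinned to ``g_mag_hypothesis * g0`` with
    direction preserved, and ``omega_hat`` is the algebraic rotation percept
    evaluated from the start-of-step conflicts (the same conflicts returned).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    a_scc = afference.alpha_scc
    a_oto = afference.alpha_oto

    g, a, x = state.g_hat, state.a_hat, state.scc_internal_state
    e_a, e_f, e_omega = _conflicts_from_arrays(g, a, x, a_oto, params)
    omega_hat = a_scc + params.k_omega * e_omega + params.k_f_omega * e_f

    k1 = _derivatives(g, a, x, a_scc, a_oto, params)
    k2 = _derivatives(
        g + 0.5 * dt * k1[0], a + 0.5 * dt * k1[1], x + 0.5 * dt * k1[2], a_scc, a_oto, params
    )
    k3 = _derivatives(
        g + 0.5 * dt * k2[0], a + 0.5 * dt * k2[1], x + 0.5 * dt * k2[2], a_scc, a_oto, params
    )
    k4 = _derivatives(g + dt * k3[0], a + dt * k3[1], x + dt * k3[2], a_scc, a_oto, params)

    sixth = dt / 6.0
    g_new = g + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    a_new = a + sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    x_new = x + sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

    # re-pin the hypothesised gravity magnitude, direction preserved
    mag = np.asarray(state.g_mag_hypothesis, dtype=float) * params.g0
    norm = np.linalg.norm(g_new, axis=-1, keepdims=True)
    safe = np.where(norm > 0, norm, 1.0)
    g_new = g_new / safe * np.expand_dims(mag, -1)

    for name, arr in (("g_hat", g_new), ("a_hat", a_new), ("scc_internal_state", x_new)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in observer state term {name!r}")

    new_state = ObserverState(
        g_hat=g_new,
        a_hat=a_new,
        omega_hat=omega_hat,
        scc_sensor_state=state.scc_sensor_state,
        scc_internal_state=x_new,
        g_mag_hypothesis=state.g_mag_hypothesis,
    )
    return new_state, ConflictSignals(e_a=e_a, e_f=e_f, e_omega=e_omega)


def perceived_tilt(state: ObserverState | np.ndarray) -> float | np.ndarray:
    """Signed roll-plane tilt (rad) of the internal gravity estimate.

    The angle between ``g_hat`` and the head +z axis, positive when gravity
    tilts toward -y (``g_hat = [0, -4.905, 8.496]`` reads +30 deg, pure
    ``[0, +g, 0]`` reads -90 deg).
    """
    g = state.g_hat if isinstance(state, ObserverState) else np.asarray(state, float)
    norm = np.linalg.norm(g, axis=-1)
    if np.any(norm == 0):
        raise ValueError("perceived_tilt undefined for zero-magnitude g_hat")
    ang = np.arccos(np.clip(g[..., 2] / norm, -1.0, 1.0))
    sign = np.where(g[..., 1] > 0, -1.0, 1.0)
    out = sign * ang
    return float(out) if np.ndim(out) == 0 else out
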