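"""Parallel hypothesis bank: NIS weighting, Bayes updates, central estimate.

A :class:`HypothesisBank` runs ``m`` observers in parallel, one per candidate
gravity magnitude ``H_j`` (g units), all fed the *same* noisy afference.  Each
observer's three conflict norms are collapsed into the scalar Normalized
Innovation Squared statistic

    eps_j = e_j^T (K_s S)^{-1} e_j,   e_j = [|e_a|, |e_f|, |e_omega|],
    S = diag(sigma_a^2, sigma_f^2, sigma_omega^2),

interpreted as the quadratic form of a zero-mean Gaussian measurement
likelihood ``p(y_k | H_j)``.  Bayes rule then updates the posterior over the
hypotheses sequentially (log domain, log-sum-exp normalisation, probability
floor), and the posterior-weighted mean (MMSE) or mode (MAP) of the grid sets
the gravity magnitude of an additional *central* observer whose outputs are
the model's percepts of tilt, acceleration and angular velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .observer import (
    G0,
    Afference,
    ConflictSignals,
    MotionSample,
    ObserverParams,
    ObserverState,
    observer_step,
    oto_transduce,
    perceived_tilt,
    scc_transduce,
)
from .scenarios import NoiseSpec

_LOG_2PI = float(np.log(2.0 * np.pi))

#: default NIS scale factor K_s; sets the (arbitrary) time scale of
#: adaptation -- see docs/methods.md for the calibration choice
DEFAULT_K_S = 200.0

DEFAULT_FLOOR = 1e-6

#: default variance weights of the three conflict norms; the direction and
#: rotation conflicts are weighted strongly relative to the acceleration
#: conflict so that tilt-driven (angle-domain) evidence dominates
#: discrimination -- see docs/methods.md
DEFAULT_SIGMA2_A = 1.0
DEFAULT_SIGMA2_F = 0.0025
DEFAULT_SIGMA2_OMEGA = 0.0025


@dataclass
class NISConfig:
    """Variance weights and scaling of the NIS statistic.

    ``sigma2_a/f/omega`` weight the three conflict norms by their expected
    reliability; ``k_s`` scales the whole S matrix and thereby modulates the
    adaptation rate without changing which hypothesis wins.  ``n`` is the
    length of the conflict-norm vector (fixed at 3).
    """

    sigma2_a: float = DEFAULT_SIGMA2_A       # (m/s^2)^2
    sigma2_f: float = DEFAULT_SIGMA2_F       # dimensionless^2
    sigma2_omega: float = DEFAULT_SIGMA2_OMEGA  # (rad/s)^2
    k_s: float = DEFAULT_K_S
    n: int = 3

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_f", "sigma2_omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_s <= 0:
            raise ValueError("k_s must be > 0")
        if self.n != 3:
            raise ValueError("the conflict-norm vector has length 3")

    @property
    def s_eff_diag(self) -> np.ndarray:
        """Diagonal of the effective covariance ``K_s * S``."""
        return self.k_s * np.array([self.sigma2_a, self.sigma2_f, self.sigma2_omega])

    @property
    def log_det_s_eff(self) -> float:
        return float(np.sum(np.log(self.s_eff_diag)))


def reliability_scaled(
    cfg: NISConfig, noise: NoiseSpec, dt: float, params: ObserverParams
) -> NISConfig:
    """Inflate the conflict variance weights by the known sensor-noise level.

    The S matrix represents the CNS's estimate of conflict variability; a
    noisier sensor yields larger estimated variances and hence weaker
    per-sample evidence.  The added terms are the delta-method propagation of
    the per-sample measurement noise (variance ``v = power/dt`` per channel)
    into each conflict norm: the acceleration conflict picks up the weighted
    otolith noise directly (``(1 + 2 w^2) v``), the direction conflict its
    transverse part on unit vectors at the 1-g scale (``2 w^2 v / g0^2``),
    and the rotation conflict the fraction of direction noise reaching it
    through the e_f -> omega feedback.
    """
    v = noise.power / dt
    if v == 0:
        return cfg
    w2 = params.w_util**2
    c_f = 2.0 * w2 / params.g0**2
    c_omega = (params.k_f_omega / (1.0 + params.k_omega)) ** 2 * c_f
    return NISConfig(
        sigma2_a=cfg.sigma2_a + (1.0 + 2.0 * w2) * v,
        sigma2_f=cfg.sigma2_f + c_f * v,
        sigma2_omega=cfg.sigma2_omega + c_omega * v,
        k_s=cfg.k_s,
        n=cfg.n,
    )


def nis(conflicts: ConflictSignals, cfg: NISConfig) -> float | np.ndarray:
    """Normalized Innovation Squared of one observer (or a batch).

    ``e^T (K_s S)^{-1} e`` with ``e`` the vector of the three conflict norms;
    returns a scalar per observer, >= 0.
    """
    e = conflicts.norms()
    eps = np.sum(e * e / cfg.s_eff_diag, axis=-1)
    return float(eps) if np.ndim(eps) == 0 else eps


def log_likelihood(epsilon: float | np.ndarray, cfg: NISConfig) -> float | np.ndarray:
    """Log of the Gaussian measurement likelihood ``N(e; 0, K_s S)``.

    ``-(n log 2pi + log|K_s S| + eps) / 2``; the terms other than ``eps`` are
    shared by all hypotheses and cancel under Bayes normalisation.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(epsilon < 0):
        raise ValueError("epsilon must be >= 0")
    out = -0.5 * (cfg.n * _LOG_2PI + cfg.log_det_s_eff + epsilon)
    return float(out) if np.ndim(out) == 0 else out


def likelihood(epsilon: float | np.ndarray, cfg: NISConfig) -> float | np.ndarray:
    """Measurement likelihood density (linear domain convenience wrapper)."""
    return np.exp(log_likelihood(epsilon, cfg))


def apply_floor(posterior: np.ndarray, floor: float) -> np.ndarray:
    """Raise components below ``floor`` and renormalise the rest.

    The floored components keep exactly ``floor``; the remaining mass is
    distributed proportionally over the others (iterated in case rescaling
    pushes further components under the floor).  Guarantees sum == 1 and
    ``min >= floor``.
    """
    if floor * len(posterior) >= 1.0:
        raise ValueError("floor * m must be < 1")
    p = np.asarray(posterior, dtype=float).copy()
    if floor <= 0:
        return p / p.sum()
    for _ in range(len(p)):
        low = p < floor
        if not low.any():
            break
        p[low] = floor
        free = ~low
        target = 1.0 - floor * low.sum()
        scale = target / p[free].sum()
        p[free] *= scale
        if np.all(p[free] >= floor):
            break
    return p / p.sum() if abs(p.sum() - 1.0) > 1e-12 else p


def bayes_update(
    posterior: np.ndarray, log_likelihoods: np.ndarray, floor: float = 0.0
) -> np.ndarray:
    """One sequential Bayes update of the hypothesis posterior.

    ``p_j' \\propto exp(logL_j) * p_j`` normalised by the marginal likelihood
    (computed stably with log-sum-exp), followed by the probability floor.
    """
    posterior = np.asarray(posterior, dtype=float)
    ll = np.asarray(log_likelihoods, dtype=float)
    if np.all(np.isneginf(ll)):
        raise ValueError("degenerate update: all log-likelihoods are -inf")
    with np.errstate(divide="ignore"):
        log_post = np.log(posterior) + ll
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    return apply_floor(post, floor)


def central_estimate(bank: "HypothesisBank", mode: str = "mmse") -> float:
    """Central gravity-magnitude estimate (g units) from the posterior.

    ``mmse`` is the posterior-weighted mean of the hypothesis grid; ``map``
    is the hypothesis with the largest posterior (ties broken toward the
    lower gravity value).
    """
    return _central(bank.hypotheses, bank.posterior, mode)


def _central(hypotheses: np.ndarray, posterior: np.ndarray, mode: str) -> float:
    if mode == "mmse":
        return float(np.dot(hypotheses, posterior))
    if mode == "map":
        return float(hypotheses[int(np.argmax(posterior))])
    raise ValueError(f"unknown estimator mode {mode!r}")


@dataclass
class StepRecord:
    """Per-step log entry of the bank."""

    t: float
    posterior: np.ndarray        # (m,)
    central_g: float             # g units
    g_hat: np.ndarray            # central observer gravity estimate (3,)
    a_hat: np.ndarray            # central acceleration percept (3,)
    omega_hat: np.ndarray        # central angular-velocity percept (3,)
    tilt: float                  # signed roll tilt percept (rad)
    conflict_norms: np.ndarray | None = None  # (m, 3) per-hypothesis norms


@dataclass
class HypothesisBank:
    """The m parallel observers, their posterior, and the central observer."""

    hypotheses: np.ndarray
    posterior: np.ndarray
    observers: ObserverState          # batched, leading dim m
    central: ObserverState
    nis_config: NISConfig
    floor: float = DEFAULT_FLOOR
    update_period: float = 0.0        # seconds between Bayes updates; 0 = every step
    estimator: str = "mmse"
    sensor_state: np.ndarray = field(default_factory=lambda: np.zeros(3))
    _time_since_update: float = 0.0

    def __post_init__(self) -> None:
        self.hypotheses = np.asarray(self.hypotheses, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if len(self.hypotheses) < 2:
            raise ValueError("need at least two hypotheses")
        if np.any(np.diff(self.hypotheses) <= 0):
            raise ValueError("hypotheses must be strictly increasing")
        if abs(self.posterior.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must sum to 1")

    @classmethod
    def create(
        cls,
        hypotheses: np.ndarray | None = None,
        nis_config: NISConfig | None = None,
        floor: float = DEFAULT_FLOOR,
        update_period: float = 0.0,
        estimator: str = "mmse",
        params: ObserverParams | None = None,
        prior: np.ndarray | None = None,
    ) -> "HypothesisBank":
        """Bank over a hypothesis grid (default 0.1..2.0 g in 0.1 g steps),
        uniform prior, observers initialised upright at rest."""
        if hypotheses is None:
            hypotheses = default_grid()
        hypotheses = np.asarray(hypotheses, dtype=float)
        m = len(hypotheses)
        if prior is None:
            prior = np.full(m, 1.0 / m)
        params = params or ObserverParams()
        nis_config = nis_config or NISConfig()
        observers = ObserverState.initial(hypotheses, g0=params.g0)
        central_mag = _central(hypotheses, prior, estimator)
        central = ObserverState.initial(np.asarray(central_mag), g0=params.g0)
        return cls(
            hypotheses=hypotheses,
            posterior=np.asarray(prior, dtype=float),
            observers=observers,
            central=central,
            nis_config=nis_config,
            floor=floor,
            update_period=update_period,
            estimator=estimator,
        )

    @property
    def m(self) -> int:
        return len(self.hypotheses)


def default_grid() -> np.ndarray:
    """Twenty gravity-magnitude hypotheses, 0.1 to 2.0 g in 0.1 g steps."""
    return np.round(np.arange(1, 21) * 0.1, 10)


def make_afference(
    bank: HypothesisBank,
    sample: MotionSample,
    params: ObserverParams,
    dt: float,
    noise: NoiseSpec | None,
    rng: np.random.Generator | None,
) -> Afference:
    """Transduce the true motion through the shared sensors and add noise.

    Advances the bank's (shared) canal sensor state; all observers and the
    central observer receive this single noisy realisation.
    """
    alpha_scc, bank.sensor_state = scc_transduce(
        sample.omega, bank.sensor_state, dt, params.tau_scc
    )
    alpha_oto = oto_transduce(sample.g_head, sample.accel)
    if noise is not None and noise.power > 0:
        if rng is None:
            raise ValueError("noisy afference requires an rng")
        std = noise.per_sample_std(dt)
        alpha_oto = alpha_oto + rng.normal(0.0, std, 3)
        alpha_scc = alpha_scc + rng.normal(0.0, std, 3)
    return Afference(alpha_oto=alpha_oto, alpha_scc=alpha_scc)


def step_bank(
    bank: HypothesisBank,
    sample: MotionSample,
    params: ObserverParams,
    dt: float,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    record_conflicts: bool = False,
) -> tuple[HypothesisBank, StepRecord]:
    """Advance the whole bank one time step.

    1. one shared noisy afference from the true motion;
    2. every parallel observer and the central observer step (the central
       one still pinned to the previous central estimate), collecting the
       parallel observers' conflicts;
    3. at the Bayes cadence, NIS -> log-likelihood -> posterior update;
    4. the central estimate is recomputed and the central observer's
       ``|g_hat|`` rescaled to it (direction and all other states persist),
       taking effect from the next step.

    The bank is updated in place and also returned.
    """
    afference = make_afference(bank, sample, params, dt, noise, rng)

    bank.observers, conflicts = observer_step(bank.observers, afference, params, dt)
    bank.central, _ = observer_step(bank.central, afference, params, dt)

    bank._time_since_update += dt
    if bank._time_since_update >= bank.update_period - 1e-12:
        eps = nis(conflicts, bank.nis_config)
        ll = log_likelihood(eps, bank.nis_config)
        bank.posterior = bayes_update(bank.posterior, ll, bank.floor)
        bank._time_since_update = 0.0

    central_g = _central(bank.hypotheses, bank.posterior, bank.estimator)
    bank.central.g_mag_hypothesis = np.asarray(central_g)
    norm = np.linalg.norm(bank.central.g_hat)
    if norm > 0:
        bank.central.g_hat = bank.central.g_hat * (central_g * params.g0 / norm)

    record = StepRecord(
        t=sample.t,
        posterior=bank.posterior.copy(),
        central_g=central_g,
        g_hat=bank.central.g_hat.copy(),
        a_hat=bank.central.a_hat.copy(),
        omega_hat=np.asarray(bank.central.omega_hat, dtype=float).copy(),
        tilt=float(perceived_tilt(bank.central)),
        conflict_norms=conflicts.norms() if record_conflicts else None,
    )
    return bank, record
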