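# Methods

## Model structure

### Single observer

Each observer is a continuous-time estimator of head-frame gravity **ĝ**,
linear acceleration **â** and angular velocity **ω̂**, driven by otolith and
semicircular-canal afference. Conventions: head-fixed right-handed frame
(x nose, y left ear, z crown), world z up, otolith afference is the
gravito-inertial reaction `α_OTO = g_head − a` (upright static 1 g reads
`[0, 0, +9.81]` m/s²), canal afference is the first-order high-passed
angular velocity `α_SCC` with torsion-pendulum time constant τ_scc = 5.7 s.
For a head orientation described by rotation of world vectors into the head
frame by angle θ about axis n̂, the head-frame angular velocity consistent
with `dv_head/dt = −ω × v_head` is `ω = −θ̇ n̂`; the motion generator and a
finite-difference property test enforce this self-consistency.

Three conflicts compare afference with expectation:

* `e_a = W (α_OTO − (ĝ − â))` — acceleration conflict (m/s²);
* `e_f = unit(W ĝ) × unit(W (α_OTO + â))` — gravito-inertial **direction**
  conflict (|e_f| = sine of the angular mismatch), comparing the internal
  gravity direction against the *resolved* gravity measurement, i.e. the
  otolith signal corrected by the current acceleration estimate. Vectors
  shorter than 0.1 m/s² (near free-fall) zero the conflict. When the
  acceleration estimate is exact this equals the textbook comparison of
  expected versus measured afference; resolving first keeps the conflict
  insensitive to translations the observer already accounts for (see
  "Design choices");
* `e_ω` — rotation conflict, the closed-form solution of the algebraic loop
  `ω̂ = α_SCC + K_ω e_ω + K_fω e_f` with the internal canal model driven by
  ω̂: `e_ω = (x_int − K_fω e_f)/(1 + K_ω)`.

`W = diag(w, w, 1)` down-weights the two utricular-plane components
(default w = 0.5). State dynamics:

    ω̂      = α_SCC + K_ω e_ω + K_fω e_f            (rotation percept)
    dĝ/dt  = −(ω̂ − K_fω e_f) × ĝ + K_ωf (e_f × ĝ)
    dâ/dt  = (K_a e_a − â)/τ_a
    dx_int/dt = (ω̂ − x_int)/τ_scc

The gravity vector is rotated by the canal-based rate estimate
(ω̂ − K_fω e_f); the e_f contribution to the rotation *percept* does not
spin ĝ. With the canonical gains this makes the zero-conflict equilibrium
attracting (rotating ĝ by the full percept would make the direction
feedback net-destabilising, since K_fω > K_ωf). Defaults: K_ω = 8,
K_fω = 8, K_ωf = 4, K_a = −4, τ_a = 1 s — the standard values of the
validated vestibular-observer lineage; all configurable.

After every RK4 step (fixed dt = 0.02 s, afference held constant across the
step) |ĝ| is re-pinned to the observer's hypothesis magnitude with direction
preserved. The canal *sensor* is advanced by its exact zero-order-hold
discretisation.

Closed-form statics (derivable from the e_f = 0, ω̂_int = 0 equilibrium with
per-channel mixing p_c = 1/(1 − K_a w_c)): perceived static roll tilt is
exactly veridical whenever the internal gravity magnitude matches the true
level, for any w; with the internal magnitude held at 1 g it satisfies
`tan φ ≈ (q_y/q_z) G tanθ / (G + (q_y − q_z)/q_z)`, giving overestimation in
hyper-gravity (≈34° perceived at 30° true in 1.5 g) and underestimation in
hypo-gravity (≈22° at 30° in 0.5 g) — the direction required by altered-
gravity tilt psychophysics. The down-weighted plane must be the utricular
one: down-weighting the saccular axis instead yields the opposite (wrong)
dependence on G.

### Hypothesis bank and central estimate

Twenty observers carry the grid H = 0.1 … 2.0 g (step 0.1), all fed one
shared noisy afference per step. Conflict norms collapse to the NIS
`ε_j = e_jᵀ (K_s S)⁻¹ e_j`; the Gaussian measurement likelihood
`log p(y|H_j) = −(n log 2π + log|K_s S| + ε_j)/2` (the constants cancel
under normalisation; the implementation keeps the full normalised form).
Sequential Bayes updates run synchronously with the integration step, in
log domain with log-sum-exp normalisation; a probability floor (default
1e-6) is applied after normalisation — floored components keep exactly the
floor and the remaining mass is rescaled — so no hypothesis becomes
irrecoverable. The central estimate is the posterior mean (MMSE) by
default, or the posterior mode (MAP, ties to the lower level). It rescales
|ĝ| of an additional central observer whose direction and remaining states
persist; that observer's outputs are the reported percepts. The central
observer steps together with the bank, so a new central estimate takes
effect on the following 0.02-s step.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| grid | 0.1–2.0 step 0.1 | g | candidate internal gravity magnitudes |
| σ_a² | 1.0 | (m/s²)² | weight of the acceleration-conflict norm |
| σ_f², σ_ω² | 0.0025 | —, (rad/s)² | weight of direction/rotation conflicts |
| K_s | 200 | — | global scale of S; sets the (arbitrary) adaptation time scale |
| floor | 1e-6 | — | minimum posterior probability |
| w (utricular weight) | 0.5 | — | tilt-misperception asymmetry in altered gravity |
| noise power P | 1e-8 (baseline) | units²·s | PSD height of white sensor noise; per-sample variance P/dt |
| dt | 0.02 | s | integration and update step |

**Why σ_f², σ_ω² ≪ σ_a².** The conflict channels carry different kinds of
information. The acceleration conflict is *absolute*: its residual for a
mismatched hypothesis scales with |G − h|·g₀ regardless of the environment,
which makes no-motion adaptation exactly symmetric between equal hypo- and
hyper-gravity steps — but, under roll tilt, richer absolute signals in
hyper-gravity would make hyper-adaptation slightly *faster*. The direction
and rotation conflicts are *ratio-scaled* (angles): their discrimination
goes like (Δh/G)², stronger at low G. Weighting them strongly makes
tilt-driven evidence dominate, which yields the empirically expected
structure: adaptation to 1.5 g slower than to 0.5 g under roll tilt, exact
hypo/hyper symmetry with no motion (where only the acceleration channel
discriminates), faster adaptation for larger transitions and for larger or
faster roll tilt, and no material effect of upright yaw or (moderate)
lateral translation. K_s then restores the overall pace; it is held
constant everywhere and calibrated once so the canonical 1 → 0.5 g run
converges within a few hundred simulated seconds — the absolute time axis
of all results is arbitrary.

**Sensor noise and reliability.** S is the filter's estimate of conflict
variability. When sensor noise is non-negligible a consistent estimator's S
must grow with it, so the effective variances are inflated by the
delta-method propagation of the known per-sample noise variance v = P/dt:
σ_a² + (1+2w²)v on the acceleration channel, σ_f² + 2w²v/g₀² on the
direction channel, and the (K_fω/(1+K_ω))² fraction of the latter on the
rotation channel. This is what makes noisier sensors adapt later: the
expected per-step log-likelihood gap between hypotheses shrinks as 1/σ_eff².
With S held fixed instead, the expected evidence rate would be noise-
independent and the model would (incorrectly) predict no initiation
slowdown. Below P ≈ 1e-4 units²·s the inflation is negligible and so is the
predicted effect; the committed sweep {1e-8, 1e-3, 1e-2, 3e-2} spaces the
predicted inflation factors (≈1.0, 1.1, 2.0, 4.1) well apart.

## Scenario generator

Profiles are sinusoidal: head-centred roll tilt (θ = A sin 2πft about head
x, zero linear acceleration — the rotation axis passes through the head and
centripetal terms are neglected), lateral translation (a_y = A sin 2πft,
upright), upright yaw (rotation about the gravity axis), or none. Gravity
schedules are piecewise constant with instantaneous transitions; every run
holds the pre-transition level for a burn-in (25 % of the duration for the
single-transition presets) so the posterior concentrates there from a
uniform initial prior rather than being imposed. White Gaussian noise of
per-sample variance P/dt is added independently to the six afferent
channels; one realisation is shared by all observers.

What the generator does *not* emulate: active or voluntary movement,
head-on-torso kinematics, translation-tilt coupling, visual or
proprioceptive input, canal/otolith transduction nonlinearities, and any
gradual (non-instantaneous) gravity change. Passing tests therefore show
that the *inference machinery* behaves as predicted under idealised
vestibular-only stimulation, not that the model fits human data.

Committed preset choices where the experiment definitions leave freedom:
translation
amplitudes 0.125–0.25 m/s² at 0.25–0.5 Hz (centimetre-scale sled motion);
yaw 30–60° at 0.25–0.5 Hz; the learned-adaptation training schedule
1.0 → 0.8 → 1.2 → 0.8 → 1.2 g at equal intervals with a 350-s final hold at
1.2 g before the drop to 0.5 g, so that both the "direct" (1.2 → 0.5) and
"learned" scenarios end with the same transition, the learned estimate has
settled, and its posterior is still wider than the direct scenario's.

## Metrics

`convergence_time`: first post-transition time after which the central
estimate stays within 0.05 g (half a grid step) of the true level
continuously for a hold period (tests use 20 s). `initiation_time`: first
departure by 0.05 g from the pre-transition baseline — by default the
trace's own mean over the 50 s before the transition, which stays meaningful
when noise or a wide posterior keeps the estimate slightly off the nominal
level; the departure from the *nominal* level is reported alongside
(`initiation_time_nominal`) and is the right readout for the learned-
adaptation comparison, where the widened posterior keeps the MMSE measurably
off the trained level (so the learned trace "initiates" immediately — the
MMSE expression of reduced commitment). `perception_error`: RMS of
(perceived − true) for tilt, acceleration or angular-velocity channels over
a window. Orderings under non-negligible noise are asserted on medians over
five seeds.

## Numerical choices

RK4 at dt = 0.02 s (slowest dynamics ≥ 1 s; the stiffest eigenvalue,
(K_a w − 1)/τ_a ≈ −3 s⁻¹, gives λ·dt ≈ 0.06); exact ZOH discretisation for
the canal sensor; gravity-magnitude re-pinning after every step; all
probability arithmetic in log space; the e_f guard (0.1 m/s²) handles
near-free-fall degeneracy; a posterior of all-(-inf) log-likelihoods raises
rather than silently renormalising; duration-zero runs return empty, valid
results. The batched numba kernel and the pure-numpy reference
implementation of the observer step are held equal to float precision by a
unit test. Determinism: a run is a pure function of its configuration and
seed (one `numpy` Generator, fixed draw order); identical configs produce
byte-identical output files.

## Known limitations

* Translation neutrality is approximate and amplitude-limited: above
  ≈0.5 m/s² lateral amplitude the residual untracked acceleration couples
  into the hypothesis-pinned gravity directions and biases discrimination
  toward higher magnitudes (adaptation can stall above the true level).
  The committed presets stay in the regime where the effect is ≤ ~10 % of
  the no-motion adaptation time.
* At large sensor-noise powers (≥ 1e-2 units²·s) the same coupling biases
  the resting posterior a grid step or two above the true level; initiation
  remains well defined against the measured baseline, but convergence to
  the exact level is not guaranteed there (consistent with the observation
  that noise delays initiation without a matching convergence trend).
* The hypothesis grid is fixed; gravity levels outside 0.1–2.0 g cannot be
  learned, and microgravity (0 g) is deliberately out of scope.
* Absolute times are arbitrary (K_s); only orderings and asymptotes are
  meaningful.
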