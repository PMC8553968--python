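"""Unit and property tests for the single-hypothesis observer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import vestadapt as va
from vestadapt.observer import _conflicts_from_arrays

G0 = va.G0


def _static_afference(g_level: float, roll_deg: float = 0.0) -> va.Afference:
    g_head = Rotation.from_euler("x", roll_deg, degrees=True).apply([0, 0, g_level * G0])
    return va.Afference(alpha_oto=g_head, alpha_scc=np.zeros(3))


def _settle(state, afference, params, steps=12000, dt=0.02):
    for _ in range(steps):
        state, conflicts = va.observer_step(state, afference, params, dt)
    return state, conflicts


class TestCanalTransduction:
    def test_constant_rotation_is_rejected(self):
        omega = np.array([0.17, 0.0, 0.0])
        state = np.zeros(3)
        for _ in range(20000):  # 400 s >> tau_scc
            alpha, state = va.scc_transduce(omega, state, 0.02, 5.7)
        assert np.allclose(alpha, 0.0, atol=1e-6)

    def test_step_has_unit_high_frequency_gain(self):
        alpha, _ = va.scc_transduce([0.17, 0, 0], np.zeros(3), 0.02, 5.7)
        assert np.allclose(alpha, [0.17, 0, 0])

    def test_step_response_matches_closed_form_within_one_percent(self):
        # alpha(t) = omega * exp(-t/tau); dt = tau/100
        tau = 5.7
        dt = tau / 100.0
        omega = np.array([0.17, 0.0, 0.0])
        state = np.zeros(3)
        for k in range(301):
            alpha, state = va.scc_transduce(omega, state, dt, tau)
            expected = 0.17 * np.exp(-k * dt / tau)
            assert abs(alpha[0] - expected) <= 0.01 * expected
        assert abs(0.17 * np.exp(-1.0) - 0.0625) < 1e-3  # the t = tau value

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            va.scc_transduce([0, 0, 0], np.zeros(3), -0.01, 5.7)
        with pytest.raises(ValueError):
            va.scc_transduce([0, 0, 0], np.zeros(3), 0.02, 0.0)


class TestOtolithTransduction:
    def test_upright_static(self):
        assert np.allclose(va.oto_transduce([0, 0, 9.81], [0, 0, 0]), [0, 0, 9.81])

    def test_rolled_gravity_matches_rotation_matrix(self):
        theta = np.deg2rad(30)
        R = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        g_head = R @ np.array([0, 0, 9.81])
        assert np.allclose(g_head, [0, -4.905, 8.4957], atol=1e-3)
        assert np.allclose(va.oto_transduce(g_head, np.zeros(3)), g_head)

    def test_free_fall_cancels(self):
        g = np.array([0.0, 1.2, 9.7])
        assert np.allclose(va.oto_transduce(g, g), 0.0)


class TestConflictSignals:
    def test_converged_matched_state_has_zero_conflicts(self):
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.0))
        conflicts = va.conflict_signals(_static_afference(1.0), state, params)
        for c in (conflicts.e_a, conflicts.e_f, conflicts.e_omega):
            assert np.allclose(c, 0.0, atol=1e-12)

    def test_magnitude_mismatch_gives_pure_acceleration_conflict(self):
        # true 1 g upright, hypothesis 0.5 g: e_a = [0, 0, 4.905], e_f parallel -> 0
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(0.5))
        conflicts = va.conflict_signals(_static_afference(1.0), state, params)
        assert np.allclose(conflicts.e_a, [0, 0, 4.905], atol=1e-9)
        assert np.allclose(conflicts.e_f, 0.0, atol=1e-12)

    def test_orthogonal_directions_give_unit_direction_conflict(self):
        params = va.ObserverParams(w_util=1.0)
        state = va.ObserverState.initial(np.asarray(1.0))  # g_hat along +z
        aff = va.Afference(alpha_oto=[0, 9.81, 0], alpha_scc=[0, 0, 0])
        conflicts = va.conflict_signals(aff, state, params)
        assert np.isclose(np.linalg.norm(conflicts.e_f), 1.0, atol=1e-12)

    def test_direction_conflict_guard_near_free_fall(self):
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.0))
        aff = va.Afference(alpha_oto=[0.0, 0.05, 0.0], alpha_scc=[0, 0, 0])
        conflicts = va.conflict_signals(aff, state, params)
        assert np.allclose(conflicts.e_f, 0.0)

    @given(
        st.floats(-np.pi, np.pi),
        st.floats(-np.pi / 2, np.pi / 2),
        st.floats(0.2, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_direction_conflict_norm_bounded_by_one(self, yaw, pitch, g_level):
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.0))
        g = Rotation.from_euler("zy", [yaw, pitch]).apply([0, 0, g_level * G0])
        conflicts = va.conflict_signals(
            va.Afference(alpha_oto=g, alpha_scc=np.zeros(3)), state, params
        )
        assert np.linalg.norm(conflicts.e_f) <= 1.0 + 1e-9


class TestObserverStep:
    def test_gravity_magnitude_pinned_every_step(self):
        params = va.ObserverParams()
        rng = np.random.default_rng(0)
        hyps = np.arange(1, 21) * 0.1
        state = va.ObserverState.initial(hyps)
        for _ in range(50):
            aff = va.Afference(
                alpha_oto=rng.normal(0, 3, 3) + [0, 0, 9.81],
                alpha_scc=rng.normal(0, 0.3, 3),
            )
            state, _ = va.observer_step(state, aff, params, 0.02)
            mags = np.linalg.norm(state.g_hat, axis=-1)
            assert np.all(np.abs(mags - hyps * G0) <= 1e-6 * G0)

    def test_zero_conflict_fixed_point_is_attracting(self):
        # decay is dominated by the velocity-storage time constant
        # (~(1 + k_omega) tau_scc ~ 51 s), so the run spans many of them
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.0))
        state.g_hat = state.g_hat + np.array([0.0, 1.0, 0.0])
        state.g_hat *= G0 / np.linalg.norm(state.g_hat)
        aff = _static_afference(1.0)
        _, first = va.observer_step(state, aff, params, 0.05)
        state, last = _settle(state, aff, params, steps=32000, dt=0.05)
        for c0, c1 in zip(first.norms(), last.norms()):
            if c0 > 0:
                assert c1 < 1e-6 * c0

    def test_mismatched_hypothesis_keeps_persistent_residual(self):
        # |e_a| -> (1/(1-k_a)) * |G - h| * g0, strictly positive
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(0.5))
        _, conflicts = _settle(state, _static_afference(1.0), params)
        expected = 0.5 * G0 / (1.0 - params.k_a)
        assert np.isclose(np.linalg.norm(conflicts.e_a), expected, rtol=1e-3)

    @pytest.mark.parametrize(
        "g_level, expect_over",
        [(1.5, True), (0.5, False)],
        ids=["hyper_overestimates", "hypo_underestimates"],
    )
    def test_static_tilt_misperception_direction(self, g_level, expect_over):
        # internal magnitude held at 1 g while the true level differs
        params = va.ObserverParams()
        assert params.w_util < 1.0
        state = va.ObserverState.initial(np.asarray(1.0))
        state, _ = _settle(state, _static_afference(g_level, roll_deg=30.0), params)
        tilt = np.degrees(va.perceived_tilt(state))
        if expect_over:
            assert tilt > 31.0
        else:
            assert tilt < 29.0

    def test_matched_magnitude_perceives_tilt_veridically(self):
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.5))
        state, _ = _settle(state, _static_afference(1.5, roll_deg=30.0), params)
        assert abs(np.degrees(va.perceived_tilt(state)) - 30.0) < 0.5

    def test_non_finite_state_raises_with_diagnostic(self):
        params = va.ObserverParams()
        state = va.ObserverState.initial(np.asarray(1.0))
        state.a_hat = np.array([np.nan, 0.0, 0.0])
        with pytest.raises(FloatingPointError, match="a_hat|g_hat"):
            va.observer_step(state, _static_afference(1.0), params, 0.02)


class TestPerceivedTilt:
    @pytest.mark.parametrize(
        "g_hat, expected_deg",
        [
            ([0, 0, 9.81], 0.0),
            ([0, -4.905, 8.4957], 30.0),
            ([0, 9.81, 0], -90.0),
        ],
    )
    def test_examples(self, g_hat, expected_deg):
        state = va.ObserverState.initial(np.asarray(1.0))
        state.g_hat = np.asarray(g_hat, dtype=float)
        assert np.isclose(np.degrees(va.perceived_tilt(state)), expected_deg, atol=0.01)

    def test_zero_gravity_estimate_is_degenerate(self):
        state = va.ObserverState.initial(np.asarray(1.0))
        state.g_hat = np.zeros(3)
        with pytest.raises(ValueError):
            va.perceived_tilt(state)


class TestKernelEquivalence:
    def test_compiled_and_reference_steps_agree(self):
        from vestadapt._kernels import bank_step, bank_step_numpy

        params = va.ObserverParams()
        rng = np.random.default_rng(3)
        m = 21
        hyps = np.linspace(0.1, 2.1, m)

        def random_state():
            g = rng.normal(0, 1, (m, 3))
            g /= np.linalg.norm(g, axis=-1, keepdims=True)
            g *= (hyps * G0)[:, None]
            return g, rng.normal(0, 0.5, (m, 3)), rng.normal(0, 0.1, (m, 3))

        for _ in range(5):
            g1, a1, x1 = random_state()
            g2, a2, x2 = g1.copy(), a1.copy(), x1.copy()
            oto = rng.normal(0, 2, 3) + [0, 0, 9.81]
            scc = rng.normal(0, 0.2, 3)
            pin = hyps * G0
            en1, om1 = bank_step(g1, a1, x1, pin, oto, scc, 0.02, params)
            en2, om2 = bank_step_numpy(g2, a2, x2, pin, oto, scc, 0.02, params)
            assert np.allclose(en1, en2, atol=1e-12)
            assert np.allclose(om1, om2, atol=1e-12)
            assert np.allclose(g1, g2, atol=1e-10) and np.allclose(a1, a2, atol=1e-10)

    def test_reference_step_matches_observer_step(self):
        from vestadapt._kernels import bank_step_numpy

        params = va.ObserverParams()
        rng = np.random.default_rng(4)
        hyps = np.array([0.5, 1.0, 1.5])
        state = va.ObserverState.initial(hyps)
        state.a_hat = rng.normal(0, 0.3, (3, 3))
        g, a, x = state.g_hat.copy(), state.a_hat.copy(), state.scc_internal_state.copy()
        aff = va.Afference(alpha_oto=[0.3, -0.4, 9.5], alpha_scc=[0.05, 0, -0.02])
        new_state, conflicts = va.observer_step(state, aff, params, 0.02)
        en, om = bank_step_numpy(
            g, a, x, hyps * G0, aff.alpha_oto, aff.alpha_scc, 0.02, params
        )
        assert np.allclose(g, new_state.g_hat, atol=1e-12)
        assert np.allclose(a, new_state.a_hat, atol=1e-12)
        assert np.allclose(x, new_state.scc_internal_state, atol=1e-12)
        assert np.allclose(en, conflicts.norms(), atol=1e-12)
        assert np.allclose(om, new_state.omega_hat, atol=1e-12)
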