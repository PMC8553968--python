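"""Inner integration kernel for a batch of observers.

One numba-compiled implementation (used when numba is importable) and one
pure-numpy reference implementation of exactly the same step:

    conflicts at the start of the step  ->  RK4 over dt (afference held)
    ->  |g_hat| re-pinned to the hypothesis magnitude.

Both paths must agree to float precision; a unit test enforces this against
:func:`vestadapt.observer.observer_step`, which is the readable reference.
"""

from __future__ import annotations

import numpy as np

from .observer import EF_DIRECTION_GUARD, ObserverParams, _conflicts_from_arrays, _derivatives

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _params_tuple(p: ObserverParams) -> tuple:
    return (p.k_a, p.k_f_omega, p.k_omega_f, p.k_omega, p.tau_a, p.tau_scc, p.w_util)


def bank_step_numpy(
    g: np.ndarray,
    a: np.ndarray,
    x: np.ndarray,
    pin_mags: np.ndarray,
    alpha_oto: np.ndarray,
    alpha_scc: np.ndarray,
    dt: float,
    params: ObserverParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance (B,3) state arrays in place; returns (conflict norms (B,3),
    omega_hat percept (B,3)) evaluated at the start of the step."""
    e_a, e_f, e_w = _conflicts_from_arrays(g, a, x, alpha_oto, params)
    omega_hat = alpha_scc + params.k_omega * e_w + params.k_f_omega * e_f
    e_norms = np.stack(
        [
            np.linalg.norm(e_a, axis=-1),
            np.linalg.norm(e_f, axis=-1),
            np.linalg.norm(e_w, axis=-1),
        ],
        axis=-1,
    )

    k1 = _derivatives(g, a, x, alpha_scc, alpha_oto, params)
    k2 = _derivatives(
        g + 0.5 * dt * k1[0], a + 0.5 * dt * k1[1], x + 0.5 * dt * k1[2],
        alpha_scc, alpha_oto, params,
    )
    k3 = _derivatives(
        g + 0.5 * dt * k2[0], a + 0.5 * dt * k2[1], x + 0.5 * dt * k2[2],
        alpha_scc, alpha_oto, params,
    )
    k4 = _derivatives(
        g + dt * k3[0], a + dt * k3[1], x + dt * k3[2], alpha_scc, alpha_oto, params
    )
    sixth = dt / 6.0
    g_new = g + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    a += sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    x += sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

    norm = np.linalg.norm(g_new, axis=-1, keepdims=True)
    safe = np.where(norm > 0, norm, 1.0)
    g[...] = g_new / safe * pin_mags[:, None]
    return e_norms, omega_hat


if HAVE_NUMBA:

    @njit(cache=True)
    def _conflicts_nb(g, a, x, a_oto, ka, kfw, kwf, kw, ta, ts, wu, e_a, e_f, e_w):
        # weighted measured / expected otolith vectors
        ne2 = 0.0
        nm2 = 0.0
        we = np.empty(3)
        wm = np.empty(3)
        for i in range(3):
            w = wu if i < 2 else 1.0
            we[i] = g[i] * w
            wm[i] = (a_oto[i] + a[i]) * w
            e_a[i] = (a_oto[i] - (g[i] - a[i])) * w
            ne2 += we[i] * we[i]
            nm2 += wm[i] * wm[i]
        ne = np.sqrt(ne2)
        nm = np.sqrt(nm2)
        if ne > EF_DIRECTION_GUARD and nm > EF_DIRECTION_GUARD:
            s = 1.0 / (ne * nm)
            e_f[0] = (we[1] * wm[2] - we[2] * wm[1]) * s
            e_f[1] = (we[2] * wm[0] - we[0] * wm[2]) * s
            e_f[2] = (we[0] * wm[1] - we[1] * wm[0]) * s
        else:
            e_f[0] = 0.0
            e_f[1] = 0.0
            e_f[2] = 0.0
        inv = 1.0 / (1.0 + kw)
        for i in range(3):
            e_w[i] = (x[i] - kfw * e_f[i]) * inv

    @njit(cache=True)
    def _derivs_nb(g, a, x, a_scc, a_oto, ka, kfw, kwf, kw, ta, ts, wu, dg, da, dx):
        e_a = np.empty(3)
        e_f = np.empty(3)
        e_w = np.empty(3)
        _conflicts_nb(g, a, x, a_oto, ka, kfw, kwf, kw, ta, ts, wu, e_a, e_f, e_w)
        om = np.empty(3)
        om_int = np.empty(3)
        for i in range(3):
            om[i] = a_scc[i] + kw * e_w[i] + kfw * e_f[i]
            om_int[i] = om[i] - kfw * e_f[i]
        # dg = -om_int x g + kwf * (e_f x g)
        dg[0] = -(om_int[1] * g[2] - om_int[2] * g[1]) + kwf * (e_f[1] * g[2] - e_f[2] * g[1])
        dg[1] = -(om_int[2] * g[0] - om_int[0] * g[2]) + kwf * (e_f[2] * g[0] - e_f[0] * g[2])
        dg[2] = -(om_int[0] * g[1] - om_int[1] * g[0]) + kwf * (e_f[0] * g[1] - e_f[1] * g[0])
        for i in range(3):
            da[i] = (ka * e_a[i] - a[i]) / ta
            dx[i] = (om[i] - x[i]) / ts

    @njit(cache=True)
    def _bank_step_nb(g, a, x, pin_mags, a_oto, a_scc, dt, ka, kfw, kwf, kw, ta, ts, wu):
        B = g.shape[0]
        e_norms = np.empty((B, 3))
        omega_hat = np.empty((B, 3))
        e_a = np.empty(3)
        e_f = np.empty(3)
        e_w = np.empty(3)
        y = np.empty(3)
        ya = np.empty(3)
        yx = np.empty(3)
        k1g = np.empty(3); k1a = np.empty(3); k1x = np.empty(3)
        k2g = np.empty(3); k2a = np.empty(3); k2x = np.empty(3)
        k3g = np.empty(3); k3a = np.empty(3); k3x = np.empty(3)
        k4g = np.empty(3); k4a = np.empty(3); k4x = np.empty(3)
        for b in range(B):
            gb = g[b]
            ab = a[b]
            xb = x[b]
            _conflicts_nb(gb, ab, xb, a_oto, ka, kfw, kwf, kw, ta, ts, wu, e_a, e_f, e_w)
            na = 0.0; nf = 0.0; nw = 0.0
            for i in range(3):
                omega_hat[b, i] = a_scc[i] + kw * e_w[i] + kfw * e_f[i]
                na += e_a[i] * e_a[i]
                nf += e_f[i] * e_f[i]
                nw += e_w[i] * e_w[i]
            e_norms[b, 0] = np.sqrt(na)
            e_norms[b, 1] = np.sqrt(nf)
            e_norms[b, 2] = np.sqrt(nw)

            _derivs_nb(gb, ab, xb, a_scc, a_oto, ka, kfw, kwf, kw, ta, ts, wu, k1g, k1a, k1x)
            for i in range(3):
                y[i] = gb[i] + 0.5 * dt * k1g[i]
                ya[i] = ab[i] + 0.5 * dt * k1a[i]
                yx[i] = xb[i] + 0.5 * dt * k1x[i]
            _derivs_nb(y, ya, yx, a_scc, a_oto, ka, kfw, kwf, kw, ta, ts, wu, k2g, k2a, k2x)
            for i in range(3):
                y[i] = gb[i] + 0.5 * dt * k2g[i]
                ya[i] = ab[i] + 0.5 * dt * k2a[i]
                yx[i] = xb[i] + 0.5 * dt * k2x[i]
            _derivs_nb(y, ya, yx, a_scc, a_oto, ka, kfw, kwf, kw, ta, ts, wu, k3g, k3a, k3x)
            for i in range(3):
                y[i] = gb[i] + dt * k3g[i]
                ya[i] = ab[i] + dt * k3a[i]
                yx[i] = xb[i] + dt * k3x[i]
            _derivs_nb(y, ya, yx, a_scc, a_oto, ka, kfw, kwf, kw, ta, ts, wu, k4g, k4a, k4x)

            sixth = dt / 6.0
            gn2 = 0.0
            for i in range(3):
                gi = gb[i] + sixth * (k1g[i] + 2 * k2g[i] + 2 * k3g[i] + k4g[i])
                y[i] = gi
                gn2 += gi * gi
                ab[i] += sixth * (k1a[i] + 2 * k2a[i] + 2 * k3a[i] + k4a[i])
                xb[i] += sixth * (k1x[i] + 2 * k2x[i] + 2 * k3x[i] + k4x[i])
            gn = np.sqrt(gn2)
            scale = pin_mags[b] / gn if gn > 0 else 0.0
            for i in range(3):
                gb[i] = y[i] * scale
        return e_norms, omega_hat

    def bank_step(g, a, x, pin_mags, alpha_oto, alpha_scc, dt, params):
        return _bank_step_nb(
            g, a, x, pin_mags,
            np.ascontiguousarray(alpha_oto, dtype=np.float64),
            np.ascontiguousarray(alpha_scc, dtype=np.float64),
            float(dt), *_params_tuple(params),
        )

else:  # pragma: no cover

    def bank_step(g, a, x, pin_mags, alpha_oto, alpha_scc, dt, params):
        return bank_step_numpy(g, a, x, pin_mags, alpha_oto, alpha_scc, dt, params)
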