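"""Fixed-step RK4 kernels for the two-variable ionic model.

The kernels integrate an *ensemble* of parameter pairs at once: every row of
the output is one (tau_out, tau_close) combination sharing the fixed
constants tau_in, tau_open and v_gate.  They are compiled with numba when it
is importable; the pure-Python path computes the identical numbers, only
slowly.  Time constants enter as precomputed reciprocals to keep divisions
out of the inner loop.

The gating equation switches regime at v = v_gate.  Steps that straddle a
gate crossing are split at the (linearly located) crossing time: the first
sub-step integrates in the pre-crossing regime, the second in the
post-crossing regime.  The forward sensitivity kernel additionally applies
the standard switch-time jump condition at the crossing,

    s_h(+) = s_h(-) + [h'(-) - h'(+)] * dts/dp,   dts/dp = -s_v(ts)/v'(ts),

without which the sensitivities would remain O(1)-wrong for all times after
repolarization (the crossing time itself depends on the parameters).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False, inline="always")
def _step2(v, h, dt, rin, rto, rtc, rtop, closed):
    """One RK4 step of (v, h) with the gating regime held fixed."""
    f1 = h * v * v * (1.0 - v) * rin - v * rto
    g1 = -h * rtc if closed else (1.0 - h) * rtop
    va = v + 0.5 * dt * f1
    ha = h + 0.5 * dt * g1
    f2 = ha * va * va * (1.0 - va) * rin - va * rto
    g2 = -ha * rtc if closed else (1.0 - ha) * rtop
    vb = v + 0.5 * dt * f2
    hb = h + 0.5 * dt * g2
    f3 = hb * vb * vb * (1.0 - vb) * rin - vb * rto
    g3 = -hb * rtc if closed else (1.0 - hb) * rtop
    vc = v + dt * f3
    hc = h + dt * g3
    f4 = hc * vc * vc * (1.0 - vc) * rin - vc * rto
    g4 = -hc * rtc if closed else (1.0 - hc) * rtop
    v_new = v + dt * (f1 + 2.0 * f2 + 2.0 * f3 + f4) / 6.0
    h_new = h + dt * (g1 + 2.0 * g2 + 2.0 * g3 + g4) / 6.0
    return v_new, h_new


@njit(cache=False)
def rk4_forward(tau_out, tau_close, tau_in, tau_open, v_gate, v0, h0, dt, n_steps):
    """Integrate (v, h) for every parameter pair; returns (V, H).

    V and H have shape (n, n_steps + 1) with column k the state at t = k*dt.
    """
    n = tau_out.shape[0]
    V = np.empty((n, n_steps + 1))
    H = np.empty((n, n_steps + 1))
    rin = 1.0 / tau_in
    rtop = 1.0 / tau_open
    for i in range(n):
        rto = 1.0 / tau_out[i]
        rtc = 1.0 / tau_close[i]
        v = v0
        h = h0
        V[i, 0] = v
        H[i, 0] = h
        for k in range(n_steps):
            closed = v >= v_gate
            v_new, h_new = _step2(v, h, dt, rin, rto, rtc, rtop, closed)
            if (v_new >= v_gate) != closed and v_new != v:
                frac = (v_gate - v) / (v_new - v)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                v_m, h_m = _step2(v, h, frac * dt, rin, rto, rtc, rtop, closed)
                v_new, h_new = _step2(
                    v_m, h_m, (1.0 - frac) * dt, rin, rto, rtc, rtop, not closed
                )
            v = v_new
            h = h_new
            V[i, k + 1] = v
            H[i, k + 1] = h
    return V, H


@njit(cache=False, inline="always")
def _rhs6(v, h, svo, sho, svc, shc, rin, rto, rtc, rtop, closed):
    """Right-hand side of the 6-dimensional augmented system, fixed regime."""
    f = h * v * v * (1.0 - v) * rin - v * rto
    fv = h * (2.0 * v - 3.0 * v * v) * rin - rto
    fh = v * v * (1.0 - v) * rin
    f_to = v * rto * rto
    if closed:
        g = -h * rtc
        gh = -rtc
        g_tc = h * rtc * rtc
    else:
        g = (1.0 - h) * rtop
        gh = -rtop
        g_tc = 0.0
    return (f, g, fv * svo + fh * sho + f_to, gh * sho,
            fv * svc + fh * shc, gh * shc + g_tc)


@njit(cache=False, inline="always")
def _step6(v, h, svo, sho, svc, shc, dt, rin, rto, rtc, rtop, closed):
    """One RK4 step of (v, h) plus sensitivities, regime held fixed."""
    a1, b1, c1, d1, e1, q1 = _rhs6(v, h, svo, sho, svc, shc,
                                   rin, rto, rtc, rtop, closed)
    w = 0.5 * dt
    a2, b2, c2, d2, e2, q2 = _rhs6(v + w * a1, h + w * b1, svo + w * c1,
                                   sho + w * d1, svc + w * e1, shc + w * q1,
                                   rin, rto, rtc, rtop, closed)
    a3, b3, c3, d3, e3, q3 = _rhs6(v + w * a2, h + w * b2, svo + w * c2,
                                   sho + w * d2, svc + w * e2, shc + w * q2,
                                   rin, rto, rtc, rtop, closed)
    a4, b4, c4, d4, e4, q4 = _rhs6(v + dt * a3, h + dt * b3, svo + dt * c3,
                                   sho + dt * d3, svc + dt * e3, shc + dt * q3,
                                   rin, rto, rtc, rtop, closed)
    s = dt / 6.0
    return (v + s * (a1 + 2.0 * a2 + 2.0 * a3 + a4),
            h + s * (b1 + 2.0 * b2 + 2.0 * b3 + b4),
            svo + s * (c1 + 2.0 * c2 + 2.0 * c3 + c4),
            sho + s * (d1 + 2.0 * d2 + 2.0 * d3 + d4),
            svc + s * (e1 + 2.0 * e2 + 2.0 * e3 + e4),
            shc + s * (q1 + 2.0 * q2 + 2.0 * q3 + q4))


@njit(cache=False)
def rk4_forward_sens(tau_out, tau_close, tau_in, tau_open, v_gate, v0, h0, dt, n_steps):
    """Integrate (v, h) together with forward sensitivities.

    Returns (V, H, SVO, SHO, SVC, SHC) where SVO = dv/dtau_out,
    SHO = dh/dtau_out, SVC = dv/dtau_close, SHC = dh/dtau_close, all of shape
    (n, n_steps + 1).  Initial sensitivities are zero (the initial condition
    does not depend on the parameters).
    """
    n = tau_out.shape[0]
    V = np.empty((n, n_steps + 1))
    H = np.empty((n, n_steps + 1))
    SVO = np.empty((n, n_steps + 1))
    SHO = np.empty((n, n_steps + 1))
    SVC = np.empty((n, n_steps + 1))
    SHC = np.empty((n, n_steps + 1))
    rin = 1.0 / tau_in
    rtop = 1.0 / tau_open
    for i in range(n):
        to = tau_out[i]
        tc = tau_close[i]
        rto = 1.0 / to
        rtc = 1.0 / tc
        v = v0
        h = h0
        svo = 0.0
        sho = 0.0
        svc = 0.0
        shc = 0.0
        V[i, 0] = v
        H[i, 0] = h
        SVO[i, 0] = svo
        SHO[i, 0] = sho
        SVC[i, 0] = svc
        SHC[i, 0] = shc
        for k in range(n_steps):
            closed = v >= v_gate
            v_n, h_n, svo_n, sho_n, svc_n, shc_n = _step6(
                v, h, svo, sho, svc, shc, dt, rin, rto, rtc, rtop, closed
            )
            if (v_n >= v_gate) != closed and v_n != v:
                frac = (v_gate - v) / (v_n - v)
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                # sub-step up to the crossing in the old regime
                v_m, h_m, svo_m, sho_m, svc_m, shc_m = _step6(
                    v, h, svo, sho, svc, shc, frac * dt, rin, rto, rtc, rtop,
                    closed,
                )
                # switch-time jump on the h-sensitivities
                f_s = h_m * v_m * v_m * (1.0 - v_m) * rin - v_m * rto
                if abs(f_s) > 1e-300:
                    g_open = (1.0 - h_m) * rtop
                    g_closed = -h_m * rtc
                    dg = g_open - g_closed if not closed else g_closed - g_open
                    sho_m = sho_m + dg * (-svo_m / f_s)
                    shc_m = shc_m + dg * (-svc_m / f_s)
                # remainder of the step in the new regime
                v_n, h_n, svo_n, sho_n, svc_n, shc_n = _step6(
                    v_m, h_m, svo_m, sho_m, svc_m, shc_m, (1.0 - frac) * dt,
                    rin, rto, rtc, rtop, not closed,
                )
            v, h, svo, sho, svc, shc = v_n, h_n, svo_n, sho_n, svc_n, shc_n
            V[i, k + 1] = v
            H[i, k + 1] = h
            SVO[i, k + 1] = svo
            SHO[i, k + 1] = sho
            SVC[i, k + 1] = svc
            SHC[i, k + 1] = shc
    return V, H, SVO, SHO, SVC, SHC
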