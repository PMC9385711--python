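"""Compiled inner loops for the TC-neuron integrator.

The public model API lives in :mod:`tcfit.tc_model`; these kernels duplicate
the right-hand side in scalar form so the fixed-step RK4 loop compiles with
numba.  ``tests/test_tc_model.py`` cross-checks a kernel step against the
pure-numpy ``derivatives`` to guard against drift between the two copies.
"""

import numba as nb
import numpy as np

__all__ = ["rk4_integrate"]


@nb.njit(inline="always")
def _dstate(v, h, r, i_ext, c_m, g_l, e_l, g_na, e_na, g_k, e_k, g_t, e_t):
    m_inf = 1.0 / (1.0 + np.exp(-(v + 37.0) / 7.0))
    p_inf = 1.0 / (1.0 + np.exp(-(v + 60.0) / 6.2))
    h_inf = 1.0 / (1.0 + np.exp((v + 41.0) / 4.0))
    r_inf = 1.0 / (1.0 + np.exp((v + 84.0) / 4.0))
    a_h = 0.128 * np.exp(-(v + 46.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(v + 23.0) / 5.0))
    tau_h = 1.0 / (a_h + b_h)
    tau_r = 28.0 + np.exp(-(v + 25.0) / 10.5)

    i_l = g_l * (v - e_l)
    i_na = g_na * m_inf ** 3 * h * (v - e_na)
    i_k = g_k * 0.75 * (1.0 - h) ** 4 * (v - e_k)
    i_t = g_t * p_inf ** 2 * r * (v - e_t)

    dv = (-i_l - i_na - i_k - i_t + i_ext) / c_m
    dh = (h_inf - h) / tau_h
    dr = 2.5 * (r_inf - r) / tau_r
    return dv, dh, dr


@nb.njit(cache=False)
def rk4_integrate(v0, h0, r0, i_app, dt, c_m, g_l, e_l, g_na, e_na,
                  g_k, e_k, g_t, e_t, i_gi, sgn_gi, sgn_sm, v_abort):
    """Fixed-step RK4 over the sampled applied current ``i_app``.

    The applied current is held constant over each step (zero-order hold at
    the left grid point).  ``sgn_gi``/``sgn_sm`` are -1.0 for the literal
    subtracted convention and +1.0 when the sign is flipped.

    Returns (v, h, r, diverged_step, gate_min, gate_max); ``diverged_step``
    is -1 on success, else the first step index at which |v| > v_abort.
    """
    n = i_app.shape[0]
    v = np.empty(n)
    h = np.empty(n)
    r = np.empty(n)
    v[0], h[0], r[0] = v0, h0, r0
    gmin = min(h0, r0)
    gmax = max(h0, r0)
    vc, hc, rc = v0, h0, r0
    for i in range(n - 1):
        i_ext = sgn_gi * i_gi + sgn_sm * i_app[i]
        k1v, k1h, k1r = _dstate(vc, hc, rc, i_ext, c_m, g_l, e_l,
                                g_na, e_na, g_k, e_k, g_t, e_t)
        k2v, k2h, k2r = _dstate(vc + 0.5 * dt * k1v, hc + 0.5 * dt * k1h,
                                rc + 0.5 * dt * k1r, i_ext, c_m, g_l, e_l,
                                g_na, e_na, g_k, e_k, g_t, e_t)
        k3v, k3h, k3r = _dstate(vc + 0.5 * dt * k2v, hc + 0.5 * dt * k2h,
                                rc + 0.5 * dt * k2r, i_ext, c_m, g_l, e_l,
                                g_na, e_na, g_k, e_k, g_t, e_t)
        k4v, k4h, k4r = _dstate(vc + dt * k3v, hc + dt * k3h,
                                rc + dt * k3r, i_ext, c_m, g_l, e_l,
                                g_na, e_na, g_k, e_k, g_t, e_t)
        vc = vc + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        hc = hc + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
        rc = rc + dt / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
        if not np.isfinite(vc) or abs(vc) > v_abort:
            return v, h, r, i + 1, gmin, gmax
        if hc < gmin:
            gmin = hc
        if rc < gmin:
            gmin = rc
        if hc > gmax:
            gmax = hc
        if rc > gmax:
            gmax = rc
        v[i + 1], h[i + 1], r[i + 1] = vc, hc, rc
    return v, h, r, -1, gmin, gmax
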