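"""Compiled fixed-step RK4 integrators.

State layout is always (V, h, n, K_out, Na_in); for the base model the
Na_in slot is carried along untouched.  Parameters travel as the flat
float tuple produced by ModelParameters.kernel_tuple().  The arithmetic
here mirrors pumpburst.model exactly (a unit test enforces agreement).
"""
import numpy as np
from numba import njit

# kernel_tuple layout indices
_GNA, _GK, _GL, _ENA, _EL, _C, _IAPP, _IMAX = range(8)
_KHALF, _KSLOPE, _NAHALF, _NASLOPE = 8, 9, 10, 11
_KINREF, _NAOUTREF, _PREF, _PHI = 12, 13, 14, 15
_GOUT, _GIN, _ELECTRO, _SODIUM = 16, 17, 18, 19


@njit(cache=True)
def _rhs(V, h, n, K, Na, pt):
    x = -35.0 - V
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = x / (10.0 * (np.exp(x / 10.0) - 1.0))
    bm = 4.0 * np.exp((-V - 60.0) / 18.0)
    minf = am / (am + bm)
    ah = 0.07 * np.exp((-V - 58.0) / 20.0)
    bh = 1.0 / (np.exp((-28.0 - V) / 10.0) + 1.0)
    xn = -34.0 - V
    if abs(xn) < 1e-7:
        an = 0.1
    else:
        an = xn / (100.0 * (np.exp(xn / 10.0) - 1.0))
    bn = 0.125 * np.exp((-V - 44.0) / 80.0)

    if pt[_SODIUM] != 0.0:
        ENa = pt[_PREF] * np.log(pt[_NAOUTREF] / Na)
    else:
        ENa = pt[_ENA]
    EK = pt[_PREF] * np.log(K / pt[_KINREF])

    INa = pt[_GNA] * h * minf ** 3 * (V - ENa)
    IK = pt[_GK] * n ** 4 * (V - EK)
    IL = pt[_GL] * (V - pt[_EL])
    IP = pt[_IMAX] / (1.0 + np.exp((pt[_KHALF] - K) / pt[_KSLOPE]))
    if pt[_SODIUM] != 0.0:
        IP = IP / (1.0 + np.exp((pt[_NAHALF] - Na) / pt[_NASLOPE]))

    IP_v = IP if pt[_ELECTRO] != 0.0 else 0.0
    dV = (pt[_IAPP] - INa - IK - IL - IP_v) / pt[_C]
    dh = pt[_PHI] * (ah * (1.0 - h) - bh * h)
    dn = pt[_PHI] * (an * (1.0 - n) - bn * n)
    dK = (IK - 2.0 * IP) * pt[_GOUT]
    if pt[_SODIUM] != 0.0:
        dNa = (-INa - 3.0 * IP) * pt[_GIN]
    else:
        dNa = 0.0
    return dV, dh, dn, dK, dNa


@njit(cache=True)
def _rhs_fast(V, h, n, K, Na, pt):
    """Fast-subsystem derivative: K_out (and Na_in) frozen."""
    dV, dh, dn, dK, dNa = _rhs(V, h, n, K, Na, pt)
    return dV, dh, dn


@njit(cache=True)
def rk4_full(y0, pt, t_end, dt, stride):
    """Integrate the complete system; record every `stride`-th step.

    Returns (times, states[nout, 5], status) where status is the index of
    the last valid recorded row + 1 (== nout normally); a non-finite state
    truncates the output there.
    """
    V, h, n, K, Na = y0[0], y0[1], y0[2], y0[3], y0[4]
    nsteps = int(round(t_end / dt))
    nout = nsteps // stride + 1
    times = np.empty(nout)
    states = np.empty((nout, 5))
    times[0] = 0.0
    states[0, 0], states[0, 1], states[0, 2] = V, h, n
    states[0, 3], states[0, 4] = K, Na
    j = 1
    for i in range(1, nsteps + 1):
        a0, a1, a2, a3, a4 = _rhs(V, h, n, K, Na, pt)
        b0, b1, b2, b3, b4 = _rhs(V + 0.5 * dt * a0, h + 0.5 * dt * a1,
                                  n + 0.5 * dt * a2, K + 0.5 * dt * a3,
                                  Na + 0.5 * dt * a4, pt)
        c0, c1, c2, c3, c4 = _rhs(V + 0.5 * dt * b0, h + 0.5 * dt * b1,
                                  n + 0.5 * dt * b2, K + 0.5 * dt * b3,
                                  Na + 0.5 * dt * b4, pt)
        d0, d1, d2, d3, d4 = _rhs(V + dt * c0, h + dt * c1, n + dt * c2,
                                  K + dt * c3, Na + dt * c4, pt)
        V += dt / 6.0 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
        h += dt / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
        n += dt / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
        K += dt / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3 + d3)
        Na += dt / 6.0 * (a4 + 2.0 * b4 + 2.0 * c4 + d4)
        if not (np.isfinite(V) and np.isfinite(K) and np.isfinite(Na)):
            return times[:j], states[:j], j
        if i % stride == 0:
            times[j] = i * dt
            states[j, 0], states[j, 1], states[j, 2] = V, h, n
            states[j, 3], states[j, 4] = K, Na
            j += 1
    return times[:j], states[:j], j


@njit(cache=True)
def rk4_fast(y0, K, pt, t_end, dt, stride):
    """Integrate the fast subsystem at frozen K_out (and Na_in = y0[4])."""
    V, h, n, Na = y0[0], y0[1], y0[2], y0[4]
    nsteps = int(round(t_end / dt))
    nout = nsteps // stride + 1
    times = np.empty(nout)
    states = np.empty((nout, 3))
    times[0] = 0.0
    states[0, 0], states[0, 1], states[0, 2] = V, h, n
    j = 1
    for i in range(1, nsteps + 1):
        a0, a1, a2 = _rhs_fast(V, h, n, K, Na, pt)
        b0, b1, b2 = _rhs_fast(V + 0.5 * dt * a0, h + 0.5 * dt * a1,
                               n + 0.5 * dt * a2, K, Na, pt)
        c0, c1, c2 = _rhs_fast(V + 0.5 * dt * b0, h + 0.5 * dt * b1,
                               n + 0.5 * dt * b2, K, Na, pt)
        d0, d1, d2 = _rhs_fast(V + dt * c0, h + dt * c1, n + dt * c2,
                               K, Na, pt)
        V += dt / 6.0 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
        h += dt / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
        n += dt / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
        if not np.isfinite(V):
            return times[:j], states[:j], j
        if i % stride == 0:
            times[j] = i * dt
            states[j, 0], states[j, 1], states[j, 2] = V, h, n
            j += 1
    return times[:j], states[:j], j


@njit(cache=True)
def fast_flow(y0, K, pt, T, dt):
    """Endpoint of the fast-subsystem flow after time T (for shooting)."""
    V, h, n, Na = y0[0], y0[1], y0[2], y0[4]
    nsteps = int(np.ceil(T / dt))
    hstep = T / nsteps
    for _ in range(nsteps):
        a0, a1, a2 = _rhs_fast(V, h, n, K, Na, pt)
        b0, b1, b2 = _rhs_fast(V + 0.5 * hstep * a0, h + 0.5 * hstep * a1,
                               n + 0.5 * hstep * a2, K, Na, pt)
        c0, c1, c2 = _rhs_fast(V + 0.5 * hstep * b0, h + 0.5 * hstep * b1,
                               n + 0.5 * hstep * b2, K, Na, pt)
        d0, d1, d2 = _rhs_fast(V + hstep * c0, h + hstep * c1,
                               n + hstep * c2, K, Na, pt)
        V += hstep / 6.0 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
        h += hstep / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
        n += hstep / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
    return V, h, n


@njit(cache=True)
def fast_section_crossings(y0, K, pt, t_end, dt, section, max_cross):
    """Upward crossings of V = section in the fast subsystem.

    Returns (crossing times, final state, interpolated state at the last
    crossing).  Crossing times and the crossing state are linearly
    interpolated between steps, so the crossing state lies on the orbit to
    O(dt^2) with V = section; the raw final state does not.  Stops early
    once max_cross crossings were collected.
    """
    V, h, n, Na = y0[0], y0[1], y0[2], y0[4]
    nsteps = int(round(t_end / dt))
    out = np.empty(max_cross)
    ncross = 0
    Vprev, hprev, nprev = V, h, n
    cs = np.array([V, h, n, K, Na])
    for i in range(1, nsteps + 1):
        a0, a1, a2 = _rhs_fast(V, h, n, K, Na, pt)
        b0, b1, b2 = _rhs_fast(V + 0.5 * dt * a0, h + 0.5 * dt * a1,
                               n + 0.5 * dt * a2, K, Na, pt)
        c0, c1, c2 = _rhs_fast(V + 0.5 * dt * b0, h + 0.5 * dt * b1,
                               n + 0.5 * dt * b2, K, Na, pt)
        d0, d1, d2 = _rhs_fast(V + dt * c0, h + dt * c1, n + dt * c2,
                               K, Na, pt)
        V += dt / 6.0 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
        h += dt / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
        n += dt / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
        if Vprev < section and V >= section:
            frac = (section - Vprev) / (V - Vprev)
            out[ncross] = (i - 1 + frac) * dt
            cs[0] = section
            cs[1] = hprev + frac * (h - hprev)
            cs[2] = nprev + frac * (n - nprev)
            ncross += 1
            if ncross >= max_cross:
                break
        Vprev, hprev, nprev = V, h, n
    final = np.array([V, h, n, K, Na])
    return out[:ncross], final, cs
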