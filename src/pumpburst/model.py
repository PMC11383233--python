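"""Model equations: gating kinetics, reversal potentials, pump and currents.

The fast subsystem is the three-dimensional (V, h, n) Wang-Buzsaki neuron
with the transient-sodium activation m eliminated through its steady state
m_inf(V).  The complete system couples it to extracellular potassium
[K+]_out through the K+ channel flux and an electrogenic Na+/K+-ATPase; an
extended variant additionally evolves intracellular sodium [Na+]_in.

These are straightforward numpy implementations used for analysis and as
the reference the compiled integrator kernels are tested against.  All
functions accept scalars or arrays for the voltage/concentration arguments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .params import ModelParameters

#: half-width of the series-expansion branch around the removable
#: singularities of alpha_n (V = -34 mV) and alpha_m (V = -35 mV)
_SINGULARITY_EPS = 1e-7


class GatingRates(NamedTuple):
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    alpha_m: float
    beta_m: float


class Currents(NamedTuple):
    I_Na: float
    I_K: float
    I_L: float
    I_P: float


@dataclass
class FastState:
    """State of the fast (spike-generating) subsystem."""
    V: float
    h: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.n], dtype=float)


@dataclass
class FullState:
    """State of the complete system; Na_in present only in the extended model."""
    V: float
    h: float
    n: float
    K_out: float
    Na_in: Optional[float] = None

    @property
    def fast(self) -> FastState:
        return FastState(self.V, self.h, self.n)

    def as_array(self) -> np.ndarray:
        vals = [self.V, self.h, self.n, self.K_out]
        if self.Na_in is not None:
            vals.append(self.Na_in)
        return np.array(vals, dtype=float)


def _check_finite(V) -> None:
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")


def _ratefrac(x, scale):
    """x / (scale * (exp(x/10) - 1)) with the x -> 0 limit 10/scale.

    The limit branch is taken symmetrically for |x| < 1e-7 where the naive
    expression is 0/0 at exactly representable inputs.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SINGULARITY_EPS
    safe = np.where(small, 1.0, x)
    out = np.where(
        small, 10.0 / scale, safe / (scale * (np.expm1(safe / 10.0)))
    )
    return out if out.ndim else float(out)


def gating_rates(V) -> GatingRates:
    """Opening/closing rates (ms^-1) of the h, n and m gates at voltage V.

    The temperature factor gating_phi multiplies dh/dt and dn/dt at the
    right-hand-side level, not the rates themselves.
    """
    _check_finite(V)
    V = np.asarray(V, dtype=float)
    alpha_h = 0.07 * np.exp((-V - 58.0) / 20.0)
    beta_h = 1.0 / (np.exp((-28.0 - V) / 10.0) + 1.0)
    alpha_n = _ratefrac(-34.0 - V, 100.0)
    beta_n = 0.125 * np.exp((-V - 44.0) / 80.0)
    alpha_m = _ratefrac(-35.0 - V, 10.0)
    beta_m = 4.0 * np.exp((-V - 60.0) / 18.0)

    def _s(x):
        x = np.asarray(x)
        return float(x) if x.ndim == 0 else x

    return GatingRates(*(_s(r) for r in
                         (alpha_h, beta_h, alpha_n, beta_n, alpha_m, beta_m)))


def m_inf(V):
    """Steady-state activation of the transient Na+ current."""
    r = gating_rates(V)
    return r.alpha_m / (r.alpha_m + r.beta_m)


def h_inf(V):
    r = gating_rates(V)
    return r.alpha_h / (r.alpha_h + r.beta_h)


def n_inf(V):
    r = gating_rates(V)
    return r.alpha_n / (r.alpha_n + r.beta_n)


def reversal_EK(K_out, p: ModelParameters):
    """Nernst potential of K+ (mV) for extracellular concentration K_out."""
    if np.any(np.asarray(K_out) <= 0):
        raise ValueError("K_out must be strictly positive")
    out = p.nernst_prefactor * np.log(np.asarray(K_out, dtype=float) / p.K_in_ref)
    return float(out) if np.ndim(out) == 0 else out


def reversal_ENa(Na_in, p: ModelParameters):
    """Nernst potential of Na+ (mV) for intracellular concentration Na_in."""
    if np.any(np.asarray(Na_in) <= 0):
        raise ValueError("Na_in must be strictly positive")
    out = p.nernst_prefactor * np.log(p.Na_out_ref / np.asarray(Na_in, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def pump_current(K_out, p: ModelParameters, Na_in=None):
    """Na+/K+-ATPase current (uA/cm^2), sigmoidal in [K+]_out.

    Base model: I_max / (1 + exp((K_half - K_out)/K_slope)).  The extended
    (sodium_dynamic) model is additionally divided by the analogous sigmoid
    in [Na+]_in.  Bounded in (0, I_max), monotone increasing in both
    concentrations.
    """
    if np.any(np.asarray(K_out) <= 0):
        raise ValueError("K_out must be strictly positive")
    I = p.I_max / (1.0 + np.exp((p.K_half - np.asarray(K_out, dtype=float)) / p.K_slope))
    if p.sodium_dynamic:
        if Na_in is None:
            raise ValueError("sodium_dynamic model requires Na_in")
        I = I / (1.0 + np.exp((p.Na_half - np.asarray(Na_in, dtype=float)) / p.Na_slope))
    return float(I) if np.ndim(I) == 0 else I


def ionic_currents(s: FullState, p: ModelParameters) -> Currents:
    """All four membrane currents at a given state (uA/cm^2)."""
    E_Na = reversal_ENa(s.Na_in, p) if p.sodium_dynamic else p.E_Na
    I_Na = p.g_Na * s.h * m_inf(s.V) ** 3 * (s.V - E_Na)
    I_K = p.g_K * s.n ** 4 * (s.V - reversal_EK(s.K_out, p))
    I_L = p.g_L * (s.V - p.E_L)
    I_P = pump_current(s.K_out, p, s.Na_in)
    return Currents(I_Na, I_K, I_L, I_P)


def fast_rhs(f, K_out: float, p: ModelParameters, Na_in=None) -> np.ndarray:
    """d(V, h, n)/dt of the fast subsystem with [K+]_out frozen.

    ``f`` may be a FastState or a length-3 array (V, h, n).  The pump term
    enters dV/dt only for the electrogenic variant.
    """
    if isinstance(f, FastState):
        V, h, n = f.V, f.h, f.n
    else:
        V, h, n = f
    s = FullState(V, h, n, K_out, Na_in)
    cur = ionic_currents(s, p)
    I_P = cur.I_P if p.electrogenic else 0.0
    dV = (p.I_app - cur.I_Na - cur.I_K - cur.I_L - I_P) / p.C
    r = gating_rates(V)
    dh = p.gating_phi * (r.alpha_h * (1.0 - h) - r.beta_h * h)
    dn = p.gating_phi * (r.alpha_n * (1.0 - n) - r.beta_n * n)
    return np.array([dV, dh, dn])


def full_rhs(s, p: ModelParameters) -> np.ndarray:
    """Time derivative of the complete system.

    Returns (dV, dh, dn, dK_out)/dt, plus dNa_in/dt for the extended model.
    dK_out/dt = (I_K - 2 I_P) * gamma_out; dNa_in/dt = (-I_Na - 3 I_P) * gamma_in.
    """
    if not isinstance(s, FullState):
        arr = np.asarray(s, dtype=float)
        s = FullState(*arr[:4], Na_in=arr[4] if arr.size > 4 else None)
    cur = ionic_currents(s, p)
    dfast = fast_rhs(s.fast, s.K_out, p, s.Na_in)
    dK = (cur.I_K - 2.0 * cur.I_P) * p.gamma_out
    if p.sodium_dynamic:
        dNa = (-cur.I_Na - 3.0 * cur.I_P) * p.gamma_in
        return np.append(dfast, [dK, dNa])
    return np.append(dfast, dK)


def resting_initial_state(p: ModelParameters, V: float = -65.0,
                          K_out: float = 4.8, Na_in: float = 18.4) -> FullState:
    """Default initial condition: gates at steady state for V, low [K+]_out."""
    return FullState(V, h_inf(V), n_inf(V), K_out,
                     Na_in if p.sodium_dynamic else None)
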