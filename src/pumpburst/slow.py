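"""Reduced slow subsystem: averaged [K+]_out dynamics and the hysteresis loop.

On the spiking branch the slow variable only senses the one-period average
of the fast currents: d[K+]_out/dt = gamma_out / tau * integral over one
limit-cycle period of (I_K - 2 I_P).  On a resting branch the fast
subsystem sits on a fixed point and the instantaneous continuity equation
applies directly.  Assembling both against the fast-subsystem bifurcation
markers yields the hysteresis diagram from which the complete-system
regime (bursting / tonic / depolarization block / rest) is predicted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .bifurcation import (BifurcationPoint, CycleNotFound, LimitCycle,
                          classify_cycle_death, find_equilibria,
                          find_limit_cycle, locate_fold, locate_hopf)
from .model import pump_current, reversal_EK
from .params import ModelParameters

#: averaging-validity guards: flag points closer than this to the branch end
#: or with periods beyond this as unreliable (timescale separation breaks)
HOM_EXCLUSION_MM = 0.05
TAU_VALID_MS = 500.0


class NoCycleError(RuntimeError):
    """No fast-subsystem limit cycle here; evaluate a resting branch instead."""


class FixedPointAbsentError(RuntimeError):
    pass


@dataclass
class ReducedBranch:
    kind: str                  # spiking | resting_low | resting_up
    K_out: np.ndarray
    dKdt: np.ndarray           # mM/ms
    valid: np.ndarray          # bool per point
    period: Optional[np.ndarray] = None   # ms, spiking branch only


@dataclass
class ReducedFixedPoint:
    K_out: float
    branch: str
    stable: bool
    slope: float


@dataclass
class HysteresisDiagram:
    I_app: float
    I_max: float
    branches: List[ReducedBranch]
    markers: List[BifurcationPoint]
    fixed_points: List[ReducedFixedPoint]
    params: Optional["ModelParameters"] = None

    def branch(self, kind: str) -> Optional[ReducedBranch]:
        for b in self.branches:
            if b.kind == kind:
                return b
        return None

    def marker(self, type_: str) -> Optional[BifurcationPoint]:
        for m in self.markers:
            if m.type == type_:
                return m
        return None


def _cycle_mean_IK(cycle: LimitCycle, p: ModelParameters) -> float:
    """Time average of I_K over one period (trapezoid on the cycle samples)."""
    V = cycle.states[:, 0]
    n = cycle.states[:, 2]
    IK = p.g_K * n ** 4 * (V - reversal_EK(cycle.K_out, p))
    return float(np.trapezoid(IK, cycle.times) / (cycle.times[-1] - cycle.times[0]))


def averaged_kout_derivative(K_out: float, I_app: float, p: ModelParameters,
                             cycle: Optional[LimitCycle] = None,
                             **cycle_kwargs) -> float:
    """d[K+]_out/dt (mM/ms) on the spiking branch at frozen K_out.

    The fast-subsystem limit cycle is averaged over one period; since the
    pump current depends only on the frozen K_out it contributes its
    instantaneous value.
    """
    if cycle is None:
        try:
            cycle = find_limit_cycle(K_out, I_app, p,
                                     compute_floquet=False, **cycle_kwargs)
        except CycleNotFound as e:
            raise NoCycleError(str(e)) from e
    q = p.replace(I_app=I_app)
    IP = pump_current(K_out, q)
    return (_cycle_mean_IK(cycle, q) - 2.0 * IP) * p.gamma_out


def resting_kout_derivative(K_out: float, I_app: float, p: ModelParameters,
                            which: str = "rest") -> float:
    """d[K+]_out/dt (mM/ms) with the fast subsystem on a fixed point.

    which="rest" uses the lowest-V stable equilibrium, which="upstate" the
    highest-V stable one (the depolarized state above the Hopf).
    """
    q = p.replace(I_app=I_app)
    eqs = [e for e in find_equilibria(K_out, I_app, p)
           if e.stability.startswith("stable")]
    if not eqs:
        raise FixedPointAbsentError(
            f"no stable fixed point at K_out={K_out}, I_app={I_app}")
    e = eqs[0] if which == "rest" else eqs[-1]
    if which == "rest" and e.V > -45.0:
        raise FixedPointAbsentError(
            f"no low-voltage rest state at K_out={K_out}, I_app={I_app}")
    if which == "upstate" and e.V <= -45.0:
        raise FixedPointAbsentError(
            f"no depolarized fixed point at K_out={K_out}, I_app={I_app}")
    IK = q.g_K * e.n ** 4 * (e.V - reversal_EK(K_out, q))
    IP = pump_current(K_out, q)
    return (IK - 2.0 * IP) * p.gamma_out


def _branch_fixed_points(branch: ReducedBranch) -> List[ReducedFixedPoint]:
    out = []
    K, d = branch.K_out, branch.dKdt
    for i in range(len(K) - 1):
        if not (np.isfinite(d[i]) and np.isfinite(d[i + 1])):
            continue
        if d[i] == 0.0 or np.sign(d[i]) * np.sign(d[i + 1]) < 0:
            frac = d[i] / (d[i] - d[i + 1])
            K0 = K[i] + frac * (K[i + 1] - K[i])
            slope = (d[i + 1] - d[i]) / (K[i + 1] - K[i])
            out.append(ReducedFixedPoint(float(K0), branch.kind,
                                         bool(slope < 0), float(slope)))
    return out


def assemble_hysteresis(I_app: float, p: ModelParameters,
                        K_window: Tuple[float, float] = (3.0, 16.0),
                        n_spiking: int = 40, n_resting: int = 40,
                        boundary_tol: float = 1e-6) -> HysteresisDiagram:
    """Sample all reduced branches and the fast-subsystem markers.

    The spiking branch runs from the window floor to the orbit's death
    (HOM/SNIC/FLC), the low-voltage resting branch from the fold (SN) up,
    and the depolarized resting branch from the Hopf up.  Points inside the
    averaging exclusion zone near the branch end, or with period beyond the
    validity cut, are flagged invalid.
    """
    markers: List[BifurcationPoint] = []
    sn = locate_fold(I_app, p, K_window=(K_window[0], K_window[1]))
    if sn:
        markers.append(sn)
    hopf = locate_hopf(I_app, p, K_window=(K_window[0], max(30.0, K_window[1])))
    if hopf:
        markers.append(hopf)
    death = classify_cycle_death(I_app, p, K_window=K_window, tol=boundary_tol)
    if death:
        markers.append(death)

    branches: List[ReducedBranch] = []

    if death is not None:
        Ks = np.linspace(K_window[0], death.K_out - 0.2, n_spiking)
        # geometric tail: the averaged derivative varies logarithmically on
        # the approach to a homoclinic, so equidistant sampling misses
        # reduced fixed points near the branch end.  The tail stops at
        # 1e-3 mM below the boundary — averaged values at distances smaller
        # than a tiny fraction of the per-cycle slow increment (~0.03 mM
        # here) no longer describe the complete system's motion
        deltas = np.geomspace(0.2, max(1e-3, 3.0 * boundary_tol), 12)
        tail = death.K_out - deltas
        Ks = np.unique(np.concatenate([Ks[Ks < death.K_out - 0.2], tail]))
        Ks = Ks[Ks > K_window[0]]
        vals = np.full(len(Ks), np.nan)
        valid = np.zeros(len(Ks), dtype=bool)
        periods = np.full(len(Ks), np.nan)
        guess = None
        prev_period = 30.0
        for i, K in enumerate(Ks):
            try:
                # convergence onto the orbit slows near the branch end (the
                # leading Floquet multiplier approaches 1), so the settle
                # time scales with the period and shooting polishes the rest
                cyc = find_limit_cycle(K, I_app, p, guess=guess,
                                       settle=2000.0 if guess is None
                                       else min(max(1000.0, 25.0 * prev_period),
                                                8000.0),
                                       polish=True, compute_floquet=False)
                prev_period = cyc.period
            except CycleNotFound:
                continue
            guess = cyc.states[0]
            vals[i] = averaged_kout_derivative(K, I_app, p, cycle=cyc)
            periods[i] = cyc.period
            valid[i] = (cyc.period <= TAU_VALID_MS
                        and death.K_out - K >= HOM_EXCLUSION_MM)
        branches.append(ReducedBranch("spiking", Ks, vals, valid, periods))

    if sn is not None:
        Ks = np.linspace(sn.K_out + 1e-3, K_window[1], n_resting)
        vals, valid = np.full(len(Ks), np.nan), np.zeros(len(Ks), dtype=bool)
        for i, K in enumerate(Ks):
            try:
                vals[i] = resting_kout_derivative(K, I_app, p, "rest")
                valid[i] = True
            except FixedPointAbsentError:
                pass
        branches.append(ReducedBranch("resting_low", Ks, vals, valid))

    if hopf is not None:
        Ks = np.linspace(hopf.K_out + 1e-3,
                         max(K_window[1], hopf.K_out + 5.0), n_resting)
        vals, valid = np.full(len(Ks), np.nan), np.zeros(len(Ks), dtype=bool)
        for i, K in enumerate(Ks):
            try:
                vals[i] = resting_kout_derivative(K, I_app, p, "upstate")
                valid[i] = True
            except FixedPointAbsentError:
                pass
        branches.append(ReducedBranch("resting_up", Ks, vals, valid))

    fixed_points: List[ReducedFixedPoint] = []
    for b in branches:
        fixed_points.extend(_branch_fixed_points(b))

    return HysteresisDiagram(I_app, p.I_max, branches, markers, fixed_points,
                             params=p)


def _crossing_validity(fp: ReducedFixedPoint, spk: ReducedBranch,
                       death: BifurcationPoint) -> bool:
    """Is a reduced fixed point inside the averaging-valid region?

    Valid means: farther than the exclusion distance from the branch end
    and at a cycle period below the validity cut (period interpolated from
    the sampled branch).
    """
    if death.K_out - fp.K_out < HOM_EXCLUSION_MM:
        return False
    if spk.period is not None:
        good = np.isfinite(spk.period)
        tau = float(np.interp(fp.K_out, spk.K_out[good], spk.period[good]))
        if tau > TAU_VALID_MS:
            return False
    return True


def predict_complete_dynamics(diagram: HysteresisDiagram,
                              simulate_when_inconclusive: bool = True) -> str:
    """Regime of the complete system read off the reduced diagram.

    Decision rule:

    * no spiking branch -> rest;
    * spiking orbit destroyed on the fold itself (SNIC; below the
      saddle-node loop) -> tonic: with no bistable strip a hysteresis loop
      cannot form, and the slow flow settles at the reduced crossing (or
      rides the infinite-period onset);
    * a stable averaged crossing in the averaging-valid region (farther
      than the exclusion distance from the branch end, period below the
      validity cut) -> tonic;
    * homoclinic end with the branch positive throughout and the resting
      branch negative down to the fold -> bursting (the hysteresis loop
      closes);
    * fold-of-limit-cycles end with no valid crossing -> depolarization
      block.

    Near the tonic/bursting boundary the averaged description is known to
    break down: a crossing confined to the exclusion zone is inconclusive
    at the reduced level.  There the predictor falls back on one direct
    simulation of the complete system (the same validation step the
    averaging method always requires near fast-subsystem bifurcations);
    pass ``simulate_when_inconclusive=False`` to get the honest label
    "requires_simulation" instead.
    """
    spk = diagram.branch("spiking")
    death = None
    for t in ("HOM", "SNIC", "FLC"):
        death = diagram.marker(t) or death
    if spk is None or not np.any(np.isfinite(spk.dKdt)):
        return "rest"
    spk_fp = [f for f in diagram.fixed_points
              if f.branch == "spiking" and f.stable]
    if death is not None and death.type == "SNIC":
        return "tonic"
    valid_fp = [f for f in spk_fp
                if death is None or _crossing_validity(f, spk, death)]
    if valid_fp:
        return "tonic"
    if spk_fp:
        # crossing exists but only inside the averaging-breakdown zone
        return (_simulate_regime(diagram) if simulate_when_inconclusive
                else "requires_simulation")
    finite = np.isfinite(spk.dKdt)
    if not np.all(spk.dKdt[finite & spk.valid] > 0):
        return (_simulate_regime(diagram) if simulate_when_inconclusive
                else "requires_simulation")
    if death is not None and death.type == "FLC":
        return "depolarization_block"
    rest = diagram.branch("resting_low")
    if death is not None and death.type == "HOM" and rest is not None:
        ok = rest.valid & np.isfinite(rest.dKdt)
        between = rest.K_out <= death.K_out
        if np.all(rest.dKdt[ok & between] < 0):
            return "bursting"
    return (_simulate_regime(diagram) if simulate_when_inconclusive
            else "requires_simulation")


def _simulate_regime(diagram: HysteresisDiagram) -> str:
    """Direct complete-system classification at the diagram's parameters."""
    from .simulate import run_and_summarize
    p = diagram.params if diagram.params is not None else ModelParameters(
        I_max=diagram.I_max)
    q = p.replace(I_app=diagram.I_app)
    return run_and_summarize(q)[2].regime
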