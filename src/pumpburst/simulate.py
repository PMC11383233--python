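"""Time integration, spike detection, burst statistics, regime classification.

The workhorse integrator is a fixed-step classical RK4 (default
dt = 0.005 ms) compiled with numba; an adaptive Runge-Kutta 4(5) mode via
scipy is available for cross-checking.  Everything downstream (burst
segmentation, the four-regime classifier, spike-count transition search)
operates on the recorded trajectory and is fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .model import FullState, resting_initial_state
from .params import ModelParameters

REGIMES = ("rest", "tonic", "bursting", "depolarization_block", "undetermined")


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class BracketError(ValueError):
    """Raised when a bisection bracket does not separate the two behaviours."""


@dataclass
class Trajectory:
    """Recorded time series of the complete or fast subsystem."""
    times: np.ndarray                 # ms, strictly increasing
    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    K_out: Optional[np.ndarray]       # None for fast-subsystem runs
    Na_in: Optional[np.ndarray]       # None unless sodium_dynamic
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.V) != len(self.times):
            raise ValueError("state count must equal time count")

    def state_array(self) -> np.ndarray:
        cols = [self.V, self.h, self.n]
        if self.K_out is not None:
            cols.append(self.K_out)
        if self.Na_in is not None:
            cols.append(self.Na_in)
        return np.column_stack(cols)

    def window(self, t_lo: float, t_hi: Optional[float] = None) -> "Trajectory":
        t_hi = self.times[-1] if t_hi is None else t_hi
        m = (self.times >= t_lo) & (self.times <= t_hi)
        pick = lambda a: None if a is None else a[m]
        return Trajectory(self.times[m], self.V[m], self.h[m], self.n[m],
                          pick(self.K_out), pick(self.Na_in),
                          self.params, dict(self.meta))


@dataclass
class SpikeTrain:
    spike_times: np.ndarray   # ms
    threshold: float          # mV
    refractory: float         # ms

    def __len__(self):
        return len(self.spike_times)


@dataclass
class BurstSummary:
    regime: str
    spikes_per_burst: Tuple[int, ...]        # complete bursts only
    interburst_period: float                 # ms, first spike to first spike
    interburst_interval: float               # ms, quiescent gap between bursts
    intra_burst_isi_mean: float
    K_out_min: float
    K_out_max: float
    period_doubled: bool
    n_bursts: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def modal_spikes_per_burst(self) -> int:
        if not self.spikes_per_burst:
            return 0
        vals, counts = np.unique(np.asarray(self.spikes_per_burst), return_counts=True)
        return int(vals[np.argmax(counts)])


def _initial_vector(p: ModelParameters, initial) -> np.ndarray:
    if initial is None:
        initial = resting_initial_state(p)
    if isinstance(initial, FullState):
        na = initial.Na_in if initial.Na_in is not None else 18.4
        return np.array([initial.V, initial.h, initial.n, initial.K_out, na])
    arr = np.asarray(initial, dtype=float)
    if arr.size == 4:
        arr = np.append(arr, 18.4)
    return arr


def integrate(p: ModelParameters, initial=None, t_end: float = 12000.0,
              dt: float = 0.005, transient_discard: float = 0.0,
              record_stride: int = 4, method: str = "rk4",
              system: str = "full", K_out: Optional[float] = None,
              rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the complete system or the fast subsystem at frozen K_out.

    Parameters mirror the published numerics: classical RK4 with
    dt = 0.005 ms by default; ``method="rk45"`` switches to an adaptive
    embedded Runge-Kutta (scipy) recorded on the same output grid.
    States at t < transient_discard are dropped from the returned
    trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not t_end > transient_discard >= 0:
        raise ValueError("require t_end > transient_discard >= 0")
    y0 = _initial_vector(p, initial)
    pt = p.kernel_tuple()
    meta = {"method": method, "dt": dt, "record_stride": record_stride,
            "system": system, "t_end": t_end,
            "transient_discard": transient_discard}

    if system == "fast":
        K = y0[3] if K_out is None else float(K_out)
        meta["K_out"] = K
        if method == "rk4":
            times, states, _ = _kernels.rk4_fast(y0, K, pt, t_end, dt,
                                                 record_stride)
        else:
            times, states = _solve_ivp(p, y0, t_end, dt * record_stride,
                                       system, K, rtol, atol)
        traj = Trajectory(times, states[:, 0], states[:, 1], states[:, 2],
                          None, None, p, meta)
    else:
        if method == "rk4":
            times, states, _ = _kernels.rk4_full(y0, pt, t_end, dt,
                                                 record_stride)
        else:
            times, states = _solve_ivp(p, y0, t_end, dt * record_stride,
                                       system, None, rtol, atol)
        na = states[:, 4] if p.sodium_dynamic else None
        traj = Trajectory(times, states[:, 0], states[:, 1], states[:, 2],
                          states[:, 3], na, p, meta)

    if traj.times[-1] < t_end - dt * record_stride * 1.5:
        raise IntegrationError(
            f"state became non-finite at t ~ {traj.times[-1]:.3f} ms",
            last_valid_time=float(traj.times[-1]))
    if transient_discard > 0:
        traj = traj.window(transient_discard)
    return traj


def _solve_ivp(p, y0, t_end, dt_out, system, K, rtol, atol):
    from scipy.integrate import solve_ivp

    from .model import fast_rhs, full_rhs
    if system == "fast":
        fun = lambda t, y: fast_rhs(y, K, p, Na_in=y0[4] if p.sodium_dynamic else None)
        y_init = y0[:3]
    else:
        fun = lambda t, y: full_rhs(y, p)
        y_init = y0 if p.sodium_dynamic else y0[:4]
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(fun, (0.0, t_end), y_init, method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message, last_valid_time=float(sol.t[-1]))
    states = sol.y.T
    if states.shape[1] == 4:
        states = np.column_stack([states, np.full(len(sol.t), y0[4])])
    elif states.shape[1] == 3:
        pass
    return sol.t, states


def detect_spikes(traj: Trajectory, threshold: float = 0.0,
                  refractory: float = 2.0) -> SpikeTrain:
    """Spike times from upward threshold crossings, linearly interpolated.

    Crossings closer than the refractory window to the previous accepted
    spike are discarded.
    """
    V, t = traj.V, traj.times
    idx = np.nonzero((V[:-1] < threshold) & (V[1:] >= threshold))[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.asarray(times), threshold, refractory)


def _bimodal_split(isis: np.ndarray, gap_ratio: float = 3.0):
    """Split sorted ISIs at the largest adjacent ratio.

    Returns (is_bimodal, split_value).  Bimodal requires the largest
    adjacent ratio among sorted ISIs to exceed ``gap_ratio`` with at least
    two members in each class.
    """
    if len(isis) < 4:
        return False, None
    srt = np.sort(isis)
    ratios = srt[1:] / srt[:-1]
    i = int(np.argmax(ratios))
    ok = ratios[i] > gap_ratio and (i + 1) >= 2 and (len(srt) - i - 1) >= 2
    if not ok:
        return False, None
    return True, float(np.sqrt(srt[i] * srt[i + 1]))


def _period_doubled(isis: np.ndarray) -> bool:
    """True when the ISI sequence alternates between two distinct values."""
    if len(isis) < 6:
        return False
    even, odd = isis[0::2], isis[1::2]
    mean = isis.mean()
    tight = (even.std() < 0.02 * mean) and (odd.std() < 0.02 * mean)
    distinct = abs(even.mean() - odd.mean()) > 0.05 * mean
    return bool(tight and distinct)


def classify_regime(traj: Trajectory, spikes: Optional[SpikeTrain] = None, *,
                    rest_ceiling: float = -60.0, block_floor: float = -50.0,
                    tail_window: float = 2000.0) -> str:
    """Label the post-transient dynamics.

    rest: no spiking in the tail and the voltage settles below the rest
    ceiling.  depolarization_block: no spiking in the tail while the voltage
    stays above the block floor (upstate) with [K+]_out settled high or still
    rising.  tonic: unimodal inter-spike intervals.  bursting: bimodal.
    Anything ambiguous is labelled "undetermined" rather than guessed.
    """
    if spikes is None:
        spikes = detect_spikes(traj)
    t_hi = traj.times[-1]
    tail = traj.window(max(traj.times[0], t_hi - tail_window))
    tail_spikes = spikes.spike_times[spikes.spike_times >= tail.times[0]]
    if len(tail_spikes) == 0:
        v_tail = float(np.mean(tail.V))
        v_settled = float(np.ptp(tail.V[-max(10, len(tail.V) // 10):]))
        if v_tail <= rest_ceiling and v_settled < 5.0:
            return "rest"
        if v_tail >= block_floor:
            if tail.K_out is None:
                return "depolarization_block"
            k = tail.K_out
            if k[-1] >= k[0] - 1e-6 or np.ptp(k[-len(k) // 4:]) < 0.05:
                return "depolarization_block"
        return "undetermined"
    if len(spikes) < 4:
        return "undetermined"
    isis = np.diff(spikes.spike_times)
    bimodal, _ = _bimodal_split(isis)
    return "bursting" if bimodal else "tonic"


def summarize_bursts(spikes: SpikeTrain, traj: Trajectory,
                     gap_threshold: Optional[float] = None) -> BurstSummary:
    """Burst statistics from a spike train and its trajectory.

    Inter-spike intervals are split into intra- and inter-burst classes at
    the largest gap of the sorted log-ISI sequence (bimodality criterion).
    ``interburst_period`` is the mean interval between first spikes of
    successive bursts (the full burst-cycle period); ``interburst_interval``
    is the mean quiescent gap separating consecutive bursts.  [K+]_out
    extrema are measured over complete cycles only.
    """
    regime = classify_regime(traj, spikes)
    st = spikes.spike_times
    diag: dict = {}
    if regime in ("rest", "depolarization_block", "undetermined") or len(st) < 2:
        k = traj.K_out
        return BurstSummary(regime, (), np.nan, np.nan, np.nan,
                            float(k.min()) if k is not None else np.nan,
                            float(k.max()) if k is not None else np.nan,
                            False, 0, diag)
    isis = np.diff(st)
    if regime == "tonic":
        k = traj.K_out
        if k is not None:
            # settled portion only, so the slow approach to the attractor
            # does not inflate the per-spike ripple
            settled = traj.times >= traj.times[0] + 2.0 * (traj.times[-1] - traj.times[0]) / 3.0
            kmin, kmax = float(k[settled].min()), float(k[settled].max())
        else:
            kmin = kmax = np.nan
        return BurstSummary("tonic", (), np.nan, np.nan, float(isis.mean()),
                            kmin, kmax, _period_doubled(isis), 0, diag)

    if gap_threshold is None:
        _, gap_threshold = _bimodal_split(isis)
    diag["gap_threshold"] = gap_threshold
    gaps = np.nonzero(isis > gap_threshold)[0]
    bursts = np.split(st, gaps + 1)
    if len(bursts) < 3:
        diag["reason"] = "fewer than 3 burst cycles in window"
        return BurstSummary("undetermined", (), np.nan, np.nan, np.nan,
                            np.nan, np.nan, False, len(bursts), diag)
    complete = bursts[1:-1]
    counts = tuple(len(b) for b in complete)
    firsts = np.array([b[0] for b in bursts])
    period = float(np.diff(firsts).mean())
    gaps_ms = np.array([bursts[i + 1][0] - bursts[i][-1]
                        for i in range(len(bursts) - 1)])
    intra = isis[isis <= gap_threshold]
    k = traj.K_out
    if k is not None:
        m = (traj.times >= firsts[1]) & (traj.times <= firsts[-1])
        kmin, kmax = float(k[m].min()), float(k[m].max())
    else:
        kmin = kmax = np.nan
    return BurstSummary("bursting", counts, period, float(gaps_ms.mean()),
                        float(intra.mean()), kmin, kmax,
                        _period_doubled(np.asarray(counts, dtype=float))
                        if len(counts) >= 6 else False,
                        len(complete), diag)


def run_and_summarize(p: ModelParameters, initial=None, t_end: float = 12000.0,
                      transient_discard: float = 2000.0, dt: float = 0.005,
                      record_stride: int = 4) -> Tuple[Trajectory, SpikeTrain, BurstSummary]:
    """Convenience: integrate, detect spikes, summarize."""
    traj = integrate(p, initial=initial, t_end=t_end, dt=dt,
                     transient_discard=transient_discard,
                     record_stride=record_stride)
    spikes = detect_spikes(traj)
    return traj, spikes, summarize_bursts(spikes, traj)


def _measured_count(p: ModelParameters, t_end, transient, dt) -> int:
    _, _, summ = run_and_summarize(p, t_end=t_end,
                                   transient_discard=transient, dt=dt)
    return summ.modal_spikes_per_burst


def locate_spike_count_transition(p: ModelParameters, vary: str,
                                  bracket: Sequence[float],
                                  counts: Tuple[int, int],
                                  tol: float = 1e-4, t_end: float = 12000.0,
                                  transient_discard: float = 2000.0,
                                  dt: float = 0.005,
                                  count_fn=None) -> float:
    """Bisection on a parameter for the boundary between k- and (k+1)-spike bursts.

    Each evaluation runs a fresh transient-discarded simulation and takes
    the modal spikes-per-burst count.  ``count_fn(p) -> int`` may replace
    the simulation-based count (used with synthetic fixtures).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    k_lo_expect, k_hi_expect = counts
    if count_fn is None:
        count_fn = lambda q: _measured_count(q, t_end, transient_discard, dt)
    c_lo = count_fn(p.replace(**{vary: lo}))
    c_hi = count_fn(p.replace(**{vary: hi}))
    if c_lo == c_hi:
        raise BracketError(
            f"identical spike counts ({c_lo}) at both bracket ends")
    if {c_lo, c_hi} != set(counts):
        raise BracketError(
            f"bracket counts ({c_lo}, {c_hi}) do not match requested {counts}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        c_mid = count_fn(p.replace(**{vary: mid}))
        # assign off-bracket counts (mixed patterns near the boundary)
        # to the nearer end
        if c_mid == c_lo or (c_mid not in (c_lo, c_hi)
                             and abs(c_mid - c_lo) <= abs(c_mid - c_hi)):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
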