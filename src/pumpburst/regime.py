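"""Parameter-plane scans of the complete system.

Maps the four regimes (rest, tonic spiking, bursting, depolarization
block) over the pump-density / applied-current plane and measures the
[K+]_out oscillation amplitude along I_max sweeps.  Cells are simulated
independently and deterministically, so results do not depend on
evaluation order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import ModelParameters
from .simulate import BurstSummary, run_and_summarize


@dataclass
class RegimeGrid:
    I_max_values: np.ndarray
    I_app_values: np.ndarray
    labels: np.ndarray                     # (n_imax, n_iapp) object array
    summaries: Dict[Tuple[float, float], BurstSummary]

    def label(self, I_max: float, I_app: float) -> str:
        i = int(np.argmin(np.abs(self.I_max_values - I_max)))
        j = int(np.argmin(np.abs(self.I_app_values - I_app)))
        return self.labels[i, j]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, imax in enumerate(self.I_max_values):
            for j, iapp in enumerate(self.I_app_values):
                s = self.summaries[(float(imax), float(iapp))]
                rows.append({
                    "I_max": imax, "I_app": iapp,
                    "regime": self.labels[i, j],
                    "spikes_per_burst": s.modal_spikes_per_burst,
                    "interburst_ms": s.interburst_interval,
                    "Kout_min": s.K_out_min, "Kout_max": s.K_out_max,
                    "period_doubled": s.period_doubled,
                })
        return pd.DataFrame(rows)


def scan_regimes(I_max_values: Sequence[float], I_app_values: Sequence[float],
                 p: ModelParameters, t_end: float = 12000.0,
                 transient_discard: float = 2000.0, dt: float = 0.005,
                 initial=None) -> RegimeGrid:
    """Classify one simulation per (I_max, I_app) cell.

    Default initial conditions start at low [K+]_out; pass ``initial`` to
    probe the coexisting depolarization-block attractor from high [K+]_out.
    """
    I_max_values = np.asarray(I_max_values, dtype=float)
    I_app_values = np.asarray(I_app_values, dtype=float)
    labels = np.empty((len(I_max_values), len(I_app_values)), dtype=object)
    summaries: Dict[Tuple[float, float], BurstSummary] = {}
    for i, imax in enumerate(I_max_values):
        for j, iapp in enumerate(I_app_values):
            q = p.replace(I_max=float(imax), I_app=float(iapp))
            _, _, summ = run_and_summarize(q, initial=initial, t_end=t_end,
                                           transient_discard=transient_discard,
                                           dt=dt)
            labels[i, j] = summ.regime
            summaries[(float(imax), float(iapp))] = summ
    return RegimeGrid(I_max_values, I_app_values, labels, summaries)


def refine_boundary(p: ModelParameters, I_app: float,
                    bracket: Tuple[float, float],
                    labels: Tuple[str, str], tol: float = 1e-3,
                    t_end: float = 12000.0,
                    transient_discard: float = 2000.0) -> float:
    """Bisect I_max between two regime labels along a fixed-I_app row."""
    lo, hi = bracket

    def lab(imax):
        q = p.replace(I_max=imax, I_app=I_app)
        return run_and_summarize(q, t_end=t_end,
                                 transient_discard=transient_discard)[2].regime

    l_lo, l_hi = lab(lo), lab(hi)
    if l_lo != labels[0] or l_hi != labels[1]:
        raise ValueError(f"bracket labels ({l_lo}, {l_hi}) != requested {labels}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if lab(mid) == labels[0]:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def amplitude_curves(I_app_values: Sequence[float],
                     I_max_values: Sequence[float], p: ModelParameters,
                     t_end: float = 12000.0, transient_discard: float = 2000.0,
                     dt: float = 0.005) -> pd.DataFrame:
    """[K+]_out oscillation extrema per (I_app, I_max) cell.

    For bursting/tonic cells the extrema are taken over post-transient
    cycles; depolarization-block cells report the settling trend (start and
    end of the post-transient [K+]_out trace) instead of oscillation
    extrema.
    """
    rows = []
    for iapp in I_app_values:
        for imax in I_max_values:
            q = p.replace(I_max=float(imax), I_app=float(iapp))
            traj, _, summ = run_and_summarize(
                q, t_end=t_end, transient_discard=transient_discard, dt=dt)
            if summ.regime == "depolarization_block":
                kmin, kmax = float(traj.K_out[0]), float(traj.K_out[-1])
            else:
                kmin, kmax = summ.K_out_min, summ.K_out_max
            rows.append({"I_app": iapp, "I_max": imax, "regime": summ.regime,
                         "Kout_min": kmin, "Kout_max": kmax,
                         "amplitude": kmax - kmin,
                         "period_doubled": summ.period_doubled})
    return pd.DataFrame(rows)
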