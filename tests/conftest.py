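"""Shared fixtures: the reference bursting run and the four anchor cases.

Session-scoped because the simulations and hysteresis diagrams are the
expensive inputs that many tests interrogate.
"""
import numpy as np
import pytest

import pumpburst as pb

#: the four labelled parameter points of the complete-system regime study:
#: (I_max, I_app) -> expected regime
ANCHORS = {
    (1.0, 0.25): "tonic",
    (1.0, 0.5): "bursting",
    (1.0, 0.9): "depolarization_block",
    (2.0, 1.0): "tonic",
}

#: K_out windows bracketing the fast-subsystem structure at each anchor
ANCHOR_WINDOWS = {
    (1.0, 0.25): (6.0, 12.0),
    (1.0, 0.5): (9.0, 12.0),
    (1.0, 0.9): (6.0, 18.0),
    (2.0, 1.0): (6.0, 16.0),
}


@pytest.fixture(scope="session")
def p_ref():
    """Reference bursting configuration (I_app = 0.5, I_max = 1)."""
    return pb.ModelParameters()


@pytest.fixture(scope="session")
def burst_run(p_ref):
    """Settled bursting attractor: 20 s simulated, 8 s discarded."""
    return pb.run_and_summarize(p_ref, t_end=20000.0, transient_discard=8000.0)


@pytest.fixture(scope="session")
def anchor_summaries(p_ref):
    """Direct-simulation burst summaries at the four anchor points."""
    out = {}
    for (imax, iapp) in ANCHORS:
        q = p_ref.replace(I_max=imax, I_app=iapp)
        out[(imax, iapp)] = pb.run_and_summarize(q)[2]
    return out


@pytest.fixture(scope="session")
def anchor_diagrams(p_ref):
    """Reduced slow-subsystem diagrams at the four anchor points."""
    out = {}
    for (imax, iapp), window in ANCHOR_WINDOWS.items():
        q = p_ref.replace(I_max=imax)
        out[(imax, iapp)] = pb.assemble_hysteresis(iapp, q, K_window=window)
    return out


@pytest.fixture(scope="session")
def hysteresis_ref(anchor_diagrams):
    """Hysteresis diagram at the reference bursting parameters."""
    return anchor_diagrams[(1.0, 0.5)]


@pytest.fixture(scope="session")
def cycle_ref(p_ref):
    """Polished fast-subsystem limit cycle in the tonic region (K = 9)."""
    return pb.find_limit_cycle(9.0, 0.5, p_ref)


def make_trajectory(times, V, params=None, K_out=None):
    """Synthetic trajectory helper for spike-detection fixtures."""
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    z = np.zeros_like(V)
    return pb.Trajectory(times, V, z, z,
                         None if K_out is None else np.asarray(K_out),
                         None, params or pb.ModelParameters(), {})
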