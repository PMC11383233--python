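"""Integration, spike detection, burst statistics and regime labels."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pumpburst as pb
from conftest import make_trajectory


class TestIntegrate:
    def test_equilibrium_stays_constant(self, p_ref):
        eq = pb.find_equilibria(11.0, 0.5, p_ref)[0]
        traj = pb.integrate(p_ref, initial=np.r_[eq.state(), 11.0],
                            t_end=100.0, system="fast", K_out=11.0)
        assert np.ptp(traj.V) < 1e-7
        assert np.ptp(traj.h) < 1e-9

    def test_deterministic(self, p_ref):
        a = pb.integrate(p_ref, t_end=200.0)
        b = pb.integrate(p_ref, t_end=200.0)
        assert np.array_equal(a.V, b.V) and np.array_equal(a.K_out, b.K_out)

    def test_dt_halving_preserves_spike_times(self, p_ref):
        spikes = {}
        for dt in (0.005, 0.0025):
            traj = pb.integrate(p_ref, t_end=4000.0, dt=dt,
                                transient_discard=1000.0, record_stride=2)
            spikes[dt] = pb.detect_spikes(traj).spike_times
        a, b = spikes[0.005], spikes[0.0025]
        assert len(a) == len(b) and len(a) > 10
        assert np.max(np.abs(a - b)) < 0.1

    def test_adaptive_matches_fixed_step(self, p_ref):
        kw = dict(t_end=300.0, system="fast", K_out=9.0)
        fixed = pb.integrate(p_ref, method="rk4", dt=0.005, record_stride=8, **kw)
        adapt = pb.integrate(p_ref, method="rk45", dt=0.005, record_stride=8,
                             rtol=1e-10, atol=1e-12, **kw)
        sa = pb.detect_spikes(fixed).spike_times
        sb = pb.detect_spikes(adapt).spike_times
        assert len(sa) == len(sb)
        assert np.max(np.abs(sa - sb)) < 0.05

    def test_rk4_order_of_accuracy(self, p_ref):
        # endpoint error over a spiking stretch halves ~16x per dt halving
        from pumpburst import _kernels
        pt = p_ref.kernel_tuple()
        y0 = np.array([-20.0, pb.h_inf(-65.0), pb.n_inf(-65.0), 9.0, 18.4])
        ref = np.array(_kernels.fast_flow(y0, 9.0, pt, 30.0, 0.0005))
        errs = []
        for dt in (0.02, 0.01):
            end = np.array(_kernels.fast_flow(y0, 9.0, pt, 30.0, dt))
            errs.append(np.linalg.norm(end - ref))
        assert errs[0] / errs[1] > 8.0  # ideal 16 for order 4

    def test_invalid_arguments(self, p_ref):
        with pytest.raises(ValueError):
            pb.integrate(p_ref, t_end=100.0, dt=-1.0)
        with pytest.raises(ValueError):
            pb.integrate(p_ref, t_end=100.0, transient_discard=200.0)

    def test_nonfinite_state_reports_last_valid_time(self, p_ref):
        # a grossly unstable step size blows RK4 up
        with pytest.raises(pb.IntegrationError) as err:
            pb.integrate(p_ref, t_end=2000.0, dt=5.0, record_stride=1)
        assert err.value.last_valid_time >= 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(V0=st.floats(-90, 30), h0=st.floats(0, 1), n0=st.floats(0, 1),
           K0=st.floats(2, 20))
    def test_gating_variables_stay_in_unit_interval(self, V0, h0, n0, K0):
        p = pb.ModelParameters()
        traj = pb.integrate(p, initial=np.array([V0, h0, n0, K0]), t_end=50.0)
        assert np.all((traj.h >= 0) & (traj.h <= 1))
        assert np.all((traj.n >= 0) & (traj.n <= 1))


class TestSpikeDetection:
    def test_subthreshold_trace_has_no_spikes(self):
        t = np.linspace(0, 100, 1001)
        traj = make_trajectory(t, np.full_like(t, -60.0))
        assert len(pb.detect_spikes(traj)) == 0

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_sawtooth_crossings_counted_exactly(self, k):
        t = np.linspace(0, 100 * k, 200 * k + 1)
        V = -60.0 + 80.0 * ((t / 100.0) % 1.0)   # rises through 0 once per 100 ms
        traj = make_trajectory(t, V)
        st_ = pb.detect_spikes(traj)
        assert len(st_) == k
        assert np.all(np.diff(st_.spike_times) >= st_.refractory)

    def test_crossing_time_interpolated(self):
        t = np.array([0.0, 1.0, 2.0])
        V = np.array([-10.0, -2.0, 6.0])   # crosses 0 at t = 1.25
        st_ = pb.detect_spikes(make_trajectory(t, V))
        assert st_.spike_times[0] == pytest.approx(1.25, abs=1e-12)

    def test_refractory_suppresses_double_counting(self):
        t = np.linspace(0, 3, 301)
        V = -10.0 + 15.0 * np.sin(2 * np.pi * t)   # two upward crossings 1 ms apart
        st_ = pb.detect_spikes(make_trajectory(t, V), refractory=2.0)
        # upward crossings once per 1 ms period; the 2 ms refractory keeps
        # every other one
        assert len(st_) == 2
        assert np.all(np.diff(st_.spike_times) >= 2.0)


class TestBurstStatistics:
    def test_regular_train_is_tonic(self):
        times = np.arange(0, 5000.0, 0.5)
        V = np.full_like(times, -60.0)
        V[::40] = 20.0  # a spike every 20 ms
        traj = make_trajectory(times, V, K_out=np.full_like(times, 6.0))
        spikes = pb.detect_spikes(traj)
        summ = pb.summarize_bursts(spikes, traj)
        assert summ.regime == "tonic"
        assert not summ.period_doubled

    def test_alternating_isis_flag_period_doubling(self):
        spike_times = np.cumsum(np.tile([20.0, 30.0], 40))
        times = np.arange(0, spike_times[-1] + 50, 0.5)
        V = np.full_like(times, -60.0)
        idx = np.searchsorted(times, spike_times)
        V[idx] = 20.0
        traj = make_trajectory(times, V, K_out=np.full_like(times, 6.0))
        summ = pb.summarize_bursts(pb.detect_spikes(traj), traj)
        assert summ.regime == "tonic"
        assert summ.period_doubled

    def test_burst_reference_statistics(self, burst_run):
        _, _, summ = burst_run
        assert summ.regime == "bursting"
        assert set(summ.spikes_per_burst) == {11}
        assert summ.interburst_interval > 5 * summ.intra_burst_isi_mean
        assert summ.K_out_min < summ.K_out_max

    def test_isis_prolong_within_burst(self, burst_run):
        traj, spikes, summ = burst_run
        isis = np.diff(spikes.spike_times)
        gap = summ.diagnostics["gap_threshold"]
        bursts = np.split(spikes.spike_times, np.nonzero(isis > gap)[0] + 1)
        for b in bursts[1:-1]:
            intra = np.diff(b)
            assert np.all(np.diff(intra) > -1e-6)

    def test_kout_waxes_during_spiking_wanes_in_quiescence(self, burst_run):
        traj, spikes, summ = burst_run
        isis = np.diff(spikes.spike_times)
        gap = summ.diagnostics["gap_threshold"]
        bursts = np.split(spikes.spike_times, np.nonzero(isis > gap)[0] + 1)
        k_at = np.interp(spikes.spike_times, traj.times, traj.K_out)
        for b in bursts[1:-1]:
            kk = np.interp(b, traj.times, traj.K_out)
            assert np.all(np.diff(kk) > 0)       # waxes spike-to-spike
        # quiescent phase: K falls from last spike of one burst to just
        # before the first spike of the next
        for b0, b1 in zip(bursts[1:-2], bursts[2:-1]):
            t0, t1 = b0[-1] + 5.0, b1[0] - 5.0
            m = (traj.times >= t0) & (traj.times <= t1)
            k = traj.K_out[m]
            assert k[0] > k[-1]
            assert np.all(np.diff(k) <= 1e-9)


class TestRegimeClassification:
    def test_rest_at_subrheobase_drive(self, p_ref):
        q = p_ref.replace(I_app=0.05)
        traj = pb.integrate(q, t_end=6000.0, transient_discard=2000.0)
        assert pb.classify_regime(traj) == "rest"

    def test_undetermined_for_ambiguous_tail(self):
        t = np.linspace(0, 5000, 5001)
        traj = make_trajectory(t, np.full_like(t, -55.0),
                               K_out=np.full_like(t, 8.0))
        assert pb.classify_regime(traj) == "undetermined"


class TestSodiumVariant:
    def test_dynamic_sodium_preserves_bursting(self):
        p = pb.ModelParameters(sodium_dynamic=True, I_app=0.5, I_max=10.0)
        traj, _, summ = pb.run_and_summarize(
            p, initial=pb.resting_initial_state(p), t_end=10000.0,
            transient_discard=2000.0)
        assert summ.regime == "bursting"
        assert np.all(traj.Na_in > 0) and np.all(traj.K_out > 0)

    def test_frozen_sodium_recovers_base_model_burst(self, p_ref):
        # fixing [Na+]_in = 18.4 mM makes the extended pump an effective
        # base-model pump with I_max ~ 1 and E_Na ~ 55 mV
        na_fac = 1.0 / (1.0 + np.exp((25.0 - 18.4) / 3.0))
        q = pb.ModelParameters(I_app=0.5, I_max=10.0 * na_fac,
                               E_Na=pb.reversal_ENa(18.4, p_ref))
        _, _, summ = pb.run_and_summarize(q)
        assert summ.regime == "bursting"
        assert summ.modal_spikes_per_burst == 11


class TestSpikeCountTransition:
    def test_synthetic_switch_point_recovered(self, p_ref):
        x_true = 0.73519
        count = lambda q: 11 if q.I_max > x_true else 12
        got = pb.locate_spike_count_transition(
            p_ref, "I_max", (0.6, 0.9), (12, 11), tol=1e-6, count_fn=count)
        assert got == pytest.approx(x_true, abs=1e-5)

    def test_identical_counts_raise(self, p_ref):
        count = lambda q: 11
        with pytest.raises(pb.BracketError):
            pb.locate_spike_count_transition(p_ref, "I_max", (0.9, 1.1),
                                             (11, 12), count_fn=count)
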