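"""Fast-subsystem bifurcation machinery against independent oracles."""
import numpy as np
import pytest

import pumpburst as pb
from pumpburst.bifurcation import SECTION_V, _pad_state
from pumpburst import _kernels


class TestEquilibria:
    def test_bistable_strip_has_three_equilibria(self, p_ref):
        eqs = pb.find_equilibria(10.5, 0.5, p_ref)
        assert [e.stability for e in eqs] == ["stable node", "saddle",
                                              "unstable"]

    def test_node_and_saddle_absent_below_fold(self, p_ref):
        below = pb.find_equilibria(10.3, 0.5, p_ref)
        assert all(e.stability == "unstable" for e in below)
        above = pb.find_equilibria(10.6, 0.5, p_ref)
        assert {"stable node", "saddle"} <= {e.stability for e in above}

    def test_residuals_below_newton_tolerance(self, p_ref):
        q = p_ref.replace(I_app=0.5)
        for e in pb.find_equilibria(11.0, 0.5, p_ref):
            assert np.linalg.norm(pb.fast_rhs(e.state(), 11.0, q)) < 1e-10

    def test_fold_has_zero_eigenvalue(self, p_ref):
        sn = pb.locate_fold(0.5, p_ref)
        assert abs(sn.diagnostics["zero_eigenvalue"]) < 1e-6

    def test_fold_matches_brute_force_grid_oracle(self, p_ref):
        sn = pb.locate_fold(0.5, p_ref)
        # oracle: bracket the change in equilibrium count on a dense grid
        Ks = np.arange(10.2, 10.7, 1e-3)
        counts = np.array([len(pb.find_equilibria(K, 0.5, p_ref,
                                                  grid=221)) for K in Ks])
        i = int(np.nonzero(np.diff(counts))[0][0])
        assert abs(sn.K_out - 0.5 * (Ks[i] + Ks[i + 1])) < 1e-3

    def test_branch_contains_one_fold_and_one_hopf(self, p_ref):
        br = pb.continue_equilibria(0.5, (9.0, 16.0), p_ref, dK=0.1)
        assert len(br.sn_points) == 1 and len(br.hopf_points) == 1
        assert br.sn_points[0].K_out < br.hopf_points[0].K_out


class TestLimitCycle:
    def test_shooting_period_matches_direct_simulation(self, p_ref, cycle_ref):
        pt = p_ref.replace(I_app=0.5).kernel_tuple()
        y = _pad_state(cycle_ref.states[0], 9.0)
        cross, _, _ = _kernels.fast_section_crossings(
            y, 9.0, pt, 2000.0, 0.002, SECTION_V, 30)
        sim_period = np.mean(np.diff(cross)[-10:])
        assert abs(cycle_ref.period - sim_period) / sim_period < 1e-3

    def test_trivial_floquet_multiplier_is_one(self, cycle_ref):
        trivial = cycle_ref.floquet[np.argmin(np.abs(cycle_ref.floquet - 1))]
        assert abs(trivial - 1.0) < 1e-4

    def test_stable_cycle_multipliers_inside_unit_circle(self, cycle_ref):
        assert np.all(np.abs(cycle_ref.nontrivial_multipliers) < 1.0)

    def test_closure_residual(self, cycle_ref):
        assert cycle_ref.residual < 1e-6

    def test_cycle_samples_bracket_spike(self, cycle_ref):
        assert cycle_ref.V_max > 0 > cycle_ref.V_min
        assert len(cycle_ref.times) >= 2000


class TestCycleDeath:
    def test_homoclinic_at_reference_drive(self, hysteresis_ref):
        death = hysteresis_ref.marker("HOM")
        sn = hysteresis_ref.marker("SN")
        assert death is not None and sn is not None
        assert death.K_out > sn.K_out  # bistable window open

    def test_period_divergence_toward_homoclinic(self, p_ref, hysteresis_ref):
        """Approaching the HOM the period grows by the logarithmic law
        tau ~ a - b ln(K_hom - K), diverging past 10x the branch minimum
        within the resolution at which the boundary is known."""
        K_star, seed = pb.locate_cycle_boundary(0.5, p_ref, (9.0, 11.0),
                                                tol=1e-6)
        deltas = np.array([1e-3, 3e-4, 1e-4, 5e-5, 2e-5])
        taus = []
        guess = seed[:3]
        for d in deltas:
            cyc = pb.find_limit_cycle(K_star - d, 0.5, p_ref, guess=guess,
                                      settle=5000.0, polish=False,
                                      compute_floquet=False)
            guess = cyc.states[0]
            taus.append(cyc.period)
        taus = np.array(taus)
        assert np.all(np.diff(taus) > 0)  # grows as the boundary nears
        slope, intercept = np.polyfit(np.log(deltas), taus, 1)
        assert slope < 0  # tau increases as delta shrinks
        fit = intercept + slope * np.log(deltas)
        r2 = 1.0 - np.sum((taus - fit) ** 2) / np.sum((taus - taus.mean()) ** 2)
        assert r2 > 0.99
        # the divergence is unbounded only in the log-law limit; measured
        # growth over the resolvable range is already several-fold above
        # the branch minimum (an FLC, by contrast, keeps a finite period)
        spk = hysteresis_ref.branch("spiking")
        tau_min = np.nanmin(spk.period)
        assert taus[-1] > 5.0 * tau_min

    def test_fold_of_limit_cycles_beyond_turning_point(self, p_ref):
        death = pb.classify_cycle_death(0.9, p_ref, K_window=(8.0, 20.0),
                                        tol=1e-4)
        assert death.type == "FLC"

    def test_snic_below_saddle_node_loop(self, p_ref):
        death = pb.classify_cycle_death(0.25, p_ref, K_window=(6.0, 14.0),
                                        tol=1e-4)
        assert death.type == "SNIC"
        assert abs(death.K_out - death.diagnostics["K_sn"]) < 2e-3


class TestTwoParameterStructure:
    def test_electroneutral_fast_subsystem_is_imax_invariant(self, p_ref):
        # without the pump in the voltage equation the fast subsystem does
        # not see I_max at all: identical vector fields, identical folds
        pn1 = p_ref.replace(electrogenic=False, I_max=1.0)
        pn2 = p_ref.replace(electrogenic=False, I_max=2.0)
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = np.array([rng.uniform(-80, 20), rng.uniform(0, 1),
                          rng.uniform(0, 1)])
            K = rng.uniform(3, 15)
            np.testing.assert_array_equal(pb.fast_rhs(y, K, pn1),
                                          pb.fast_rhs(y, K, pn2))
        sn1 = pb.locate_fold(0.15, pn1)
        sn2 = pb.locate_fold(0.15, pn2)
        assert sn1.K_out == pytest.approx(sn2.K_out, abs=1e-9)

    def test_electrogenic_fold_shears_with_pump_density(self, p_ref):
        # a stronger pump hyperpolarizes more, so the fold (spike onset on
        # the way down in K) is met at lower [K+]_out: monotone shear
        folds = [pb.locate_fold(0.5, p_ref.replace(I_max=imax)).K_out
                 for imax in (0.5, 1.0, 2.0)]
        assert folds[0] > folds[1] > folds[2]

    def test_traced_curves_order(self, p_ref):
        curves = pb.trace_two_parameter_curves([0.4, 0.5, 0.6], p_ref,
                                               K_window=(6.0, 16.0), tol=1e-3)
        sn = next(c for c in curves if c.kind == "SN")
        hom = next(c for c in curves if c.kind == "HOM")
        for K_sn, I in zip(sn.K_out, sn.I_app):
            j = np.argmin(np.abs(hom.I_app - I))
            assert hom.K_out[j] >= K_sn - 1e-6


class TestOrganizingCenters:
    def test_snl_and_hom_inflection_bracket_reference_drive(self, p_ref):
        snl = pb.locate_SNL(p_ref, I_app_bracket=(0.25, 0.6),
                            K_window=(4.0, 16.0), tol_I=0.02)
        inf = pb.locate_HOM_inflection(p_ref, I_app_bracket=(0.5, 0.9),
                                       K_window=(4.0, 20.0), tol_I=0.02)
        # bursting at I_app = 0.5 requires SNL < 0.5 < HOM turning point;
        # the tonic case sits below the SNL and the block case beyond the
        # turning point (the locators themselves verify the classification
        # flip across each bracket)
        assert 0.25 < snl.I_app < 0.5 < inf.I_app < 0.9
        lo, hi = snl.diagnostics["bracket"]
        assert hi - lo <= 0.021
        lo2, hi2 = inf.diagnostics["bracket"]
        assert hi2 - lo2 <= 0.021

    def test_curve_based_inflection_refinement(self):
        # quadratic fit around the discrete maximum of a synthetic curve
        K = np.array([9.0, 10.0, 11.0, 12.0, 13.0])
        I = 0.8 - 0.01 * (K - 11.3) ** 2
        curve = pb.TwoParameterCurve("HOM", K, I)
        pt = pb.locate_HOM_inflection(curve=curve)
        assert pt.K_out == pytest.approx(11.3, abs=1e-6)
        assert pt.I_app == pytest.approx(0.8, abs=1e-6)


class TestRegionClassificationOracle:
    """Continuation-based region labels vs long direct simulation."""

    @pytest.mark.parametrize("K,I_app", [(9.5, 0.5), (10.6, 0.5), (11.5, 0.5),
                                         (8.0, 0.25), (9.5, 0.25)])
    def test_fast_subsystem_region(self, p_ref, K, I_app):
        eqs = pb.find_equilibria(K, I_app, p_ref)
        has_rest = any(e.stability == "stable node" and e.V < -45
                       for e in eqs)
        try:
            pb.find_limit_cycle(K, I_app, p_ref, polish=False,
                                compute_floquet=False)
            has_cycle = True
        except pb.CycleNotFound:
            has_cycle = False
        by_continuation = ("bistable" if has_rest and has_cycle else
                           "tonic" if has_cycle else "quiescent")
        # oracle: direct simulation from near-rest and mid-spike states
        q = p_ref.replace(I_app=I_app)
        outcomes = set()
        for init in ([-65.0, pb.h_inf(-65.0), pb.n_inf(-65.0), K],
                     [-20.0, 0.2, 0.6, K]):
            traj = pb.integrate(q, initial=np.array(init), t_end=4000.0,
                                transient_discard=2000.0,
                                system="fast", K_out=K)
            outcomes.add("spiking" if len(pb.detect_spikes(traj)) > 2
                         else "quiet")
        by_simulation = ("bistable" if outcomes == {"spiking", "quiet"} else
                         "tonic" if outcomes == {"spiking"} else "quiescent")
        assert by_continuation == by_simulation
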