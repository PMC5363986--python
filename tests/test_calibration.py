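import numpy as np
import pytest

import notchwnt as nw
from notchwnt.calibration import WNT_PARAMETERS
from notchwnt.errors import FittingError, InputError, ParameterError

P = nw.default_params()


class TestSensitivityIndex:
    def test_constant_output_has_zero_sensitivity(self):
        s, ns = nw.sensitivity_index(lambda p: 7.0, P, "alpha4")
        assert s == 0.0 and ns == 0.0

    def test_linear_output_has_unit_normalised_index(self):
        s, ns = nw.sensitivity_index(lambda p: p.alpha4, P, "alpha4",
                                     delta_frac=1e-6)
        assert ns == pytest.approx(1.0, rel=1e-6)

    def test_normalised_index_is_scale_invariant(self):
        """Rescaling the parameter's units leaves NS unchanged."""
        def out(p):
            return nw.bstar_decoupled(p, 1.0)

        _, ns = nw.sensitivity_index(out, P, "alpha4")
        scaled = P.replace(alpha4=P.alpha4 * 1000.0)

        def out_scaled(p):
            return nw.bstar_decoupled(p.replace(alpha4=p.alpha4 / 1000.0), 1.0)

        _, ns_scaled = nw.sensitivity_index(out_scaled, scaled, "alpha4")
        assert ns_scaled == pytest.approx(ns, rel=1e-4)

    def test_zero_parameter_rejected(self):
        p = P.replace(alpha3=0.0)
        with pytest.raises(ParameterError):
            nw.sensitivity_index(lambda q: 1.0, p, "alpha3")

    def test_zero_output_flags_nan_index(self):
        s, ns = nw.sensitivity_index(lambda p: p.alpha4 - P.alpha4, P, "alpha4",
                                     delta_frac=1e-6)
        assert np.isnan(ns) and s == pytest.approx(1.0, rel=1e-6)


class TestMse:
    def test_identical_series_score_zero(self):
        assert nw.mse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset_squares(self):
        a = np.arange(6, dtype=float)
        assert nw.mse(a + 0.5, a) == pytest.approx(0.25)

    def test_hand_arithmetic(self):
        assert nw.mse([1.0, 2.0, 3.0], [1.0, 1.0, 5.0]) == pytest.approx(5.0 / 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            nw.mse([1.0, 2.0], [1.0])


class TestSequentialFit:
    def test_quadratic_minimum_found_to_grid_resolution(self):
        target = 0.9
        params0 = P.replace(alpha4=2.0)

        def objective(p):
            return (p.alpha4 - target) ** 2

        res = nw.sequential_fit(objective, params0, ["alpha4"], grid_points=201,
                                target_tol=0.0, max_loops=1)
        spacing = 2 * 2.0 / 200
        assert abs(res.params.alpha4 - target) <= spacing / 2 + 1e-12

    def test_trace_is_non_increasing(self):
        params0 = P.replace(alpha4=2.0, alpha3=1.0)

        def objective(p):
            return (p.alpha4 - 0.7) ** 2 + (p.alpha3 - 0.4) ** 2

        res = nw.sequential_fit(objective, params0, ["alpha4", "alpha3"],
                                grid_points=101, target_tol=0.0, max_loops=2)
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))
        assert res.objective < 1e-3

    def test_ties_break_toward_smallest_change(self):
        params0 = P.replace(alpha4=1.0)
        res = nw.sequential_fit(lambda p: 1.0, params0, ["alpha4"],
                                grid_points=11, target_tol=-1.0, max_loops=1)
        assert res.params.alpha4 == pytest.approx(1.0)

    def test_all_infinite_grid_raises_naming_parameter(self):
        def objective(p):
            raise FittingError("always broken")

        with pytest.raises(FittingError) as err:
            nw.sequential_fit(objective, P, ["alpha4"], grid_points=5,
                              max_loops=1)
        assert err.value.parameter == "alpha4"

    def test_tolerance_termination(self):
        res = nw.sequential_fit(lambda p: 1e-6, P, ["alpha4"], grid_points=5,
                                target_tol=0.01, max_loops=3)
        assert res.termination == "tolerance"


class TestSyntheticTarget:
    def test_noise_free_samples_match_trajectory(self):
        scen = nw.build_scenario("healthy_pair", params=P, horizon_h=4.0)
        tab = nw.generate_synthetic_target(P, scen, species="B",
                                           sample_times_h=[0.5, 1, 2, 3],
                                           noise_sd=0.0, seed=0)
        traj = nw.run_deterministic(scen, P)
        ref = np.interp(np.array([0.5, 1, 2, 3]) * 60.0, traj.t_min,
                        traj.series("cell1", "B"))
        assert np.allclose(tab["value"].to_numpy(), ref)

    def test_same_seed_reproduces_noise(self):
        scen = nw.build_scenario("healthy_pair", params=P, horizon_h=4.0)
        a = nw.generate_synthetic_target(P, scen, noise_sd=0.3, seed=5)
        b = nw.generate_synthetic_target(P, scen, noise_sd=0.3, seed=5)
        assert np.array_equal(a["value"], b["value"])

    def test_noise_variance_calibrates(self):
        scen = nw.build_scenario("healthy_pair", params=P, horizon_h=1.2)
        times = [0.1, 0.3, 0.5, 0.7, 0.9, 1.1]
        clean = nw.generate_synthetic_target(P, scen, sample_times_h=times,
                                             noise_sd=0.0, seed=0)
        draws = np.concatenate([
            nw.generate_synthetic_target(P, scen, sample_times_h=times,
                                         noise_sd=0.5, seed=s)["value"]
            - clean["value"]
            for s in range(80)
        ])
        assert np.std(draws) == pytest.approx(0.5, rel=0.1)

    def test_sample_times_outside_horizon_rejected(self):
        scen = nw.build_scenario("healthy_pair", params=P, horizon_h=2.0)
        with pytest.raises(InputError):
            nw.generate_synthetic_target(P, scen, sample_times_h=[0.5, 3.0])


class TestTwoPointPrefit:
    def test_recovers_production_coefficients_exactly(self):
        b1 = nw.bstar_decoupled(P, 1.0)
        b2 = nw.bstar_decoupled(P, 2.0)
        a3, a4 = nw.fit_bstar_two_point(P.replace(alpha3=1.0, alpha4=1.0),
                                        [(1.0, b1), (2.0, b2)])
        assert a3 == pytest.approx(P.alpha3, rel=1e-8)
        assert a4 == pytest.approx(P.alpha4, rel=1e-8)

    def test_identical_stimuli_rejected(self):
        with pytest.raises(InputError):
            nw.fit_bstar_two_point(P, [(1.0, 10.0), (1.0, 20.0)])


class TestParameterRecovery:
    """Noise-free synthetic-target recovery: the headline check that the
    sequential 1D fit inverts the model it simulates."""

    def test_wnt_parameter_recovered_within_one_grid_step(self):
        truth = P
        perturbed = P.replace(alpha4=1.5 * P.alpha4)
        scen = nw.build_scenario("healthy_pair", params=truth, horizon_h=3.5)
        # six observations over three hours, mirroring the timecourse design
        times = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        target = nw.generate_synthetic_target(truth, scen, species="B",
                                              sample_times_h=times, noise_sd=0.0)

        def objective(p):
            sim = nw.generate_synthetic_target(p, scen, species="B",
                                               sample_times_h=times, noise_sd=0.0)
            return nw.mse(sim["value"].to_numpy(), target["value"].to_numpy())

        grid_points = 61
        res = nw.sequential_fit(objective, perturbed, ["alpha4"],
                                grid_points=grid_points, target_tol=1e-8,
                                max_loops=1)
        spacing = 2 * 1.5 * P.alpha4 / (grid_points - 1)
        assert abs(res.params.alpha4 - P.alpha4) <= spacing + 1e-9


def test_sensitivity_rankings_on_shipped_defaults():
    """On the shipped set, the Wnt-coupled production rate dominates the
    beta-catenin steady state and the Wnt-route promoter constant dominates
    the oscillation period."""
    bstar_rank = nw.sensitivity_report(nw.bstar_output(1.0), P).ranking
    assert bstar_rank[0] == "alpha4"
    period_rank = nw.sensitivity_report(nw.period_output(1.0), P).ranking
    assert period_rank[0] == "kappa7"


def test_wnt_parameter_set_is_well_defined():
    assert "kappa7" in WNT_PARAMETERS
    assert "kappa_psi" not in WNT_PARAMETERS
    assert all(hasattr(P, k) for k in WNT_PARAMETERS)
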