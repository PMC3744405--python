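"""Wald functional response and Rosenzweig-MacArthur analysis."""

import numpy as np
import pytest

from sensearch.popdyn import (
    FunctionalResponse,
    PopulationModel,
    coexistence_fixed_point,
    critical_carrying_capacity,
    integrate,
    linearized_below,
    monte_carlo_functional_response,
    power_law_rate,
    rm_derivatives,
    steady_state_sweep,
    table_rate,
)
from sensearch.scaling import RateTable


@pytest.fixture
def linear_response():
    # f(N) = N, M = 10 hunts, T = 1 day
    return FunctionalResponse(power_law_rate(1.0, 1.0), hunts_per_day=10, mean_hunt_duration=1.0)


@pytest.fixture
def textbook_model(linear_response):
    return PopulationModel(
        linear_response,
        growth_rate=1.0,
        carrying_capacity=1.0,
        conversion_efficiency=0.5,
        mortality=1.0,
    )


class TestFunctionalResponse:
    def test_limits_and_midpoint(self, linear_response):
        g = linear_response
        assert g(0.0) == 0.0
        assert g(1.0) == pytest.approx(10.0 / 2.0)  # f T = 1 -> g = M/2
        assert g(1e9) == pytest.approx(10.0, rel=1e-6)  # satiation at M per day

    def test_increasing_and_concave(self, linear_response):
        N = np.linspace(0.0, 20.0, 200)
        g = linear_response(N)
        assert np.all(np.diff(g) > 0)
        assert np.all(np.diff(g, 2) < 1e-12)
        assert np.all(g / linear_response.hunts_per_day < 1.0)

    @pytest.mark.parametrize("N", [0.05, 0.5, 3.0])
    def test_matches_monte_carlo_hunt_process(self, N, linear_response, rng):
        mc, se = monte_carlo_functional_response(linear_response, N, 60_000, rng)
        assert abs(mc - linear_response(N)) < 3 * se

    def test_table_rate_interpolates_and_extrapolates(self):
        t = RateTable.from_arrays([1.0, 10.0, 100.0], [2.0, 20.0, 200.0])
        f = table_rate(t)
        assert f(10.0) == pytest.approx(20.0, rel=1e-9)
        assert f(3.0) == pytest.approx(6.0, rel=1e-9)
        assert f(1000.0) == pytest.approx(2000.0, rel=1e-6)  # edge-slope power law
        assert f(0.1) == pytest.approx(0.2, rel=1e-6)

    def test_linearized_below_matches_above_and_linear_below(self):
        f = power_law_rate(1.0, 0.5)
        g = linearized_below(f, 20.0)
        assert g(25.0) == pytest.approx(f(25.0))
        assert g(10.0) == pytest.approx(f(20.0) / 2.0)
        # linearization can only lower the rate below the splice (gamma < 1)
        assert g(10.0) < f(10.0)


class TestFixedPoint:
    def test_hand_derived_equilibrium(self, textbook_model):
        # c g(N*) = m with g = 10 N/(1+N), c = 0.5, m = 1  =>  N* = 0.25
        fp = coexistence_fixed_point(textbook_model)
        assert fp.exists
        assert fp.N_star == pytest.approx(0.25, abs=1e-8)
        assert fp.P_star == pytest.approx(0.09375, abs=1e-8)
        dN, dP = rm_derivatives(fp.N_star, fp.P_star, textbook_model)
        assert abs(dN) < 1e-8 and abs(dP) < 1e-8

    def test_transcritical_boundary(self, linear_response):
        # as m -> c g(K), N* -> K and P* -> 0
        gK = linear_response(1.0)
        m = 0.5 * gK * (1.0 - 1e-6)
        model = PopulationModel(linear_response, 1.0, 1.0, 0.5, m)
        fp = coexistence_fixed_point(model)
        assert fp.N_star == pytest.approx(1.0, rel=1e-4)
        assert fp.P_star == pytest.approx(0.0, abs=1e-4)

    def test_no_coexistence_reported_not_raised(self, linear_response):
        model = PopulationModel(linear_response, 1.0, 1.0, 0.5, mortality=100.0)
        fp = coexistence_fixed_point(model)
        assert not fp.exists

    def test_trivial_derivative_cases(self, textbook_model):
        assert rm_derivatives(0.0, 3.0, textbook_model) == (0.0, -3.0)
        assert rm_derivatives(1.0, 0.0, textbook_model) == (0.0, 0.0)


class TestStability:
    def test_small_K_is_stable_large_K_cycles(self, linear_response):
        kc = critical_carrying_capacity(
            PopulationModel(linear_response, 1.0, 1.0, 0.5, 1.0)
        )
        assert kc == pytest.approx(1.5, abs=1e-6)  # hand algebra: trace = 0.2 - 0.3/K
        below = coexistence_fixed_point(
            PopulationModel(linear_response, 1.0, kc * 0.9, 0.5, 1.0)
        )
        above = coexistence_fixed_point(
            PopulationModel(linear_response, 1.0, kc * 1.3, 0.5, 1.0)
        )
        assert below.stable and not above.stable
        # above K_crit the orbit is a bounded cycle around the fixed point
        traj = integrate(
            PopulationModel(linear_response, 1.0, kc * 1.3, 0.5, 1.0),
            above.N_star * 1.01,
            above.P_star,
            (0.0, 3000.0),
        )
        assert not traj.converged_to_point
        cyc = traj.cycle_stats
        assert cyc["N_min"] < above.N_star < cyc["N_max"]

    def test_bisection_matches_trace_sign_grid(self, linear_response):
        model = PopulationModel(linear_response, 1.0, 1.0, 0.5, 1.0)
        kc = critical_carrying_capacity(model)
        Ks = np.linspace(0.5, 4.0, 141)
        stable_flags = []
        for K in Ks:
            fp = coexistence_fixed_point(PopulationModel(linear_response, 1.0, K, 0.5, 1.0))
            stable_flags.append(fp.stable if fp.exists else None)
        flips = [
            0.5 * (Ks[i] + Ks[i + 1])
            for i in range(len(Ks) - 1)
            if stable_flags[i] is True and stable_flags[i + 1] is False
        ]
        assert len(flips) == 1
        assert abs(flips[0] - kc) <= (Ks[1] - Ks[0])

    def test_eigen_classification_agrees_with_integration(self):
        # random parameter draws: linear stability must predict whether the
        # orbit settles onto the fixed point
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 20:
            a = rng.uniform(0.5, 3.0)
            M = rng.integers(2, 12)
            T = rng.uniform(0.2, 2.0)
            c = rng.uniform(0.2, 0.9)
            m = rng.uniform(0.3, 2.0)
            K = rng.uniform(0.5, 5.0)
            r = rng.uniform(0.5, 2.0)
            fr = FunctionalResponse(power_law_rate(a, 1.0), int(M), T)
            model = PopulationModel(fr, r, K, c, m)
            fp = coexistence_fixed_point(model)
            if not fp.exists or abs(fp.jacobian[0, 0]) < 5e-3:
                continue  # skip near-marginal cases where horizons explode
            traj = integrate(model, fp.N_star * 1.05, fp.P_star * 1.05, (0.0, 4000.0))
            tail = slice(int(0.8 * len(traj.t)), None)
            drift = np.hypot(traj.N[tail] - fp.N_star, traj.P[tail] - fp.P_star)
            if fp.stable:
                assert drift.max() < 0.05 * max(fp.N_star, fp.P_star)
            else:
                assert drift.max() > 1e-4
            checked += 1


class TestSweep:
    def test_sublinear_forager_depresses_prey_further(self):
        # calibrate both encounter models to agree at N = 20
        f_lin = power_law_rate(1.0, 1.0)
        f_sub = power_law_rate(20.0 / 20.0**0.5, 0.5)
        fr = {
            "linear": FunctionalResponse(f_lin, 5, 0.2),
            "sublinear": FunctionalResponse(f_sub, 5, 0.2),
        }
        df = steady_state_sweep(fr, cm_ratio_grid=np.linspace(1.5, 6.0, 6))
        piv = df.pivot(index="cm_ratio", columns="strategy", values="N_star")
        assert (piv["sublinear"] < piv["linear"]).all()

    def test_persistence_threshold_lower_for_sublinear(self):
        f_lin = power_law_rate(0.05, 1.0)
        f_sub = power_law_rate(0.05 * 20.0 / 20.0**0.5, 0.5)
        fr = {
            "linear": FunctionalResponse(f_lin, 5, 0.2),
            "sublinear": FunctionalResponse(f_sub, 5, 0.2),
        }
        df = steady_state_sweep(fr, K_grid=np.geomspace(0.05, 50.0, 40))
        first_K = df[df["persists"]].groupby("strategy")["K"].min()
        assert first_K["sublinear"] < first_K["linear"]

    def test_boundary_equilibrium_below_threshold(self):
        fr = FunctionalResponse(power_law_rate(0.05, 1.0), 5, 0.2)
        df = steady_state_sweep({"lin": fr}, K_grid=np.array([0.05]))
        row = df.iloc[0]
        assert not row["persists"]
        assert row["N_star"] == pytest.approx(0.05)
        assert row["P_star"] == 0.0
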