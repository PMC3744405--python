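"""Prey fields, torus geometry, and Poisson coverage identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sensearch.environment import (
    EmptyFieldError,
    PreyField,
    TorusEnvironment,
    covered_fraction,
    domain_for_density,
    nearest_prey,
    sample_clustered_prey,
    sample_poisson_prey,
    torus_distance,
)


class TestTorusGeometry:
    def test_identical_points_have_zero_distance(self):
        env = TorusEnvironment(10.0)
        assert torus_distance(np.array([3.0, 4.0]), np.array([3.0, 4.0]), env) == 0.0

    def test_wraparound_shortcut(self):
        env = TorusEnvironment(1.0, dimension=1)
        d = torus_distance(np.array([0.1]), np.array([0.9]), env)
        assert d == pytest.approx(0.2)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_minimum_image_never_exceeds_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        env = TorusEnvironment(7.0)
        a, b = rng.uniform(0, 7.0, size=(2, 2))
        d = torus_distance(a, b, env)
        assert d <= np.linalg.norm(a - b) + 1e-12
        assert d <= 7.0 * np.sqrt(2) / 2 + 1e-12
        # symmetry and a random triangle inequality
        assert d == pytest.approx(torus_distance(b, a, env))
        c = rng.uniform(0, 7.0, size=2)
        assert d <= torus_distance(a, c, env) + torus_distance(c, b, env) + 1e-12


class TestPoissonField:
    def test_domain_scaled_from_expected_count(self):
        env = domain_for_density(0.5e-4, 600.0)
        assert env.side_length == pytest.approx(np.sqrt(600.0 / 0.5e-4))

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_poisson_prey(0.0, 600, rng)
        with pytest.raises(ValueError):
            sample_poisson_prey(1.0, 0.0, rng)

    def test_expected_count_and_positions_in_domain(self, rng):
        fields = [sample_poisson_prey(1e-2, 100, rng) for _ in range(200)]
        counts = [len(f) for f in fields]
        # Poisson(100): mean within 4 standard errors over 200 draws
        assert abs(np.mean(counts) - 100) < 4 * 10 / np.sqrt(200)
        f = fields[0]
        assert np.all(f.positions >= 0) and np.all(f.positions < f.env.side_length)

    def test_nearest_neighbor_mean_matches_closed_form(self, rng):
        # E[D] = 1/(2 sqrt(rho)) for a 2-D Poisson process
        rho = 4e-2
        dists = []
        for _ in range(400):
            f = sample_poisson_prey(rho, 80, rng)
            p = rng.uniform(0, f.env.side_length, size=2)
            _, d, _ = nearest_prey(p, f)
            dists.append(d)
        expected = 1.0 / (2.0 * np.sqrt(rho))
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(np.mean(dists) - expected) < 3 * se

    def test_nearest_neighbor_distance_distribution(self, rng):
        # CDF 1 - exp(-rho pi r^2), Kolmogorov-Smirnov at alpha = 0.01
        rho = 1e-2
        dists = []
        for _ in range(1000):
            f = sample_poisson_prey(rho, 150, rng)
            p = rng.uniform(0, f.env.side_length, size=2)
            _, d, _ = nearest_prey(p, f)
            dists.append(d)
        cdf = lambda r: 1.0 - np.exp(-rho * np.pi * np.asarray(r) ** 2)
        assert stats.kstest(dists, cdf).pvalue > 0.01


class TestNearestPrey:
    def test_single_prey_returned_with_direction(self, layouts):
        f = layouts.single_prey
        i, d, theta = nearest_prey(np.array([50.0, 30.0]), f)
        assert i == 0
        assert d == pytest.approx(10.0)
        assert theta == pytest.approx(0.0)

    def test_ties_break_to_lowest_index(self):
        env = TorusEnvironment(10.0)
        f = PreyField(np.array([[2.0, 5.0], [8.0, 5.0]]), env)
        i, d, _ = nearest_prey(np.array([5.0, 5.0]), f)
        assert i == 0 and d == pytest.approx(3.0)

    def test_matches_bruteforce_scan(self, rng):
        env = TorusEnvironment(20.0)
        f = PreyField(rng.uniform(0, 20.0, size=(60, 2)), env)
        f.alive[rng.choice(60, size=10, replace=False)] = False
        for _ in range(25):
            p = rng.uniform(0, 20.0, size=2)
            i, d, _ = nearest_prey(p, f)
            brute = [
                (torus_distance(p, q, env), k)
                for k, q in enumerate(f.positions)
                if f.alive[k]
            ]
            bd, bi = min(brute)
            assert i == bi and d == pytest.approx(bd)

    def test_empty_field_raises(self):
        env = TorusEnvironment(10.0)
        f = PreyField(np.array([[1.0, 1.0]]), env)
        f.alive[0] = False
        with pytest.raises(EmptyFieldError):
            nearest_prey(np.array([5.0, 5.0]), f)


class TestCoveredFraction:
    @pytest.mark.parametrize(
        "rho,delta,expected",
        [
            (0.0, 1.0, 0.0),
            (np.log(2) / np.pi, 1.0, 0.5),
            (1.0, 1.0, 1.0 - np.exp(-np.pi)),
        ],
    )
    def test_closed_form_values(self, rho, delta, expected):
        assert covered_fraction(rho, delta) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_coverage_of_poisson_field(self, rng):
        rho, delta = 2e-2, 1.5
        f = sample_poisson_prey(rho, 200, rng)
        pts = rng.uniform(0, f.env.side_length, size=(10_000, 2))
        hits = sum(nearest_prey(p, f)[1] <= delta for p in pts)
        p_emp = hits / len(pts)
        p_th = covered_fraction(rho, delta)
        # binomial error plus realized-count fluctuation of one field
        assert abs(p_emp - p_th) < 0.03


class TestClusteredField:
    def test_seed_fraction_one_is_pure_poisson_layout(self, rng):
        f = sample_clustered_prey(1e-2, 50, rng, seed_fraction=1.0)
        assert len(f) > 0
        assert np.all(f.positions < f.env.side_length)

    def test_local_density_below_global_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_clustered_prey(1e-2, 50, rng, local_density=1e-3)

    def test_total_count_distribution_matches_poisson_generator(self, rng):
        counts = [len(sample_clustered_prey(1e-3, 60, rng)) for _ in range(300)]
        assert abs(np.mean(counts) - 60) < 4 * np.sqrt(60 / 300)

    def test_clusters_share_local_density(self, rng):
        # daughters of each seed live in a disc sized to one shared density
        local = 0.5
        f = sample_clustered_prey(1e-3, 200, rng, seed_fraction=0.05, local_density=local)
        # with clusters this tight, most nearest-neighbour distances are set
        # by the local (not global) density scale
        d_local = 1.0 / (2.0 * np.sqrt(local))
        dists = []
        for k in range(len(f)):
            others = np.delete(np.arange(len(f)), k)
            disp = f.env.displacement(f.positions[k], f.positions[others])
            dists.append(np.min(np.linalg.norm(disp, axis=1)))
        assert np.median(dists) < 5 * d_local


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, layouts):
        f = layouts.two_clusters
        f.alive[3] = False
        path = tmp_path / "prey.csv"
        f.to_csv(path)
        g = PreyField.from_csv(path, f.env)
        np.testing.assert_allclose(g.positions, f.positions)
        np.testing.assert_array_equal(g.alive, f.alive)
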