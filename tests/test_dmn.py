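"""Dirichlet-multinomial likelihood, fitting, and structure-matched simulation."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from dmnull import (
    CommunityMatrix,
    dm_log_likelihood,
    fit_dmn,
    simulate_structure_matched,
    theta_standard_error,
)
from dmnull.dmn import _moment_init, _dm_loglik_gamma
from dmnull.synthetic import N2_PI, N2_SPECIES, N2_THETA

from conftest import make_matrix


def compositions(n, k):
    """All length-k nonnegative integer vectors summing to n (brute force)."""
    for cuts in itertools.combinations(range(n + k - 1), k - 1):
        prev, out = -1, []
        for c in cuts:
            out.append(c - prev - 1)
            prev = c
        out.append(n + k - 2 - prev)
        yield tuple(out)


def polya_pmf(x, pi, theta):
    """Independent Polya-urn oracle for the DMN pmf (closed form by hand)."""
    x = np.asarray(x, dtype=float)
    n = x.sum()
    gamma = np.asarray(pi) * (1 - theta) / theta
    g = gamma.sum()
    log_p = (
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(g)
        - gammaln(n + g)
        + (gammaln(x + gamma) - gammaln(gamma)).sum()
    )
    return np.exp(log_p)


class TestLogLikelihood:
    def test_single_host_matches_hand_value(self):
        m = make_matrix([[1, 1]])
        ll = dm_log_likelihood(m, [0.5, 0.5], 0.5)
        # theta=0.5 -> gamma=(0.5,0.5): P(1,1) = 2 * G(1)G(1.5)^2 / (G(2)G(0.5)^2) = 1/4
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_single_species_probability_one(self):
        m = make_matrix([[5], [17]], species=["only"])
        assert dm_log_likelihood(m, [1.0], 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_sums_over_hosts(self):
        m = make_matrix([[3, 1], [0, 2]])
        a = make_matrix([[3, 1]])
        b = make_matrix([[0, 2]])
        pi, th = [0.7, 0.3], 0.2
        assert dm_log_likelihood(m, pi, th) == pytest.approx(
            dm_log_likelihood(a, pi, th) + dm_log_likelihood(b, pi, th)
        )

    def test_small_theta_approaches_multinomial(self):
        counts = np.array([[4, 3, 1]])
        m = make_matrix(counts)
        pi = np.array([0.5, 0.3, 0.2])
        ll = dm_log_likelihood(m, pi, 1e-8)
        mult = (
            gammaln(9) - gammaln(counts + 1.0).sum() + (counts * np.log(pi)).sum()
        )
        assert ll == pytest.approx(mult, abs=1e-4)

    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("n_total", [2, 3, 4, 5, 6])
    def test_pmf_normalizes(self, k, n_total):
        pi = np.array([0.5, 0.3, 0.2][:k])
        pi = pi / pi.sum()
        theta = 0.25
        total = sum(
            polya_pmf(x, pi, theta) for x in compositions(n_total, k)
        )
        assert total == pytest.approx(1.0, abs=1e-10)
        # and dm_log_likelihood agrees with the oracle on each composition
        for x in compositions(n_total, k):
            m = make_matrix([list(x)])
            assert dm_log_likelihood(m, pi, theta) == pytest.approx(
                np.log(polya_pmf(x, pi, theta)), abs=1e-10
            )

    def test_matches_scipy_dirichlet_multinomial(self, rng):
        from scipy.stats import dirichlet_multinomial

        counts = rng.integers(0, 200, size=(6, 4))
        m = make_matrix(counts)
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        theta = 0.17
        gamma = pi * (1 - theta) / theta
        want = sum(
            dirichlet_multinomial.logpmf(row, gamma, row.sum())
            for row in counts
        )
        assert dm_log_likelihood(m, pi, theta) == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.1, 1.5])
    def test_theta_boundary_rejected(self, theta):
        m = make_matrix([[1, 1]])
        with pytest.raises(ValueError, match="theta"):
            dm_log_likelihood(m, [0.5, 0.5], theta)

    def test_pi_off_simplex_rejected(self):
        m = make_matrix([[1, 1]])
        with pytest.raises(ValueError, match="pi"):
            dm_log_likelihood(m, [0.5, 0.6], 0.2)


class TestFit:
    def test_recovers_known_parameters(self):
        from dmnull.synthetic import SyntheticSpec, TotalModel, generate_neutral

        spec = SyntheticSpec(
            n_hosts=1000,
            species_names=("a", "b", "c"),
            pi=np.array([0.6, 0.3, 0.1]),
            theta=0.2,
            total_model=TotalModel.fixed([5000] * 1000),
            seed=7,
        )
        m = generate_neutral(spec)
        fit = fit_dmn(m)
        assert fit.converged
        se = theta_standard_error(fit, m)
        assert abs(fit.theta - 0.2) < 3 * se
        assert np.allclose(fit.pi, [0.6, 0.3, 0.1], atol=0.05)

    def test_loglik_consistent_and_beats_moment_init(self):
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        m = generate_neutral(n2_neutral_spec(n_hosts=120, seed=5))
        fit = fit_dmn(m)
        assert fit.loglik == pytest.approx(
            dm_log_likelihood(
                m.select_hosts(m.totals > 0), fit.pi, fit.theta
            ),
            rel=1e-12,
        )
        counts = m.counts.astype(float)
        pbar, theta0 = _moment_init(counts, m.totals.astype(float))
        ll0 = dm_log_likelihood(m, pbar, theta0)
        assert fit.loglik >= ll0 - 1e-8

    def test_fit_invariants(self):
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        fit = fit_dmn(generate_neutral(n2_neutral_spec(n_hosts=80, seed=21)))
        assert fit.pi.min() >= 0
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0 < fit.theta < 1
        assert np.all(fit.gamma > 0)
        assert fit.gamma.sum() == pytest.approx(
            (1 - fit.theta) / fit.theta, rel=1e-10
        )

    def test_all_zero_species_dropped(self):
        m = make_matrix(
            [[10, 0, 5], [8, 0, 12], [20, 0, 3]], species=["a", "MYb181", "c"]
        )
        with pytest.warns(UserWarning, match="MYb181"):
            fit = fit_dmn(m)
        assert fit.dropped_species == ("MYb181",)
        assert fit.species_names == ("a", "c")

    def test_single_host_errors(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            fit_dmn(make_matrix([[3, 4]]))

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            fit_dmn(make_matrix([[0, 0], [0, 0]]))

    def test_column_order_invariance(self):
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        m = generate_neutral(n2_neutral_spec(n_hosts=60, seed=33))
        perm = [3, 0, 7, 1, 6, 2, 5, 4]
        mp = CommunityMatrix(
            m.host_ids,
            m.lineage,
            [m.species_names[j] for j in perm],
            m.counts[:, perm],
        )
        f1, f2 = fit_dmn(m), fit_dmn(mp)
        d1 = dict(zip(f1.species_names, f1.pi))
        d2 = dict(zip(f2.species_names, f2.pi))
        assert d1 == d2
        assert f1.theta == f2.theta

    def test_fit_beats_coarse_grid_search(self):
        """The MLE's log-likelihood dominates a coarse (pi, theta) grid."""
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        m = generate_neutral(n2_neutral_spec(n_hosts=60, seed=77))
        fit = fit_dmn(m)
        rng = np.random.default_rng(1)
        best_grid = -np.inf
        for theta in (0.05, 0.1, 0.17, 0.25, 0.4):
            for _ in range(40):
                pi = rng.dirichlet(np.ones(m.n_species))
                best_grid = max(best_grid, dm_log_likelihood(m, pi, theta))
        assert fit.loglik >= best_grid

    def test_bias_shrinks_with_sample_size(self):
        from dmnull.synthetic import SyntheticSpec, TotalModel, generate_neutral

        errs = {}
        for n in (200, 2000):
            reps = []
            for r in range(5):
                spec = SyntheticSpec(
                    n_hosts=n,
                    species_names=("a", "b", "c"),
                    pi=np.array([0.6, 0.3, 0.1]),
                    theta=0.2,
                    total_model=TotalModel.fixed([2000] * n),
                    seed=100 + r,
                )
                reps.append(fit_dmn(generate_neutral(spec)).theta - 0.2)
            errs[n] = np.abs(np.mean(reps))
        assert errs[2000] < errs[200] + 0.01  # bias shrinks (noise allowance)
        assert errs[2000] < 0.01


class TestSimulate:
    def test_row_sums_match_totals_exactly(self):
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        m = generate_neutral(n2_neutral_spec(n_hosts=40, seed=2))
        fit = fit_dmn(m)
        sim = simulate_structure_matched(fit, [100, 200, 0, 55555], seed=1)
        assert sim.totals.tolist() == [100, 200, 0, 55555]
        assert sim.species_names == fit.species_names

    def test_seed_determinism(self):
        from dmnull.synthetic import generate_neutral, n2_neutral_spec

        fit = fit_dmn(generate_neutral(n2_neutral_spec(n_hosts=40, seed=2)))
        a = simulate_structure_matched(fit, [500] * 10, seed=7)
        b = simulate_structure_matched(fit, [500] * 10, seed=7)
        c = simulate_structure_matched(fit, [500] * 10, seed=8)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_small_theta_means_match_pi(self):
        from dmnull.dmn import DMFit

        pi = np.array([0.5, 0.5])
        fit = DMFit(
            species_names=("a", "b"),
            pi=pi,
            theta=1e-4,
            loglik=0.0,
            n_hosts=0,
            converged=True,
            iterations=0,
        )
        sim = simulate_structure_matched(fit, [100] * 10_000, seed=3)
        means = sim.counts.mean(axis=0)
        assert np.allclose(means, 50, rtol=0.01)

    def test_composition_variance_matches_moment_formula(self):
        from dmnull.dmn import DMFit

        pi = np.array([0.3, 0.7])
        theta, N = 0.15, 400
        fit = DMFit(
            species_names=("a", "b"),
            pi=pi,
            theta=theta,
            loglik=0.0,
            n_hosts=0,
            converged=True,
            iterations=0,
        )
        sim = simulate_structure_matched(fit, [N] * 40_000, seed=4)
        props = sim.counts / N
        expected = pi * (1 - pi) * (theta + (1 - theta) / N)
        observed = props.var(axis=0, ddof=1)
        assert np.allclose(observed, expected, rtol=0.05)
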