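"""Degree tables, moment summaries and percolation transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromperc import degree_model as dm

from conftest import poisson_dist


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


class TestTabulate:
    def test_coupled_poisson_mass_and_support(self, coupled):
        assert coupled.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert not (coupled.counts == 0).all(axis=1).any()  # k = 0 excluded
        assert 1e3 < len(coupled.probs) < 1e5

    def test_coupled_poisson_moments_match_direct_summation(self, coupled_moments):
        """Brute-force summation over a generous box is the oracle."""
        w = np.array([3.0, 2.0, 4.0])
        k = np.stack(np.meshgrid(np.arange(30), np.arange(40), np.arange(22),
                                 indexing="ij")).reshape(3, -1).T
        pw = stats.poisson.pmf(k @ w, 3.0)
        pw[(k == 0).all(axis=1)] = 0.0
        pw /= pw.sum()
        mu0 = pw @ k
        e2 = (k * pw[:, None]).T @ k
        M = e2 / mu0[None, :] - np.eye(3)
        assert np.allclose(coupled_moments.mu0, mu0, atol=1e-8)
        assert np.allclose(coupled_moments.M, M, atol=1e-8)

    @pytest.mark.parametrize("tol", [1e-8, 1e-12])
    def test_modular_poisson_moments_vs_analytic(self, tol):
        """Table moments agree with direct analytic summation at two
        truncation levels."""
        alpha = 0.1
        d = dm.tabulate("modular_poisson", alpha=alpha, truncation_tol=tol)
        rates = np.array([1.5, 2.5, 5.0])
        norm = 3.0 + alpha
        # E[k_i] = (rate_i + alpha) / (3 + alpha) branch-wise
        mu0 = (rates + alpha) / norm
        e2_diag = (rates ** 2 + rates + alpha) / norm
        s = dm.moments(d)
        assert np.allclose(s.mu0, mu0, atol=1e-8)
        assert np.allclose(np.diag(s.M), e2_diag / mu0 - 1, atol=1e-8)
        # off-diagonal mixed moments come only from the bridging atom
        assert s.M[0, 1] == pytest.approx(alpha / (mu0[1] * norm), abs=1e-8)

    def test_degenerate_poisson_rate_zero(self):
        d = dm.tabulate("poisson", rates=[0.0])
        assert d.prob_of([0]) == pytest.approx(1.0)

    def test_unknown_generator_and_bad_tol(self):
        with pytest.raises(ValueError, match="unknown generator"):
            dm.tabulate("no_such_generator")
        with pytest.raises(ValueError, match="truncation_tol"):
            dm.tabulate("poisson", truncation_tol=0.0, rates=[1.0])

    def test_support_cap_unreachable(self):
        with pytest.raises(ValueError, match="support cap"):
            dm.tabulate("coupled_poisson", weights=(1e-3, 1e-3, 1e-3),
                        lam=3.0, support_cap=5)


# ---------------------------------------------------------------------------
# moments and excess
# ---------------------------------------------------------------------------


class TestMoments:
    def test_deterministic_degree(self):
        d = dm.DegreeDistribution(np.array([[3]]), np.array([1.0]))
        s = dm.moments(d)
        assert s.mu0[0] == 3.0
        assert s.M[0, 0] == pytest.approx(2.0)    # E[k^2]/E[k] - 1
        assert s.T[0, 0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.7])
    def test_poisson_excess_is_poisson(self, lam):
        """Excess of a Poisson stays Poisson: M = [[lam]], excess table
        equals the original."""
        d = poisson_dist(lam)
        s = dm.moments(d)
        assert s.M[0, 0] == pytest.approx(lam, abs=1e-9)
        exc = dm.excess(d, 0)
        common = min(len(d.probs), len(exc.probs))
        assert np.allclose(exc.to_dense()[:common], d.to_dense()[:common],
                           atol=1e-10)

    def test_zero_mean_colour_rejected_and_droppable(self):
        d = dm.DegreeDistribution(np.array([[1, 0], [2, 0]]),
                                  np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="colour 2"):
            dm.moments(d)
        with pytest.raises(ValueError, match="zero expected count"):
            dm.excess(d, 1)
        d1 = dm.drop_colour(d, 1)
        assert d1.n_colours == 1
        assert dm.moments(d1).mu0[0] == pytest.approx(1.5)

    def test_regular_excess_point_mass(self):
        d = dm.DegreeDistribution(np.array([[4]]), np.array([1.0]))
        exc = dm.excess(d, 0)
        assert exc.prob_of([3]) == pytest.approx(1.0)

    def test_excess_mean_is_column_of_M(self, coupled, coupled_moments):
        for i in range(3):
            exc = dm.excess(coupled, i)
            assert np.allclose(exc.mean(), coupled_moments.M[:, i], atol=1e-8)
            assert exc.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_T_symmetric_psd_and_M_nonnegative(self, coupled_moments,
                                               two_colour_mixture):
        for s in (coupled_moments, dm.moments(two_colour_mixture)):
            assert (s.M >= 0).all()
            for Ti in s.T:
                assert np.allclose(Ti, Ti.T, atol=1e-12)
                assert np.linalg.eigvalsh(Ti).min() >= -1e-10


# ---------------------------------------------------------------------------
# percolation transforms
# ---------------------------------------------------------------------------


class TestPercolation:
    def test_thinning_endpoints(self, two_colour_mixture):
        d = two_colour_mixture
        same = dm.percolate_distribution(d, 1.0)
        assert np.allclose(same.to_dense(), d.to_dense(), atol=1e-12)
        empty = dm.percolate_distribution(d, 0.0)
        assert empty.prob_of([0, 0]) == pytest.approx(1.0)

    def test_binomial_two_edges(self):
        d = dm.DegreeDistribution(np.array([[2]]), np.array([1.0]))
        thinned = dm.percolate_distribution(d, 0.5)
        assert thinned.prob_of([0]) == pytest.approx(0.25)
        assert thinned.prob_of([1]) == pytest.approx(0.5)
        assert thinned.prob_of([2]) == pytest.approx(0.25)

    def test_summary_endpoints(self, coupled_moments):
        s = coupled_moments
        ident = dm.percolate_summary(s, 1.0)
        assert np.allclose(ident.M, s.M) and np.allclose(ident.T, s.T)
        dead = dm.percolate_summary(s, 0.0)
        assert np.allclose(dead.mu0, 0) and np.allclose(dead.M, 0)

    def test_deterministic_degree_halved(self):
        d = dm.DegreeDistribution(np.array([[3]]), np.array([1.0]))
        s = dm.percolate_summary(dm.moments(d), 0.5)
        oracle = dm.moments(dm.percolate_distribution(d, 0.5))
        assert s.M[0, 0] == pytest.approx(1.0)
        assert np.allclose(s.M, oracle.M, atol=1e-10)
        assert np.allclose(s.T, oracle.T, atol=1e-10)

    @pytest.mark.parametrize("p", [0.25, 0.6, 0.9])
    def test_scalar_transform_equals_thinning(self, two_colour_mixture, p):
        """Commutation: moments(thin(d, p)) == transform(moments(d), p)."""
        d = two_colour_mixture
        direct = dm.moments(dm.percolate_distribution(d, p))
        trans = dm.percolate_summary(dm.moments(d), p)
        assert np.allclose(direct.mu0, trans.mu0, atol=1e-8)
        assert np.allclose(direct.M, trans.M, atol=1e-8)
        assert np.allclose(direct.T, trans.T, atol=1e-8)

    def test_coloured_transform_equals_thinning(self, coupled, coupled_moments):
        p = np.array([0.9, 0.5, 0.7])
        direct = dm.moments(dm.percolate_distribution(coupled, p))
        trans = dm.percolate_summary_coloured(coupled_moments, p)
        assert np.allclose(direct.mu0, trans.mu0, atol=1e-8)
        assert np.allclose(direct.M, trans.M, atol=1e-8)
        assert np.allclose(direct.T, trans.T, atol=1e-8)

    def test_uniform_vector_reduces_to_scalar(self, coupled_moments):
        a = dm.percolate_summary(coupled_moments, 0.37)
        b = dm.percolate_summary_coloured(coupled_moments,
                                          np.full(3, 0.37))
        assert np.allclose(a.M, b.M) and np.allclose(a.T, b.T)

    def test_p_out_of_range(self, coupled_moments):
        with pytest.raises(ValueError):
            dm.percolate_summary(coupled_moments, 1.2)
        with pytest.raises(ValueError):
            dm.percolate_summary_coloured(coupled_moments,
                                          np.array([0.5, -0.1, 0.5]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lam=st.floats(0.2, 3.0), p=st.floats(0.05, 1.0))
    def test_thinned_poisson_stays_poisson(self, lam, p):
        """Binomial thinning of Poisson(lam) is Poisson(p*lam) — the
        transform must reproduce M' = p M exactly."""
        d = poisson_dist(lam, tol=1e-12)
        s = dm.percolate_summary(dm.moments(d), p)
        assert s.M[0, 0] == pytest.approx(p * lam, abs=1e-7)
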