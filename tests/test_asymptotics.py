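"""Tail-asymptote coefficients and the colour-fraction law."""

import warnings

import numpy as np
import pytest

from chromperc import asymptotics as asy
from chromperc import criticality as cr
from chromperc import degree_model as dm

from conftest import poisson_dist, random_summary


def unicoloured_closed_forms(dist):
    """Printed single-colour closed forms from the raw moments."""
    k = dist.counts[:, 0].astype(float)
    e1, e2, e3 = (dist.probs @ k, dist.probs @ k**2, dist.probs @ k**3)
    denom = e1 * e3 - e2 ** 2
    return (e1 ** 2 / np.sqrt(2 * np.pi * denom),
            (e2 - 2 * e1) ** 2 / (2 * denom))


class TestObjective:
    def test_single_colour_closed_form(self):
        d = poisson_dist(0.8)
        s = dm.moments(d)
        _, c2 = unicoloured_closed_forms(d)
        assert asy.f_objective(np.empty(0), s.M, s.T) == pytest.approx(
            c2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_kernel_vector_zeroes_f(self, seed):
        """At criticality f vanishes exactly at the normalised kernel
        vector's tail."""
        rng = np.random.default_rng(seed)
        s = random_summary(rng, n=3, rho=1.0)
        v = cr.is_critical(s.M).certificate
        assert v is not None
        assert asy.f_objective(v[1:], s.M, s.T) == pytest.approx(0.0, abs=1e-12)

    def test_singular_sigma_raises(self):
        # sigma loses rank on a face AND the residual (M-I)v leaves its range
        M = np.array([[0.5, 0.3], [0.4, 0.5]])
        T = np.zeros((2, 2, 2))
        T[0] = np.diag([1.0, 0.0])
        T[1] = np.diag([1.0, 0.0])
        with pytest.raises(ValueError, match="singular"):
            asy.f_objective(np.array([0.5]), M, T)


class TestMinimiser:
    def test_single_colour_reduction(self):
        d = poisson_dist(0.8)
        z, fmin, H = asy.minimise_f(dm.moments(d))
        assert z.size == 0 and H.size == 0
        assert fmin == pytest.approx(unicoloured_closed_forms(d)[1], rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_critical_summary_minimum_is_kernel(self, seed):
        rng = np.random.default_rng(50 + seed)
        s = random_summary(rng, n=3, rho=1.0)
        v = cr.is_critical(s.M).certificate
        z, fmin, _ = asy.minimise_f(s)
        assert fmin == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(z, v[1:], atol=1e-4)

    def test_coupled_network_minimum(self, coupled_moments):
        """Converged interior minimum of the worked example; the exact
        exponential tail rate (fold point of the component
        generating-function system) independently confirms the scale."""
        z, fmin, H = asy.minimise_f(coupled_moments)
        assert fmin == pytest.approx(3.8657e-4, rel=1e-3)   # regression pin
        assert np.allclose(z, [0.73657, 0.07026], atol=1e-4)
        assert np.linalg.eigvalsh(H).min() > 0
        # gradient vanishes at an interior optimum
        _, g = asy._f_and_grad(z, coupled_moments.M - np.eye(3),
                               coupled_moments.T)
        assert np.abs(g).max() < 1e-6

    def test_boundary_minimiser_flagged(self, modular0):
        s = dm.moments(modular0)
        perc = dm.percolate_summary(s, 0.3)
        with pytest.warns(RuntimeWarning, match="boundary"):
            asy.minimise_f(perc)


class TestHessian:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(200 + seed)
        s = random_summary(rng, n=3, rho=0.8)
        z = np.array([0.3, 0.25])
        H = asy.hessian_f(z, s.M, s.T)
        h = 1e-4
        e = np.eye(2)
        Hfd = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                Hfd[i, j] = (
                    asy.f_objective(z + h * e[i] + h * e[j], s.M, s.T)
                    - asy.f_objective(z + h * e[i] - h * e[j], s.M, s.T)
                    - asy.f_objective(z - h * e[i] + h * e[j], s.M, s.T)
                    + asy.f_objective(z - h * e[i] - h * e[j], s.M, s.T)
                ) / (4 * h * h)
        assert np.allclose(H, Hfd, rtol=1e-4, atol=1e-6)


class TestAsymptote:
    @pytest.mark.parametrize("maker,param", [
        ("poisson", 0.5), ("poisson", 0.8), ("poisson", 0.95),
        ("geometric", 0.2), ("geometric", 0.3),
    ])
    def test_unicoloured_reduction_matches_closed_forms(self, maker, param):
        d = (poisson_dist(param) if maker == "poisson"
             else dm.tabulate("geometric", q=param, truncation_tol=1e-14))
        coef = asy.asymptote(dm.moments(d))
        c1, c2 = unicoloured_closed_forms(d)
        assert coef.C1 == pytest.approx(c1, rel=1e-6)
        assert coef.C2 == pytest.approx(c2, rel=1e-6)

    def test_coupled_network_coefficients(self, coupled_moments):
        coef = asy.asymptote(coupled_moments)
        assert coef.C2 == pytest.approx(3.8657e-4, rel=1e-3)
        assert coef.C1 == pytest.approx(0.8005, rel=1e-3)
        assert coef.C1 > 0
        w = coef.w_inf(np.array([10.0, 100.0]))
        assert np.allclose(w, coef.C1 * np.array([10.0, 100.0]) ** -1.5
                           * np.exp(-coef.C2 * np.array([10.0, 100.0])))

    @pytest.mark.parametrize("seed", range(3))
    def test_critical_input_scale_free(self, seed):
        rng = np.random.default_rng(300 + seed)
        s = random_summary(rng, n=3, rho=1.0)
        coef = asy.asymptote(s)
        assert coef.C2 == pytest.approx(0.0, abs=1e-10)
        assert coef.meta["critical"]


class TestColourFractionLaw:
    def test_coupled_network_mean_and_covariance(self, coupled_moments):
        law = asy.colour_fraction_law(coupled_moments)
        assert law.m.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(law.m, [0.193, 0.737, 0.070], atol=2e-3)
        assert np.allclose(law.Sigma_scale.sum(axis=1), 0.0, atol=1e-10)
        assert np.linalg.eigvalsh(law.Sigma_scale).min() >= -1e-10
        assert np.allclose(np.diag(law.Sigma_scale), [0.221, 0.245, 0.067],
                           atol=2e-3)
        assert law.Sigma_scale[0, 1] == pytest.approx(-0.20, abs=5e-3)

    def test_single_colour_trivial(self):
        law = asy.colour_fraction_law(dm.moments(poisson_dist(0.7)))
        assert law.m[0] == pytest.approx(1.0)
        assert law.Sigma_scale[0, 0] == 0.0

    def test_block_bordering_consistency(self, coupled_moments):
        law = asy.colour_fraction_law(coupled_moments)
        C = law.Sigma_scale[1:, 1:]
        assert law.block_a == pytest.approx(C.sum())
        assert np.allclose(law.block_b, -C.sum(axis=1))


class TestC2Profile:
    def test_disjoint_communities_zero_set(self, modular0):
        """C2(p) vanishes exactly at the three reciprocal eigenvalues."""
        s = dm.moments(modular0)
        targets = np.array([0.2, 0.4, 2 / 3])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            at_pc = asy.C2_profile(s, targets)
            off_pc = asy.C2_profile(s, targets + 0.05)
        assert np.abs(at_pc).max() < 1e-10
        assert (off_pc > 1e-5).all()

    def test_zero_set_matches_critical_probabilities(self, modular01):
        s = dm.moments(modular01)
        pcs = cr.critical_probabilities(s.M).probabilities
        pcs = pcs[pcs <= 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            at_pc = asy.C2_profile(s, pcs)
        assert np.abs(at_pc).max() < 1e-6

    def test_critical_network_at_p1(self):
        rng = np.random.default_rng(7)
        s = random_summary(rng, n=2, rho=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = asy.C2_profile(s, np.array([1.0]))
        assert prof[0] == pytest.approx(0.0, abs=1e-10)


class TestKernelEquivalence:
    @pytest.mark.parametrize("rho,critical", [(1.0, True), (0.82, False),
                                              (1.25, False)])
    def test_c2_zero_iff_kernel_criterion(self, rho, critical):
        """C2 = 0 exactly when M - I has a sign-consistent kernel vector
        (randomised check; the full 100-matrix sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(int(rho * 1000))
        for _ in range(8):
            s = random_summary(rng, n=3, rho=rho)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, fmin, _ = asy.minimise_f(s)
            assert (fmin < 1e-10) == critical
            assert cr.is_critical(s.M).is_critical == critical
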