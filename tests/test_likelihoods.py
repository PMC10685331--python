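"""Per-family log-likelihoods: closed forms, high-precision oracles and
normalization of every mass/density."""

import numpy as np
import pytest
from scipy import integrate

from jointomics import likelihoods as lk
from jointomics.data import ModalitySpec, ValidationError

LOG_2PI = np.log(2 * np.pi)


def spec(fam, dim=1, **kw):
    return ModalitySpec("m", dim, fam, **kw)


class TestGaussian:
    def test_at_mean_unit_sd(self):
        x = np.array([[0.3, -1.0]])
        p = lk.GaussianParams(mean=x.copy(), sd=1.0)
        out = lk.log_prob(x, p, spec("gaussian", 2))
        assert np.allclose(out, -0.5 * LOG_2PI)

    def test_eq_average_is_mean_of_per_feature_terms(self, rng):
        x = rng.normal(size=(4, 6))
        p = lk.GaussianParams(mean=rng.normal(size=(4, 6)), sd=rng.uniform(0.5, 2, 6))
        per = lk.log_prob(x, p, spec("gaussian", 6))
        # independent summation oracle
        oracle = np.array([sum(row) / 6 for row in per])
        assert np.allclose(lk.feature_mean_ll(x, p, spec("gaussian", 6)), oracle)


class TestCategorical:
    def test_one_hot_gives_zero(self):
        x = np.array([[2.0, 0.0]])
        probs = np.zeros((1, 2, 5))
        probs[0, 0, 2] = 1.0
        probs[0, 1, 0] = 1.0
        out = lk.log_prob(x, lk.CategoricalParams(probs=probs), spec("categorical", 2))
        assert np.allclose(out, 0.0)
        assert np.allclose(
            lk.feature_mean_ll(x, lk.CategoricalParams(probs=probs),
                               spec("categorical", 2)), 0.0)


class TestNegBin:
    def test_geometric_special_case(self):
        # mu = 1, phi = 1, x = 0  ->  P = 1/2
        p = lk.NegBinParams(mean=np.array([[1.0]]), dispersion=np.array([1.0]))
        out = lk.log_prob(np.array([[0.0]]), p, spec("negbin", 1))
        assert np.allclose(out, np.log(0.5))

    def test_matches_sympy_pmf_oracle(self):
        import sympy as sp

        rng = np.random.default_rng(8)
        s = spec("negbin", 1)
        for _ in range(12):
            mu = float(rng.uniform(0.2, 30))
            phi = float(rng.uniform(0.2, 8))
            k = int(rng.integers(0, 40))
            p = lk.NegBinParams(mean=np.array([[mu]]), dispersion=np.array([phi]))
            got = float(lk.log_prob(np.array([[float(k)]]), p, s)[0, 0])
            m, f = sp.Float(mu, 30), sp.Float(phi, 30)
            pmf = (sp.gamma(k + f) / (sp.gamma(f) * sp.factorial(k))
                   * (f / (f + m)) ** f * (m / (f + m)) ** k)
            expected = float(sp.log(pmf).evalf(30))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_mode_near_mean_for_large_phi(self):
        mu, phi = 20.0, 500.0
        ks = np.arange(0, 80, dtype=float).reshape(-1, 1)
        p = lk.NegBinParams(mean=np.full((80, 1), mu), dispersion=np.array([phi]))
        ll = lk.log_prob(ks, p, spec("negbin", 1)).ravel()
        assert abs(int(np.argmax(ll)) - mu) <= 1


class TestNegBinMixture:
    def _params(self, mu, alpha, phi, pi, n=1):
        return lk.NegBinMixtureParams(
            mean=np.full((n, 1), mu), fold_change=np.full((n, 1), alpha),
            dispersion=np.array([phi]), mixing=np.full((n, 1), pi))

    def test_vanishing_foreground_limit(self):
        x = np.array([[3.0]])
        s = spec("negbin_mixture", 1)
        got = lk.log_prob(x, self._params(2.0, 3.0, 1.5, 1e-14), s)
        nb = lk.log_prob(x, lk.NegBinParams(mean=np.array([[2.0]]),
                                            dispersion=np.array([1.5])),
                         spec("negbin", 1))
        assert np.allclose(got, nb, atol=1e-10)

    def test_identical_components_limit(self):
        x = np.array([[5.0]])
        s = spec("negbin_mixture", 1)
        got = lk.log_prob(x, self._params(4.0, 1.0 + 1e-12, 2.0, 0.37), s)
        nb = lk.log_prob(x, lk.NegBinParams(mean=np.array([[4.0]]),
                                            dispersion=np.array([2.0])),
                         spec("negbin", 1))
        assert np.allclose(got, nb, atol=1e-9)

    def test_matches_two_term_sum_oracle(self):
        import sympy as sp

        rng = np.random.default_rng(4)
        s = spec("negbin_mixture", 1)
        for _ in range(10):
            mu = float(rng.uniform(0.5, 20))
            alpha = float(rng.uniform(1.2, 8))
            phi = float(rng.uniform(0.3, 5))
            pi = float(rng.uniform(0.05, 0.95))
            k = int(rng.integers(0, 50))
            got = float(lk.log_prob(np.array([[float(k)]]),
                                    self._params(mu, alpha, phi, pi), s)[0, 0])

            def nb_pmf(m):
                m, f = sp.Float(m, 30), sp.Float(phi, 30)
                return (sp.gamma(k + f) / (sp.gamma(f) * sp.factorial(k))
                        * (f / (f + m)) ** f * (m / (f + m)) ** k)

            mix = (1 - sp.Float(pi, 30)) * nb_pmf(mu) + sp.Float(pi, 30) * nb_pmf(alpha * mu)
            expected = float(sp.log(mix).evalf(30))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_alpha_below_one_rejected(self):
        with pytest.raises(ValidationError):
            lk.log_prob(np.array([[1.0]]), self._params(2.0, 0.9, 1.0, 0.5),
                        spec("negbin_mixture", 1))


class TestBeta:
    def test_uniform_density_is_zero_loglik(self):
        x = np.array([[0.1, 0.9]])
        p = lk.BetaParams(mean=np.full((1, 2), 0.5), concentration=np.full((1, 2), 2.0))
        assert np.allclose(lk.log_prob(x, p, spec("beta", 2)), 0.0)

    def test_symmetry(self, rng):
        x = rng.uniform(0.05, 0.95, size=(3, 2))
        m = rng.uniform(0.2, 0.8, size=(3, 2))
        c = rng.uniform(1.0, 8.0, size=(3, 2))
        a = lk.log_prob(x, lk.BetaParams(mean=m, concentration=c), spec("beta", 2))
        b = lk.log_prob(1 - x, lk.BetaParams(mean=1 - m, concentration=c), spec("beta", 2))
        assert np.allclose(a, b)

    def test_boundary_rejected_with_hint(self):
        p = lk.BetaParams(mean=np.array([[0.5]]), concentration=np.array([[2.0]]))
        with pytest.raises(ValidationError, match="clip_beta_values"):
            lk.log_prob(np.array([[0.0]]), p, spec("beta", 1))

    def test_density_integrates_to_one(self, rng):
        for _ in range(5):
            m = float(rng.uniform(0.15, 0.85))
            c = float(rng.uniform(0.8, 10.0))
            p = lk.BetaParams(mean=np.array([[m]]), concentration=np.array([[c]]))

            def dens(x):
                return float(np.exp(lk.log_prob(np.array([[x]]), p, spec("beta", 1)))[0, 0])

            total, _ = integrate.quad(dens, 1e-9, 1 - 1e-9, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("fam", ["gaussian", "bernoulli", "categorical", "beta",
                                 "negbin", "negbin_mixture"])
def test_normalization_every_family(fam, rng):
    """Exponentiated masses sum (or densities integrate) to 1 +- 1e-6."""
    if fam == "gaussian":
        p = lk.GaussianParams(mean=np.array([[0.7]]), sd=np.array([1.3]))
        f = lambda x: float(np.exp(lk.log_prob(np.array([[x]]), p, spec(fam, 1)))[0, 0])
        total, _ = integrate.quad(f, -20, 20)
    elif fam == "beta":
        p = lk.BetaParams(mean=np.array([[0.3]]), concentration=np.array([[4.0]]))
        f = lambda x: float(np.exp(lk.log_prob(np.array([[x]]), p, spec(fam, 1)))[0, 0])
        total, _ = integrate.quad(f, 1e-9, 1 - 1e-9, limit=200)
    elif fam == "bernoulli":
        p = lk.BernoulliParams(prob=np.array([[0.42]]))
        total = sum(float(np.exp(lk.log_prob(np.array([[x]]), p, spec(fam, 1)))[0, 0])
                    for x in (0.0, 1.0))
    elif fam == "categorical":
        probs = rng.dirichlet(np.ones(5)).reshape(1, 1, 5)
        p = lk.CategoricalParams(probs=probs)
        total = sum(float(np.exp(lk.log_prob(np.array([[float(k)]]), p, spec(fam, 1)))[0, 0])
                    for k in range(5))
    elif fam == "negbin":
        p = lk.NegBinParams(mean=np.array([[6.0]]), dispersion=np.array([1.7]))
        ks = np.arange(0, 600, dtype=float).reshape(-1, 1)
        pp = lk.NegBinParams(mean=np.full((600, 1), 6.0), dispersion=np.array([1.7]))
        total = float(np.exp(lk.log_prob(ks, pp, spec(fam, 1))).sum())
    else:
        n = 800
        pp = lk.NegBinMixtureParams(mean=np.full((n, 1), 5.0),
                                    fold_change=np.full((n, 1), 4.0),
                                    dispersion=np.array([1.2]),
                                    mixing=np.full((n, 1), 0.35))
        ks = np.arange(0, n, dtype=float).reshape(-1, 1)
        total = float(np.exp(lk.log_prob(ks, pp, spec(fam, 1))).sum())
    assert total == pytest.approx(1.0, abs=1e-6)


def test_feature_mean_invariant_to_duplication(rng):
    x = rng.normal(size=(3, 4))
    p = lk.GaussianParams(mean=rng.normal(size=(3, 4)), sd=1.0)
    s4 = spec("gaussian", 4)
    base = lk.feature_mean_ll(x, p, s4)
    x2 = np.concatenate([x, x], axis=1)
    p2 = lk.GaussianParams(mean=np.concatenate([p.mean, p.mean], axis=1), sd=1.0)
    doubled = lk.feature_mean_ll(x2, p2, spec("gaussian", 8))
    assert np.allclose(base, doubled)


def test_log_prob_permutation_equivariance(rng):
    x = rng.normal(size=(2, 5))
    mean = rng.normal(size=(2, 5))
    perm = rng.permutation(5)
    s = spec("gaussian", 5)
    out = lk.log_prob(x, lk.GaussianParams(mean=mean, sd=1.0), s)
    out_p = lk.log_prob(x[:, perm], lk.GaussianParams(mean=mean[:, perm], sd=1.0), s)
    assert np.allclose(out[:, perm], out_p)


def test_single_feature_average_equals_value():
    x = np.array([[2.0]])
    p = lk.GaussianParams(mean=np.array([[1.0]]), sd=1.0)
    s = spec("gaussian", 1)
    assert np.allclose(lk.feature_mean_ll(x, p, s), lk.log_prob(x, p, s).ravel())
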