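import math

import numpy as np
import pytest
from scipy import stats

from ednadensity.errors import DataValidationError, EDNADensityError
from ednadensity.likelihoods import (
    ModelSpec,
    ParameterVector,
    mean_function,
    nb_success_prob,
    negbin_loglik,
    normal_loglik,
    poisson_loglik,
)

from conftest import make_dataset


def _one_obs(w, density, unit="copies_per_ml"):
    return make_dataset({"s": [w]}, densities={"s": density}, unit=unit)


class TestLinkFunctions:
    @pytest.mark.parametrize(
        "beta0, d, expected", [(2, 3, 6), (5, 0, 0), (1, 47.2, 47.2)]
    )
    def test_mean_function(self, beta0, d, expected):
        assert mean_function(beta0, d) == pytest.approx(expected)

    def test_mean_function_domain(self):
        with pytest.raises(DataValidationError):
            mean_function(2.0, -1.0)

    @pytest.mark.parametrize("mu, r, expected", [(1, 1, 0.5), (0, 5, 1.0), (3, 1, 0.25)])
    def test_nb_success_prob(self, mu, r, expected):
        assert nb_success_prob(mu, r) == pytest.approx(expected)

    def test_nb_success_prob_domain(self):
        with pytest.raises(DataValidationError):
            nb_success_prob(1.0, 0.0)


class TestPointValues:
    def test_normal_at_mean(self):
        ds = _one_obs(3.0, 3.0, unit="ng_per_l")
        p = ParameterVector(beta0=1.0, dispersion=1.0)
        assert normal_loglik(ds, p) == pytest.approx(-0.918939, abs=1e-6)

    def test_normal_unit_deviation(self):
        ds = _one_obs(4.0, 3.0, unit="ng_per_l")
        p = ParameterVector(beta0=1.0, dispersion=1.0)
        assert normal_loglik(ds, p) == pytest.approx(-1.418939, abs=1e-6)

    @pytest.mark.parametrize(
        "w, mu, expected",
        [(0, 1.0, -1.0), (1, 1.0, -1.0), (3, 2.0, 3 * math.log(2) - 2 - math.log(6))],
    )
    def test_poisson_values(self, w, mu, expected):
        ds = _one_obs(w, mu)
        p = ParameterVector(beta0=1.0)
        assert poisson_loglik(ds, p) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "w, mu, r, expected",
        [(0, 1.0, 1.0, math.log(0.5)), (2, 2.0, 2.0, math.log(0.1875))],
    )
    def test_negbin_values(self, w, mu, r, expected):
        ds = _one_obs(w, mu)
        p = ParameterVector(beta0=1.0, dispersion=r)
        assert negbin_loglik(ds, p) == pytest.approx(expected, abs=1e-6)


def _random_instance(rng):
    """Random small dataset + admissible parameters (count-valued data)."""
    n_sites = int(rng.integers(1, 5))
    beta0 = float(rng.uniform(0.5, 30.0))
    values, densities, latent = {}, {}, {}
    for i in range(n_sites):
        sid = f"s{i}"
        d = float(rng.uniform(0.1, 20.0))
        k = int(rng.integers(1, 5))
        values[sid] = rng.poisson(beta0 * d, size=k).tolist()
        if rng.random() < 0.5:
            densities[sid] = d
        else:
            latent[sid] = d
    if not densities:  # likelihoods need every site to have a density anyway
        densities["s0"] = latent.pop("s0")
    return make_dataset(values, densities), beta0, latent


class TestOracles:
    """Each log-likelihood equals the sum of independently evaluated
    per-observation log-densities (scipy.stats as the oracle)."""

    def test_matches_scipy_per_observation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ds, beta0, latent = _random_instance(rng)
            sigma2 = float(rng.uniform(0.5, 50.0))
            r = float(rng.uniform(0.2, 20.0))
            dens = {**ds.densities(), **latent}
            expected = {"normal": 0.0, "poisson": 0.0, "negbin": 0.0}
            for site in ds.sites:
                mu = beta0 * dens[site.site_id]
                for w in site.values:
                    expected["normal"] += stats.norm.logpdf(
                        w, loc=mu, scale=math.sqrt(sigma2)
                    )
                    expected["poisson"] += stats.poisson.logpmf(w, mu)
                    expected["negbin"] += stats.nbinom.logpmf(w, r, r / (mu + r))
            pn = ParameterVector(beta0, sigma2, latent)
            pp = ParameterVector(beta0, None, latent)
            pr = ParameterVector(beta0, r, latent)
            assert normal_loglik(ds, pn) == pytest.approx(expected["normal"], abs=1e-8)
            assert poisson_loglik(ds, pp) == pytest.approx(expected["poisson"], abs=1e-8)
            assert negbin_loglik(ds, pr) == pytest.approx(expected["negbin"], abs=1e-8)

    @pytest.mark.parametrize("r", [1e6, 1e8])
    def test_negbin_poisson_limit(self, r):
        """As r -> inf the Negative Binomial degenerates to the Poisson."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            ds, beta0, latent = _random_instance(rng)
            pp = ParameterVector(beta0, None, latent)
            pr = ParameterVector(beta0, r, latent)
            per_obs_tol = 1e-4 * ds.n_obs
            assert negbin_loglik(ds, pr) == pytest.approx(
                poisson_loglik(ds, pp), abs=per_obs_tol
            )

    def test_ordering_invariance(self):
        """Log-likelihoods do not depend on site or replicate order."""
        rng = np.random.default_rng(5)
        ds, beta0, latent = _random_instance(rng)
        sites = list(ds.sites)
        rng.shuffle(sites)
        shuffled = make_dataset(
            {s.site_id: list(s.values)[::-1] for s in sites},
            {s.site_id: s.density for s in sites if s.density is not None},
        )
        for fam, disp in [("normal", 4.0), ("poisson", None), ("negbin", 2.0)]:
            fn = {"normal": normal_loglik, "poisson": poisson_loglik, "negbin": negbin_loglik}[fam]
            p = ParameterVector(beta0, disp, latent)
            assert fn(ds, p) == pytest.approx(fn(shuffled, p), abs=1e-10)


class TestConventionsAndErrors:
    def test_count_families_reject_noninteger(self):
        ds = _one_obs(2.5, 1.0, unit="ng_per_l")
        p = ParameterVector(beta0=1.0, dispersion=1.0)
        with pytest.raises(DataValidationError):
            poisson_loglik(ds, ParameterVector(beta0=1.0))
        with pytest.raises(DataValidationError):
            negbin_loglik(ds, p)

    def test_missing_density_raises(self):
        ds = make_dataset({"a": [1, 2]})  # eDNA-only, no latent value given
        p = ParameterVector(beta0=1.0, dispersion=1.0)
        with pytest.raises(EDNADensityError):
            normal_loglik(ds, p)

    def test_zero_mean_point_mass(self):
        zero_ok = _one_obs(0, 0.0)
        positive = _one_obs(3, 0.0)
        for fn, p in [
            (poisson_loglik, ParameterVector(beta0=1.0)),
            (negbin_loglik, ParameterVector(beta0=1.0, dispersion=2.0)),
        ]:
            assert fn(zero_ok, p) == 0.0
            assert fn(positive, p) == -math.inf

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(DataValidationError):
            ParameterVector(beta0=1.0, dispersion=0.0)
        with pytest.raises(DataValidationError):
            ParameterVector(beta0=-1.0)


def test_negbin_pmf_normalizes():
    """The implemented negbin log-pmf sums to 1 over its support, so it is
    a genuine probability distribution in the (mu, r) parameterization."""
    for mu, r in [(3.0, 0.7), (10.0, 2.5)]:
        probs = [
            math.exp(
                negbin_loglik(_one_obs(w, mu), ParameterVector(1.0, r))
            )
            for w in range(2000)
        ]
        assert sum(probs) == pytest.approx(1.0, abs=1e-8)
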