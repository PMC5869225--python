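"""Exact log-likelihoods for the three observation models.

All three families share the linear-through-origin mean link

    mu_i = beta0 * D_i

so that zero animals imply zero expected eDNA.  The families differ in how
replicate values w_ik scatter around mu_i:

* ``normal``  — w_ik ~ Normal(mu_i, sigma^2); continuous data.
* ``poisson`` — w_ik ~ Poisson(mu_i); integer counts, variance = mean.
* ``negbin`` — w_ik ~ NegBin(mu_i, r) with success probability
  p_i = r / (mu_i + r); integer counts, variance = mu + mu^2/r, so small r
  means strong overdispersion and r -> inf recovers the Poisson.

All gamma-function arithmetic is done in log space (``gammaln``): observed
copy numbers reach tens of thousands and direct Gamma evaluation would
overflow.

Conventions at mu_i = 0 (a dual site with zero animals): the count families
place a point mass at zero, so an observation contributes 0 to the
log-likelihood if w_ik = 0 and -inf otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import EDNADataset
from .errors import DataValidationError, EDNADensityError

FAMILIES = ("normal", "poisson", "negbin")

#: Families whose data must be non-negative integers.
COUNT_FAMILIES = ("poisson", "negbin")


@dataclass(frozen=True)
class ModelSpec:
    """Which distribution family to use; the mean link is always linear
    through the origin."""

    family: str
    link: str = "linear_through_origin"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise EDNADensityError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.link != "linear_through_origin":
            raise EDNADensityError("only the linear-through-origin link is supported")

    @property
    def has_dispersion(self) -> bool:
        return self.family in ("normal", "negbin")

    @property
    def dispersion_name(self) -> str | None:
        return {"normal": "sigma2", "negbin": "r"}.get(self.family)


@dataclass
class ParameterVector:
    """A full parameter point: calibration slope, family dispersion, and the
    latent densities of the eDNA-only sites.

    ``dispersion`` is sigma^2 for the normal family, r for the negative
    binomial, and ``None`` for the Poisson.  ``latent_densities`` maps
    site_id -> D_i for every eDNA-only site of the dataset being evaluated.
    """

    beta0: float
    dispersion: float | None = None
    latent_densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta0) or self.beta0 <= 0:
            raise DataValidationError(f"beta0 must be > 0, got {self.beta0!r}")
        if self.dispersion is not None and (
            not np.isfinite(self.dispersion) or self.dispersion <= 0
        ):
            raise DataValidationError(
                f"dispersion must be > 0, got {self.dispersion!r}"
            )
        for sid, d in self.latent_densities.items():
            if not np.isfinite(d) or d < 0:
                raise DataValidationError(
                    f"latent density must be >= 0, got {d!r} for site {sid!r}"
                )


def mean_function(beta0: float, density: float) -> float:
    """Expected eDNA quantity mu = beta0 * D."""
    if beta0 <= 0:
        raise DataValidationError(f"beta0 must be > 0, got {beta0!r}")
    if density < 0:
        raise DataValidationError(f"density must be >= 0, got {density!r}")
    return beta0 * density


def nb_success_prob(mu: float, r: float) -> float:
    """Negative-binomial success probability p = r / (mu + r); 1 at mu = 0."""
    if r <= 0:
        raise DataValidationError(f"r must be > 0, got {r!r}")
    if mu < 0:
        raise DataValidationError(f"mu must be >= 0, got {mu!r}")
    return r / (mu + r)


def _per_obs_arrays(
    dataset: EDNADataset, params: ParameterVector
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the dataset to per-observation (w, mu) arrays."""
    w_parts = []
    mu_parts = []
    for site in dataset.sites:
        if site.density is not None:
            d = float(site.density)
        elif site.site_id in params.latent_densities:
            d = float(params.latent_densities[site.site_id])
        else:
            raise EDNADensityError(
                f"site {site.site_id!r} has neither a known nor a latent density"
            )
        w = site.values
        w_parts.append(w)
        mu_parts.append(np.full(w.shape, params.beta0 * d))
    return np.concatenate(w_parts), np.concatenate(mu_parts)


def _require_integer(w: np.ndarray, family: str) -> None:
    if not np.all(w == np.floor(w)):
        raise DataValidationError(
            f"the {family} model requires integer data; integerize first"
        )


def normal_loglik(dataset: EDNADataset, params: ParameterVector) -> float:
    """Log-likelihood of the Normal model, summed over all observations."""
    if params.dispersion is None or params.dispersion <= 0:
        raise DataValidationError("normal family requires dispersion sigma2 > 0")
    w, mu = _per_obs_arrays(dataset, params)
    sigma2 = float(params.dispersion)
    return float(
        np.sum(-0.5 * math.log(2.0 * math.pi * sigma2) - (w - mu) ** 2 / (2.0 * sigma2))
    )


def poisson_loglik(dataset: EDNADataset, params: ParameterVector) -> float:
    """Log-likelihood of the Poisson model.

    Uses the convention 0*log(0) = 0; returns -inf when mu_i = 0 but a
    positive count was observed.
    """
    w, mu = _per_obs_arrays(dataset, params)
    _require_integer(w, "Poisson")
    zero_mu = mu == 0.0
    if np.any(zero_mu & (w > 0)):
        return -math.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            zero_mu, 0.0, w * np.log(np.where(zero_mu, 1.0, mu)) - mu - gammaln(w + 1.0)
        )
    return float(np.sum(terms))


def negbin_loglik(dataset: EDNADataset, params: ParameterVector) -> float:
    """Log-likelihood of the Negative Binomial model with p_i = r/(mu_i + r).

    Per-observation term:

        lnGamma(w+r) - lnGamma(w+1) - lnGamma(r) + r*ln(p_i) + w*ln(1-p_i)

    ``log1p``-based evaluation keeps the term accurate for large r, where
    the family approaches the Poisson.
    """
    if params.dispersion is None or params.dispersion <= 0:
        raise DataValidationError("negbin family requires dispersion r > 0")
    w, mu = _per_obs_arrays(dataset, params)
    _require_integer(w, "Negative Binomial")
    r = float(params.dispersion)
    zero_mu = mu == 0.0
    if np.any(zero_mu & (w > 0)):
        return -math.inf
    mu_safe = np.where(zero_mu, 1.0, mu)
    # log p = log r - log(mu+r); log(1-p) = log mu - log(mu+r)
    log_denom = np.log(mu_safe + r)
    terms = (
        gammaln(w + r)
        - gammaln(w + 1.0)
        - gammaln(r)
        + r * (math.log(r) - log_denom)
        + w * (np.log(mu_safe) - log_denom)
    )
    terms = np.where(zero_mu, 0.0, terms)
    return float(np.sum(terms))


LOGLIK_BY_FAMILY = {
    "normal": normal_loglik,
    "poisson": poisson_loglik,
    "negbin": negbin_loglik,
}


def loglik(dataset: EDNADataset, model: ModelSpec, params: ParameterVector) -> float:
    """Dispatch to the family log-likelihood of ``model``."""
    return LOGLIK_BY_FAMILY[model.family](dataset, params)
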