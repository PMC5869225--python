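"""Joint maximum-likelihood estimation with Wald uncertainty.

The model treats the unknown densities of eDNA-only sites as parameters and
maximizes the family log-likelihood jointly over (beta0, dispersion,
{D_i : eDNA-only}).  Positivity is enforced by optimizing the logs of all
parameters ("working coordinates"); standard errors come from the inverse
negative Hessian of the log-likelihood in working coordinates, mapped back
to the natural scale by the delta method (SE_nat = estimate * SE_log).
All model parameters are positive, and with few replicates per site the
sampling distributions of the density estimates are strongly right-skewed,
so the fit's 95% intervals are built on the log (working) scale and
back-transformed: estimate * exp(+/- q * SE_log), with q the Student-t
quantile at n_obs - n_params degrees of freedom.  This keeps intervals
inside the parameter space and gives near-nominal small-sample coverage
where a symmetric natural-scale interval is markedly anti-conservative
(see docs/methods.md).  The generic :func:`confidence_interval` helper
remains the plain symmetric z-interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import norm as _norm
from scipy.stats import t as _tdist

from .data import EDNADataset
from .errors import (
    DataValidationError,
    DegenerateDataError,
    EDNADensityError,
    IdentifiabilityError,
    NotConvergedError,
)
from .likelihoods import COUNT_FAMILIES, ModelSpec, ParameterVector, loglik

#: Additive offset inside log(D + eps) keeping the transform defined at D = 0.
_DENSITY_EPS = 1e-12

#: Box for working (log-scale) coordinates; wide enough to be inactive for
#: any realistic data while stopping the optimizer from wandering to inf.
_WORKING_BOUNDS = (-32.0, 36.0)

#: Ceiling for the negbin dispersion r.  Beyond ~1e6 the family is
#: numerically indistinguishable from the Poisson while the log-gamma
#: difference gammaln(w+r) - gammaln(r) loses all precision, so the MLE of
#: underdispersed data is pinned here (the Poisson limit).
_MAX_NEGBIN_R = 1e6


@dataclass
class FitResult:
    """Outcome of a joint ML fit.

    ``vcov`` is the variance-covariance matrix over the working
    (log-transformed) parameters, ordered as ``param_names``; ``se`` and
    ``ci95`` are on the natural scale.
    """

    model: ModelSpec
    estimates: ParameterVector
    loglik: float
    param_names: list[str]
    vcov: np.ndarray
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    converged: bool
    n_obs: int
    dataset_summary: dict
    n_restarts_used: int = 0
    message: str = ""
    edna_only_ids: list[str] = field(default_factory=list)

    def estimate_of(self, name: str) -> float:
        if name == "beta0":
            return self.estimates.beta0
        if name in ("sigma2", "r"):
            return float(self.estimates.dispersion)
        if name.startswith("D[") and name.endswith("]"):
            return self.estimates.latent_densities[name[2:-1]]
        raise KeyError(name)


def confidence_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval: estimate +/- z_(1-(1-level)/2) * se."""
    if not 0.0 < level < 1.0:
        raise DataValidationError(f"level must lie in (0, 1), got {level!r}")
    if se < 0:
        raise DataValidationError(f"se must be >= 0, got {se!r}")
    z = float(_norm.ppf(1.0 - (1.0 - level) / 2.0))
    return estimate - z * se, estimate + z * se


def _moment_start_r(dataset: EDNADataset) -> float:
    """Method-of-moments start for r from dual-site replicates.

    Per dual site with K_i >= 2 and s^2 > mean, r = mean^2 / (s^2 - mean);
    the median across sites is used, clamped to [0.01, 1e6].  Data with no
    overdispersed site start near the Poisson limit.
    """
    cands = []
    for site in dataset.dual_sites:
        w = site.values
        if w.size < 2:
            continue
        m = float(np.mean(w))
        s2 = float(np.var(w, ddof=1))
        if m > 0 and s2 > m:
            cands.append(m * m / (s2 - m))
    r0 = float(np.median(cands)) if cands else 1e4
    return float(np.clip(r0, 0.01, 1e6))


def _starting_values(dataset: EDNADataset, model: ModelSpec) -> np.ndarray:
    """Deterministic data-driven starting point in working coordinates."""
    dual = dataset.dual_sites
    num = sum(float(np.mean(s.values)) * float(s.density) for s in dual)
    den = sum(float(s.density) ** 2 for s in dual)
    beta0 = num / den if den > 0 and num > 0 else max(
        np.mean([np.mean(s.values) for s in dataset.sites]), 1e-6
    )
    beta0 = max(float(beta0), 1e-8)

    x = [math.log(beta0)]
    if model.family == "normal":
        resid = np.concatenate(
            [s.values - beta0 * float(s.density) for s in dual]
        )
        sigma2 = max(float(np.mean(resid**2)), 1e-8)
        x.append(math.log(sigma2))
    elif model.family == "negbin":
        x.append(math.log(_moment_start_r(dataset)))
    for site in dataset.edna_only_sites:
        d0 = max(float(np.mean(site.values)) / beta0, 0.0)
        x.append(math.log(d0 + _DENSITY_EPS))
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, model: ModelSpec, edna_only_ids: list[str]) -> ParameterVector:
    beta0 = math.exp(x[0])
    idx = 1
    dispersion = None
    if model.has_dispersion:
        dispersion = math.exp(x[idx])
        idx += 1
    latent = {
        sid: max(math.exp(xi) - _DENSITY_EPS, 0.0)
        for sid, xi in zip(edna_only_ids, x[idx:])
    }
    return ParameterVector(beta0=beta0, dispersion=dispersion, latent_densities=latent)


def _make_objective(dataset: EDNADataset, model: ModelSpec):
    """Fast negative log-likelihood (with analytic gradient) over working
    coordinates.

    Pre-flattens the dataset into arrays; known (dual) densities are fixed,
    latent densities enter via exp of their working coordinates.  The
    gradient is exact (chain rule through the log transform), which keeps
    L-BFGS-B convergence tight and independent of site ordering.
    """
    w_parts, site_rows, fixed_d = [], [], []
    latent_slot = []  # per site: -1 if dual else index into latent block
    n_latent = 0
    for site in dataset.sites:
        w_parts.append(site.values)
        site_rows.append(site.n_replicates)
        if site.density is not None:
            fixed_d.append(float(site.density))
            latent_slot.append(-1)
        else:
            fixed_d.append(0.0)
            latent_slot.append(n_latent)
            n_latent += 1
    w = np.concatenate(w_parts)
    reps = np.asarray(site_rows)
    obs_site = np.repeat(np.arange(len(dataset.sites)), reps)
    fixed_d = np.asarray(fixed_d)
    latent_slot = np.asarray(latent_slot)
    family = model.family
    has_disp = model.has_dispersion
    lgw1 = gammaln(w + 1.0)  # constant across evaluations

    n_params = 1 + int(has_disp) + n_latent
    latent_obs = latent_slot[obs_site]  # per-obs latent index or -1

    def _unfold(x):
        beta0 = math.exp(x[0])
        idx = 1
        disp = None
        if has_disp:
            disp = math.exp(x[idx])
            idx += 1
        d_site = fixed_d.copy()
        if n_latent:
            d_site[latent_slot >= 0] = np.maximum(np.exp(x[idx:]) - _DENSITY_EPS, 0.0)
        return beta0, disp, d_site, idx

    def neg_loglik(x: np.ndarray) -> float:
        beta0, disp, d_site, _ = _unfold(x)
        mu = beta0 * d_site[obs_site]
        if family == "normal":
            ll = np.sum(
                -0.5 * math.log(2.0 * math.pi * disp) - (w - mu) ** 2 / (2.0 * disp)
            )
        else:
            zero = mu == 0.0
            if np.any(zero & (w > 0)):
                return math.inf
            mu_s = np.where(zero, 1.0, mu)
            if family == "poisson":
                ll = np.sum(np.where(zero, 0.0, w * np.log(mu_s) - mu - lgw1))
            else:
                r = disp
                log_denom = np.log(mu_s + r)
                terms = (
                    gammaln(w + r)
                    - lgw1
                    - gammaln(r)
                    + r * (math.log(r) - log_denom)
                    + w * (np.log(mu_s) - log_denom)
                )
                ll = np.sum(np.where(zero, 0.0, terms))
        return -float(ll) if np.isfinite(ll) else math.inf

    def neg_loglik_grad(x: np.ndarray):
        """(f, grad f) in working coordinates."""
        f = neg_loglik(x)
        beta0, disp, d_site, idx = _unfold(x)
        mu = beta0 * d_site[obs_site]
        grad = np.zeros(n_params)
        if not np.isfinite(f):
            return f, grad
        mu_tiny = np.maximum(mu, 1e-300)
        if family == "normal":
            dl_dmu = (w - mu) / disp
            dl_ddisp = np.sum(-0.5 / disp + (w - mu) ** 2 / (2.0 * disp * disp))
        elif family == "poisson":
            dl_dmu = np.where(mu == 0.0, 0.0, w / mu_tiny - 1.0)
            dl_ddisp = 0.0
        else:
            r = disp
            dl_dmu = np.where(
                mu == 0.0, 0.0, w / mu_tiny - (r + w) / (mu_tiny + r)
            )
            dl_ddisp = float(
                np.sum(
                    np.where(
                        mu == 0.0,
                        0.0,
                        digamma(w + r)
                        - digamma(r)
                        + math.log(r)
                        + 1.0
                        - np.log(mu_tiny + r)
                        - (r + w) / (mu_tiny + r),
                    )
                )
            )
        # chain rule through the exp transforms
        grad[0] = float(np.sum(dl_dmu * mu))  # d mu/d log beta0 = mu
        if has_disp:
            grad[1] = dl_ddisp * disp
        if n_latent:
            contrib = dl_dmu * beta0 * (d_site[obs_site] + _DENSITY_EPS)
            mask = latent_obs >= 0
            np.add.at(grad, idx + latent_obs[mask], contrib[mask])
        return f, -grad

    return neg_loglik, neg_loglik_grad


def _hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of scalar f at x."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f(x) + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def fit(
    dataset: EDNADataset,
    model: ModelSpec,
    *,
    tol: float = 1e-8,
    maxiter: int = 10_000,
    ci_level: float = 0.95,
    n_restarts: int = 5,
) -> FitResult:
    """Jointly estimate beta0, the dispersion parameter, and all latent
    densities by maximum likelihood.

    Requires at least one dual site (beta0 is otherwise unidentifiable) and
    integer data for the count families.  Optimizer failure is reported via
    ``converged=False``, never an exception; when the first optimization
    fails, up to ``n_restarts`` deterministically jittered restarts are
    tried and the best optimum kept.
    """
    if dataset.J < 1:
        raise IdentifiabilityError(
            "at least one dual (known-density) site is required to identify beta0"
        )
    if model.family in COUNT_FAMILIES:
        for site in dataset.sites:
            if not np.all(site.values == np.floor(site.values)):
                raise DataValidationError(
                    f"the {model.family} model requires integer data "
                    f"(site {site.site_id!r}); integerize first"
                )
    if all(np.all(s.values == 0) for s in dataset.dual_sites):
        raise DegenerateDataError(
            "every dual site has all-zero eDNA values; beta0 is degenerate"
        )

    edna_only_ids = [s.site_id for s in dataset.edna_only_sites]
    neg_loglik, neg_loglik_grad = _make_objective(dataset, model)
    x0 = _starting_values(dataset, model)
    bounds = [_WORKING_BOUNDS] * x0.size
    if model.family == "negbin":
        bounds[1] = (_WORKING_BOUNDS[0], math.log(_MAX_NEGBIN_R))
        x0[1] = min(x0[1], math.log(_MAX_NEGBIN_R))

    def _solve(x_start):
        return minimize(
            neg_loglik_grad,
            np.clip(x_start, *_WORKING_BOUNDS),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            # analytic gradient: drive convergence by the gradient norm
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": tol},
        )

    def _ok(res) -> bool:
        # L-BFGS-B reports ABNORMAL when rounding noise stalls the line
        # search below ftol; a near-zero projected gradient at a finite
        # point is still an optimum, so judge by gradient norm as well.
        if not np.isfinite(res.fun):
            return False
        return bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4

    best = _solve(x0)
    n_restarts_used = 0
    if not _ok(best):
        rng = np.random.default_rng(0)  # fixed: restarts must be replayable
        for _ in range(n_restarts):
            n_restarts_used += 1
            res = _solve(x0 + rng.normal(0.0, 0.5, size=x0.size))
            if np.isfinite(res.fun) and (not np.isfinite(best.fun) or res.fun < best.fun):
                best = res
            if _ok(best):
                break

    xhat = np.asarray(best.x, dtype=float)
    converged = _ok(best)
    message = str(best.message)

    param_names = ["beta0"]
    if model.has_dispersion:
        param_names.append(model.dispersion_name)
    param_names += [f"D[{sid}]" for sid in edna_only_ids]

    # Observed information in working coordinates; Hessian of neg loglik.
    H = _hessian(neg_loglik, xhat)
    vcov = None
    if np.all(np.isfinite(H)):
        try:
            eigvals = np.linalg.eigvalsh((H + H.T) / 2.0)
            if np.all(eigvals > 0):
                vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None
    if vcov is None:
        # Diagonal fallback when the information matrix is not PD.
        diag = np.where(np.isfinite(np.diag(H)) & (np.diag(H) > 0), np.diag(H), np.inf)
        vcov = np.diag(1.0 / diag)
        converged = False
        message = message + "; Hessian not positive definite (diagonal fallback)"

    estimates = _unpack(xhat, model, edna_only_ids)
    natural = np.array([math.exp(v) for v in xhat])
    se_working = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    se_natural = natural * se_working  # delta method for exp transform

    # Log-scale Wald-t intervals: t quantile with residual degrees of
    # freedom guards against the optimism of plug-in dispersion estimates.
    dof = max(dataset.n_obs - len(param_names), 1)
    q = float(_tdist.ppf(1.0 - (1.0 - ci_level) / 2.0, dof))
    se = {}
    ci95 = {}
    for k, name in enumerate(param_names):
        est = natural[k] - (_DENSITY_EPS if name.startswith("D[") else 0.0)
        est = max(est, 0.0)
        sw = float(se_working[k])
        if np.isfinite(sw) and q * sw < 700.0:
            lo = est * math.exp(-q * sw)
            hi = est * math.exp(q * sw)
        else:
            lo, hi = 0.0, math.inf
        se[name] = float(se_natural[k])
        ci95[name] = (float(lo), float(hi))

    ll = float(-best.fun) if np.isfinite(best.fun) else -math.inf
    summary = {
        "I": dataset.I,
        "J": dataset.J,
        "K": [s.n_replicates for s in dataset.sites],
    }
    return FitResult(
        model=model,
        estimates=estimates,
        loglik=ll,
        param_names=param_names,
        vcov=vcov,
        se=se,
        ci95=ci95,
        converged=converged,
        n_obs=dataset.n_obs,
        dataset_summary=summary,
        n_restarts_used=n_restarts_used,
        message=message,
        edna_only_ids=edna_only_ids,
    )


def predict_densities(fit_result: FitResult) -> list[dict]:
    """Per-site density predictions for the eDNA-only sites of a converged
    fit: (site_id, density_estimate, se, ci_low, ci_high)."""
    if not fit_result.converged:
        raise NotConvergedError(
            f"fit did not converge ({fit_result.message}); refusing to predict"
        )
    records = []
    for sid in fit_result.edna_only_ids:
        name = f"D[{sid}]"
        lo, hi = fit_result.ci95[name]
        records.append(
            {
                "site_id": sid,
                "density_estimate": fit_result.estimates.latent_densities[sid],
                "se": fit_result.se[name],
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return records


def check_loglik_consistency(fit_result: FitResult, dataset: EDNADataset) -> float:
    """Re-evaluate the family log-likelihood at the reported estimates;
    returns the absolute discrepancy with the stored value."""
    ll = loglik(dataset, fit_result.model, fit_result.estimates)
    if not np.isfinite(ll) or not np.isfinite(fit_result.loglik):
        raise EDNADensityError("non-finite log-likelihood")
    return abs(ll - fit_result.loglik)
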