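"""Pre-analysis data characterization and count-model preparation.

Two descriptive diagnostics guide the choice of observation model:

* the per-site **variance-to-mean ratio** (VMR) of replicate eDNA values —
  VMR > 1 flags overdispersion relative to the Poisson, VMR < 1
  underdispersion;
* the replicate-level **Pearson correlation** between eDNA values and the
  known densities of the dual sites, a quick gauge of how much calibration
  information the data carry.

The module also provides the integerization transform that continuous
(ng/L) measurements need before a count model can be applied: values are
scaled to the precision at which concentration is actually resolved and
rounded to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .data import EDNADataset
from .errors import DataValidationError, EDNADensityError


@dataclass
class DiagnosticsReport:
    per_site_vmr: dict[str, float]
    mean_vmr: float
    pearson_r: float | None = None
    r_squared: float | None = None
    slope_through_origin: float | None = None


def per_site_vmr(dataset: EDNADataset) -> DiagnosticsReport:
    """Per-site VMR = s^2 / mean with the (K_i - 1)-denominator sample
    variance; sites with zero mean get VMR 0.  Needs K_i >= 2 everywhere."""
    vmrs: dict[str, float] = {}
    for site in dataset.sites:
        if site.n_replicates < 2:
            raise DataValidationError(
                f"VMR needs >= 2 replicates; site {site.site_id!r} has "
                f"{site.n_replicates}"
            )
        w = site.values
        m = float(np.mean(w))
        vmrs[site.site_id] = float(np.var(w, ddof=1) / m) if m > 0 else 0.0
    return DiagnosticsReport(
        per_site_vmr=vmrs, mean_vmr=float(np.mean(list(vmrs.values())))
    )


def edna_density_correlation(dataset: EDNADataset) -> tuple[float, float]:
    """Replicate-level Pearson correlation between eDNA values and site
    density across the dual sites; returns (r, r^2).  Needs J >= 3."""
    if dataset.J < 3:
        raise DataValidationError(
            f"correlation needs >= 3 dual sites, got J={dataset.J}"
        )
    w, d = [], []
    for site in dataset.dual_sites:
        for v in site.values:
            w.append(float(v))
            d.append(float(site.density))
    w = np.asarray(w)
    d = np.asarray(d)
    if np.var(w) == 0.0 or np.var(d) == 0.0:
        raise EDNADensityError(
            "correlation undefined: zero variance in eDNA or density values"
        )
    r = float(pearsonr(w, d).statistic)
    return r, r * r


def diagnose(dataset: EDNADataset) -> DiagnosticsReport:
    """Full diagnostics: VMR table plus, when J >= 3 dual sites exist,
    correlation and the least-squares through-origin slope."""
    report = per_site_vmr(dataset)
    if dataset.J >= 3:
        r, r2 = edna_density_correlation(dataset)
        report.pearson_r = r
        report.r_squared = r2
        num = sum(
            float(np.mean(s.values)) * float(s.density) for s in dataset.dual_sites
        )
        den = sum(float(s.density) ** 2 for s in dataset.dual_sites)
        report.slope_through_origin = num / den if den > 0 else float("nan")
    return report


def integerize(values, scale: float) -> list[int]:
    """Scale non-negative concentrations and round half-away-from-zero to
    integers, making continuous measurements usable by the count families."""
    if scale <= 0:
        raise DataValidationError(f"scale must be > 0, got {scale!r}")
    out = []
    for v in values:
        v = float(v)
        if v < 0:
            raise DataValidationError(f"values must be >= 0, got {v!r}")
        out.append(int(math.floor(v * scale + 0.5)))
    return out


def default_integerization_scale(values) -> float:
    """Power-of-ten scale mapping the smallest positive value to >= 1, so
    no positive detection collapses to zero."""
    positive = [float(v) for v in values if float(v) > 0]
    if not positive:
        return 1.0
    return 10.0 ** max(0, math.ceil(-math.log10(min(positive))))


def integerize_dataset(dataset: EDNADataset, scale: float | None = None) -> EDNADataset:
    """Return a copy of the dataset with all eDNA values integerized
    (unit becomes ``integerized``); ``scale=None`` auto-selects."""
    from .data import EDNAObservation, SurveySite

    all_values = [o.value for s in dataset.sites for o in s.observations]
    if scale is None:
        scale = default_integerization_scale(all_values)
    sites = []
    for s in dataset.sites:
        obs = tuple(
            EDNAObservation(
                site_id=o.site_id,
                replicate_index=o.replicate_index,
                value=float(integerize([o.value], scale)[0]),
                unit="integerized",
            )
            for o in s.observations
        )
        sites.append(SurveySite(site_id=s.site_id, observations=obs, density=s.density))
    return EDNADataset(sites=sites)
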