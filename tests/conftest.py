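import numpy as np
import pytest

from ednadensity.data import EDNADataset, EDNAObservation, SurveySite


def make_dataset(values_by_site, densities=None, unit="copies_per_ml"):
    """Build an EDNADataset from {site_id: [w values]} and an optional
    {site_id: density} map (sites present there become dual)."""
    densities = densities or {}
    sites = []
    for sid, vals in values_by_site.items():
        obs = tuple(
            EDNAObservation(site_id=sid, replicate_index=k + 1, value=float(v), unit=unit)
            for k, v in enumerate(vals)
        )
        sites.append(
            SurveySite(site_id=sid, observations=obs, density=densities.get(sid))
        )
    return EDNADataset(sites=sites)


@pytest.fixture
def all_dual_counts():
    """Small all-dual integer dataset for count-family fits."""
    rng = np.random.default_rng(11)
    densities = {"a": 2.0, "b": 5.0, "c": 9.0, "d": 14.0}
    values = {
        sid: rng.poisson(10.0 * d, size=3).tolist() for sid, d in densities.items()
    }
    return make_dataset(values, densities)


@pytest.fixture
def mixed_roles_counts():
    """Overdispersed integer dataset with both dual and eDNA-only sites
    (the regime the Negative Binomial model targets)."""
    rng = np.random.default_rng(7)
    truths = {"a": 2.0, "b": 5.0, "c": 9.0, "d": 14.0, "e": 20.0}
    r = 2.0
    values = {
        sid: rng.negative_binomial(r, r / (10.0 * d + r), size=4).tolist()
        for sid, d in truths.items()
    }
    dual = {sid: truths[sid] for sid in ("a", "c", "e")}
    return make_dataset(values, dual), truths
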