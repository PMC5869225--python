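"""Core domain types and table I/O.

The data model mirrors how quantitative eDNA surveys are recorded in the
field: a replicate-level table of eDNA concentrations (one row per
site x water-sample replicate) and, for the *dual data* subset of sites,
an independent animal-density measurement (animals/m^2).  Sites carrying
a density are the calibration ("dual") sites; the remaining sites are
"eDNA-only" and their densities are latent parameters of the model.

Tables are plain CSV with a header row; ``site_id`` is an opaque string.
Mixed measurement units within one dataset are rejected rather than
auto-converted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    DataValidationError,
    UnknownSiteError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .inference import FitResult

#: Recognized measurement units.  ``copies_per_ml`` (ddPCR absolute copy
#: counts) and ``integerized`` (scaled-and-rounded qPCR values) are integer
#: valued; ``ng_per_l`` (qPCR concentration) is continuous.
UNITS = ("copies_per_ml", "ng_per_l", "integerized")
INTEGER_UNITS = ("copies_per_ml", "integerized")

DUAL = "dual"
EDNA_ONLY = "edna_only"


def _is_integral(x: float) -> bool:
    return float(x) == math.floor(float(x))


@dataclass(frozen=True)
class EDNAObservation:
    """One replicate eDNA quantification w_ik at one site.

    Parameters
    ----------
    site_id : str
        Opaque site identifier.
    replicate_index : int
        1-based replicate number k within the site.
    value : float
        eDNA quantity w_ik (>= 0); integral when the unit is a count unit.
    unit : str
        One of :data:`UNITS`.
    """

    site_id: str
    replicate_index: int
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DataFormatError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        if not np.isfinite(self.value) or self.value < 0:
            raise DataValidationError(
                f"eDNA value must be finite and >= 0, got {self.value!r} "
                f"at site {self.site_id!r}"
            )
        if self.replicate_index < 1:
            raise DataValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )
        if self.unit in INTEGER_UNITS and not _is_integral(self.value):
            raise DataValidationError(
                f"unit {self.unit!r} requires integer values, got "
                f"{self.value!r} at site {self.site_id!r}"
            )


@dataclass(frozen=True)
class SurveySite:
    """A surveyed site: its K_i eDNA replicates and, if dual, its density."""

    site_id: str
    observations: tuple[EDNAObservation, ...]
    density: float | None = None

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise DataValidationError(
                f"site {self.site_id!r} has no observations (K_i >= 1 required)"
            )
        if any(o.site_id != self.site_id for o in self.observations):
            raise DataValidationError(
                f"observation site_id mismatch at site {self.site_id!r}"
            )
        if self.density is not None and (
            not np.isfinite(self.density) or self.density < 0
        ):
            raise DataValidationError(
                f"density must be finite and >= 0, got {self.density!r} "
                f"at site {self.site_id!r}"
            )

    @property
    def role(self) -> str:
        """``"dual"`` when a known density is attached, else ``"edna_only"``."""
        return DUAL if self.density is not None else EDNA_ONLY

    @property
    def n_replicates(self) -> int:
        return len(self.observations)

    @property
    def values(self) -> np.ndarray:
        """Replicate eDNA values as a float array (length K_i)."""
        return np.array([o.value for o in self.observations], dtype=float)


@dataclass
class EDNADataset:
    """The full survey: I sites, of which J carry a known density."""

    sites: list[SurveySite] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate site_ids: {dupes}")
        units = {o.unit for s in self.sites for o in s.observations}
        if len(units) > 1:
            raise DataValidationError(
                f"mixed units in one dataset: {sorted(units)}; convert first"
            )

    @property
    def I(self) -> int:  # noqa: E743 - field notation
        return len(self.sites)

    @property
    def J(self) -> int:
        return sum(1 for s in self.sites if s.role == DUAL)

    @property
    def unit(self) -> str | None:
        for s in self.sites:
            for o in s.observations:
                return o.unit
        return None

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def dual_sites(self) -> list[SurveySite]:
        return [s for s in self.sites if s.role == DUAL]

    @property
    def edna_only_sites(self) -> list[SurveySite]:
        return [s for s in self.sites if s.role == EDNA_ONLY]

    @property
    def n_obs(self) -> int:
        return sum(s.n_replicates for s in self.sites)

    def site(self, site_id: str) -> SurveySite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise UnknownSiteError(f"no site {site_id!r} in dataset")

    def densities(self) -> dict[str, float]:
        """Known densities of the dual sites."""
        return {s.site_id: float(s.density) for s in self.dual_sites}

    def with_masked_densities(self, keep_dual: set[str] | list[str]) -> "EDNADataset":
        """Copy of the dataset where only ``keep_dual`` retain their density.

        Used by the cross-validation harness: held-out sites become
        eDNA-only and their densities turn into latent parameters.
        """
        keep = set(keep_dual)
        unknown = keep - set(self.site_ids)
        if unknown:
            raise UnknownSiteError(f"unknown site_ids: {sorted(unknown)}")
        sites = [
            SurveySite(
                site_id=s.site_id,
                observations=s.observations,
                density=s.density if s.site_id in keep else None,
            )
            for s in self.sites
        ]
        return EDNADataset(sites=sites)


def read_dataset(
    edna_table: str | Path | pd.DataFrame,
    density_table: str | Path | pd.DataFrame | None = None,
) -> EDNADataset:
    """Build a validated :class:`EDNADataset` from tabular sources.

    ``edna_table`` must have columns (site_id, replicate_index, value, unit);
    ``density_table``, if given, must have columns (site_id, density).  Sites
    present in the density table become dual sites; replicate counts K_i are
    derived from the rows (ragged designs allowed).
    """
    edna = _load_table(edna_table, ("site_id", "replicate_index", "value", "unit"))
    dup = edna.duplicated(subset=["site_id", "replicate_index"])
    if dup.any():
        bad = edna.loc[dup, ["site_id", "replicate_index"]].values.tolist()
        raise DataFormatError(f"duplicate (site_id, replicate_index) rows: {bad}")

    densities: dict[str, float] = {}
    if density_table is not None:
        dens = _load_table(density_table, ("site_id", "density"))
        if dens["site_id"].duplicated().any():
            raise DataFormatError("duplicate site_id rows in density table")
        known_sites = set(edna["site_id"].astype(str))
        for _, row in dens.iterrows():
            sid = str(row["site_id"])
            if sid not in known_sites:
                raise UnknownSiteError(
                    f"density table site {sid!r} absent from eDNA table"
                )
            densities[sid] = float(row["density"])

    sites = []
    for sid, group in edna.groupby("site_id", sort=False):
        group = group.sort_values("replicate_index")
        obs = tuple(
            EDNAObservation(
                site_id=str(sid),
                replicate_index=int(row["replicate_index"]),
                value=float(row["value"]),
                unit=str(row["unit"]),
            )
            for _, row in group.iterrows()
        )
        sites.append(
            SurveySite(site_id=str(sid), observations=obs, density=densities.get(str(sid)))
        )
    return EDNADataset(sites=sites)


def _load_table(
    source: str | Path | pd.DataFrame, required: tuple[str, ...]
) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing columns {missing}; found {list(df.columns)}")
    df["site_id"] = df["site_id"].astype(str)
    return df


def write_dataset(
    dataset: EDNADataset,
    edna_path: str | Path,
    density_path: str | Path | None = None,
) -> None:
    """Write the dataset back to CSV; inverse of :func:`read_dataset`."""
    rows = [
        {
            "site_id": o.site_id,
            "replicate_index": o.replicate_index,
            "value": o.value,
            "unit": o.unit,
        }
        for s in dataset.sites
        for o in s.observations
    ]
    pd.DataFrame(rows).to_csv(edna_path, index=False, float_format="%.12g")
    if density_path is not None:
        drows = [
            {"site_id": s.site_id, "density": s.density} for s in dataset.dual_sites
        ]
        pd.DataFrame(drows, columns=["site_id", "density"]).to_csv(
            density_path, index=False, float_format="%.12g"
        )


def write_fit_report(fit: "FitResult", destination: str | Path) -> None:
    """Serialize a fit to JSON: one record per estimated quantity
    (name, estimate, SE, CI bounds) plus log-likelihood and convergence flag.

    Floats are written at full ``repr`` precision so that
    :func:`read_fit_report` round-trips losslessly.
    """
    record = {
        "family": fit.model.family,
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
        "n_obs": fit.n_obs,
        "dataset_summary": fit.dataset_summary,
        "parameters": [
            {
                "name": name,
                "estimate": fit.estimate_of(name),
                "se": fit.se[name],
                "ci_low": fit.ci95[name][0],
                "ci_high": fit.ci95[name][1],
            }
            for name in fit.param_names
        ],
    }
    path = Path(destination)
    try:
        path.write_text(json.dumps(record, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write fit report to {path}: {exc}") from exc


def read_fit_report(source: str | Path) -> dict:
    """Read back a JSON fit report as a plain dictionary."""
    return json.loads(Path(source).read_text())
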