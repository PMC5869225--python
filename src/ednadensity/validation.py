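"""Exhaustive leave-p-out cross-validation and performance metrics.

The assessment asks: if densities were only known at J of the I sites,
how well would the model recover the held-out densities?  Every one of the
C(I, J) ways of choosing the J calibration sites is enumerated; for each
split the held-out sites are treated as eDNA-only, the model is refit, and
the held-out predictions are scored against the masked truths.

Three summary metrics are pooled over all held-out records of all
converged splits:

* **RMSE** of the errors eps_i = Dhat_i - D_i;
* **realized coverage** — the fraction of held-out truths inside their
  95% Wald intervals (should be near 0.95 for a well-behaved estimator);
* **rank accuracy** — pairwise concordance of the held-out estimates with
  the held-out truths within each repetition (ties score 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .data import EDNADataset
from .errors import DataValidationError, EDNADensityError
from .inference import fit as _fit
from .inference import predict_densities
from .likelihoods import ModelSpec


@dataclass
class HeldOutRecord:
    site_id: str
    true_density: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def error(self) -> float:
        """eps_i = Dhat_i - D_i."""
        return self.estimate - self.true_density

    @property
    def covered(self) -> bool:
        return self.ci_low <= self.true_density <= self.ci_high


@dataclass
class CVRepetition:
    """One split: the J calibration site ids and the held-out scores."""

    dual_ids: tuple[str, ...]
    heldout: list[HeldOutRecord] = field(default_factory=list)


@dataclass
class CVResult:
    J: int
    n_splits: int
    repetitions: list[CVRepetition]
    rmse: float
    coverage: float
    rank_accuracy: float
    n_failed: int

    @property
    def n_heldout_records(self) -> int:
        return sum(len(r.heldout) for r in self.repetitions)


def enumerate_splits(I: int, J: int) -> list[tuple[int, ...]]:
    """All C(I, J) index subsets of size J, in lexicographic order."""
    if not 1 <= J <= I:
        raise DataValidationError(f"need 1 <= J <= I, got J={J}, I={I}")
    return list(combinations(range(I), J))


def rmse(errors) -> float:
    """Root mean squared error sqrt(mean(eps^2))."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise DataValidationError("rmse of an empty error list is undefined")
    return float(np.sqrt(np.mean(errors**2)))


def realized_coverage(repetitions: list[CVRepetition]) -> float:
    """Fraction of all held-out records whose interval contains the truth."""
    records = [rec for rep in repetitions for rec in rep.heldout]
    if not records:
        raise DataValidationError("no held-out records; coverage undefined")
    return float(np.mean([rec.covered for rec in records]))


def rank_accuracy(repetitions: list[CVRepetition]) -> float:
    """Pairwise rank concordance of held-out estimates with truths.

    Within each repetition, every unordered pair of held-out sites is
    scored 1 if the estimates order the pair like the truths, 0 if they
    reverse it, and 1/2 when either the truths or the estimates are tied.
    The reported rate pools all pairs across repetitions.
    """
    n_pairs = 0
    score = 0.0
    for rep in repetitions:
        if len(rep.heldout) < 2:
            raise DataValidationError(
                "rank accuracy needs >= 2 held-out sites per repetition"
            )
        for a, b in combinations(rep.heldout, 2):
            n_pairs += 1
            dt = a.true_density - b.true_density
            de = a.estimate - b.estimate
            if dt == 0.0 or de == 0.0:
                score += 0.5
            elif math.copysign(1.0, dt) == math.copysign(1.0, de):
                score += 1.0
    if n_pairs == 0:
        raise DataValidationError("no pairs available for rank accuracy")
    return score / n_pairs


def cross_validate(
    dataset: EDNADataset,
    J: int,
    model: ModelSpec,
    *,
    progress: bool = False,
    **fit_kwargs,
) -> CVResult:
    """Run the exhaustive leave-p-out assessment with J calibration sites.

    Requires a density at every site (the held-out truths); splits whose
    fit does not converge are counted in ``n_failed`` and excluded from
    the aggregates.
    """
    if dataset.J != dataset.I:
        missing = [s.site_id for s in dataset.edna_only_sites]
        raise EDNADensityError(
            f"cross-validation requires a known density at every site; "
            f"missing at {missing}"
        )
    if not 1 <= J < dataset.I:
        raise DataValidationError(f"need 1 <= J < I, got J={J}, I={dataset.I}")

    site_ids = dataset.site_ids
    truths = dataset.densities()
    splits = enumerate_splits(dataset.I, J)
    repetitions: list[CVRepetition] = []
    n_failed = 0
    for split_no, idx in enumerate(splits, 1):
        keep = [site_ids[i] for i in idx]
        masked = dataset.with_masked_densities(keep)
        result = _fit(masked, model, **fit_kwargs)
        if not result.converged:
            n_failed += 1
            continue
        rep = CVRepetition(dual_ids=tuple(keep))
        for rec in predict_densities(result):
            rep.heldout.append(
                HeldOutRecord(
                    site_id=rec["site_id"],
                    true_density=truths[rec["site_id"]],
                    estimate=rec["density_estimate"],
                    se=rec["se"],
                    ci_low=rec["ci_low"],
                    ci_high=rec["ci_high"],
                )
            )
        repetitions.append(rep)
        if progress:  # pragma: no cover - cosmetic
            import sys

            print(f"split {split_no}/{len(splits)} done", file=sys.stderr)

    if repetitions:
        all_errors = [rec.error for rep in repetitions for rec in rep.heldout]
        agg_rmse = rmse(all_errors)
        agg_cov = realized_coverage(repetitions)
        agg_rank = (
            rank_accuracy(repetitions)
            if all(len(r.heldout) >= 2 for r in repetitions)
            else float("nan")
        )
    else:
        agg_rmse = agg_cov = agg_rank = float("nan")

    assert len(splits) == comb(dataset.I, J)
    return CVResult(
        J=J,
        n_splits=len(splits),
        repetitions=repetitions,
        rmse=agg_rmse,
        coverage=agg_cov,
        rank_accuracy=agg_rank,
        n_failed=n_failed,
    )
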