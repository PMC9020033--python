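"""Pooling of cross-validation estimates.

Two pooling stages follow the cross-validation:

* across the m imputed datasets, Rubin's rule: pooled mean = average of the
  per-imputation means; total variance T = W + (1 + 1/m) B where W is the
  mean within-imputation (cross-validation) variance and B the sample
  variance of the per-imputation means; SD = sqrt(T);
* across cohorts, inverse-variance weighting: weights 1/sd_i^2, pooled
  estimate = weighted mean, pooled SD = sqrt(1 / sum of weights).

The within-imputation variance fed to Rubin's rule is the cross-validation
sample variance of the per-split estimates (SD_CV squared); feeding the
resulting cohort-level SDs into the inverse-variance stage reproduces the
published two-cohort pooled columns from the cohort-level ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cv_pipeline import CVResult
from .datatypes import ValidationError

__all__ = [
    "PooledEstimate",
    "rubin_pool",
    "inverse_variance_pool",
    "pool_imputations",
    "pool_cohorts",
]


@dataclass
class PooledEstimate:
    """A pooled estimate with its pooled SD."""

    estimate: float
    sd: float
    n_units: int
    method: str  # "rubin" | "inverse_variance"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "sd": self.sd,
            "n_units": self.n_units,
            "method": self.method,
        }


def rubin_pool(
    estimates: Sequence[float], within_vars: Sequence[float]
) -> PooledEstimate:
    """Rubin's rule over per-imputation estimates and within-imputation variances."""
    estimates = np.asarray(estimates, dtype=float)
    within_vars = np.asarray(within_vars, dtype=float)
    m = estimates.size
    if m < 2:
        raise ValidationError("Rubin pooling needs at least 2 imputations")
    if within_vars.size != m:
        raise ValidationError("estimates and within_vars differ in length")
    if (within_vars < 0).any():
        raise ValidationError("within-imputation variances must be non-negative")
    w_bar = float(within_vars.mean())
    b = float(estimates.var(ddof=1))
    total = w_bar + (1.0 + 1.0 / m) * b
    return PooledEstimate(
        estimate=float(estimates.mean()),
        sd=float(np.sqrt(total)),
        n_units=m,
        method="rubin",
    )


def inverse_variance_pool(
    cohort_estimates: Sequence[tuple[float, float]]
) -> PooledEstimate:
    """Inverse-variance weighted average of (estimate, sd) pairs across cohorts."""
    if len(cohort_estimates) < 2:
        raise ValidationError("inverse-variance pooling needs at least 2 cohorts")
    est = np.array([e for e, _ in cohort_estimates], dtype=float)
    sd = np.array([s for _, s in cohort_estimates], dtype=float)
    if (sd <= 0).any():
        raise ValidationError("all cohort SDs must be strictly positive")
    w = 1.0 / sd**2
    return PooledEstimate(
        estimate=float(np.sum(w * est) / np.sum(w)),
        sd=float(np.sqrt(1.0 / np.sum(w))),
        n_units=len(cohort_estimates),
        method="inverse_variance",
    )


_COLUMNS = ("delta_r2", "r2_baseline", "r2_methylation")


def pool_imputations(cv_results: Iterable[CVResult]) -> dict[str, PooledEstimate]:
    """Rubin-pool per-imputation CV results for delta, baseline and
    methylation R^2 independently."""
    results = list(cv_results)
    out: dict[str, PooledEstimate] = {}
    means = {
        "delta_r2": [r.mean_delta for r in results],
        "r2_baseline": [r.mean_r2_baseline for r in results],
        "r2_methylation": [r.mean_r2_methylation for r in results],
    }
    sds = {
        "delta_r2": [r.sd_cv for r in results],
        "r2_baseline": [r.sd_r2_baseline for r in results],
        "r2_methylation": [r.sd_r2_methylation for r in results],
    }
    for col in _COLUMNS:
        out[col] = rubin_pool(means[col], np.asarray(sds[col]) ** 2)
    return out


def pool_cohorts(
    cohort_summaries: Sequence[dict[str, PooledEstimate] | dict[str, dict]]
) -> dict[str, PooledEstimate]:
    """Inverse-variance pool per-cohort pooled columns into the final row."""
    out: dict[str, PooledEstimate] = {}
    for col in _COLUMNS:
        pairs = []
        for summary in cohort_summaries:
            entry = summary[col]
            if isinstance(entry, PooledEstimate):
                pairs.append((entry.estimate, entry.sd))
            else:
                pairs.append((entry["estimate"], entry["sd"]))
        out[col] = inverse_variance_pool(pairs)
    return out
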