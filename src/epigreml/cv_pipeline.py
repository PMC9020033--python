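"""Monte-Carlo cross-validation of the methylation GREML model.

For each of ``n_splits`` random 90/10 train/test splits the pipeline fits
two models on the training samples — a baseline model (covariates fixed,
batch random) and a methylation model (the same plus the similarity random
effect) — predicts the held-out outcomes via BLUP, and computes the
out-of-sample squared Pearson correlation of each model. The per-split
difference

    delta_r2 = r2_methylation - r2_baseline

is the variance explained by genome-wide methylation beyond the covariates
(Delta R^2_Methylation). Per-split deltas (including negative ones) are
aggregated into their mean and sample SD across splits (SD_CV).

The similarity matrix is computed once on the full sample and held fixed
across splits; only the model fits and predictions are re-done per split.
Baseline and methylation models always share the same split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SimilarityMatrix, ValidationError
from .greml_core import (
    MethylationGREML,
    blup_predict,
    build_design,
    model_r2,
)

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "make_split", "run_cv"]


@dataclass
class CVResult:
    """Per-split and aggregate cross-validation estimates for one model pair."""

    records: pd.DataFrame
    n_splits: int
    train_fraction: float
    covariate_set: str
    outcome: str
    seed: int
    n_failed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def _ok(self) -> pd.DataFrame:
        return self.records[~self.records["failed"]]

    @property
    def mean_delta(self) -> float:
        return float(self._ok["delta_r2"].mean())

    @property
    def sd_cv(self) -> float:
        return float(self._ok["delta_r2"].std(ddof=1))

    @property
    def mean_r2_baseline(self) -> float:
        return float(self._ok["r2_baseline"].mean())

    @property
    def mean_r2_methylation(self) -> float:
        return float(self._ok["r2_methylation"].mean())

    @property
    def sd_r2_baseline(self) -> float:
        return float(self._ok["r2_baseline"].std(ddof=1))

    @property
    def sd_r2_methylation(self) -> float:
        return float(self._ok["r2_methylation"].std(ddof=1))

    def summary_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "covariate_set": self.covariate_set,
            "r2_baseline": self.mean_r2_baseline,
            "r2_methylation": self.mean_r2_methylation,
            "delta_r2": self.mean_delta,
            "sd_cv": self.sd_cv,
            "n_splits": self.n_splits,
            "n_failed": self.n_failed,
        }

    def to_dict(self) -> dict:
        row = self.summary_row()
        row.update(
            {
                "sd_r2_baseline": self.sd_r2_baseline,
                "sd_r2_methylation": self.sd_r2_methylation,
                "train_fraction": self.train_fraction,
                "seed": self.seed,
            }
        )
        return row

    def plot(self, ax=None):
        """Histogram of per-split delta R^2 with the mean marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        deltas = self._ok["delta_r2"]
        ax.hist(deltas, bins=min(30, max(5, len(deltas) // 3)), alpha=0.7)
        ax.axvline(self.mean_delta, color="black", lw=2)
        ax.set_xlabel(r"$\Delta R^2$ (methylation beyond covariates)")
        ax.set_ylabel("cross-validation splits")
        ax.set_title(f"{self.outcome} ({self.covariate_set})")
        return ax


def make_split(
    n: int, train_fraction: float = 0.9, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test split; train size = round(train_fraction * n)
    (round-half-to-even)."""
    if n < 10:
        raise ValidationError("cross-validation needs at least 10 samples")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n - n_train < 3:
        raise ValidationError(
            f"test set of {n - n_train} is too small for a squared correlation"
        )
    rng = rng or np.random.default_rng()
    perm = rng.permutation(n)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return train, test


def run_cv(
    outcome: str,
    pheno: pd.DataFrame,
    M: SimilarityMatrix,
    covariates: list[str],
    covariate_set: str = "custom",
    n_splits: int = 100,
    train_fraction: float = 0.9,
    seed: int = 0,
    include_batch_blup: bool = True,
) -> CVResult:
    """Monte-Carlo cross-validation of baseline vs methylation models.

    ``pheno`` must be complete in the outcome and covariate columns
    (multiple imputation runs upstream); its rows are aligned to the
    similarity matrix by ``sample_id``.
    """
    pheno = (
        pheno.set_index("sample_id").loc[M.sample_ids].reset_index()
        if "sample_id" in pheno.columns
        else pheno
    )
    needed = [outcome] + covariates
    if pheno[needed].isna().any().any():
        raise ValidationError(
            "phenotype table has missing cells in the outcome or covariates; "
            "run chained imputation first"
        )
    y = pheno[outcome].to_numpy(dtype=float)
    W, _ = build_design(pheno, covariates)
    batch = pheno["batch"].to_numpy() if "batch" in pheno.columns else None
    n = y.size

    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for s in range(n_splits):
        train, test = make_split(n, train_fraction, rng)
        row: dict = {"split": s, "failed": False}
        try:
            batch_tr = batch[train] if batch is not None else None
            batch_te = batch[test] if batch is not None else None

            base = MethylationGREML(
                y[train], W[train], similarity=None, batch=batch_tr
            ).fit()
            pred_base = blup_predict(
                base,
                base._workspace.spec,
                M_cross=None,
                W_test=W[test],
                batch_test=batch_te,
                include_batch_blup=include_batch_blup,
            )
            meth = MethylationGREML(
                y[train],
                W[train],
                similarity=M.submatrix(train, train),
                batch=batch_tr,
            ).fit()
            pred_meth = blup_predict(
                meth,
                meth._workspace.spec,
                M_cross=M.submatrix(test, train),
                W_test=W[test],
                batch_test=batch_te,
                include_batch_blup=include_batch_blup,
            )
            row["r2_baseline"] = model_r2(pred_base, y[test])
            row["r2_methylation"] = model_r2(pred_meth, y[test])
            row["delta_r2"] = row["r2_methylation"] - row["r2_baseline"]
            row["converged_baseline"] = base.converged
            row["converged_methylation"] = meth.converged
        except (ValidationError, np.linalg.LinAlgError) as exc:
            logger.warning("split %d failed: %s", s, exc)
            row.update(
                r2_baseline=np.nan,
                r2_methylation=np.nan,
                delta_r2=np.nan,
                converged_baseline=False,
                converged_methylation=False,
                failed=True,
            )
            n_failed += 1
        rows.append(row)
    if n_failed:
        logger.warning("%d of %d splits failed outright", n_failed, n_splits)

    return CVResult(
        records=pd.DataFrame(rows),
        n_splits=n_splits,
        train_fraction=train_fraction,
        covariate_set=covariate_set,
        outcome=outcome,
        seed=seed,
        n_failed=n_failed,
    )
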