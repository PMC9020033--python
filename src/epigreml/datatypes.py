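"""Core containers shared across the pipeline.

The pipeline's tabular objects are thin wrappers around numpy arrays and
pandas DataFrames: a methylation matrix (samples x CpG probes), a probe
manifest with genomic coordinates, an n x n methylation similarity matrix,
and small configuration records. Phenotype/covariate tables are plain
pandas DataFrames with a ``sample_id`` column, an outcome column, covariate
columns and a categorical ``batch`` column; helpers here validate that
convention rather than wrapping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))

#: allowed processing stages of a methylation matrix, in order
STAGES = ("raw", "winsorized", "standardized")


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class MethylationMatrix:
    """Samples x probes methylation matrix.

    ``values`` holds beta values in [0, 1] while ``stage`` is ``"raw"`` or
    ``"winsorized"`` and unit-free z-scores once ``stage == "standardized"``.
    Stage transitions are one-way: raw -> winsorized -> standardized.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        if self.values.ndim != 2:
            raise ValidationError("methylation values must be a 2-D array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.probe_ids) != p:
            raise ValidationError(f"{len(self.probe_ids)} probe ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")
        if len(set(self.probe_ids)) != p:
            raise ValidationError("probe ids must be unique")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if np.isnan(self.values).any():
            raise ValidationError("methylation matrix must not contain missing values")
        if self.stage in ("raw", "winsorized"):
            self._check_beta_range()

    def _check_beta_range(self) -> None:
        bad = np.argwhere((self.values < 0.0) | (self.values > 1.0))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"sample {self.sample_ids[i]!r}, probe {self.probe_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, keep: Sequence[int]) -> "MethylationMatrix":
        keep = list(keep)
        return replace(
            self,
            values=self.values[:, keep],
            probe_ids=[self.probe_ids[j] for j in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)


@dataclass
class ProbeManifest:
    """Probe genomic coordinates: probe_id, chromosome label, 1-based position.

    Chromosome labels are "1".."22" for autosomes plus "X"/"Y" which are
    flagged non-autosomal. Probes are sortable by (chromosome, position).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["probe_id"] = tab["probe_id"].astype(str)
        tab["chromosome"] = tab["chromosome"].astype(str).str.replace(
            "^chr", "", regex=True
        )
        tab["position"] = tab["position"].astype(int)
        if tab["probe_id"].duplicated().any():
            dup = tab.loc[tab["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id {dup!r} in manifest")
        if (tab["position"] <= 0).any():
            raise ValidationError("manifest positions must be positive (1-based)")
        self.table = tab.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    def is_autosomal(self) -> pd.Series:
        return self.table["chromosome"].isin(AUTOSOMES)

    def sorted_by_position(self) -> "ProbeManifest":
        def _chrom_key(c: pd.Series) -> pd.Series:
            order = {c: i for i, c in enumerate(AUTOSOMES + ("X", "Y"))}
            return c.map(lambda v: order.get(v, len(order)))

        tab = self.table.sort_values(
            by=["chromosome", "position"],
            key=lambda col: _chrom_key(col) if col.name == "chromosome" else col,
            kind="mergesort",
        ).reset_index(drop=True)
        return ProbeManifest(tab)

    def subset(self, probe_ids: Sequence[str]) -> "ProbeManifest":
        ids = set(probe_ids)
        return ProbeManifest(self.table[self.table["probe_id"].isin(ids)])


@dataclass
class SimilarityMatrix:
    """n x n methylation similarity matrix M with unit mean diagonal."""

    values: np.ndarray
    sample_ids: list[str]
    n_features: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("similarity matrix contains non-finite values")

    def validate(self, tol: float = 1e-10, psd_tol: float = 1e-8) -> None:
        """Check symmetry, unit mean diagonal and positive semidefiniteness."""
        if not np.allclose(self.values, self.values.T, atol=tol, rtol=0):
            raise ValidationError("similarity matrix is not symmetric")
        md = float(np.mean(np.diag(self.values)))
        if abs(md - 1.0) > tol:
            raise ValidationError(f"mean diagonal {md} differs from 1")
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        if w.min() < -psd_tol:
            raise ValidationError(
                f"similarity matrix has negative eigenvalue {w.min():.3e}"
            )

    def submatrix(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        return self.values[np.ix_(list(rows), list(cols))]


@dataclass
class AnalysisConfig:
    """Run configuration for the cross-validation pipeline.

    covariate_sets maps a label ("basic", "full", ...) to the list of
    phenotype-table columns used as fixed effects; batch never appears here
    because it always enters as a random intercept.
    """

    outcome: str = "outcome"
    covariate_sets: dict[str, list[str]] = field(
        default_factory=lambda: {"basic": ["sex"]}
    )
    n_splits: int = 100
    train_fraction: float = 0.9
    n_imputations: int = 10
    imputation_iterations: int = 30
    seed: int = 0
    winsorize_k: float = 3.0
    mcb_r: float = 0.3
    mcb_gap: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie strictly in (0, 1)")
        if self.n_splits < 1:
            raise ValidationError("n_splits must be >= 1")
        for label, cols in self.covariate_sets.items():
            if self.outcome in cols:
                raise ValidationError(
                    f"outcome {self.outcome!r} cannot be a covariate in set {label!r}"
                )


@dataclass
class SimulationTruth:
    """Ground-truth variance decomposition of a simulated cohort.

    Fractions refer to the outcome's variance: ``h2_m`` is the share from
    the genome-wide methylation signal, ``var_batch`` and ``var_covariates``
    the batch and covariate shares, ``var_resid`` the residual. They are
    normalized to sum to one at construction.
    """

    h2_m: float
    var_batch: float = 0.0
    var_covariates: float = 0.0
    var_resid: float | None = None
    causal_fraction: float = 0.01
    seed: int = 0
    causal_probes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_m <= 1.0):
            raise ValidationError("h2_m must lie in [0, 1]")
        if self.var_batch < 0 or self.var_covariates < 0:
            raise ValidationError("variance fractions must be non-negative")
        if self.var_resid is None:
            self.var_resid = 1.0 - self.h2_m - self.var_batch - self.var_covariates
        if self.var_resid <= 0:
            raise ValidationError("residual variance fraction must be positive")
        total = self.h2_m + self.var_batch + self.var_covariates + self.var_resid
        self.h2_m /= total
        self.var_batch /= total
        self.var_covariates /= total
        self.var_resid /= total
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValidationError("causal_fraction must lie in (0, 1]")


def validate_pheno(pheno: pd.DataFrame, outcome: str | None = None) -> None:
    """Validate the phenotype-table convention.

    Requires a unique ``sample_id`` column and a ``batch`` column with at
    least one level; missing values are allowed elsewhere (they are handled
    by multiple imputation downstream).
    """
    for col in ("sample_id", "batch"):
        if col not in pheno.columns:
            raise ValidationError(f"phenotype table missing {col!r} column")
    if pheno["sample_id"].duplicated().any():
        raise ValidationError("phenotype sample ids must be unique")
    if pheno["batch"].dropna().nunique() < 1:
        raise ValidationError("batch must have at least one level")
    if outcome is not None and outcome not in pheno.columns:
        raise ValidationError(f"outcome column {outcome!r} not in phenotype table")
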