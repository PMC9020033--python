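"""Chained-equations multiple imputation for the phenotype table.

A deliberately compact chained-equations implementation (not a port of any
existing framework): variables with missing cells are visited in order of
increasing missingness and cycled ``iterations`` times per imputation.
Continuous variables are imputed by linear regression followed by a
predictive-mean-matching draw (5 donors), binary variables by a logistic
draw, and multi-level categoricals by a multinomial draw. Predictors are
the remaining covariate and outcome variables — never the methylation
matrix. Cell-type proportion columns (``cell_*``) are renormalized after
completion so each imputed row's composition sums to the typical observed
total.

Observed cells are never altered, so the m completed tables agree with the
input (and each other) everywhere the input was observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datatypes import ValidationError, validate_pheno

logger = logging.getLogger(__name__)

__all__ = ["ImputedSet", "chained_impute"]

_N_DONORS = 5  # predictive-mean-matching donor pool


@dataclass
class ImputedSet:
    """m completed phenotype tables plus a record of how each was produced."""

    tables: list[pd.DataFrame]
    methods: dict[str, str]
    iterations: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.tables)

    def log(self) -> dict:
        return {
            "m": self.m,
            "iterations": self.iterations,
            "seed": self.seed,
            "methods": self.methods,
        }


def _variable_kind(col: pd.Series) -> str:
    obs = col.dropna()
    if pd.api.types.is_numeric_dtype(obs):
        return "binary" if obs.nunique() <= 2 else "continuous"
    return "binary" if obs.nunique() <= 2 else "categorical"


def _encode_predictors(
    pheno: pd.DataFrame, exclude: str, columns: list[str]
) -> np.ndarray:
    """Dummy-encode every current (completed) variable except the target."""
    parts = [np.ones((len(pheno), 1))]
    for c in columns:
        if c == exclude:
            continue
        col = pheno[c]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            sd = v.std()
            parts.append(((v - v.mean()) / sd if sd > 0 else v * 0.0)[:, None])
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            if dummies.shape[1]:
                parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def _impute_continuous(
    X: np.ndarray, y: np.ndarray, obs: np.ndarray, mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    pred_obs = X[obs] @ coef
    pred_mis = X[mis] @ coef
    y_obs = y[obs]
    out = np.empty(mis.sum())
    k = min(_N_DONORS, y_obs.size)
    for i, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm))[:k]
        out[i] = y_obs[rng.choice(donors)]
    return out


def _impute_discrete(
    X: np.ndarray, y: pd.Series, obs: np.ndarray, mis: np.ndarray,
    rng: np.random.Generator,
):
    y_obs = y[obs].to_numpy()
    if pd.api.types.is_numeric_dtype(y):
        y_obs = y_obs.astype(float)
    levels, codes = np.unique(y_obs, return_inverse=True)
    if levels.size == 1:
        return np.repeat(levels[0], mis.sum())
    clf = LogisticRegression(max_iter=500)
    clf.fit(X[obs], codes)
    proba = clf.predict_proba(X[mis])
    draws = np.array([rng.choice(proba.shape[1], p=p) for p in proba])
    return levels[draws]


def chained_impute(
    pheno: pd.DataFrame, m: int = 10, iterations: int = 30, seed: int = 0
) -> ImputedSet:
    """Produce m completed phenotype tables by chained equations."""
    validate_pheno(pheno)
    if m < 2:
        raise ValidationError("m >= 2 imputations required for Rubin pooling")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")

    variables = [c for c in pheno.columns if c != "sample_id"]
    for c in variables:
        if pheno[c].notna().sum() == 0:
            raise ValidationError(f"variable {c!r} has no observed values")

    miss_cols = [c for c in variables if pheno[c].isna().any()]
    # visit order: increasing missingness
    miss_cols.sort(key=lambda c: pheno[c].isna().sum())
    kinds = {c: _variable_kind(pheno[c]) for c in miss_cols}
    methods = {
        c: {"continuous": "pmm", "binary": "logistic", "categorical": "multinomial"}[
            kinds[c]
        ]
        for c in miss_cols
    }

    master = np.random.SeedSequence(seed)
    tables: list[pd.DataFrame] = []
    for sub in master.spawn(m):
        rng = np.random.default_rng(sub)
        tab = pheno.copy()
        # initialization: random draws from the observed marginals
        for c in miss_cols:
            mis = tab[c].isna()
            donors = tab.loc[~mis, c].to_numpy()
            tab.loc[mis, c] = rng.choice(donors, size=int(mis.sum()))
        if not miss_cols:
            tables.append(tab)
            continue
        masks = {c: pheno[c].isna().to_numpy() for c in miss_cols}
        n_iter = iterations if miss_cols else 0
        for _ in range(n_iter):
            for c in miss_cols:
                mis = masks[c]
                obs = ~mis
                X = _encode_predictors(tab, c, variables)
                if kinds[c] == "continuous":
                    y = tab[c].to_numpy(dtype=float)
                    tab.loc[mis, c] = _impute_continuous(X, y, obs, mis, rng)
                else:
                    tab.loc[mis, c] = _impute_discrete(X, tab[c], obs, mis, rng)
        _renormalize_cells(tab, pheno)
        tables.append(tab)

    return ImputedSet(tables=tables, methods=methods, iterations=iterations, seed=seed)


def _renormalize_cells(tab: pd.DataFrame, original: pd.DataFrame) -> None:
    """Rescale cell-proportion columns of imputed rows to the typical
    observed row total (compositional consistency)."""
    cell_cols = [c for c in tab.columns if c.startswith("cell_")]
    if not cell_cols:
        return
    complete = original[cell_cols].dropna()
    target = float(complete.sum(axis=1).mean()) if len(complete) else 1.0
    miss = original[cell_cols].isna().to_numpy()
    imputed_rows = np.flatnonzero(miss.any(axis=1))
    if imputed_rows.size == 0:
        return
    # rescale only the imputed cells of a row so its composition sums to the
    # target; observed cells are never altered
    vals = tab[cell_cols].to_numpy(dtype=float)
    for i in imputed_rows:
        row_miss = miss[i]
        observed_sum = vals[i, ~row_miss].sum()
        imputed_sum = vals[i, row_miss].sum()
        remainder = target - observed_sum
        if imputed_sum > 0 and remainder > 0:
            vals[i, row_miss] *= remainder / imputed_sum
    tab[cell_cols] = vals
    logger.info("renormalized cell proportions on %d imputed rows", imputed_rows.size)
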