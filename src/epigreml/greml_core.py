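"""Linear mixed model with a dense methylation similarity random effect.

The model for n training samples is

    y = W beta + g + b + e,
    g ~ N(0, sigma2_m * M),  b ~ N(0, sigma2_batch * Z Z'),  e ~ N(0, sigma2_e * I),

where W is the fixed-effects design (intercept + encoded covariates), M the
methylation similarity matrix and Z the batch indicator matrix, so that

    V = sigma2_m * M + sigma2_batch * Z Z' + sigma2_e * I.

Variance components are estimated by restricted maximum likelihood using
average-information (AI) updates with an EM fallback when an AI step leaves
the feasible region, and non-negativity enforced by clamping at zero
(boundary solutions are allowed and flagged). Out-of-sample predictions use
the BLUP of the methylation random effect,

    g_test = sigma2_m * M_cross V^-1 (y - W beta),

plus the batch BLUP for test samples whose batch level occurred in training.

Internally all solves are done in the eigenbasis of M, where
sigma2_m * D + sigma2_e * I is diagonal and the batch term is handled by a
rank-B Woodbury identity; this makes each REML iteration O(n^2) after a
one-off eigendecomposition.

The module exposes both a statsmodels-style surface — :class:`MethylationGREML`
with ``fit()`` returning :class:`GREMLResults` — and plain functions
(:func:`reml_loglik`, :func:`reml_fit`, :func:`blup_predict`,
:func:`model_r2`) over an explicit :class:`MixedModelSpec`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import SimilarityMatrix, ValidationError

__all__ = [
    "MixedModelSpec",
    "MethylationGREML",
    "GREMLResults",
    "build_design",
    "reml_loglik",
    "reml_fit",
    "blup_predict",
    "model_r2",
]

_ZERO_TOL = 1e-10  # relative floor below which a component is treated as 0


@dataclass
class MixedModelSpec:
    """Data for one mixed-model fit.

    ``M`` may be None (baseline covariates-only model with a batch random
    intercept) and ``batch`` may be None (no batch effect); at least the
    residual component is always present.
    """

    y: np.ndarray
    W: np.ndarray
    M: np.ndarray | None = None
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        n = self.y.size
        if self.W.shape[0] != n:
            raise ValidationError(
                f"design has {self.W.shape[0]} rows for {n} outcomes"
            )
        if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
            raise ValidationError("fixed-effects design is rank deficient")
        if self.M is not None:
            self.M = np.asarray(self.M, dtype=float)
            if self.M.shape != (n, n):
                raise ValidationError(
                    f"similarity matrix shape {self.M.shape} does not match n={n}"
                )
            if not np.allclose(self.M, self.M.T, atol=1e-8, rtol=0):
                raise ValidationError("similarity matrix is not symmetric")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.size != n:
                raise ValidationError("batch vector length does not match n")
            if pd.unique(self.batch).size < 2:
                # a single level is indistinguishable from the intercept
                self.batch = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def components(self) -> list[str]:
        out = []
        if self.M is not None:
            out.append("m")
        if self.batch is not None:
            out.append("batch")
        out.append("e")
        return out


class _Workspace:
    """Rotated representation of a spec for fast repeated REML evaluations."""

    def __init__(self, spec: MixedModelSpec):
        self.spec = spec
        n = spec.n
        if spec.M is not None:
            # eigenbasis of M; negative eigenvalues from round-off are clipped
            D, U = np.linalg.eigh((spec.M + spec.M.T) / 2.0)
            self.D = np.clip(D, 0.0, None)
            self.U = U
            self.y = U.T @ spec.y
            self.W = U.T @ spec.W
        else:
            self.D = np.zeros(n)
            self.U = None
            self.y = spec.y.copy()
            self.W = spec.W.copy()
        if spec.batch is not None:
            self.levels, codes = np.unique(spec.batch, return_inverse=True)
            Z = np.zeros((n, self.levels.size))
            Z[np.arange(n), codes] = 1.0
            self.Z_orig = Z
            self.Z = self.U.T @ Z if self.U is not None else Z
        else:
            self.levels = np.array([])
            self.Z_orig = np.zeros((n, 0))
            self.Z = np.zeros((n, 0))

    # -- V^-1 machinery ----------------------------------------------------
    def _factor(self, s2m: float, s2b: float, s2e: float):
        a = s2m * self.D + s2e
        if np.any(a <= 0):
            raise ValidationError(
                "covariance matrix numerically singular "
                "(residual component collapsed)"
            )
        if s2b > 0 and self.Z.shape[1]:
            G = self.Z / a[:, None]  # A^-1 Z
            C = np.eye(self.Z.shape[1]) / s2b + self.Z.T @ G
            C_chol = np.linalg.cholesky(C)
            logdet = (
                float(np.sum(np.log(a)))
                + 2.0 * float(np.sum(np.log(np.diag(C_chol))))
                + self.Z.shape[1] * np.log(s2b)
            )
            return a, G, C_chol, logdet
        return a, None, None, float(np.sum(np.log(a)))

    @staticmethod
    def _vinv(mat: np.ndarray, a, G, C_chol) -> np.ndarray:
        out = mat / a[:, None] if mat.ndim == 2 else mat / a
        if G is not None:
            Gt = G.T @ mat
            sol = np.linalg.solve(
                C_chol.T, np.linalg.solve(C_chol, Gt)
            )
            out = out - G @ sol
        return out

    def core(self, params: Sequence[float]):
        """GLS quantities at the given (sigma2_m, sigma2_batch, sigma2_e)."""
        s2m, s2b, s2e = params
        a, G, C_chol, logdetV = self._factor(s2m, s2b, s2e)
        VinvW = self._vinv(self.W, a, G, C_chol)
        B = self.W.T @ VinvW
        sign, logdetB = np.linalg.slogdet(B)
        if sign <= 0:
            raise ValidationError("W' V^-1 W is singular")
        beta = np.linalg.solve(B, VinvW.T @ self.y)
        r = self.y - self.W @ beta
        Py = self._vinv(r, a, G, C_chol)
        quad = float(r @ Py)
        loglik = -0.5 * (logdetV + logdetB + quad)
        return {
            "a": a,
            "G": G,
            "C_chol": C_chol,
            "VinvW": VinvW,
            "B": B,
            "beta": beta,
            "Py": Py,
            "loglik": loglik,
        }

    # -- score and AI matrix ----------------------------------------------
    def _K_dot(self, comp: str, v: np.ndarray) -> np.ndarray:
        if comp == "m":
            return self.D * v
        if comp == "e":
            return v
        return self.Z @ (self.Z.T @ v)

    def _trace_vinv_K(self, comp: str, a, G, C_chol) -> float:
        if comp in ("m", "e"):
            d = self.D if comp == "m" else np.ones_like(a)
            t = float(np.sum(d / a))
            if G is not None:
                S = G.T @ (d[:, None] * G)
                Cinv_S = np.linalg.solve(
                    C_chol.T, np.linalg.solve(C_chol, S)
                )
                t -= float(np.trace(Cinv_S))
            return t
        VinvZ = self._vinv(self.Z, a, G, C_chol)
        return float(np.sum(self.Z * VinvZ))

    def score_ai(self, params: Sequence[float], free: list[str]):
        """REML score vector and average-information matrix for free components."""
        s2m, s2b, s2e = params
        c = self.core(params)
        a, G, C_chol = c["a"], c["G"], c["C_chol"]
        VinvW, B, Py = c["VinvW"], c["B"], c["Py"]
        Binv = np.linalg.inv(B)

        score = np.zeros(len(free))
        t_vecs = []
        for i, comp in enumerate(free):
            tr_vinv = self._trace_vinv_K(comp, a, G, C_chol)
            if comp in ("m", "e"):
                d = self.D if comp == "m" else np.ones_like(a)
                WKW = VinvW.T @ (d[:, None] * VinvW)
            else:
                ZtVW = self.Z.T @ VinvW
                WKW = ZtVW.T @ ZtVW
            tr_P = tr_vinv - float(np.sum(Binv * WKW))
            KPy = self._K_dot(comp, Py)
            quad = float(Py @ KPy)
            score[i] = -0.5 * (tr_P - quad)
            t_vecs.append(KPy)

        # P t = V^-1 t - V^-1 W B^-1 W' V^-1 t
        AI = np.zeros((len(free), len(free)))
        Pt = []
        for t in t_vecs:
            Vt = self._vinv(t, a, G, C_chol)
            Pt.append(Vt - VinvW @ (Binv @ (VinvW.T @ t)))
        for i in range(len(free)):
            for j in range(i, len(free)):
                AI[i, j] = AI[j, i] = 0.5 * float(t_vecs[i] @ Pt[j])
        return c, score, AI


def _params_tuple(theta: dict[str, float]) -> tuple[float, float, float]:
    return (theta.get("m", 0.0), theta.get("batch", 0.0), theta.get("e", 0.0))


def reml_loglik(
    spec: MixedModelSpec, params: Sequence[float], workspace: _Workspace | None = None
) -> float:
    """Restricted log-likelihood (up to an additive constant).

    ``params`` is (sigma2_m, sigma2_batch, sigma2_e); a component absent
    from the spec must be passed as 0.
    """
    s2m, s2b, s2e = params
    if s2e <= 0:
        raise ValidationError("sigma2_e must be positive")
    if s2m < 0 or s2b < 0:
        raise ValidationError("variance components must be non-negative")
    if s2m > 0 and spec.M is None:
        raise ValidationError("sigma2_m > 0 but the spec has no similarity matrix")
    if s2b > 0 and spec.batch is None:
        s2b = 0.0
    ws = workspace or _Workspace(spec)
    return ws.core((s2m, s2b, s2e))["loglik"]


@dataclass
class GREMLResults:
    """REML fit of the methylation mixed model (the MixedModelFit record).

    Carries the variance components, fixed effects, restricted
    log-likelihood and convergence diagnostics, plus enough state to
    produce BLUP predictions for new samples.
    """

    sigma2_m: float
    sigma2_batch: float
    sigma2_e: float
    fe_params: np.ndarray
    reml_loglik: float
    converged: bool
    n_iter: int
    on_boundary: list[str] = field(default_factory=list)
    fe_names: list[str] | None = None
    _workspace: _Workspace | None = field(default=None, repr=False)

    @property
    def beta_hat(self) -> np.ndarray:
        return self.fe_params

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "sigma2_m": self.sigma2_m,
            "sigma2_batch": self.sigma2_batch,
            "sigma2_e": self.sigma2_e,
        }

    @property
    def variance_share(self) -> float:
        """sigma2_m as a share of the total modelled variance."""
        total = self.sigma2_m + self.sigma2_batch + self.sigma2_e
        return self.sigma2_m / total if total > 0 else 0.0

    def predict(
        self,
        M_cross: np.ndarray | None = None,
        W_new: np.ndarray | None = None,
        batch_new: np.ndarray | None = None,
        include_batch_blup: bool = True,
    ) -> np.ndarray:
        spec = self._workspace.spec
        return blup_predict(
            self,
            spec,
            M_cross=M_cross,
            W_test=W_new,
            batch_test=batch_new,
            include_batch_blup=include_batch_blup,
        )

    def to_dict(self) -> dict:
        return {
            "sigma2_m": self.sigma2_m,
            "sigma2_batch": self.sigma2_batch,
            "sigma2_e": self.sigma2_e,
            "variance_share": self.variance_share,
            "fe_params": self.fe_params.tolist(),
            "fe_names": self.fe_names,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "on_boundary": self.on_boundary,
        }

    def summary(self) -> str:
        lines = [
            "Methylation GREML (REML) results",
            "=" * 44,
            f"{'converged':<26}{self.converged}",
            f"{'iterations':<26}{self.n_iter}",
            f"{'restricted log-lik':<26}{self.reml_loglik:.4f}",
            "-" * 44,
            f"{'sigma2_m (methylation)':<26}{self.sigma2_m:.6f}",
            f"{'sigma2_batch':<26}{self.sigma2_batch:.6f}",
            f"{'sigma2_e (residual)':<26}{self.sigma2_e:.6f}",
            f"{'variance share (m)':<26}{self.variance_share:.4f}",
            "-" * 44,
        ]
        names = self.fe_names or [f"x{i}" for i in range(self.fe_params.size)]
        for name, b in zip(names, self.fe_params):
            lines.append(f"{name:<26}{b: .6f}")
        if self.on_boundary:
            lines.append("boundary components: " + ", ".join(self.on_boundary))
        return "\n".join(lines)


class MethylationGREML:
    """Mixed model regressing an outcome on covariates with a methylation
    similarity random effect and a batch random intercept.

    Parameters
    ----------
    endog : outcome vector (n,)
    exog : fixed-effects design (n, q), including the intercept
    similarity : n x n methylation similarity matrix M, or None for the
        covariates-only baseline model
    batch : length-n batch labels, or None
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        similarity: np.ndarray | SimilarityMatrix | None = None,
        batch: np.ndarray | None = None,
        exog_names: list[str] | None = None,
    ):
        if isinstance(similarity, SimilarityMatrix):
            similarity = similarity.values
        self.spec = MixedModelSpec(y=endog, W=exog, M=similarity, batch=batch)
        self.exog_names = exog_names
        self._workspace: _Workspace | None = None

    @classmethod
    def from_dataframe(
        cls,
        pheno: pd.DataFrame,
        outcome: str,
        covariates: Sequence[str],
        similarity: np.ndarray | SimilarityMatrix | None = None,
        batch_col: str = "batch",
    ) -> "MethylationGREML":
        """Build the model from a phenotype table, dummy-encoding covariates."""
        y = pheno[outcome].to_numpy(dtype=float)
        W, names = build_design(pheno, covariates)
        batch = pheno[batch_col].to_numpy() if batch_col in pheno else None
        return cls(y, W, similarity=similarity, batch=batch, exog_names=names)

    @property
    def workspace(self) -> _Workspace:
        if self._workspace is None:
            self._workspace = _Workspace(self.spec)
        return self._workspace

    def loglike(self, params: Sequence[float]) -> float:
        return reml_loglik(self.spec, params, workspace=self.workspace)

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        start: Sequence[float] | None = None,
    ) -> GREMLResults:
        """Maximize the restricted likelihood by AI-REML with EM fallback."""
        spec = self.spec
        if spec.n <= spec.q + 2:
            raise ValidationError(
                f"n={spec.n} too small for q={spec.q} fixed effects"
            )
        ws = self.workspace
        comps = spec.components
        vary = float(np.var(spec.y, ddof=1))
        if vary <= 0:
            raise ValidationError("outcome has zero variance")

        if start is None:
            theta = {c: vary / len(comps) for c in comps}
        else:
            s2m, s2b, s2e = start
            theta = {"e": float(s2e)}
            if "m" in comps:
                theta["m"] = float(s2m)
            if "batch" in comps:
                theta["batch"] = float(s2b)
        floor = _ZERO_TOL * vary
        theta["e"] = max(theta["e"], floor * 10)

        fixed_zero: set[str] = set()
        loglik_prev = -np.inf
        converged = False
        n_iter = 0
        core = None

        for n_iter in range(1, max_iter + 1):
            free = [c for c in comps if c not in fixed_zero]
            params = _params_tuple(theta)
            core, score, AI = ws.score_ai(params, free)
            loglik = core["loglik"]

            # allow a clamped component back in if its gradient is positive
            released = False
            for c in sorted(fixed_zero):
                _, s_all, _ = ws.score_ai(params, [c])
                if s_all[0] > 0:
                    fixed_zero.discard(c)
                    theta[c] = floor * 100
                    released = True
            if released:
                continue

            if n_iter > 1 and abs(loglik - loglik_prev) < tol * (1 + abs(loglik_prev)):
                converged = True
                break
            loglik_prev = loglik

            new_theta = self._ai_step(ws, theta, free, score, AI, loglik, vary)
            if new_theta is None:  # EM fallback
                n = spec.n
                new_theta = dict(theta)
                Py = core["Py"]
                for i, c in enumerate(free):
                    a, G, C_chol = core["a"], core["G"], core["C_chol"]
                    tr_vinv = ws._trace_vinv_K(c, a, G, C_chol)
                    KPy = ws._K_dot(c, Py)
                    quad = float(Py @ KPy)
                    # EM: theta += theta^2 (y'PKPy - tr(PK)) / n, tr(PK)~tr(V^-1 K)
                    new_theta[c] = max(
                        theta[c] + theta[c] ** 2 * (quad - tr_vinv) / n, 0.0
                    )
            theta = new_theta
            # clamp vanishing components to the boundary
            for c in list(theta):
                if c != "e" and theta[c] < floor:
                    theta[c] = 0.0
                    fixed_zero.add(c)
            theta["e"] = max(theta["e"], floor * 10)

        if not converged:
            warnings.warn(
                f"REML did not converge in {max_iter} iterations", RuntimeWarning
            )
        params = _params_tuple(theta)
        core = ws.core(params)
        if "m" in comps and "m" not in fixed_zero:
            _, _, AI_full = ws.score_ai(
                params, [c for c in comps if c not in fixed_zero]
            )
            if np.linalg.cond(AI_full) > 1e10:
                warnings.warn(
                    "variance components weakly identified "
                    "(near-flat restricted likelihood)",
                    RuntimeWarning,
                )
        beta = core["beta"]
        return GREMLResults(
            sigma2_m=theta.get("m", 0.0),
            sigma2_batch=theta.get("batch", 0.0),
            sigma2_e=theta["e"],
            fe_params=np.asarray(beta),
            reml_loglik=core["loglik"],
            converged=converged,
            n_iter=n_iter,
            on_boundary=sorted(fixed_zero),
            fe_names=self.exog_names,
            _workspace=ws,
        )

    @staticmethod
    def _ai_step(ws, theta, free, score, AI, loglik, vary):
        """One AI update with step-halving; None signals the EM fallback."""
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(len(free)), score)
        except np.linalg.LinAlgError:
            return None
        step = 1.0
        for _ in range(8):
            proposal = dict(theta)
            ok = True
            for i, c in enumerate(free):
                v = theta[c] + step * delta[i]
                if c == "e" and v <= _ZERO_TOL * vary:
                    ok = False
                    break
                proposal[c] = max(v, 0.0)
            if ok:
                try:
                    ll_new = ws.core(_params_tuple(proposal))["loglik"]
                except ValidationError:
                    ll_new = -np.inf
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-10:
                    return proposal
            step /= 2.0
        return None


def reml_fit(
    spec: MixedModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
    start: Sequence[float] | None = None,
) -> GREMLResults:
    """Fit the mixed model by REML (functional wrapper over MethylationGREML)."""
    model = MethylationGREML(
        spec.y, spec.W, similarity=spec.M, batch=spec.batch
    )
    return model.fit(tol=tol, max_iter=max_iter, start=start)


def blup_predict(
    fit: GREMLResults,
    spec: MixedModelSpec,
    M_cross: np.ndarray | None,
    W_test: np.ndarray,
    batch_test: np.ndarray | None = None,
    include_batch_blup: bool = True,
) -> np.ndarray:
    """BLUP-based outcome predictions for held-out samples.

    g_test = sigma2_m * M_cross V^-1 (y - W beta); the batch BLUP is added
    for test samples whose batch level occurred in training (unseen levels
    contribute 0).
    """
    W_test = np.atleast_2d(np.asarray(W_test, dtype=float))
    if W_test.shape[1] != spec.q:
        raise ValidationError(
            f"test design has {W_test.shape[1]} columns, expected {spec.q}"
        )
    ws = fit._workspace or _Workspace(spec)
    params = (fit.sigma2_m, fit.sigma2_batch, fit.sigma2_e)
    core = ws.core(params)
    Py_rot = core["Py"]
    # back to the original basis for the cross-similarity product
    Vinv_r = ws.U @ Py_rot if ws.U is not None else Py_rot

    pred = W_test @ fit.fe_params
    if fit.sigma2_m > 0 and M_cross is not None:
        M_cross = np.atleast_2d(np.asarray(M_cross, dtype=float))
        if M_cross.shape != (W_test.shape[0], spec.n):
            raise ValidationError(
                f"M_cross shape {M_cross.shape} does not match "
                f"(n_test={W_test.shape[0]}, n_train={spec.n})"
            )
        pred = pred + fit.sigma2_m * (M_cross @ Vinv_r)
    if (
        include_batch_blup
        and fit.sigma2_batch > 0
        and batch_test is not None
        and ws.Z_orig.shape[1]
    ):
        u = fit.sigma2_batch * (ws.Z_orig.T @ Vinv_r)
        level_idx = {lev: k for k, lev in enumerate(ws.levels)}
        add = np.array(
            [u[level_idx[b]] if b in level_idx else 0.0 for b in np.asarray(batch_test)]
        )
        pred = pred + add
    return pred


def model_r2(predictions: np.ndarray, observed: np.ndarray) -> float:
    """Out-of-sample R^2 as the squared Pearson correlation.

    Sign-blind by construction; constant predictions give 0 with a warning.
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predictions.size != observed.size:
        raise ValidationError("predictions and observed differ in length")
    if predictions.size < 3:
        raise ValidationError("R^2 needs at least 3 test samples")
    if np.std(predictions) == 0 or np.std(observed) == 0:
        warnings.warn("constant predictions or outcome; R^2 set to 0", RuntimeWarning)
        return 0.0
    r = float(np.corrcoef(predictions, observed)[0, 1])
    return r * r


def build_design(
    pheno: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Encode covariates into a fixed-effects design with an intercept.

    Numeric columns enter as-is; categorical/object/boolean columns are
    dummy-encoded dropping the first (reference) level. Compositional
    covariates such as cell-type proportions must be passed with one
    component already omitted by the caller.
    """
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in pheno.columns:
            raise ValidationError(f"covariate {cov!r} not in phenotype table")
        col = pheno[cov]
        if col.isna().any():
            raise ValidationError(
                f"covariate {cov!r} has missing values; run imputation first"
            )
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
    return np.column_stack(cols), names
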