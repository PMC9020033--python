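"""Synthetic birth-cohort generator with known ground truth.

Generates cohorts with the statistical structure the GREML analysis
assumes: block-correlated beta values along chromosomes (latent per-probe
normals with AR(1) within-block correlation, mapped through a logistic link
into (0, 1)), a poly-epigenetic outcome signal built from a configurable
fraction of causal probes, a batch random effect, covariate effects with a
Table-1-like covariate distribution (sex, maternal age, smoking, education,
cord-blood cell-type proportions), and missing-completely-at-random (or
optionally MAR) covariate/outcome entries. Methylation itself is always
complete.

Each variance component of the outcome is empirically standardized before
scaling, so the generated decomposition matches the requested fractions up
to the (small) sample correlations between components. The true per-sample
components are kept on the returned :class:`Cohort` for test oracles.

Randomness is organised as independent sub-streams (methylation,
covariates, outcome, missingness, per cohort) spawned from one master seed,
so identical configurations reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .datatypes import (
    MethylationMatrix,
    ProbeManifest,
    SimulationTruth,
    ValidationError,
)

__all__ = ["Cohort", "simulate_cohort", "simulate_two_cohorts", "write_cohort"]

# cord-blood cell-type mean proportions (CD8 T, NK, CD4 T, B, granulocytes,
# monocytes, nucleated RBC), loosely matching published cord-blood estimates
_CELL_TYPES = ("cd8t", "nk", "cd4t", "bcell", "gran", "mono", "nrbc")
_CELL_MEANS = np.array([0.06, 0.08, 0.09, 0.06, 0.51, 0.08, 0.12])
_CELL_CONCENTRATION = 60.0  # Dirichlet scale giving per-type SDs of a few percent


@dataclass
class Cohort:
    """One simulated cohort bundle (unpacks like the 4-tuple)."""

    betas: MethylationMatrix
    pheno: pd.DataFrame
    manifest: ProbeManifest
    truth: SimulationTruth
    components: dict[str, np.ndarray] | None = None

    def __iter__(self):
        return iter((self.betas, self.pheno, self.manifest, self.truth))

    def variance_decomposition(self) -> dict[str, float]:
        """Empirical outcome-variance share of each generating component."""
        y = self.components["outcome"]
        total = float(np.var(y))
        return {
            name: float(np.var(vals)) / total
            for name, vals in self.components.items()
            if name != "outcome"
        }


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(
    n: int,
    p: int,
    truth: SimulationTruth,
    block_structure: tuple[int, float] = (10, 0.7),
    missing_rate: float = 0.0,
    n_batches: int = 6,
    n_chromosomes: int = 22,
    within_block_gap: int = 200,
    between_block_gap: int = 5000,
    missing_mechanism: str = "mcar",
    sample_prefix: str = "S",
    seed: int | None = None,
) -> Cohort:
    """Simulate one cohort with the given ground-truth decomposition.

    ``block_structure`` is (block size, within-block AR(1) correlation);
    probes are laid out on ``n_chromosomes`` autosomes with small gaps
    inside blocks and large gaps between blocks, so co-methylation block
    recovery can be tested against the layout.
    """
    if n < 2 or p < 1:
        raise ValidationError("need n >= 2 samples and p >= 1 probes")
    if not (0.0 <= missing_rate < 1.0):
        raise ValidationError("missing_rate must lie in [0, 1)")
    block_size, rho = block_structure
    if block_size > p:
        raise ValidationError(f"block size {block_size} exceeds p={p}")
    if not (0.0 <= rho < 1.0):
        raise ValidationError("within-block correlation must lie in [0, 1)")
    if missing_mechanism not in ("mcar", "mar"):
        raise ValidationError("missing_mechanism must be 'mcar' or 'mar'")

    master = np.random.SeedSequence(truth.seed if seed is None else seed)
    rng_meth, rng_cov, rng_out, rng_miss = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    manifest = _make_manifest(
        p, block_size, n_chromosomes, within_block_gap, between_block_gap
    )
    probe_ids = manifest.probe_ids

    # latent AR(1)-in-blocks normals -> logistic link -> betas in (0, 1)
    latent = np.empty((n, p))
    for start in range(0, p, block_size):
        width = min(block_size, p - start)
        eps = rng_meth.standard_normal((n, width))
        z = np.empty((n, width))
        z[:, 0] = eps[:, 0]
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * eps[:, j]
        latent[:, start : start + width] = z
    mu = rng_meth.uniform(-1.5, 1.5, size=p)
    scale = rng_meth.uniform(0.5, 1.5, size=p)
    betas_vals = 1.0 / (1.0 + np.exp(-(mu + scale * latent)))

    sample_ids = [f"{sample_prefix}{i:05d}" for i in range(n)]
    betas = MethylationMatrix(
        values=betas_vals, sample_ids=sample_ids, probe_ids=probe_ids, stage="raw"
    )

    # poly-epigenetic causal score over a random subset of probes
    n_causal = max(1, int(round(truth.causal_fraction * p)))
    causal_idx = np.sort(rng_out.choice(p, size=n_causal, replace=False))
    effects = rng_out.standard_normal(n_causal)
    X_std = (betas_vals - betas_vals.mean(axis=0)) / np.where(
        betas_vals.std(axis=0) > 0, betas_vals.std(axis=0), 1.0
    )
    raw_score = X_std[:, causal_idx] @ effects
    g = np.sqrt(truth.h2_m) * _standardized(raw_score)

    # batch random intercept
    batch_codes = rng_cov.integers(0, n_batches, size=n)
    batch_levels_eff = rng_cov.standard_normal(n_batches)
    batch_eff = np.sqrt(truth.var_batch) * _standardized(batch_levels_eff[batch_codes])

    # covariates with realistic marginals and collinearity
    pheno = pd.DataFrame({"sample_id": sample_ids})
    pheno["sex"] = rng_cov.binomial(1, 0.5, size=n)
    pheno["maternal_age"] = rng_cov.normal(30.0, 4.3, size=n)
    pheno["smoking"] = rng_cov.binomial(1, 0.13, size=n)
    pheno["education"] = rng_cov.choice(
        ["primary", "secondary", "higher"], size=n, p=[0.05, 0.35, 0.60]
    )
    cells = rng_cov.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)
    for k, name in enumerate(_CELL_TYPES):
        pheno[f"cell_{name}"] = cells[:, k]
    pheno["batch"] = [f"batch{b}" for b in batch_codes]

    cov_design = np.column_stack(
        [
            _standardized(pheno["sex"].to_numpy(float)),
            _standardized(pheno["maternal_age"].to_numpy(float)),
            _standardized(pheno["smoking"].to_numpy(float)),
            _standardized((pheno["education"] == "higher").to_numpy(float)),
            _standardized(cells[:, 0]),
            _standardized(cells[:, 4]),
        ]
    )
    cov_weights = rng_out.standard_normal(cov_design.shape[1])
    cov_eff = np.sqrt(truth.var_covariates) * _standardized(cov_design @ cov_weights)

    resid = np.sqrt(truth.var_resid) * _standardized(rng_out.standard_normal(n))
    y = g + batch_eff + cov_eff + resid
    pheno["outcome"] = y

    # record the realised causal architecture on the truth object
    truth_out = replace(
        truth,
        causal_probes={probe_ids[j]: float(b) for j, b in zip(causal_idx, effects)},
    )

    components = {
        "outcome": y.copy(),
        "methylation": g,
        "batch": batch_eff,
        "covariates": cov_eff,
        "residual": resid,
    }

    if missing_rate > 0:
        _apply_missingness(pheno, missing_rate, missing_mechanism, rng_miss)

    return Cohort(
        betas=betas,
        pheno=pheno,
        manifest=manifest,
        truth=truth_out,
        components=components,
    )


def _make_manifest(
    p: int,
    block_size: int,
    n_chromosomes: int,
    within_gap: int,
    between_gap: int,
) -> ProbeManifest:
    n_chromosomes = min(n_chromosomes, 22)
    per_chrom = int(np.ceil(p / n_chromosomes))
    rows = []
    j = 0
    for c in range(1, n_chromosomes + 1):
        pos = 1000
        for k in range(per_chrom):
            if j >= p:
                break
            rows.append((f"cg{j:07d}", str(c), pos))
            j += 1
            pos += between_gap if (k + 1) % block_size == 0 else within_gap
    return ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])
    )


def _apply_missingness(
    pheno: pd.DataFrame,
    rate: float,
    mechanism: str,
    rng: np.random.Generator,
) -> None:
    """Blank covariate/outcome cells in place; batch, sample_id and (for MAR)
    maternal age stay observed."""
    n = len(pheno)
    targets = [
        c for c in pheno.columns if c not in ("sample_id", "batch")
    ]
    if mechanism == "mar":
        targets = [c for c in targets if c != "maternal_age"]
        age = _standardized(pheno["maternal_age"].to_numpy(float))
        # logistic dependence on an always-observed covariate, mean rate kept
        base = np.log(rate / (1 - rate))
        prob = 1.0 / (1.0 + np.exp(-(base + age)))
        prob *= rate / prob.mean()
        prob = np.clip(prob, 0.0, 0.95)
    else:
        prob = np.full(n, rate)
    for col in targets:
        mask = rng.random(n) < prob
        if mask.all():  # keep at least one observed value per variable
            mask[rng.integers(0, n)] = False
        pheno.loc[mask, col] = np.nan


def simulate_two_cohorts(
    truth: SimulationTruth,
    n_per_cohort: tuple[int, int],
    p: int = 500,
    missing_rate: float = 0.0,
    **kwargs,
) -> tuple[Cohort, Cohort]:
    """Two independent cohorts sharing one ground truth.

    Emulates a two-cohort replication design: shared variance decomposition
    and probe layout, independent draws, distinct batch structures and
    disjoint sample ids.
    """
    if min(n_per_cohort) < 2:
        raise ValidationError("both cohorts need n >= 2")
    master = np.random.SeedSequence(truth.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(2)]
    cohort_a = simulate_cohort(
        n_per_cohort[0],
        p,
        truth,
        missing_rate=missing_rate,
        n_batches=kwargs.pop("n_batches_a", 6),
        sample_prefix="A",
        seed=seeds[0],
        **kwargs,
    )
    cohort_b = simulate_cohort(
        n_per_cohort[1],
        p,
        truth,
        missing_rate=missing_rate,
        n_batches=kwargs.pop("n_batches_b", 4),
        sample_prefix="B",
        seed=seeds[1],
        **kwargs,
    )
    return cohort_a, cohort_b


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the formats the readers consume, plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": out / "betas.tsv",
        "manifest": out / "manifest.tsv",
        "pheno": out / "pheno.csv",
        "truth": out / "truth.json",
    }
    io_formats.write_beta_matrix(cohort.betas, paths["betas"])
    io_formats.write_manifest(cohort.manifest, paths["manifest"])
    io_formats.write_pheno(cohort.pheno, paths["pheno"])
    io_formats.write_json(
        {
            "h2_m": cohort.truth.h2_m,
            "var_batch": cohort.truth.var_batch,
            "var_covariates": cohort.truth.var_covariates,
            "var_resid": cohort.truth.var_resid,
            "causal_fraction": cohort.truth.causal_fraction,
            "seed": cohort.truth.seed,
            "causal_probes": cohort.truth.causal_probes,
        },
        paths["truth"],
    )
    return paths
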