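"""Methylation preprocessing: winsorization, autosomal filtering, z-scoring.

Extreme beta values are winsorized per probe with the 3*IQR rule: values
above Q3 + k*IQR (or below Q1 - k*IQR) are replaced by the most extreme
observation still inside the fence — not by the fence itself. Quartiles use
linear interpolation between order statistics. Probes on the sex
chromosomes are removed, and the remaining probes are z-score standardized
(mean 0, sample SD 1 with the n-1 denominator) before the similarity matrix
is computed.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .datatypes import MethylationMatrix, ProbeManifest, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "winsorize_probe",
    "winsorize_matrix",
    "filter_autosomal",
    "standardize",
]


def winsorize_probe(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Winsorize one probe's values with the k*IQR fence rule.

    Out-of-fence values are replaced by the maximum (upper side) or minimum
    (lower side) in-fence observation. A constant vector is returned
    unchanged; a vector with *no* in-fence observation is degenerate and
    raises.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("winsorization needs at least 4 values per probe")
    if k <= 0:
        raise ValidationError("winsorize_k must be positive")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if iqr == 0 and np.ptp(values) == 0:
        return values.copy()
    lo_fence = q1 - k * iqr
    hi_fence = q3 + k * iqr
    in_fence = (values >= lo_fence) & (values <= hi_fence)
    if not in_fence.any():
        raise ValidationError("all values fall outside the winsorization fences")
    out = values.copy()
    out[values > hi_fence] = values[in_fence].max()
    out[values < lo_fence] = values[in_fence].min()
    return out


def winsorize_matrix(matrix: MethylationMatrix, k: float = 3.0) -> MethylationMatrix:
    """Winsorize every probe of a raw beta matrix; stage becomes 'winsorized'."""
    if matrix.stage != "raw":
        raise ValidationError(f"cannot winsorize a {matrix.stage!r}-stage matrix")
    out = np.empty_like(matrix.values)
    n_cells = 0
    for j in range(matrix.n_probes):
        out[:, j] = winsorize_probe(matrix.values[:, j], k=k)
        n_cells += int(np.sum(out[:, j] != matrix.values[:, j]))
    if n_cells:
        logger.info("winsorized %d cells across %d probes", n_cells, matrix.n_probes)
    return replace(matrix, values=out, stage="winsorized")


def filter_autosomal(
    matrix: MethylationMatrix, manifest: ProbeManifest
) -> MethylationMatrix:
    """Keep only probes on chromosomes 1-22, preserving column order."""
    chrom = dict(
        zip(manifest.table["probe_id"], manifest.is_autosomal())
    )
    missing = [p for p in matrix.probe_ids if p not in chrom]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} absent from manifest")
    keep = [j for j, p in enumerate(matrix.probe_ids) if chrom[p]]
    if not keep:
        raise ValidationError("no autosomal probes remain after filtering")
    if len(keep) < matrix.n_probes:
        logger.info(
            "removed %d non-autosomal probes", matrix.n_probes - len(keep)
        )
    return matrix.subset_probes(keep)


def standardize(matrix: MethylationMatrix) -> MethylationMatrix:
    """z-score each probe (mean 0, sample SD 1); constant probes are dropped."""
    if matrix.stage != "winsorized":
        raise ValidationError(
            f"standardize expects a winsorized matrix, got stage {matrix.stage!r}"
        )
    if matrix.n_samples < 2:
        raise ValidationError("standardization needs at least 2 samples")
    sd = matrix.values.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        raise ValidationError("all probes are constant; nothing to standardize")
    if keep.size < matrix.n_probes:
        logger.info("dropped %d constant probes", matrix.n_probes - keep.size)
    vals = matrix.values[:, keep]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    return MethylationMatrix(
        values=z,
        sample_ids=matrix.sample_ids,
        probe_ids=[matrix.probe_ids[j] for j in keep],
        stage="standardized",
    )
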