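"""Methylation similarity matrix M = ZZ' / mean(diag(ZZ')).

Z is the samples x probes matrix of methylation z-scores. Dividing the
cross-product by the mean of its diagonal fixes the average diagonal of M
at exactly 1; no per-pair feature-count normalization is applied. M is the
methylation analogue of the genomic relatedness matrix used in GREML.
"""

from __future__ import annotations

import numpy as np

from .datatypes import MethylationMatrix, SimilarityMatrix, ValidationError

__all__ = ["compute_similarity"]


def compute_similarity(
    Z: MethylationMatrix, block_size: int | None = None
) -> SimilarityMatrix:
    """Compute M from a standardized methylation matrix.

    ``block_size`` switches to a probe-blocked accumulation of ZZ' that
    bounds peak memory for very wide matrices; the result is identical to
    the naive product up to floating-point accumulation order.
    """
    if Z.stage != "standardized":
        raise ValidationError(
            f"similarity expects a standardized matrix, got stage {Z.stage!r}"
        )
    n, p = Z.values.shape
    if p == 0:
        raise ValidationError("no probes available for the similarity matrix")
    if n < 2:
        raise ValidationError("similarity needs at least 2 samples")
    if not np.isfinite(Z.values).all():
        raise ValidationError("non-finite values in standardized matrix")

    if block_size is None or block_size >= p:
        xxt = Z.values @ Z.values.T
    else:
        xxt = np.zeros((n, n))
        for start in range(0, p, block_size):
            chunk = Z.values[:, start : start + block_size]
            xxt += chunk @ chunk.T
    xxt = (xxt + xxt.T) / 2.0  # enforce exact symmetry
    mean_diag = float(np.mean(np.diag(xxt)))
    if mean_diag <= 0:
        raise ValidationError("mean diagonal of ZZ' is not positive")
    return SimilarityMatrix(
        values=xxt / mean_diag, sample_ids=list(Z.sample_ids), n_features=p
    )
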