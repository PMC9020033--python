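"""Methylation-correlated blocks (MCBs).

Neighboring CpG probes are often co-methylated. For the sensitivity
analysis, runs of neighbors with pairwise correlation >= r (default 0.3)
and gaps of at most ``max_gap`` base pairs (default 1000) are aggregated
into blocks; each block is summarized by the per-sample mean beta, and the
blocks are combined with the remaining independent CpGs (r < 0.3) into a
reduced feature set that then flows through standardization and the
similarity matrix as usual.

The scan is greedy and left-to-right within each chromosome: a block is
extended to the next probe iff the Pearson correlation between the block's
last probe and the candidate passes the threshold AND the positional gap is
within ``max_gap``. Blocks never span chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, ProbeManifest, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["BlockAssignment", "find_mcbs", "aggregate_mcbs"]


@dataclass
class BlockAssignment:
    """Partition of probes into multi-probe blocks and independent singletons.

    ``blocks`` holds ordered probe-id groups of size >= 2; ``singletons``
    the independent CpGs. ``positions`` maps each block to its first probe's
    position (the block's representative coordinate).
    """

    blocks: list[list[str]]
    singletons: list[str]
    positions: list[int] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.blocks) + len(self.singletons)

    def covered_probes(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(b)
        out.extend(self.singletons)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Assignment as a (probe_id, block_id) table; singletons get their own id."""
        rows = []
        for k, block in enumerate(self.blocks):
            for pid in block:
                rows.append((pid, f"MCB{k:06d}"))
        for pid in self.singletons:
            rows.append((pid, pid))
        return pd.DataFrame(rows, columns=["probe_id", "block_id"])

    def summary(self) -> dict[str, int]:
        return {
            "n_mcbs": len(self.blocks),
            "n_independent_cpgs": len(self.singletons),
            "n_features": self.n_features,
            "n_probes": len(self.covered_probes()),
        }


def find_mcbs(
    betas: MethylationMatrix,
    manifest: ProbeManifest,
    r_threshold: float = 0.3,
    max_gap: int = 1000,
) -> BlockAssignment:
    """Greedy left-to-right block construction over position-sorted probes."""
    if betas.stage == "standardized":
        raise ValidationError("MCBs are built on (winsorized) betas, not z-scores")
    if betas.n_samples < 3:
        raise ValidationError("correlation needs at least 3 samples")

    man = manifest.subset(betas.probe_ids)
    if len(man.table) != betas.n_probes:
        raise ValidationError("manifest does not cover every probe in the matrix")
    sorted_man = man.sorted_by_position()
    if sorted_man.probe_ids != man.probe_ids:
        logger.info("manifest not position-sorted; sorting internally")
    col = {p: j for j, p in enumerate(betas.probe_ids)}

    blocks: list[list[str]] = []
    singletons: list[str] = []
    positions: list[int] = []

    for _, chrom_tab in sorted_man.table.groupby("chromosome", sort=False):
        pids = chrom_tab["probe_id"].tolist()
        pos = chrom_tab["position"].tolist()
        current = [pids[0]]
        start_pos = pos[0]
        for i in range(1, len(pids)):
            gap = pos[i] - pos[i - 1]
            r = _pearson(
                betas.values[:, col[current[-1]]], betas.values[:, col[pids[i]]]
            )
            if gap <= max_gap and r >= r_threshold:
                current.append(pids[i])
            else:
                _emit(current, start_pos, blocks, singletons, positions)
                current = [pids[i]]
                start_pos = pos[i]
        _emit(current, start_pos, blocks, singletons, positions)

    return BlockAssignment(blocks=blocks, singletons=singletons, positions=positions)


def _emit(
    current: list[str],
    start_pos: int,
    blocks: list[list[str]],
    singletons: list[str],
    positions: list[int],
) -> None:
    if len(current) >= 2:
        blocks.append(list(current))
        positions.append(start_pos)
    else:
        singletons.append(current[0])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def aggregate_mcbs(
    betas: MethylationMatrix, assignment: BlockAssignment
) -> MethylationMatrix:
    """Average betas within each block; singletons pass through unchanged.

    The output has one column per block (named after its first probe with an
    ``MCB:`` prefix) plus one per singleton, and keeps the input stage so it
    can be standardized downstream.
    """
    col = {p: j for j, p in enumerate(betas.probe_ids)}
    unknown = [p for p in assignment.covered_probes() if p not in col]
    if unknown:
        raise ValidationError(f"assignment references unknown probe {unknown[0]!r}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for block in assignment.blocks:
        idx = [col[p] for p in block]
        cols.append(betas.values[:, idx].mean(axis=1))
        names.append("MCB:" + block[0])
    for pid in assignment.singletons:
        cols.append(betas.values[:, col[pid]])
        names.append(pid)
    return MethylationMatrix(
        values=np.column_stack(cols),
        sample_ids=list(betas.sample_ids),
        probe_ids=names,
        stage=betas.stage,
    )
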