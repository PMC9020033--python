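"""Readers and writers for the pipeline's external formats.

Formats handled here:

* beta matrix TSV — header row of probe ids, one row per sample, first
  column ``sample_id``; optional HDF5 container with the same content
* probe manifest TSV (BED-like) — columns ``chromosome``, ``position``,
  ``probe_id``
* phenotype/covariate CSV — ``sample_id``, outcome, covariates, ``batch``
* GCTA-style text GRM — ``<prefix>.grm.txt`` with one line per lower-triangle
  element ``i  j  n_features  value`` (1-based indices, diagonal included)
  and ``<prefix>.grm.id`` with family/individual id columns
* YAML analysis config and JSON run summaries
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    MethylationMatrix,
    ProbeManifest,
    SimilarityMatrix,
    ValidationError,
    validate_pheno,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_pheno",
    "write_pheno",
    "write_grm",
    "read_grm",
    "read_config",
    "write_config",
    "write_json",
    "read_json",
]


def read_manifest(path: str | Path) -> ProbeManifest:
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return ProbeManifest(tab)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table[["chromosome", "position", "probe_id"]].to_csv(
        path, sep="\t", index=False
    )


def read_beta_matrix(
    path: str | Path, manifest_path: str | Path | None = None
) -> MethylationMatrix:
    """Read a beta matrix TSV (or HDF5 container) and validate against a manifest.

    Values must lie in [0, 1]; probes are aligned to manifest order when a
    manifest is given, and a probe absent from the manifest is an error.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        mat = _read_beta_h5(path)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
        mat = MethylationMatrix(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame.index],
            probe_ids=[str(c) for c in frame.columns],
        )
    if manifest_path is not None:
        manifest = read_manifest(manifest_path)
        known = manifest.probe_ids
        missing = [p for p in mat.probe_ids if p not in set(known)]
        if missing:
            raise ValidationError(
                f"probe {missing[0]!r} not present in manifest ({len(missing)} missing)"
            )
        order = [p for p in known if p in set(mat.probe_ids)]
        idx = {p: j for j, p in enumerate(mat.probe_ids)}
        mat = mat.subset_probes([idx[p] for p in order])
    return mat


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_beta_h5(matrix, path)
        return
    # %.17g guarantees an exact float64 round-trip through text
    matrix.to_frame().to_csv(
        path, sep="\t", index_label="sample_id", float_format="%.17g"
    )


def _write_beta_h5(matrix: MethylationMatrix, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("betas", data=matrix.values)
        h5.create_dataset(
            "sample_ids", data=np.array(matrix.sample_ids, dtype="S")
        )
        h5.create_dataset("probe_ids", data=np.array(matrix.probe_ids, dtype="S"))
        h5.attrs["stage"] = matrix.stage


def _read_beta_h5(path: Path) -> MethylationMatrix:
    import h5py

    with h5py.File(path, "r") as h5:
        return MethylationMatrix(
            values=h5["betas"][()],
            sample_ids=[s.decode() for s in h5["sample_ids"][()]],
            probe_ids=[p.decode() for p in h5["probe_ids"][()]],
            stage=h5.attrs.get("stage", "raw"),
        )


def read_pheno(path: str | Path, outcome: str | None = None) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    validate_pheno(pheno, outcome)
    return pheno


def write_pheno(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_pheno(pheno)
    pheno.to_csv(path, index=False)


def write_grm(
    M: SimilarityMatrix | np.ndarray,
    ids: list[str],
    path_prefix: str | Path,
    n_features: int | None = None,
) -> tuple[Path, Path]:
    """Write a similarity matrix in the GCTA text GRM layout.

    Emits ``<prefix>.grm.txt`` (tab-separated ``i j n_features value`` for the
    lower triangle including the diagonal, indices 1-based) and
    ``<prefix>.grm.id`` (family id = individual id = sample id).
    """
    if isinstance(M, SimilarityMatrix):
        values = M.values
        if n_features is None:
            n_features = M.n_features
    else:
        values = np.asarray(M, dtype=float)
        if n_features is None:
            raise ValidationError("n_features required when M is a bare array")
    n = values.shape[0]
    if values.shape != (n, n):
        raise ValidationError("GRM must be square")
    if len(ids) != n:
        raise ValidationError(f"{len(ids)} ids for a {n}x{n} matrix")
    if not np.allclose(values, values.T, atol=1e-10, rtol=0):
        raise ValidationError("GRM must be symmetric")

    prefix = Path(path_prefix)
    grm_path = prefix.with_name(prefix.name + ".grm.txt")
    id_path = prefix.with_name(prefix.name + ".grm.id")
    with open(grm_path, "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_features}\t{values[i, j]:.17g}\n")
    with open(id_path, "w") as fh:
        for sid in ids:
            fh.write(f"{sid}\t{sid}\n")
    return grm_path, id_path


def read_grm(path_prefix: str | Path) -> SimilarityMatrix:
    """Read a text GRM written by :func:`write_grm`."""
    prefix = Path(path_prefix)
    tab = pd.read_csv(
        prefix.with_name(prefix.name + ".grm.txt"),
        sep="\t",
        names=["i", "j", "n_features", "value"],
    )
    ids = pd.read_csv(
        prefix.with_name(prefix.name + ".grm.id"),
        sep="\t",
        names=["fid", "iid"],
        dtype=str,
    )["iid"].tolist()
    n = int(tab["i"].max())
    values = np.zeros((n, n))
    ii = tab["i"].to_numpy() - 1
    jj = tab["j"].to_numpy() - 1
    values[ii, jj] = tab["value"].to_numpy()
    values[jj, ii] = tab["value"].to_numpy()
    return SimilarityMatrix(
        values=values, sample_ids=ids, n_features=int(tab["n_features"].iloc[0])
    )


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    payload = {
        "outcome": config.outcome,
        "covariate_sets": config.covariate_sets,
        "n_splits": config.n_splits,
        "train_fraction": config.train_fraction,
        "n_imputations": config.n_imputations,
        "imputation_iterations": config.imputation_iterations,
        "seed": config.seed,
        "winsorize_k": config.winsorize_k,
        "mcb_r": config.mcb_r,
        "mcb_gap": config.mcb_gap,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_json(payload: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
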