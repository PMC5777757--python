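"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as gene-by-sample TSV/CSV or GCT 1.2; drug
response tables as sample-by-drug CSV; gene sets as GMT; configuration
as a single YAML file mirroring :class:`~chemoscreen.datatypes.RunConfig`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    VALID_MEASURES,
    ChemoscreenError,
    DrugResponseTable,
    ExpressionMatrix,
    GeneSetCollection,
    PredictionMatrix,
    RunConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_drug_response",
    "write_drug_response",
    "read_predictions",
    "write_predictions",
    "load_config",
    "save_config",
    "write_run_summary",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _coerce_numeric(df: pd.DataFrame, what: str, allow_missing: bool) -> pd.DataFrame:
    """Coerce body to float, naming the offending cell on failure."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ChemoscreenError(
            f"non-numeric {what} value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not allow_missing and out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise ChemoscreenError(
            f"missing {what} value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return out.astype(float)


def _check_header_duplicates(path, sep: str, skip: int, drop_leading: int = 1) -> None:
    """Reject duplicated sample ids in the header (pandas would mangle them)."""
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split(sep)[drop_leading:]
    dups = [h for i, h in enumerate(header) if h in header[:i]]
    if dups:
        raise ChemoscreenError(f"duplicate sample ids in {path}: {sorted(set(dups))[:5]}")


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows by their mean (order of first occurrence)."""
    if not df.index.has_duplicates:
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    logger.info(
        "collapsing %d duplicated gene id(s) by mean: %s%s",
        len(dups), dups[:5], "..." if len(dups) > 5 else "",
    )
    order = df.index.drop_duplicates()
    return df.groupby(level=0, sort=False).mean().loc[order]


def read_expression(path, format: str = "tsv", platform: str = "") -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix.

    ``format`` is ``tsv``/``csv`` (first column gene ids, header sample
    ids) or ``gct`` (GCT 1.2: ``#1.2`` line, dimensions line, then a body
    with Name and Description columns). Duplicate gene rows are collapsed
    by mean; duplicate sample ids are an error; missing values are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ChemoscreenError(f"no such file: {path}")
    if format in _SEPS:
        _check_header_duplicates(path, _SEPS[format], skip=0)
        df = pd.read_csv(path, sep=_SEPS[format], index_col=0)
    elif format == "gct":
        _check_header_duplicates(path, "\t", skip=2, drop_leading=2)
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ChemoscreenError(
                    f"unsupported GCT version line {version!r} in {path}"
                )
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ChemoscreenError(f"malformed GCT dimensions line in {path}")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=df.columns[0])  # Description column
        if df.shape != (n_genes, n_samples):
            raise ChemoscreenError(
                f"GCT header declares {n_genes}x{n_samples} but body is "
                f"{df.shape[0]}x{df.shape[1]} in {path}"
            )
    else:
        raise ChemoscreenError(f"unknown expression format {format!r}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ChemoscreenError(f"duplicate sample ids in {path}: {dups[:5]}")
    df = _coerce_numeric(df, "expression", allow_missing=False)
    df = _collapse_duplicate_genes(df)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, platform=platform)


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format in _SEPS:
        expr.data.to_csv(path, sep=_SEPS[format], index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            body = expr.data.copy()
            body.insert(0, "Description", "na")
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ChemoscreenError(f"unknown expression format {format!r}")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT: name, description, then >=1 gene per line.

    Descriptions are discarded; duplicate genes within a set are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ChemoscreenError(f"no such file: {path}")
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ChemoscreenError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ChemoscreenError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ChemoscreenError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_drug_response(path, measure: str) -> DrugResponseTable:
    """Read a sample-by-drug response CSV; blank cells become missing."""
    if measure not in VALID_MEASURES:
        raise ChemoscreenError(
            f"measure must be one of {VALID_MEASURES}, got {measure!r}"
        )
    path = Path(path)
    if not path.exists():
        raise ChemoscreenError(f"no such file: {path}")
    _check_header_duplicates(path, ",", skip=0)
    df = pd.read_csv(path, index_col=0)
    df = _coerce_numeric(df, "drug response", allow_missing=True)
    df.index.name = None
    df.columns.name = None
    if measure == "auc" and (df.to_numpy() < 0).any():
        logger.warning("negative AUC value(s) in %s; kept as-is", path)
    return DrugResponseTable(df, measure=measure)


def write_drug_response(table: DrugResponseTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")


def read_predictions(path, platform: str = "") -> PredictionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = _coerce_numeric(df, "predicted IC50", allow_missing=False)
    df.index.name = None
    df.columns.name = None
    return PredictionMatrix(df, platform=platform)


def write_predictions(pred: PredictionMatrix, path) -> None:
    pred.data.to_csv(path, sep="\t", index_label="sample_id")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are an error."""
    path = Path(path)
    if not path.exists():
        raise ChemoscreenError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ChemoscreenError(f"config {path} must be a YAML mapping")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_run_summary(path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the JSON run summary (config echo, seed, package version)."""
    from . import __version__

    payload = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
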