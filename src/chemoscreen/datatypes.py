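"""Domain containers shared by every pipeline stage.

All expression data is held genes x samples on a log scale; drug-response
tables are samples x drugs. Converters to/from files live in :mod:`chemoscreen.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "GeneSetCollection",
    "RunConfig",
    "PredictionMatrix",
]

VALID_MEASURES = ("log_ic50", "auc")


class ChemoscreenError(ValueError):
    """Base class for user-facing input/validation errors."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ChemoscreenError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes in rows, samples in columns.

    Parameters
    ----------
    data :
        DataFrame indexed by gene id with one column per sample id.
        Values must all be finite (missing expression is not allowed).
    platform :
        Free-text label for the profiling platform
        (e.g. ``"affymetrix"``, ``"agilent"``, ``"rnaseq"``).
    """

    data: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ChemoscreenError("expression values must be numeric")
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ChemoscreenError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ChemoscreenError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.platform)


@dataclass
class DrugResponseTable:
    """Measured drug response, samples in rows, drugs in columns.

    ``measure`` is ``"log_ic50"`` for training screens (lower = more
    sensitive) or ``"auc"`` for dose-response validation screens
    (higher = more resistant). Missing entries (NaN) are allowed and
    used pairwise-complete downstream.
    """

    data: pd.DataFrame
    measure: str = "log_ic50"

    def __post_init__(self) -> None:
        if self.measure not in VALID_MEASURES:
            raise ChemoscreenError(
                f"measure must be one of {VALID_MEASURES}, got {self.measure!r}"
            )
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "drug ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ChemoscreenError("drug response values must be numeric")
        if values.size and np.isinf(values).any():
            raise ChemoscreenError("infinite drug response value")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def drug_ids(self) -> list:
        return self.data.columns.tolist()


@dataclass
class PredictionMatrix:
    """Imputed log-IC50 surface: samples in rows, drugs in columns."""

    data: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "drug ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ChemoscreenError("predicted IC50s must be finite")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def drug_ids(self) -> list:
        return self.data.columns.tolist()


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) as read from a GMT file."""

    sets: Mapping[str, list]
    source: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in dict(self.sets).items():
            # de-duplicate preserving first occurrence
            seen: dict = {}
            for g in genes:
                seen.setdefault(g, None)
            deduped = list(seen)
            if not deduped:
                raise ChemoscreenError(f"gene set {name!r} is empty")
            cleaned[name] = deduped
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)


@dataclass
class RunConfig:
    """All tunable parameters of the screen, mirrored by the YAML config.

    Defaults encode the study conditions: SOC = mean predicted log-IC50
    of cisplatin and docetaxel, top-20% SOC score labelled non-responder,
    raw P < 0.05 candidacy, GSEA FDR q < 0.25.
    """

    soc_drugs: Sequence[str] = ("cisplatin", "docetaxel")
    resistant_fraction: float = 0.20
    alpha: float = 0.05
    gsea_fdr_q: float = 0.25
    n_permutations: int = 1000
    seed: int = 0
    variance_filter_fraction: float = 0.8
    ridge_penalty_grid: Sequence[float] = tuple(
        float(x) for x in np.logspace(-2, 2, 7)
    )
    cv_folds: int = 10
    gsea_min_set_size: int = 5
    gsea_max_set_size: int = 500
    gsea_weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        self.soc_drugs = list(self.soc_drugs)
        if not self.soc_drugs:
            raise ChemoscreenError("soc_drugs must be non-empty")
        if not 0.0 < self.resistant_fraction < 1.0:
            raise ChemoscreenError("resistant_fraction must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ChemoscreenError("alpha must be in (0, 1)")
        if not 0.0 < self.gsea_fdr_q <= 1.0:
            raise ChemoscreenError("gsea_fdr_q must be in (0, 1]")
        if self.n_permutations < 1:
            raise ChemoscreenError("n_permutations must be >= 1")
        if not 0.0 < self.variance_filter_fraction <= 1.0:
            raise ChemoscreenError("variance_filter_fraction must be in (0, 1]")
        self.ridge_penalty_grid = sorted(float(x) for x in self.ridge_penalty_grid)
        if any(lam < 0 for lam in self.ridge_penalty_grid):
            raise ChemoscreenError("ridge penalties must be non-negative")
        if not self.ridge_penalty_grid:
            raise ChemoscreenError("ridge_penalty_grid must be non-empty")
        if self.cv_folds < 2:
            raise ChemoscreenError("cv_folds must be >= 2")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["soc_drugs"] = list(self.soc_drugs)
        d["ridge_penalty_grid"] = [float(x) for x in self.ridge_penalty_grid]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ChemoscreenError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in known})
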