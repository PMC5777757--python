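"""Synthetic training panels, tumor cohorts and AUC screens.

A linear-Gaussian latent-program model generates everything: expression
is program loadings times per-sample program activities plus noise, and
each drug's log-IC50 is a linear combination of the same activities plus
noise. Program 0 is the "SOC-resistance program": the SOC component
drugs couple to it positively (active program -> higher IC50 -> more
resistant) and the planted candidate drugs couple negatively, giving the
screen a recoverable ground truth. Multi-platform tumor cohorts apply an
affine shift/scale, a random gene subset, and extra noise per platform
to the same underlying tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ChemoscreenError,
    DrugResponseTable,
    ExpressionMatrix,
    GeneSetCollection,
)

__all__ = [
    "PlatformEffect",
    "SyntheticTruth",
    "DEFAULT_PLATFORMS",
    "generate_cell_line_panel",
    "generate_tumor_cohorts",
    "generate_measured_auc",
]


@dataclass(frozen=True)
class PlatformEffect:
    """Affine + subset + noise distortion of one profiling platform."""

    shift: float = 0.0
    scale: float = 1.0
    gene_subset_fraction: float = 1.0
    noise_sd: float = 0.0


#: Two stylized platforms profiling the same tumors. Technical noise
#: dominates gene-level variation (per-gene cross-platform concordance
#: in multi-platform cohorts is modest), and each platform reports its
#: own gene subset.
DEFAULT_PLATFORMS: Mapping[str, PlatformEffect] = {
    "affymetrix": PlatformEffect(shift=0.3, scale=1.2, gene_subset_fraction=0.70, noise_sd=2.0),
    "rnaseq": PlatformEffect(shift=-0.4, scale=0.8, gene_subset_fraction=0.65, noise_sd=2.0),
}


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic study.

    ``program_loadings`` (genes x programs) and ``drug_coupling``
    (drugs x programs) define the generative model; program 0 is the
    SOC-resistance program. ``planted_candidates`` lists the drugs
    anti-coupled to it (always disjoint from ``soc_drugs``).
    """

    program_loadings: pd.DataFrame
    drug_coupling: pd.DataFrame
    drug_intercepts: pd.Series
    planted_candidates: list
    soc_drugs: list
    noise_sd_expression: float
    noise_sd_response: float
    seed: int
    platform_effects: Mapping[str, PlatformEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_candidates) & set(self.soc_drugs):
            raise ChemoscreenError("planted candidates must be disjoint from SOC drugs")

    @property
    def null_drugs(self) -> list:
        special = set(self.planted_candidates) | set(self.soc_drugs)
        return [d for d in self.drug_coupling.index if d not in special]

    def planted_gene_sets(self) -> GeneSetCollection:
        """One gene set per program: the genes with non-zero loadings."""
        sets = {}
        for j, prog in enumerate(self.program_loadings.columns):
            genes = self.program_loadings.index[
                self.program_loadings[prog] != 0
            ].tolist()
            sets[f"planted_{prog}"] = genes
        return GeneSetCollection(sets, source="synthetic truth")

    def decoy_gene_sets(
        self, n_sets: int = 10, set_size: int = 25, seed: int = 0
    ) -> GeneSetCollection:
        """Random gene sets avoiding the SOC-resistance program.

        The synthetic gene universe is far smaller than a genome, so a
        uniformly random set would contain several resistance-program
        genes and be genuinely (weakly) enriched; drawing decoys off the
        resistance program emulates the genome-scale situation where a
        random pathway misses the planted program entirely.
        """
        resistance = set(
            self.program_loadings.index[self.program_loadings.iloc[:, 0] != 0]
        )
        pool = np.asarray(
            [g for g in self.program_loadings.index if g not in resistance],
            dtype=object,
        )
        rng = np.random.default_rng(seed)
        sets = {
            f"decoy_{i + 1:02d}": rng.choice(pool, size=set_size, replace=False).tolist()
            for i in range(n_sets)
        }
        return GeneSetCollection(sets, source="synthetic decoys")


def _program_loadings(
    rng: np.random.Generator,
    n_genes: int,
    n_programs: int,
    block_fraction: float,
) -> pd.DataFrame:
    """Disjoint positive loading blocks, one per program."""
    block = int(np.floor(block_fraction * n_genes))
    if block < 1 or block * n_programs > n_genes:
        raise ChemoscreenError("program blocks do not fit in the gene universe")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    L = np.zeros((n_genes, n_programs))
    for j in range(n_programs):
        idx = order[j * block : (j + 1) * block]
        L[idx, j] = rng.uniform(0.5, 1.5, size=block)
    return pd.DataFrame(
        L, index=genes, columns=[f"program_{j}" for j in range(n_programs)]
    )


def generate_cell_line_panel(
    n_lines: int = 300,
    n_genes: int = 1000,
    n_drugs: int = 138,
    n_candidates: int = 5,
    n_programs: int = 3,
    block_fraction: float = 0.10,
    coupling: float = 1.0,
    noise_sd_expression: float = 0.5,
    noise_sd_response: float = 0.5,
    soc_drugs: Sequence[str] = ("cisplatin", "docetaxel"),
    seed: int = 0,
) -> tuple[ExpressionMatrix, DrugResponseTable, SyntheticTruth]:
    """Generate the cell-line training panel and its ground truth.

    Expression = loadings @ activity' + Gaussian noise; log-IC50 =
    activity @ coupling' + per-drug intercept + Gaussian noise. The SOC
    drugs carry +``coupling`` on program 0, the ``n_candidates`` planted
    candidates carry -``coupling``, and all other drugs are null (zero
    coupling). Fully reproducible from ``seed``.
    """
    if n_lines < 20:
        raise ChemoscreenError("need n_lines >= 20")
    if n_programs < 1:
        raise ChemoscreenError("need at least one latent program")
    if n_drugs < len(soc_drugs) + n_candidates:
        raise ChemoscreenError("n_drugs too small for SOC drugs + candidates")
    rng = np.random.default_rng(seed)
    loadings = _program_loadings(rng, n_genes, n_programs, block_fraction)

    lines = [f"CL{i:04d}" for i in range(n_lines)]
    activity = rng.standard_normal((n_lines, n_programs))

    expr = loadings.to_numpy() @ activity.T
    expr += rng.normal(scale=noise_sd_expression, size=expr.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=loadings.index, columns=lines),
        platform="cell_line_panel",
    )

    candidates = [f"candidate_{i + 1:02d}" for i in range(n_candidates)]
    n_null = n_drugs - len(soc_drugs) - n_candidates
    nulls = [f"drug_{i + 1:04d}" for i in range(n_null)]
    drug_ids = list(soc_drugs) + candidates + nulls
    B = np.zeros((n_drugs, n_programs))
    B[: len(soc_drugs), 0] = coupling
    B[len(soc_drugs) : len(soc_drugs) + n_candidates, 0] = -coupling
    coupling_df = pd.DataFrame(B, index=drug_ids, columns=loadings.columns)
    intercepts = pd.Series(rng.normal(loc=3.0, scale=1.0, size=n_drugs), index=drug_ids)

    ic50 = activity @ B.T + intercepts.to_numpy()
    ic50 += rng.normal(scale=noise_sd_response, size=ic50.shape)
    response = DrugResponseTable(
        pd.DataFrame(ic50, index=lines, columns=drug_ids), measure="log_ic50"
    )

    truth = SyntheticTruth(
        program_loadings=loadings,
        drug_coupling=coupling_df,
        drug_intercepts=intercepts,
        planted_candidates=candidates,
        soc_drugs=list(soc_drugs),
        noise_sd_expression=noise_sd_expression,
        noise_sd_response=noise_sd_response,
        seed=seed,
    )
    return expression, response, truth


def generate_tumor_cohorts(
    truth: SyntheticTruth,
    n_tumors: int = 200,
    platforms: Mapping[str, PlatformEffect] | None = None,
    seed: int = 1,
    base_noise_sd: float | None = None,
) -> tuple[list[ExpressionMatrix], pd.Series]:
    """Generate multi-platform tumor cohorts from the shared truth.

    All platforms profile the SAME tumors (same program activities) as
    technical replications: each platform applies its affine
    shift/scale, keeps a random subset of genes, and adds its own
    measurement noise. ``base_noise_sd`` is biological gene-level
    variation shared by all platforms (default: the truth's expression
    noise, matching the cell-line panel). Returns the cohort list and
    the tumors' true SOC-resistance score (program-0 activity; higher =
    more resistant).
    """
    platforms = dict(platforms if platforms is not None else DEFAULT_PLATFORMS)
    if base_noise_sd is None:
        base_noise_sd = truth.noise_sd_expression
    rng = np.random.default_rng(seed)
    tumors = [f"TUMOR_{i:04d}" for i in range(n_tumors)]
    L = truth.program_loadings.to_numpy()
    n_genes, n_programs = L.shape
    activity = rng.standard_normal((n_tumors, n_programs))
    base = L @ activity.T
    if base_noise_sd > 0:
        base = base + rng.normal(scale=base_noise_sd, size=(n_genes, n_tumors))
    cohorts = []
    for name, effect in platforms.items():
        keep = int(np.floor(effect.gene_subset_fraction * n_genes))
        if keep < 50:
            raise ChemoscreenError(
                f"platform {name!r}: gene subset leaves {keep} genes (< 50)"
            )
        idx = np.sort(rng.choice(n_genes, size=keep, replace=False))
        values = base[idx] * effect.scale + effect.shift
        if effect.noise_sd > 0:
            values = values + rng.normal(scale=effect.noise_sd, size=values.shape)
        cohorts.append(
            ExpressionMatrix(
                pd.DataFrame(
                    values, index=truth.program_loadings.index[idx], columns=tumors
                ),
                platform=name,
            )
        )
    true_soc = pd.Series(activity[:, 0], index=tumors, name="soc_resistance_activity")
    return cohorts, true_soc


def generate_measured_auc(
    truth: SyntheticTruth,
    cell_panel_response: DrugResponseTable,
    noise_sd: float = 0.5,
    seed: int = 2,
) -> DrugResponseTable:
    """Measured dose-response AUCs as a noisy monotone transform of the
    panel's log-IC50s (higher AUC = more resistant).

    Per drug, the log-IC50 column is z-standardized and pushed through
    AUC = 10 + 2*tanh(z/2) + Gaussian noise. With ``noise_sd = 0`` the
    per-drug Spearman correlation between AUC and log-IC50 is exactly 1.
    """
    rng = np.random.default_rng(seed)
    ic50 = cell_panel_response.data
    z = (ic50 - ic50.mean()) / ic50.std(ddof=1).replace(0.0, 1.0)
    auc = 10.0 + 2.0 * np.tanh(z / 2.0)
    if noise_sd > 0:
        auc = auc + rng.normal(scale=noise_sd, size=auc.shape)
    return DrugResponseTable(auc, measure="auc")
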