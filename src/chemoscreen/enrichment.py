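"""Continuous-phenotype gene set enrichment analysis.

Genes are ranked by their Pearson correlation with a continuous
phenotype (a predicted drug IC50 vector); each gene set's enrichment
score is the signed maximum deviation of the weighted Kolmogorov-Smirnov
running sum (hits weighted by |metric|^p, p = 1 by default); significance
comes from phenotype permutation with sign-matched normalization (NES)
and a permutation-based FDR q-value. The opposite-sign filter keeps
pathways positively enriched for the SOC phenotype and negatively
enriched for every candidate drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ChemoscreenError,
    ExpressionMatrix,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "PathwayOppositionResult",
    "gene_phenotype_metric",
    "enrichment_score",
    "permutation_null",
    "opposite_sign_filter",
    "enrichment_results_to_frame",
]


@dataclass
class RankedGeneList:
    """Genes ordered by metric, non-increasing; ties ordered by gene id."""

    gene_ids: list
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise ChemoscreenError("gene/metric length mismatch")
        if np.any(np.diff(self.metric) > 0):
            raise ChemoscreenError("metric must be sorted non-increasing")


@dataclass
class EnrichmentResult:
    set_name: str
    phenotype_id: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    set_size: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


@dataclass
class PathwayOppositionResult:
    """Pathways positively enriched for SOC and negatively for every
    candidate drug, all at the FDR threshold."""

    pathways: list
    q_threshold: float


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with y; constant rows -> 0."""
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    r = np.zeros(X.shape[0])
    ok = xnorm > 0
    r[ok] = (Xc[ok] @ yc) / (xnorm[ok] * ynorm)
    return np.clip(r, -1.0, 1.0)


def _rank(gene_ids: Sequence, metric: np.ndarray) -> tuple[list, np.ndarray]:
    """Sort descending by metric, ties broken by gene id (ascending)."""
    ids = np.asarray(gene_ids, dtype=object)
    idx = np.lexsort((ids.astype(str), -metric))
    return ids[idx].tolist(), metric[idx]


def gene_phenotype_metric(
    expr: ExpressionMatrix, phenotype: pd.Series | np.ndarray
) -> RankedGeneList:
    """Rank genes by Pearson correlation of expression with the phenotype."""
    if isinstance(phenotype, pd.Series):
        phenotype = phenotype.reindex(expr.data.columns)
        if phenotype.isna().any():
            raise ChemoscreenError("phenotype missing for some samples")
        y = phenotype.to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != expr.n_samples:
            raise ChemoscreenError("phenotype length != number of samples")
    if expr.n_samples < 3:
        raise ChemoscreenError("need n >= 3 samples for the correlation metric")
    if np.ptp(y) == 0.0:
        raise ChemoscreenError("phenotype is constant")
    r = _pearson_rows(expr.values, y)
    ids, metric = _rank(expr.gene_ids, r)
    return RankedGeneList(ids, metric)


def _es_from_mask(
    metric: np.ndarray, hit: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and running sum for a hit mask."""
    n = len(metric)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ChemoscreenError("gene set has no overlap with the ranked list")
    if n_hit == n:
        # no miss positions: running sum climbs to exactly 1
        steps = np.abs(metric) ** weight_exponent
        total = steps.sum()
        if total == 0:
            steps = np.full(n, 1.0 / n)
        else:
            steps = steps / total
        rs = np.cumsum(steps)
        return 1.0, rs
    w = np.abs(metric) ** weight_exponent
    hit_total = w[hit].sum()
    steps = np.where(hit, (w / hit_total) if hit_total > 0 else 0.0, -1.0 / (n - n_hit))
    if hit_total == 0:  # all hits carry zero metric: equal hit weights
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    rs = np.cumsum(steps)
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i]), rs


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Sequence,
    weight_exponent: float = 1.0,
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Hits are weighted by |metric|^p normalized to sum 1 over the set's
    genes; each miss steps down by 1/(N - N_hit). The running sum
    terminates at exactly 0, which is asserted for every call.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked.gene_ids))
    es, rs = _es_from_mask(ranked.metric, hit, weight_exponent)
    if int(hit.sum()) < len(ranked.gene_ids):
        assert abs(rs[-1]) < 1e-9, "running sum must terminate at 0"
    return es


def permutation_null(
    expr: ExpressionMatrix,
    phenotype: pd.Series | np.ndarray,
    sets: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    phenotype_id: str = "phenotype",
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA for every eligible gene set.

    The phenotype vector is re-randomized ``n_permutations`` times; the
    per-gene metric, ranking and every set's ES are recomputed each
    time. NES divides ES by the mean |null ES| of matching sign;
    nominal p uses the plus-one permutation estimator on same-sign null
    ES; the FDR q compares the sign-matched null and observed NES tail
    fractions (capped at 1). Sets outside [min_size, max_size] after
    restriction to measured genes are skipped with a log message.
    """
    if n_permutations < 1:
        raise ChemoscreenError("n_permutations must be >= 1")
    if isinstance(phenotype, pd.Series):
        phenotype = phenotype.reindex(expr.data.columns)
        y = phenotype.to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    measured = set(expr.gene_ids)
    eligible: dict[str, set] = {}
    for name, genes in sets.sets.items():
        present = set(genes) & measured
        if not min_size <= len(present) <= max_size:
            logger.info(
                "skipping set %s: %d gene(s) on the list outside [%d, %d]",
                name, len(present), min_size, max_size,
            )
            continue
        eligible[name] = present
    if not eligible:
        return []

    X = expr.values
    gene_arr = np.asarray(expr.gene_ids, dtype=object)
    masks = {
        name: np.fromiter((g in members for g in gene_arr), bool, len(gene_arr))
        for name, members in eligible.items()
    }

    def all_es(metric_raw: np.ndarray) -> dict[str, float]:
        ids_sorted_idx = np.lexsort((gene_arr.astype(str), -metric_raw))
        metric = metric_raw[ids_sorted_idx]
        out = {}
        for name, mask in masks.items():
            es, _ = _es_from_mask(metric, mask[ids_sorted_idx], weight_exponent)
            out[name] = es
        return out

    observed = all_es(_pearson_rows(X, y))

    rng = np.random.default_rng(seed)
    null_es = {name: np.empty(n_permutations) for name in eligible}
    for b in range(n_permutations):
        perm = rng.permutation(y)
        es_b = all_es(_pearson_rows(X, perm))
        for name, val in es_b.items():
            null_es[name][b] = val

    # sign-matched NES normalization
    nes_obs: dict[str, float] = {}
    nes_null_all: list[np.ndarray] = []
    nominal_p: dict[str, float] = {}
    for name, es in observed.items():
        null = null_es[name]
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        denom = mean_pos if es >= 0 else mean_neg
        nes_obs[name] = float(es / denom) if denom and np.isfinite(denom) and denom > 0 else 0.0
        same_sign = pos if es >= 0 else neg
        count = int((np.abs(same_sign) >= abs(es)).sum())
        # plus-one permutation estimator over the sign-matched null
        nominal_p[name] = (count + 1) / (same_sign.size + 1)
        # normalized null NES for the FDR pool
        nn = np.zeros_like(null)
        if pos.size and mean_pos > 0:
            nn[null >= 0] = null[null >= 0] / mean_pos
        if neg.size and mean_neg > 0:
            nn[null < 0] = null[null < 0] / mean_neg
        nes_null_all.append(nn)

    null_pool = np.concatenate(nes_null_all)
    obs_vals = np.array([nes_obs[name] for name in observed])
    results = []
    for name, es in observed.items():
        nes = nes_obs[name]
        if nes >= 0:
            null_tail = (null_pool >= nes).mean() if (null_pool >= 0).any() else 0.0
            null_frac = (null_pool >= 0).mean()
            obs_tail = (obs_vals >= nes).mean()
            obs_frac = (obs_vals >= 0).mean()
        else:
            null_tail = (null_pool <= nes).mean()
            null_frac = (null_pool < 0).mean()
            obs_tail = (obs_vals <= nes).mean()
            obs_frac = (obs_vals < 0).mean()
        num = null_tail / null_frac if null_frac > 0 else 0.0
        den = obs_tail / obs_frac if obs_frac > 0 else 1.0
        q = min(1.0, num / den) if den > 0 else 1.0
        results.append(
            EnrichmentResult(
                set_name=name,
                phenotype_id=phenotype_id,
                es=float(es),
                nes=nes,
                nominal_p=float(nominal_p[name]),
                fdr_q=float(q),
                set_size=len(eligible[name]),
            )
        )
    return results


def opposite_sign_filter(
    soc_results: Sequence[EnrichmentResult],
    candidate_results: Mapping[str, Sequence[EnrichmentResult]],
    q_threshold: float = 0.25,
) -> PathwayOppositionResult:
    """Pathways positively enriched for the SOC phenotype and negatively
    enriched for every candidate drug, all with FDR q below threshold."""
    if not candidate_results:
        raise ChemoscreenError("no candidate-drug enrichment results given")
    soc_pos = {
        r.set_name for r in soc_results if r.es > 0 and r.fdr_q < q_threshold
    }
    kept = soc_pos
    for drug, results in candidate_results.items():
        if not results:
            raise ChemoscreenError(f"candidate drug {drug!r} has no enrichment results")
        neg = {r.set_name for r in results if r.es < 0 and r.fdr_q < q_threshold}
        kept = kept & neg
    return PathwayOppositionResult(sorted(kept), q_threshold)


def enrichment_results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "phenotype_id": r.phenotype_id,
                "set_size": r.set_size,
                "es": r.es,
                "nes": r.nes,
                "nominal_p": r.nominal_p,
                "fdr_q": r.fdr_q,
            }
            for r in results
        ]
    ).set_index("set_name")
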