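"""The standard-of-care (SOC) stratified drug screen.

A sample's SOC score is the mean of its predicted log-IC50s for the SOC
component drugs (cisplatin and docetaxel by default). Samples in the top
fraction of SOC scores are labelled non-responders; each remaining drug
is then tested for a lower predicted IC50 in the non-responder group
(pooled-variance two-sample t-test with a directional filter), and
per-platform candidate lists are intersected into the final list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ChemoscreenError, PredictionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SOCStratification",
    "DrugScreenRecord",
    "CorrelationRecord",
    "CandidateSet",
    "compute_soc_score",
    "stratify",
    "pooled_t_test",
    "differential_screen",
    "intersect_candidates",
    "correlate_with_soc",
    "screen_records_to_frame",
    "correlation_records_to_frame",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class SOCStratification:
    """Per-sample SOC score and responder / non-responder labels."""

    soc_score: pd.Series
    labels: pd.Series  # values in {responder, non_responder}
    resistant_fraction: float
    rule: str  # top_quantile | mean_split

    @property
    def sample_ids(self) -> list:
        return self.soc_score.index.tolist()

    @property
    def responders(self) -> list:
        return self.labels.index[self.labels == RESPONDER].tolist()

    @property
    def non_responders(self) -> list:
        return self.labels.index[self.labels == NON_RESPONDER].tolist()


@dataclass
class DrugScreenRecord:
    """One drug's differential statistics between SOC groups."""

    drug_id: str
    mean_responder: float
    mean_non_responder: float
    t_statistic: float
    p_value: float
    tail: str
    candidate: bool
    fdr_q: float = float("nan")  # informational only; candidacy uses raw p


@dataclass
class CorrelationRecord:
    """Correlation of one drug's predicted IC50 with the SOC score."""

    drug_id: str
    method: str  # pearson | spearman
    on: str  # values | ranks
    r: float
    p_value: float
    excluded: bool = False  # constant drug column: r undefined


@dataclass
class CandidateSet:
    """Per-platform candidate drug lists and their intersection."""

    per_platform: Mapping[str, list]
    final: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lists = [set(v) for v in self.per_platform.values()]
        inter = set.intersection(*lists) if lists else set()
        self.final = sorted(inter)


def compute_soc_score(pred: PredictionMatrix, soc_drugs: Sequence[str]) -> pd.Series:
    """Mean predicted log-IC50 over the SOC component drugs, per sample."""
    missing = [d for d in soc_drugs if d not in pred.data.columns]
    if missing:
        raise ChemoscreenError(f"SOC drug(s) absent from predictions: {missing}")
    score = pred.data[list(soc_drugs)].mean(axis=1)
    score.name = "soc_score"
    return score


def stratify(
    soc_score: pd.Series,
    resistant_fraction: float = 0.20,
    rule: str = "top_quantile",
) -> SOCStratification:
    """Label samples as SOC responders / non-responders.

    ``top_quantile``: the k = round(fraction * n) highest-scoring samples
    are non-responders, ties at the cut broken by sample-id lexicographic
    order (round = half away from zero, deterministically). ``mean_split``:
    scores above the mean are non-responders.
    """
    n = len(soc_score)
    if rule == "top_quantile":
        if n < 5:
            raise ChemoscreenError("top_quantile stratification needs n >= 5")
        if not 0.0 < resistant_fraction < 1.0:
            raise ChemoscreenError("resistant_fraction must be in (0, 1)")
        if np.ptp(soc_score.to_numpy()) == 0.0:
            raise ChemoscreenError(
                "all SOC scores identical: no meaningful top-quantile ranking"
            )
        k = int(np.floor(resistant_fraction * n + 0.5))
        order = (
            soc_score.to_frame("score")
            .assign(sample=soc_score.index.astype(str))
            .sort_values(["score", "sample"], ascending=[False, True])
        )
        non_resp = set(order.index[:k])
        labels = pd.Series(
            [NON_RESPONDER if s in non_resp else RESPONDER for s in soc_score.index],
            index=soc_score.index,
            name="label",
        )
    elif rule == "mean_split":
        cut = soc_score.mean()
        labels = pd.Series(
            np.where(soc_score > cut, NON_RESPONDER, RESPONDER),
            index=soc_score.index,
            name="label",
        )
    else:
        raise ChemoscreenError(f"unknown stratification rule {rule!r}")
    return SOCStratification(soc_score, labels, resistant_fraction, rule)


def pooled_t_test(
    a: np.ndarray, b: np.ndarray, tail: str = "two_sided"
) -> tuple[float, float]:
    """Pooled-variance Student's t for mean(a) - mean(b).

    ``tail="one_sided"`` tests the alternative mean(a) < mean(b).
    Degenerate inputs (zero pooled variance) follow the conventions:
    equal means -> (0, 1); unequal means -> (+/-inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ChemoscreenError("each group needs >= 2 observations")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0 if tail == "two_sided" else 0.5
        logger.warning("zero pooled variance with unequal means; p reported as 0")
        t = np.inf if a.mean() > b.mean() else -np.inf
        if tail == "two_sided":
            return float(t), 0.0
        return float(t), 0.0 if t < 0 else 1.0
    alternative = "two-sided" if tail == "two_sided" else "less"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def differential_screen(
    pred: PredictionMatrix,
    strat: SOCStratification,
    alpha: float = 0.05,
    tail: str = "two_sided",
    soc_drugs: Sequence[str] = (),
) -> list[DrugScreenRecord]:
    """Test every non-SOC drug for differential predicted IC50 between
    SOC responders and non-responders.

    A drug is a candidate iff its mean predicted IC50 is lower in
    non-responders AND its t-test p-value is below ``alpha``. A
    Benjamini-Hochberg q-value is attached for information only.
    """
    if tail not in ("two_sided", "one_sided"):
        raise ChemoscreenError(f"unknown tail {tail!r}")
    responders = strat.responders
    non_responders = strat.non_responders
    if len(responders) < 2 or len(non_responders) < 2:
        raise ChemoscreenError("need >= 2 samples in each SOC group")
    drugs = [d for d in pred.data.columns if d not in set(soc_drugs)]
    records = []
    for drug in drugs:
        col = pred.data[drug]
        a = col.loc[non_responders].to_numpy()
        b = col.loc[responders].to_numpy()
        t, p = pooled_t_test(a, b, tail=tail)
        mean_nr, mean_r = float(a.mean()), float(b.mean())
        records.append(
            DrugScreenRecord(
                drug_id=drug,
                mean_responder=mean_r,
                mean_non_responder=mean_nr,
                t_statistic=t,
                p_value=p,
                tail=tail,
                candidate=bool(mean_nr < mean_r and p < alpha),
            )
        )
    if records:
        qs = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for rec, q in zip(records, qs):
            rec.fdr_q = float(q)
    return records


def intersect_candidates(per_platform: Mapping[str, Iterable[str]]) -> CandidateSet:
    """Intersect per-platform candidate lists into the final list
    (reported in lexicographic order)."""
    if not per_platform:
        raise ChemoscreenError("need at least one platform candidate list")
    return CandidateSet({k: sorted(set(v)) for k, v in per_platform.items()})


def correlate_with_soc(
    pred: PredictionMatrix,
    soc_score: pd.Series,
    method: str = "pearson",
    on: str = "values",
    soc_drugs: Sequence[str] = (),
) -> list[CorrelationRecord]:
    """Correlate each drug's predicted IC50 with the SOC score.

    ``on="ranks"`` rank-transforms both variables (average ranks for
    ties) before a Pearson correlation — identical to Spearman on
    values. Constant drug columns are flagged ``excluded`` with r = NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ChemoscreenError(f"unknown method {method!r}")
    if on not in ("values", "ranks"):
        raise ChemoscreenError(f"unknown 'on' {on!r}")
    if len(soc_score) < 3:
        raise ChemoscreenError("need n >= 3 samples for correlation")
    y = soc_score.to_numpy(dtype=float)
    if on == "ranks":
        y = stats.rankdata(y)
    records = []
    for drug in pred.data.columns:
        if drug in set(soc_drugs):
            continue
        x = pred.data[drug].loc[soc_score.index].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            records.append(
                CorrelationRecord(drug, method, on, float("nan"), float("nan"), True)
            )
            continue
        xv = stats.rankdata(x) if on == "ranks" else x
        if method == "pearson":
            r, p = stats.pearsonr(xv, y)
        else:
            r, p = stats.spearmanr(xv, y)
        records.append(CorrelationRecord(drug, method, on, float(r), float(p)))
    return records


def screen_records_to_frame(records: Sequence[DrugScreenRecord]) -> pd.DataFrame:
    """Table-shaped view: drug, group means, t, p, q, candidate flag."""
    return pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "mean_responder": r.mean_responder,
                "mean_non_responder": r.mean_non_responder,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "fdr_q": r.fdr_q,
                "tail": r.tail,
                "candidate": r.candidate,
            }
            for r in records
        ]
    ).set_index("drug_id")


def correlation_records_to_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "method": r.method,
                "on": r.on,
                "r": r.r,
                "p_value": r.p_value,
                "excluded": r.excluded,
            }
            for r in records
        ]
    ).set_index("drug_id")
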