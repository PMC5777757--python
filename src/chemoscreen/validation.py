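"""Independent-cohort replication, in vitro AUC validation, and the
survival proof-of-concept.

The in vitro check stratifies cell lines by *predicted* SOC score
(mean-split) and asks whether a candidate drug's *measured* AUC is lower
(more sensitive) in the predicted-resistant group, by one-sided pooled
t-test. The survival check compares predicted IC50 between alive and
dead patients (t-test and Wilcoxon rank-sum) and fits a linear model of
outcome on predicted IC50 adjusting for disease stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    ChemoscreenError,
    DrugResponseTable,
    PredictionMatrix,
    RunConfig,
)
from .screen import (
    SOCStratification,
    compute_soc_score,
    correlate_with_soc,
    differential_screen,
    pooled_t_test,
    stratify,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InVitroValidationRecord",
    "SurvivalAssociationRecord",
    "ReplicationResult",
    "replicate_screen",
    "invitro_validate",
    "survival_association",
    "invitro_records_to_frame",
]


@dataclass
class InVitroValidationRecord:
    """One candidate drug's measured-AUC contrast between predicted SOC groups.

    ``validated`` is None when the drug was not screened in the measured
    panel (not testable), mirroring how unscreened candidates are
    reported as NA.
    """

    drug_id: str
    mean_auc_sensitive: float
    mean_auc_resistant: float
    t_statistic: float
    p_value: float  # one-sided: resistant group lower
    validated: bool | None
    reason: str = ""


@dataclass
class SurvivalAssociationRecord:
    """Association between one drug's predicted IC50 and vital status."""

    drug_id: str
    t_statistic: float
    t_p_value: float
    wilcoxon_statistic: float
    wilcoxon_p_value: float
    adjusted_p: float  # p of the IC50 term in outcome ~ IC50 + stage dummies
    n_alive: int
    n_dead: int


@dataclass
class ReplicationResult:
    """Screen outputs of one cohort at one stratification cutoff."""

    cutoff: float
    stratification: SOCStratification
    records: list
    correlations: list

    @property
    def candidates(self) -> list:
        return sorted(r.drug_id for r in self.records if r.candidate)


def replicate_screen(
    pred: PredictionMatrix,
    config: RunConfig,
    cutoffs: Sequence[float] = (0.20, 0.50),
) -> dict[float, ReplicationResult]:
    """Re-run the SOC screen on an independent cohort at each cutoff.

    Each cutoff stratifies the cohort into the top ``cutoff`` fraction
    of SOC scores (non-responders) vs the rest, then repeats the
    differential screen and the SOC correlation analysis.
    """
    soc = compute_soc_score(pred, config.soc_drugs)
    out: dict[float, ReplicationResult] = {}
    for cutoff in cutoffs:
        strat = stratify(soc, resistant_fraction=cutoff, rule="top_quantile")
        records = differential_screen(
            pred, strat, alpha=config.alpha, soc_drugs=config.soc_drugs
        )
        corr = correlate_with_soc(pred, soc, soc_drugs=config.soc_drugs)
        out[cutoff] = ReplicationResult(cutoff, strat, records, corr)
    return out


def invitro_validate(
    pred_cell_lines: PredictionMatrix,
    measured: DrugResponseTable,
    candidates: Sequence[str],
    alpha: float = 0.05,
    soc_drugs: Sequence[str] = ("cisplatin", "docetaxel"),
) -> list[InVitroValidationRecord]:
    """Validate candidates against measured cell-line AUCs.

    Cell lines are split by mean predicted SOC score (above-mean =
    predicted resistant); for each candidate present in the measured
    panel, a one-sided pooled t-test asks whether AUC is lower in the
    predicted-resistant group. The stratification uses only predicted
    SOC scores — measured AUCs play no part in it.
    """
    if measured.measure != "auc":
        raise ChemoscreenError(
            f"measured responses must be auc, got {measured.measure!r}"
        )
    soc = compute_soc_score(pred_cell_lines, soc_drugs)
    strat = stratify(soc, rule="mean_split")
    sensitive, resistant = strat.responders, strat.non_responders
    records = []
    for drug in candidates:
        if drug not in measured.data.columns:
            logger.info("candidate %s not screened in measured panel; NA", drug)
            records.append(
                InVitroValidationRecord(
                    drug, float("nan"), float("nan"), float("nan"), float("nan"),
                    None, reason="not screened in measured panel",
                )
            )
            continue
        col = measured.data[drug]
        a = col.reindex(resistant).dropna().to_numpy()
        b = col.reindex(sensitive).dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ChemoscreenError(
                f"{drug}: fewer than 2 measured lines in a SOC group"
            )
        t, p = pooled_t_test(a, b, tail="one_sided")
        mean_res, mean_sen = float(a.mean()), float(b.mean())
        records.append(
            InVitroValidationRecord(
                drug_id=drug,
                mean_auc_sensitive=mean_sen,
                mean_auc_resistant=mean_res,
                t_statistic=t,
                p_value=p,
                validated=bool(mean_res < mean_sen and p < alpha),
            )
        )
    return records


def survival_association(
    pred: PredictionMatrix,
    drug_id: str,
    vital_status: pd.Series,
    stage: pd.Series | None = None,
) -> SurvivalAssociationRecord:
    """Compare predicted IC50 between alive and dead patients.

    ``vital_status`` holds "alive"/"dead" per sample. Reports the
    two-sample pooled t-test and Wilcoxon rank-sum p-values, and — when
    ``stage`` is given — the p-value of the IC50 term in a linear
    probability model of death on predicted IC50 plus stage dummies.
    """
    if drug_id not in pred.data.columns:
        raise ChemoscreenError(f"drug {drug_id!r} absent from predictions")
    status = vital_status.reindex(pred.data.index).dropna().astype(str).str.lower()
    bad = set(status.unique()) - {"alive", "dead"}
    if bad:
        raise ChemoscreenError(f"vital_status values must be alive/dead, got {bad}")
    ic50 = pred.data[drug_id].loc[status.index]
    alive = ic50[status == "alive"].to_numpy()
    dead = ic50[status == "dead"].to_numpy()
    if len(alive) < 2 or len(dead) < 2:
        raise ChemoscreenError("need >= 2 samples in each vital-status group")
    t, t_p = pooled_t_test(alive, dead, tail="two_sided")
    w, w_p = stats.ranksums(alive, dead)

    adjusted_p = float("nan")
    if stage is not None:
        stage_al = stage.reindex(status.index)
        keep = stage_al.notna()
        stage_al = stage_al[keep].astype(str)
        y = (status[keep] == "dead").astype(float).to_numpy()
        x = ic50[keep].to_numpy()
        if stage_al.nunique() < 2:
            logger.warning("stage has a single level; covariate dropped")
            X = sm.add_constant(pd.DataFrame({"ic50": x}))
        else:
            dummies = pd.get_dummies(stage_al, prefix="stage", drop_first=True)
            X = sm.add_constant(
                pd.concat(
                    [pd.Series(x, index=stage_al.index, name="ic50"), dummies], axis=1
                )
            ).astype(float)
        fit = sm.OLS(y, np.asarray(X)).fit()
        # column 1 is the IC50 term (column 0 is the constant)
        adjusted_p = float(fit.pvalues[1])

    return SurvivalAssociationRecord(
        drug_id=drug_id,
        t_statistic=t,
        t_p_value=t_p,
        wilcoxon_statistic=float(w),
        wilcoxon_p_value=float(w_p),
        adjusted_p=adjusted_p,
        n_alive=len(alive),
        n_dead=len(dead),
    )


def invitro_records_to_frame(records: Sequence[InVitroValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "mean_auc_sensitive": r.mean_auc_sensitive,
                "mean_auc_resistant": r.mean_auc_resistant,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "validated": "NA" if r.validated is None else r.validated,
                "reason": r.reason,
            }
            for r in records
        ]
    ).set_index("drug_id")
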