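"""Model/Results surface for the whole repurposing screen.

:class:`DrugRepurposingScreen` bundles the training panel, the target
cohorts and the run configuration; :meth:`~DrugRepurposingScreen.fit`
runs imputation, SOC stratification, the per-platform differential
screen and the cross-platform intersection, returning a
:class:`ScreenResults` that carries the predictions, the per-drug
statistics, the final candidate list, and convenience methods for the
downstream validation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .datatypes import (
    ChemoscreenError,
    DrugResponseTable,
    ExpressionMatrix,
    PredictionMatrix,
    RunConfig,
)
from .imputation import impute_all
from .screen import (
    CandidateSet,
    SOCStratification,
    compute_soc_score,
    correlate_with_soc,
    correlation_records_to_frame,
    differential_screen,
    intersect_candidates,
    screen_records_to_frame,
    stratify,
)
from .validation import invitro_validate, replicate_screen

__all__ = ["DrugRepurposingScreen", "ScreenResults"]


class DrugRepurposingScreen:
    """Expression-trained drug-repurposing screen for SOC-resistant tumors.

    Parameters
    ----------
    train_expr :
        Cell-line training expression (genes x lines, log scale).
    train_response :
        Cell-line drug responses (lines x drugs, log-IC50).
    cohorts :
        One target expression cohort per profiling platform. Every
        cohort is homogenized with the training panel independently.
    config :
        Run parameters; defaults encode the standard study conditions.

    Examples
    --------
    >>> model = DrugRepurposingScreen(expr, response, cohorts)
    >>> results = model.fit()
    >>> results.candidates.final
    ['candidate_01', ...]
    """

    def __init__(
        self,
        train_expr: ExpressionMatrix,
        train_response: DrugResponseTable,
        cohorts: Sequence[ExpressionMatrix],
        config: RunConfig | None = None,
    ) -> None:
        self.train_expr = train_expr
        self.train_response = train_response
        self.cohorts = list(cohorts)
        self.config = config if config is not None else RunConfig()
        if not self.cohorts:
            raise ChemoscreenError("need at least one target cohort")
        names = [c.platform for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ChemoscreenError(f"cohort platform labels must be unique: {names}")

    @classmethod
    def from_files(
        cls,
        train_expr_path,
        train_response_path,
        cohort_paths: Sequence[tuple],
        config: RunConfig | None = None,
        expr_format: str = "tsv",
    ) -> "DrugRepurposingScreen":
        """Build the model from files; ``cohort_paths`` is a sequence of
        (path, platform_label) pairs."""
        from .io import read_drug_response, read_expression

        train_expr = read_expression(train_expr_path, format=expr_format)
        train_response = read_drug_response(train_response_path, measure="log_ic50")
        cohorts = [
            read_expression(path, format=expr_format, platform=platform)
            for path, platform in cohort_paths
        ]
        return cls(train_expr, train_response, cohorts, config=config)

    def fit(self) -> "ScreenResults":
        """Impute per-drug IC50s for every cohort, stratify by SOC score,
        run the differential screen per platform, and intersect."""
        cfg = self.config
        predictions, details = impute_all(
            self.train_expr, self.train_response, self.cohorts, cfg,
            return_details=True,
        )
        stratifications: dict[str, SOCStratification] = {}
        screen_tables: dict[str, pd.DataFrame] = {}
        correlation_tables: dict[str, pd.DataFrame] = {}
        per_platform: dict[str, list] = {}
        for pred in predictions:
            soc = compute_soc_score(pred, cfg.soc_drugs)
            strat = stratify(soc, cfg.resistant_fraction, rule="top_quantile")
            records = differential_screen(
                pred, strat, alpha=cfg.alpha, soc_drugs=cfg.soc_drugs
            )
            corr = correlate_with_soc(pred, soc, soc_drugs=cfg.soc_drugs)
            stratifications[pred.platform] = strat
            screen_tables[pred.platform] = screen_records_to_frame(records)
            correlation_tables[pred.platform] = correlation_records_to_frame(corr)
            per_platform[pred.platform] = sorted(
                r.drug_id for r in records if r.candidate
            )
        candidates = intersect_candidates(per_platform)
        model_summaries = {
            pred.platform: det for pred, det in zip(predictions, details)
        }
        return ScreenResults(
            model=self,
            config=cfg,
            predictions={p.platform: p for p in predictions},
            stratifications=stratifications,
            screen_tables=screen_tables,
            correlation_tables=correlation_tables,
            candidates=candidates,
            model_summaries=model_summaries,
        )


@dataclass
class ScreenResults:
    """Fitted screen: imputed IC50 surfaces, per-platform statistics and
    the final candidate drug list."""

    model: DrugRepurposingScreen
    config: RunConfig
    predictions: dict
    stratifications: dict
    screen_tables: dict
    correlation_tables: dict
    candidates: CandidateSet
    model_summaries: dict = field(default_factory=dict)

    @property
    def platforms(self) -> list:
        return list(self.predictions)

    def validate_invitro(
        self,
        pred_cell_lines: PredictionMatrix,
        measured: DrugResponseTable,
        candidates: Sequence[str] | None = None,
    ):
        """One-sided AUC validation of the final candidates on a
        measured cell-line screen (see :func:`~chemoscreen.validation.invitro_validate`)."""
        return invitro_validate(
            pred_cell_lines,
            measured,
            candidates if candidates is not None else self.candidates.final,
            alpha=self.config.alpha,
            soc_drugs=self.config.soc_drugs,
        )

    def replicate(self, pred: PredictionMatrix, cutoffs=(0.20, 0.50)):
        """Re-run the screen on an independent cohort's predictions at
        additional stratification cutoffs."""
        return replicate_screen(pred, self.config, cutoffs=cutoffs)

    def summary(self) -> str:
        """Human-readable run summary shaped like the candidate table:
        per platform counts and, for each final candidate, the group
        means and t-test p-value on every platform."""
        cfg = self.config
        lines = [
            "Drug repurposing screen for SOC-resistant samples",
            "=" * 58,
            f"SOC drugs: {', '.join(cfg.soc_drugs)}   "
            f"resistant fraction: {cfg.resistant_fraction:g}   alpha: {cfg.alpha:g}",
            f"platforms: {', '.join(self.platforms)}",
            "",
            "Per-platform candidates:",
        ]
        for platform, table in self.screen_tables.items():
            n_cand = int(table["candidate"].sum())
            lines.append(
                f"  {platform}: {n_cand} candidate(s) of {len(table)} screened drugs"
            )
        lines.append("")
        lines.append(f"Final candidates (intersection): {len(self.candidates.final)}")
        for drug in self.candidates.final:
            lines.append(f"  {drug}")
            for platform, table in self.screen_tables.items():
                row = table.loc[drug]
                lines.append(
                    f"    {platform:<14} responders {row['mean_responder']:.3f}  "
                    f"non-responders {row['mean_non_responder']:.3f}  "
                    f"p {row['p_value']:.3g}"
                )
        return "\n".join(lines)

    def to_dir(self, out_dir) -> dict:
        """Write predictions, screen tables, correlations and the final
        candidate list as TSVs; returns {name: path}."""
        from pathlib import Path

        from .io import write_predictions

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {}
        for platform, pred in self.predictions.items():
            p = out_dir / f"predictions_{platform}.tsv"
            write_predictions(pred, p)
            written[f"predictions_{platform}"] = str(p)
        for platform, table in self.screen_tables.items():
            p = out_dir / f"screen_{platform}.tsv"
            table.to_csv(p, sep="\t")
            written[f"screen_{platform}"] = str(p)
        for platform, table in self.correlation_tables.items():
            p = out_dir / f"correlations_{platform}.tsv"
            table.to_csv(p, sep="\t")
            written[f"correlations_{platform}"] = str(p)
        p = out_dir / "final_candidates.tsv"
        pd.Series(self.candidates.final, name="drug_id").to_csv(
            p, sep="\t", index=False
        )
        written["final_candidates"] = str(p)
        for platform, summary in self.model_summaries.items():
            if len(summary):
                p = out_dir / f"model_summary_{platform}.tsv"
                summary.to_csv(p, sep="\t")
                written[f"model_summary_{platform}"] = str(p)
        return written
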