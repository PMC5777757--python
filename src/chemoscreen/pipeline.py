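"""End-to-end orchestration: simulate -> impute+screen -> validate -> GSEA.

One YAML config drives the whole run; all randomness flows from one root
seed split deterministically per stage; a JSON manifest records the
config echo, per-stage outputs with SHA-256 digests, the seed and the
package version. The manifest is written even when a stage fails (the
failing stage is named).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import ChemoscreenError, RunConfig
from .enrichment import (
    enrichment_results_to_frame,
    opposite_sign_filter,
    permutation_null,
)
from .imputation import impute_all
from .io import write_drug_response, write_expression, write_gmt
from .model import DrugRepurposingScreen
from .screen import compute_soc_score
from .synthetic import (
    DEFAULT_PLATFORMS,
    PlatformEffect,
    generate_cell_line_panel,
    generate_measured_auc,
    generate_tumor_cohorts,
)
from .validation import invitro_records_to_frame, invitro_validate, replicate_screen

logger = logging.getLogger(__name__)

__all__ = ["run_all", "derive_seed", "load_pipeline_config"]

_SIMULATE_KEYS = {
    "n_lines", "n_genes", "n_drugs", "n_candidates", "n_programs",
    "block_fraction", "coupling", "noise_sd_expression", "noise_sd_response",
    "n_tumors", "platforms", "auc_noise_sd",
}
_GSEA_KEYS = {"enabled", "n_decoy_sets", "decoy_set_size", "n_permutations"}


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_pipeline_config(path) -> tuple[RunConfig, dict, dict]:
    """Split the YAML config into (RunConfig, simulate section, gsea section).

    Schema violations (unknown keys anywhere) raise before any compute.
    """
    path = Path(path)
    if not path.exists():
        raise ChemoscreenError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ChemoscreenError("pipeline config must be a YAML mapping")
    simulate = raw.pop("simulate", {}) or {}
    gsea = raw.pop("gsea", {}) or {}
    unknown = set(simulate) - _SIMULATE_KEYS
    if unknown:
        raise ChemoscreenError(f"unknown simulate config keys: {sorted(unknown)}")
    unknown = set(gsea) - _GSEA_KEYS
    if unknown:
        raise ChemoscreenError(f"unknown gsea config keys: {sorted(unknown)}")
    config = RunConfig.from_dict(raw)
    return config, simulate, gsea


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _platforms_from_config(spec: Mapping | None) -> dict[str, PlatformEffect]:
    if not spec:
        return dict(DEFAULT_PLATFORMS)
    return {name: PlatformEffect(**params) for name, params in spec.items()}


def run_all(config_path, out_dir, record_timestamps: bool = True) -> dict:
    """Run every stage in order and return the manifest dict.

    Stage outputs are pure functions of (config, seed); the manifest's
    digest table is therefore stable across same-seed reruns.
    """
    from . import __version__

    config, sim_cfg, gsea_cfg = load_pipeline_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "simulate_config": dict(sim_cfg),
        "gsea_config": dict(gsea_cfg),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    if record_timestamps:
        manifest["started_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    current_stage = "simulate"
    try:
        # ---- simulate -------------------------------------------------
        platforms = _platforms_from_config(sim_cfg.pop("platforms", None))
        n_tumors = sim_cfg.pop("n_tumors", 200)
        auc_noise = sim_cfg.pop("auc_noise_sd", 0.5)
        panel_expr, panel_response, truth = generate_cell_line_panel(
            soc_drugs=config.soc_drugs,
            seed=derive_seed(config.seed, "panel"),
            **sim_cfg,
        )
        cohorts, true_soc = generate_tumor_cohorts(
            truth, n_tumors=n_tumors, platforms=platforms,
            seed=derive_seed(config.seed, "tumors"),
        )
        measured_auc = generate_measured_auc(
            truth, panel_response, noise_sd=auc_noise,
            seed=derive_seed(config.seed, "auc"),
        )
        write_expression(panel_expr, out_dir / "train_expression.tsv")
        write_drug_response(panel_response, out_dir / "train_response.csv")
        for cohort in cohorts:
            write_expression(cohort, out_dir / f"cohort_{cohort.platform}.tsv")
        write_drug_response(measured_auc, out_dir / "measured_auc.csv")
        true_soc.to_csv(out_dir / "true_soc_resistance.tsv", sep="\t")
        register("train_expression", out_dir / "train_expression.tsv")
        register("train_response", out_dir / "train_response.csv")
        for cohort in cohorts:
            register(f"cohort_{cohort.platform}", out_dir / f"cohort_{cohort.platform}.tsv")
        register("measured_auc", out_dir / "measured_auc.csv")
        register("true_soc_resistance", out_dir / "true_soc_resistance.tsv")
        manifest["stages"]["simulate"] = {
            "planted_candidates": truth.planted_candidates,
            "platforms": [c.platform for c in cohorts],
        }

        # ---- impute + screen -----------------------------------------
        current_stage = "screen"
        model = DrugRepurposingScreen(panel_expr, panel_response, cohorts, config)
        results = model.fit()
        written = results.to_dir(out_dir)
        for name, path in written.items():
            register(name, Path(path))
        manifest["stages"]["screen"] = {
            "per_platform_candidates": dict(results.candidates.per_platform),
            "final_candidates": results.candidates.final,
        }

        # ---- validate -------------------------------------------------
        current_stage = "validate"
        # impute the training panel's own lines to score SOC for in vitro
        (panel_pred,) = impute_all(panel_expr, panel_response, [panel_expr], config)
        from .io import write_predictions

        write_predictions(panel_pred, out_dir / "predictions_cell_lines.tsv")
        register("predictions_cell_lines", out_dir / "predictions_cell_lines.tsv")
        invitro = invitro_validate(
            panel_pred, measured_auc, results.candidates.final,
            alpha=config.alpha, soc_drugs=config.soc_drugs,
        )
        invitro_frame = invitro_records_to_frame(invitro)
        invitro_frame.to_csv(out_dir / "invitro_validation.tsv", sep="\t")
        register("invitro_validation", out_dir / "invitro_validation.tsv")

        first = results.predictions[results.platforms[0]]
        replication = replicate_screen(first, config, cutoffs=(config.resistant_fraction, 0.50))
        rep_rows = []
        for cutoff, rep in replication.items():
            for drug in rep.candidates:
                rep_rows.append({"cutoff": cutoff, "drug_id": drug})
        pd.DataFrame(rep_rows, columns=["cutoff", "drug_id"]).to_csv(
            out_dir / "replication_candidates.tsv", sep="\t", index=False
        )
        register("replication_candidates", out_dir / "replication_candidates.tsv")
        manifest["stages"]["validate"] = {
            "validated_invitro": [
                r.drug_id for r in invitro if r.validated
            ],
            "replication_cutoffs": sorted(replication),
        }

        # ---- gsea -----------------------------------------------------
        current_stage = "gsea"
        if gsea_cfg.get("enabled", True):
            n_perm = int(gsea_cfg.get("n_permutations", config.n_permutations))
            n_decoys = int(gsea_cfg.get("n_decoy_sets", 10))
            decoy_size = int(gsea_cfg.get("decoy_set_size", 25))
            sets = dict(truth.planted_gene_sets().sets)
            sets.update(
                truth.decoy_gene_sets(
                    n_sets=n_decoys, set_size=decoy_size,
                    seed=derive_seed(config.seed, "gsea_decoys"),
                ).sets
            )
            from .datatypes import GeneSetCollection

            collection = GeneSetCollection(sets, source="synthetic truth + decoys")
            write_gmt(collection, out_dir / "gene_sets.gmt")
            register("gene_sets", out_dir / "gene_sets.gmt")

            expr0 = cohorts[0]
            soc = compute_soc_score(first, config.soc_drugs)
            phenos = {"SOC": soc}
            for drug in results.candidates.final:
                phenos[drug] = first.data[drug]
            all_results = {}
            frames = []
            for pid, pheno in phenos.items():
                res = permutation_null(
                    expr0, pheno, collection,
                    n_permutations=n_perm,
                    seed=derive_seed(config.seed, f"gsea_{pid}"),
                    phenotype_id=pid,
                    min_size=config.gsea_min_set_size,
                    max_size=config.gsea_max_set_size,
                    weight_exponent=config.gsea_weight_exponent,
                )
                all_results[pid] = res
                frames.append(enrichment_results_to_frame(res).assign(phenotype=pid))
            pd.concat(frames).to_csv(out_dir / "gsea_results.tsv", sep="\t")
            register("gsea_results", out_dir / "gsea_results.tsv")
            opposition_pathways: list = []
            if results.candidates.final:
                opposition = opposite_sign_filter(
                    all_results["SOC"],
                    {d: all_results[d] for d in results.candidates.final},
                    q_threshold=config.gsea_fdr_q,
                )
                opposition_pathways = opposition.pathways
            pd.Series(opposition_pathways, name="pathway").to_csv(
                out_dir / "opposition_pathways.tsv", sep="\t", index=False
            )
            register("opposition_pathways", out_dir / "opposition_pathways.tsv")
            manifest["stages"]["gsea"] = {"opposition_pathways": opposition_pathways}

        manifest["status"] = "ok"
    except Exception as err:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(err)
        raise ChemoscreenError(f"stage {current_stage!r} failed: {err}") from err
    finally:
        if record_timestamps:
            manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest
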