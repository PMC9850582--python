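"""End-to-end pipeline: (simulate | ingest) -> consensus clustering ->
signature derivation -> score fitting -> projection -> evaluation.

One YAML configuration drives the whole run; every stage persists its
artifact into the output directory and a manifest records parameters,
derived seeds and input checksums so a run can be audited and re-entered
stage by stage. Stage seeds are derived from the global seed by fixed
offsets, so a fixed config yields byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ValidationError
from .io_formats import (
    ExpressionMatrix, PhenotypeTable, FerroptosisGeneSet,
    read_expression, read_phenotypes, read_gene_set,
    write_expression, write_phenotypes, write_gene_set,
    save_model,
)
from .synthetic import CohortConfig, generate_cohort, attach_survival
from .consensus import consensus_cluster, subset_to_panel
from .diffexp import moderated_t_test, derive_signatures
from .scoring import fit_score_model, project_scores, write_scores
from .evaluation import roc_auc, compare_groups, survival_report

logger = logging.getLogger(__name__)

# seed offsets per stage, applied to the global seed
SEED_OFFSETS = {"training": 0, "clustering": 1000, "validation": 2000}

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "output_dir": str,
    "panel": (str, type(None)),
    "training": dict,
    "validation": list,
    "clustering": dict,
    "de": dict,
    "scoring": dict,
    "evaluation": dict,
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "panel": None,
    "validation": [],
    "clustering": {"k_min": 2, "k_max": 9, "resamples": 200, "fraction": 0.8,
                   "base": "hierarchical", "select": "pac"},
    "de": {"lfc": 0.5, "fdr": 0.05},
    "scoring": {"scale": False},
    "evaluation": {"positive_label": "TCMR", "horizon_days": 1095.0,
                   "split": "median"},
}

_COHORT_KEYS = {"name", "expression", "phenotypes", "dialect", "log2", "simulate"}


def validate_config(config: dict) -> dict:
    """Resolve defaults, reject unknown keys, aggregate all errors."""
    errors: list[str] = []
    normalized = json.loads(json.dumps(_DEFAULTS))
    for key in config:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, value in config.items():
        if key in _SCHEMA:
            expected = _SCHEMA[key]
            if not isinstance(value, expected):
                errors.append(f"{key}: expected {expected}, got {type(value).__name__}")
            elif isinstance(value, dict) and key in _DEFAULTS and isinstance(_DEFAULTS[key], dict):
                merged = dict(_DEFAULTS[key])
                for sub, subval in value.items():
                    if key in ("clustering", "de", "scoring", "evaluation") \
                            and sub not in merged:
                        errors.append(f"{key}.{sub}: unknown key")
                    else:
                        merged[sub] = subval
                normalized[key] = merged
            else:
                normalized[key] = value
    if "training" not in config:
        errors.append("training: required (paths or a 'simulate' block)")
    for label, cohort in [("training", normalized.get("training", {}))] + [
            (f"validation[{i}]", c) for i, c in enumerate(normalized.get("validation", []))]:
        if not isinstance(cohort, dict):
            errors.append(f"{label}: expected a mapping")
            continue
        for sub in cohort:
            if sub not in _COHORT_KEYS:
                errors.append(f"{label}.{sub}: unknown key")
        if "simulate" not in cohort and "expression" not in cohort:
            errors.append(f"{label}: needs either 'simulate' or 'expression'")
    de = normalized.get("de", {})
    if not isinstance(de.get("lfc", 0.5), (int, float)) or de.get("lfc", 0.5) <= 0:
        errors.append("de.lfc: threshold must be > 0")
    if not (0 < de.get("fdr", 0.05) <= 1):
        errors.append("de.fdr: must lie in (0, 1]")
    clustering = normalized.get("clustering", {})
    if clustering.get("k_min", 2) < 2:
        errors.append("clustering.k_min: must be >= 2")
    if clustering.get("k_max", 9) < clustering.get("k_min", 2):
        errors.append("clustering.k_max: must be >= k_min")
    for path_key in ("panel",):
        value = normalized.get(path_key)
        if value is not None and not Path(value).exists():
            errors.append(f"{path_key}: path {value!r} does not exist")
    if errors:
        raise ValidationError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return normalized


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


@dataclass
class _Cohort:
    name: str
    matrix: ExpressionMatrix
    phenotypes: PhenotypeTable
    truth: Any = None


def _load_cohort(spec: dict, name: str, seed: int,
                 manifest: dict) -> tuple[_Cohort, FerroptosisGeneSet | None]:
    panel = None
    if "simulate" in spec:
        params = dict(spec["simulate"])
        params.setdefault("seed", seed)
        config = CohortConfig(**params)
        matrix, phenotypes, truth = generate_cohort(config)
        if config.hazard_ratio_per_sd is not None:
            phenotypes = attach_survival(phenotypes, truth.latent_scores, config)
        from .synthetic import generate_gene_universe

        panel, _ = generate_gene_universe(config)
        manifest["cohorts"][name] = {"simulated": config.to_dict()}
        return _Cohort(name, matrix, phenotypes, truth), panel
    expr_path = Path(spec["expression"])
    matrix = read_expression(expr_path, dialect=spec.get("dialect", "tsv"),
                             log2_transform=bool(spec.get("log2", False)))
    phenotypes = read_phenotypes(Path(spec["phenotypes"]))
    manifest["cohorts"][name] = {
        "expression": str(expr_path), "expression_sha256": _sha256(expr_path),
        "phenotypes": spec["phenotypes"],
        "phenotypes_sha256": _sha256(Path(spec["phenotypes"])),
    }
    return _Cohort(name, matrix, phenotypes, None), panel


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Artifacts: panel.tsv, expression/phenotypes per simulated cohort,
    clusters.json, de_table.tsv, signatures.json, model.json, per-cohort
    scores_<name>.tsv and evaluation_<name>.json, survival_<name>.json
    where follow-up exists, and manifest.json.
    """
    config = validate_config(config)
    run_dir = Path(out_dir or config["output_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("ferroscore").addHandler(handler)
    seed = int(config["seed"])
    manifest: dict = {"version": __version__, "seed": seed,
                      "parameters": config, "cohorts": {}, "stages": []}
    stage = "ingest-training"
    try:
        training, sim_panel = _load_cohort(config["training"], "training",
                                           seed + SEED_OFFSETS["training"], manifest)
        if config["panel"] is not None:
            panel = read_gene_set(config["panel"])
            manifest["cohorts"]["panel"] = {
                "path": config["panel"], "sha256": _sha256(Path(config["panel"]))}
        elif sim_panel is not None:
            panel = sim_panel
        else:
            raise ValidationError("no gene panel: set 'panel' or simulate training")
        write_gene_set(panel, run_dir / "panel.tsv")
        if training.truth is not None:
            write_expression(training.matrix, run_dir / "expression_training.tsv")
            write_phenotypes(training.phenotypes, run_dir / "phenotypes_training.csv")
        manifest["stages"].append(stage)

        stage = "clustering"
        clus = config["clustering"]
        panel_matrix = subset_to_panel(training.matrix, panel)
        result = consensus_cluster(
            panel_matrix,
            k_range=range(int(clus["k_min"]), int(clus["k_max"]) + 1),
            n_resamples=int(clus["resamples"]),
            subsample_fraction=float(clus["fraction"]),
            seed=seed + SEED_OFFSETS["clustering"],
            base=clus["base"], select=clus["select"],
        )
        clusters_payload = {
            "chosen_k": result.chosen_k,
            "labels": result.labels,
            "pac": {str(k): result.pac[k] for k in result.k_range},
            "delta_area": {str(k): result.delta_area[k] for k in result.k_range},
        }
        (run_dir / "clusters.json").write_text(json.dumps(clusters_payload, indent=2))
        manifest["stages"].append(stage)

        stage = "signatures"
        diagnosis = training.phenotypes.diagnosis_of()
        positive = config["evaluation"]["positive_label"]
        label_series = pd.Series(result.labels)
        # the case-enriched cluster: highest fraction of positive diagnoses
        fractions = {
            c: float((diagnosis.loc[label_series.index[label_series == c]] == positive).mean())
            for c in sorted(set(label_series))
        }
        case_cluster = max(sorted(fractions), key=lambda c: fractions[c])
        de_result = moderated_t_test(panel_matrix, label_series,
                                     case_group=case_cluster)
        de_result.table.to_csv(run_dir / "de_table.tsv", sep="\t", index=False)
        signatures = derive_signatures(de_result, lfc_threshold=float(config["de"]["lfc"]),
                                       fdr_threshold=float(config["de"]["fdr"]))
        (run_dir / "signatures.json").write_text(json.dumps({
            "signature_A": signatures.signature_A,
            "signature_B": signatures.signature_B,
            "case_cluster": int(case_cluster),
            "cluster_case_fractions": fractions,
            "lfc_threshold": signatures.lfc_threshold,
            "fdr_threshold": signatures.fdr_threshold,
        }, indent=2))
        manifest["stages"].append(stage)

        stage = "fit"
        model = fit_score_model(training.matrix, signatures,
                                labels=diagnosis, case_label=positive,
                                scale=bool(config["scoring"]["scale"]))
        save_model(model, run_dir / "model.json")
        manifest["stages"].append(stage)

        stage = "score-evaluate"
        cohorts = [training]
        for i, spec in enumerate(config["validation"]):
            name = spec.get("name", f"validation{i}")
            cohort, _ = _load_cohort(spec, name,
                                     seed + SEED_OFFSETS["validation"] + i, manifest)
            cohorts.append(cohort)
        for cohort in cohorts:
            scores = project_scores(model, cohort.matrix)
            write_scores(scores, run_dir / f"scores_{cohort.name}.tsv")
            diag = cohort.phenotypes.diagnosis_of().loc[scores.index]
            report: dict = {"cohort": cohort.name, "n_samples": int(len(scores))}
            binary = (diag == positive).astype(int)
            if 0 < binary.sum() < len(binary):
                roc = roc_auc(scores.to_numpy(), binary.to_numpy())
                t_stat, p = compare_groups(scores.to_numpy(), binary.to_numpy())
                report["roc"] = roc.to_dict()
                report["t_test"] = {"t": t_stat, "p": p}
            surv = cohort.phenotypes.survival()
            if len(surv) and surv["event"].sum() > 0:
                surv = surv.set_index("sample_id").loc[scores.index.intersection(
                    surv["sample_id"] if "sample_id" in surv else surv.index)]
                sreport = survival_report(
                    scores.loc[surv.index], surv["time"].to_numpy(),
                    surv["event"].to_numpy(),
                    horizon=float(config["evaluation"]["horizon_days"]),
                    split=config["evaluation"]["split"],
                )
                (run_dir / f"survival_{cohort.name}.json").write_text(
                    json.dumps(sreport.to_dict(), indent=2))
                report["logrank_p"] = sreport.logrank_p
            (run_dir / f"evaluation_{cohort.name}.json").write_text(
                json.dumps(report, indent=2))
        manifest["stages"].append(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.error("pipeline aborted at stage %s: %s", stage, err)
        raise
    finally:
        logging.getLogger("ferroscore").removeHandler(handler)
        handler.close()
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return run_dir


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle) or {}
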