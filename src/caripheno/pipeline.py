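"""End-to-end desk-scale pipeline: cohorts in, harmonized phenotypes out.

One configuration drives the full chain: load (or simulate) surface-level
cohorts, compute tier-1/2 phenotypes and tier-3 cluster scores per subject,
roll each cohort up into a summary row, meta-regress cohort cluster means on
cohort mean age, and evaluate the requested GWAS power specs.  Every output
is a CSV re-readable by the module that defines its schema, and a manifest
records the path and SHA-256 checksum of each artifact so that reruns with
the same configuration and seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import dentition, metareg, phenotypes, power
from .clusters import load_cluster_map, score_frame, summarize_cohort
from .metareg import CohortPoint, standard_error_of_mean
from .simulate import SyntheticCohortParams, generate_consortium

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return json.loads(Path(config).read_text())
    return dict(config)


def _cohorts_from_config(cfg: dict):
    """Yield (name, records, truth-or-None) per cohort from input or simulation."""
    has_inputs = bool(cfg.get("input_csvs"))
    has_sim = bool(cfg.get("simulate"))
    if has_inputs == has_sim:
        raise ConfigError(
            "exactly one of 'input_csvs' and 'simulate' must be configured")
    if has_inputs:
        loader = cfg.get("loader", {})
        for path in cfg["input_csvs"]:
            records = dentition.read_surface_csv(
                path,
                icdas_threshold=int(loader.get("icdas_threshold", 3)),
                unlisted_policy=loader.get("unlisted_policy", "error"),
                tooth_numbering=loader.get("tooth_numbering", "fdi"),
            )
            yield Path(path).stem, records, None
    else:
        sim = cfg["simulate"]
        params = [SyntheticCohortParams(**p) for p in sim["cohorts"]]
        cohorts = generate_consortium(params, master_seed=sim.get("master_seed"))
        for p, (records, truth) in zip(params, cohorts):
            yield p.name, records, truth


def run_pipeline(config) -> dict:
    """Run the full pipeline; returns the manifest (paths and checksums)."""
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = load_cluster_map(cfg.get("cluster_map"))

    outputs: list[Path] = []
    summary_rows = []
    cluster_points: dict[int, list[CohortPoint]] = {c: [] for c in cmap.cluster_ids}

    for name, records, truth in _cohorts_from_config(cfg):
        cohort_dir = out_dir / name
        cohort_dir.mkdir(exist_ok=True)
        surfaces_csv = cohort_dir / "surfaces.csv"
        dentition.write_surface_csv(records, surfaces_csv)
        outputs.append(surfaces_csv)
        if truth is not None:
            truth_json = cohort_dir / "truth.json"
            truth_json.write_text(json.dumps(truth, indent=2, default=str))
            outputs.append(truth_json)

        pheno = phenotypes.phenotype_frame(records)
        pheno_csv = cohort_dir / "phenotypes.csv"
        pheno.to_csv(pheno_csv, index=False)
        outputs.append(pheno_csv)

        scores = score_frame(records, cmap)
        scores_csv = cohort_dir / "cluster_scores.csv"
        scores.to_csv(scores_csv, index=False)
        outputs.append(scores_csv)

        summary = summarize_cohort(records, cmap)
        row = summary.to_row(cohort=name)
        summary_rows.append(row)
        pd.DataFrame([row]).to_csv(cohort_dir / "summary.csv", index=False)
        outputs.append(cohort_dir / "summary.csv")

        for c in cmap.cluster_ids:
            col = scores[f"c{c}"]
            if len(col) > 1 and col.std() > 0:
                mean, se = standard_error_of_mean(col)
                cluster_points[c].append(
                    CohortPoint(estimate=mean, se=se,
                                covariate=row["age_mean"], n=row["n"], cohort=name)
                )
        logger.info("cohort %s: %d subjects scored", name, len(records))

    summary_csv = out_dir / "cohort_summaries.csv"
    pd.DataFrame(summary_rows).to_csv(summary_csv, index=False)
    outputs.append(summary_csv)

    fit_rows = []
    for c, points in cluster_points.items():
        if len(points) >= 3:
            fit = metareg.fit_meta_regression(
                points, weight_scheme=cfg.get("weight_scheme", "inverse_variance"))
            fit_rows.append({
                "cluster": c, "n_cohorts": len(points),
                "slope": fit.slope, "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "ci95_lo": fit.slope_ci95[0], "ci95_hi": fit.slope_ci95[1],
            })
    metareg_csv = out_dir / "meta_regression.csv"
    pd.DataFrame(
        fit_rows,
        columns=["cluster", "n_cohorts", "slope", "slope_se", "intercept",
                 "ci95_lo", "ci95_hi"],
    ).to_csv(metareg_csv, index=False)
    outputs.append(metareg_csv)

    power_rows = []
    for spec in cfg.get("power", []):
        kind = spec.get("trait_type", "quantitative")
        alpha = float(spec.get("alpha", power.GENOME_WIDE_ALPHA))
        if kind == "quantitative":
            res = power.quantitative_power(
                int(spec["n"]), float(spec["variance_explained_pct"]), alpha)
        elif kind == "binary":
            res = power.binary_power(
                int(spec["n_cases"]), int(spec["n_controls"]),
                float(spec["maf"]), float(spec["odds_ratio"]), alpha)
        else:
            raise ConfigError(f"unknown power trait_type: {kind!r}")
        power_rows.append({**spec, "power": res.power, "ncp": res.ncp})
    power_csv = out_dir / "power_report.csv"
    pd.DataFrame(power_rows).to_csv(power_csv, index=False)
    outputs.append(power_csv)

    manifest = {
        "outputs": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for p in outputs
        ]
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
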