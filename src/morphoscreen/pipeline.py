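"""One-command end-to-end run: simulate -> qc -> reduce -> separate ->
train -> score -> call-hits -> enrich, with a machine-readable report.

Per-stage seeds are derived deterministically from the single root seed,
so one integer reproduces a whole screen; identical config + seed yields
identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, enrich, hits, qc, reduction, separation
from .config import PipelineConfig
from .design import build_design
from .io import write_feature_table
from .manifest import default_library_manifest, write_manifest
from .simulate import SimulationParams, simulate_screen

logger = logging.getLogger("morphoscreen")

STAGES = [
    "simulate", "qc", "reduce", "separate", "train", "score", "call_hits", "enrich",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _packaged(name: str) -> Path:
    return Path(resources.files("morphoscreen").joinpath("data", name))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    write_tables: bool = False,
) -> dict:
    """Execute every stage and return the screen report dict.

    When ``outdir`` is given, stage outputs (config echo, QC report,
    model, scores, separation, classifier report, hit table, enrichment
    TSV, report JSON) are written there; partial outputs are retained if
    a later stage fails.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    seeds = stage_seeds(config.seed)
    report: dict = {"config": config.model_dump(), "stage_seeds": seeds}
    t0 = time.time()

    def _run(stage, fn):
        try:
            logger.info("stage %s ...", stage)
            return fn()
        except Exception as e:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, e) from e

    # ---- simulate
    def _simulate():
        design = build_design(**config.design.model_dump())
        params = SimulationParams(**config.simulation.model_dump(), seed=seeds["simulate"])
        table, truth = simulate_screen(design, params)
        manifest = default_library_manifest(design.n_compounds)
        return design, table, truth, manifest

    design, image_table, truth, manifest = _run("simulate", _simulate)
    report["design"] = {
        "n_plates": design.n_plates,
        "n_compounds": design.n_compounds,
        "wt_vehicle_wells_per_plate": design.wt_vehicle_wells_per_plate,
        "ko_vehicle_wells_per_plate": design.ko_vehicle_wells_per_plate,
        "ko_untreated_wells_per_plate": design.ko_untreated_wells_per_plate,
        "fields_per_well": design.fields_per_well,
        "wells_per_plate": design.wells_per_plate,
    }
    if out is not None:
        truth.to_json(out / "ground_truth.json")
        write_manifest(manifest, out / "manifest.csv")
        if write_tables:
            write_feature_table(image_table, out / "image_features.csv")

    # ---- qc
    def _qc():
        well_table, qc_report = qc.run_qc(
            image_table,
            anchor=config.qc.anchor,
            rank_tol=config.qc.rank_tol,
            r_threshold=config.qc.r_threshold,
            alpha=config.qc.alpha,
            statistic=config.qc.aggregation,
        )
        # image-level table normalized and restricted to the retained features
        norm_images, _ = qc.normalize_to_controls(image_table, anchor=config.qc.anchor)
        meta = [c for c in ("plate_id", "well", "subclone_id", "genotype",
                            "treatment", "concentration_nM", "field")
                if c in norm_images.columns]
        norm_images = norm_images[meta + qc_report.feature_names]
        return well_table, qc_report, norm_images

    well_table, qc_report, image_norm = _run("qc", _qc)
    report["qc"] = {
        "n_input_features": qc_report.n_input_features,
        "n_dropped_degenerate": len(qc_report.dropped_degenerate),
        "n_dropped_redundant": len(qc_report.dropped_redundant),
        "n_retained": qc_report.n_retained,
        "n_significant": qc_report.n_significant,
        "n_untestable": len(qc_report.untestable),
    }
    if out is not None:
        qc_report.to_json(out / "qc_report.json")

    # ---- reduce
    def _reduce():
        fit_table = well_table
        if config.reduction.controls_only_fit:
            fit_table = well_table[well_table["treatment"].isin(["VEHICLE"])]
        model = reduction.fit_reduction(
            fit_table,
            rule=config.reduction.rule,
            k0=config.reduction.k0,
            rotate=config.reduction.rotate,
            gamma=config.reduction.gamma,
            seed=seeds["reduce"],
        )
        return model, model.transform(well_table), model.transform(image_norm)

    model, well_scores, image_scores = _run("reduce", _reduce)
    report["reduction"] = {
        "k": model.k,
        "rule": model.selection_rule,
        "rotated": model.rotate,
        "kaiser_k": int(np.sum(model.pca.eigenvalues > 1.0)),
        "top_eigenvalues": [float(v) for v in model.pca.eigenvalues[:5]],
    }
    if out is not None:
        model.to_json(out / "reduction_model.json")
        well_scores.to_csv(out / "well_scores.csv", index=False)

    # ---- separate
    def _separate():
        ctrl = well_scores[
            (well_scores["treatment"] == "VEHICLE")
        ]
        X = ctrl[model.score_names].to_numpy()
        return separation.permutation_test(
            X, ctrl["genotype"].to_numpy(),
            metric=config.separation.metric,
            n_perm=config.separation.n_perm,
            seed=seeds["separate"],
        )

    sep = _run("separate", _separate)
    report["separation"] = {
        "metric": sep.metric,
        "statistic": sep.statistic,
        "p_value": sep.p_value,
        "n_perm": sep.n_perm,
        "group_sizes": sep.group_sizes,
    }
    if out is not None:
        sep.to_json(out / "separation.json")

    # ---- train / evaluate
    def _train():
        spec = classify.ClassifierSpec(
            algorithm=config.classifier.algorithm,
            sizes=tuple(config.classifier.sizes),
            decays=tuple(config.classifier.decays),
            cv_folds=config.classifier.cv_folds,
            test_fraction=config.classifier.test_fraction,
            focus_class=config.classifier.focus_class,
            seed=seeds["train"],
        )
        controls = image_scores[image_scores["treatment"] == "VEHICLE"]
        train, test = classify.split_controls(controls, spec)
        trained = classify.train_classifier(train, spec)
        eval_report = classify.evaluate_classifier(trained, test)
        return trained, eval_report

    trained, clf_report = _run("train", _train)
    report["classifier"] = {
        "algorithm": clf_report.algorithm,
        "tp": clf_report.tp, "fp": clf_report.fp,
        "tn": clf_report.tn, "fn": clf_report.fn,
        "accuracy": clf_report.accuracy,
        "sensitivity": clf_report.sensitivity,
        "specificity": clf_report.specificity,
        "detection_rate": clf_report.detection_rate,
        "mean_focus_probability": clf_report.mean_focus_probability,
        "mean_focus_probability_well": clf_report.mean_focus_probability_well,
        "chosen_size": clf_report.chosen_size,
        "chosen_decay": clf_report.chosen_decay,
    }
    if out is not None:
        clf_report.to_json(out / "classifier_report.json")

    # ---- score treated
    def _score():
        treated = image_scores[
            ~image_scores["treatment"].isin(["VEHICLE", "UNTREATED"])
        ]
        return classify.score_treated(trained, treated)

    treated_scores = _run("score", _score)
    if out is not None:
        treated_scores.to_csv(out / "treated_scores.csv", index=False)

    # ---- call hits
    def _call_hits():
        hit_table = hits.call_hits(
            treated_scores, tau=config.hits.tau, mode=config.hits.mode
        )
        drug_table = hits.collapse_salt_forms(hit_table, manifest)
        mech = hits.summarize_by_mechanism(drug_table, manifest)
        recovery = hits.recovery_vs_truth(hit_table, truth.true_hits)
        return hit_table, drug_table, mech, recovery

    hit_table, drug_table, mech_summary, recovery = _run("call_hits", _call_hits)
    report["hits"] = {
        "tau": config.hits.tau,
        "mode": config.hits.mode,
        "n_compound_hits": int(hit_table["hit"].sum()),
        "n_drug_hits": int(len(drug_table)),
        "hit_compounds": sorted(hit_table.loc[hit_table["hit"], "compound_id"]),
        "mechanism_summary": mech_summary.to_dict(orient="records"),
        "recovery": recovery,
    }
    if out is not None:
        hit_table.to_csv(out / "hit_table.csv", index=False)
        drug_table.to_csv(out / "drug_hits.csv", index=False)
        mech_summary.to_csv(out / "mechanism_summary.csv", index=False)

    # ---- enrichment (on the fixture gene sets unless paths are given)
    def _enrich():
        gmt = config.enrichment.gmt_path or _packaged("genesets.gmt")
        expressed_path = config.enrichment.expressed_path or _packaged("expressed_genes.txt")
        collection = enrich.read_gmt(gmt)
        expressed = enrich.read_gene_list(expressed_path)
        targets = pd.read_csv(_packaged("drug_targets.csv"))
        hit_drugs = set(drug_table["parent_drug"])
        query = set(targets.loc[targets["parent_drug"].isin(hit_drugs), "target_gene"])
        if not query:
            return None
        query = enrich.filter_by_expression(query, expressed)
        if not query:
            return None
        return enrich.hypergeometric_enrichment(query, collection, expressed)

    enrichment_rows = _run("enrich", _enrich)
    if enrichment_rows is not None:
        sig = enrichment_rows[enrichment_rows["q"] < config.enrichment.alpha]
        report["enrichment"] = {
            "n_sets_tested": int(len(enrichment_rows)),
            "n_significant": int(len(sig)),
            "top_sets": enrichment_rows.head(5).to_dict(orient="records"),
        }
        if out is not None:
            enrich.write_enrichment_tsv(enrichment_rows, out / "enrichment.tsv")
    else:
        report["enrichment"] = {"n_sets_tested": 0, "n_significant": 0, "top_sets": []}

    report["runtime_seconds"] = round(time.time() - t0, 2)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
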