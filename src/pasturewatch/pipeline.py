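"""End-to-end orchestration: simulate -> features -> label -> train ->
predict -> evaluate -> trends.

Each stage writes flat CSV artifacts into the run directory and the run
closes with a JSON manifest (configuration, its hash, seeds, package
version, and the files every stage produced).  Re-running with an
identical configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import PasturewatchError
from .evaluate import (
    DEFAULT_SUBGROUPS,
    evaluate,
    evaluate_subgroups,
    milk_as_predictor,
    positives_by_day,
)
from .features import plausibility_filter
from .models import fit_glm, fit_rfm, predict_status, save_model
from .reference import (
    attribute_milk_day,
    classify_days,
    combine,
    compute_baselines,
    compute_limits,
)
from .simulate import herd_to_frame, make_herd, simulate_experiment, simulate_training_set
from .trends import fit_day_spline, flag_relevance, trend_table
from .variables import BEHAVIOR_VARS, PREDICTOR_SETS

__all__ = ["run_pipeline"]

log = logging.getLogger("pasturewatch")

DAY_KEY = ["cow_id", "month", "cycle", "day"]


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return path.name


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all seven stages and return the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, list[str]] = {}
    t0 = time.time()

    def _stage(name: str):
        log.info("stage %-9s +%.1fs", name, time.time() - t0)
        stages[name] = []
        return stages[name]

    try:
        # 1. simulate ---------------------------------------------------
        files = _stage("simulate")
        design, effects = config.design, config.effects
        herd = make_herd(design.n_groups * design.cows_per_group, seed=config.seed, **config.herd)
        cow_days = simulate_experiment(design, herd, effects)
        training = simulate_training_set(
            config.n_sufficient, config.n_scarce, seed=config.seed + 1
        )
        files.append(_write(herd_to_frame(herd), outdir / "01_herd.csv"))
        files.append(_write(cow_days, outdir / "01_cow_days.csv"))
        files.append(_write(training, outdir / "01_training.csv"))

        # 2. features ---------------------------------------------------
        files = _stage("features")
        kept, removed = plausibility_filter(cow_days)
        files.append(_write(kept, outdir / "02_features.csv"))
        files.append(_write(removed, outdir / "02_features_removed.csv"))

        # 3. label ------------------------------------------------------
        files = _stage("label")
        attributed = attribute_milk_day(kept)
        baselines = compute_baselines(attributed)
        limits = compute_limits(attributed, k=config.limit_k)
        labels = classify_days(attributed, baselines, limits)
        milk_labels = labels[labels["indicator"] == "milk"]
        rumen_labels = labels[labels["indicator"] == "rumen"]
        combined = combine(milk_labels, rumen_labels)
        all_labels = pd.concat([labels, combined], ignore_index=True)
        files.append(_write(all_labels, outdir / "03_labels.csv"))
        (outdir / "03_limits.json").write_text(
            json.dumps(
                {
                    "k": limits.k,
                    "rumen_abs_limit": limits.rumen_abs_limit,
                    "milk_rel_limit_pct": limits.milk_rel_limit,
                    "milk_sd_outliers_excluded": limits.outliers_excluded,
                },
                indent=2,
            )
        )
        files.append("03_limits.json")

        # 4. train ------------------------------------------------------
        files = _stage("train")
        predictors = PREDICTOR_SETS[config.predictor_variant]
        glm = fit_glm(training, predictors)
        rfm = fit_rfm(training, predictors, n_trees=config.n_trees, seed=config.seed + 2)
        save_model(glm, outdir / "04_model_glm.json")
        save_model(rfm, outdir / "04_model_rfm.joblib")
        files += ["04_model_glm.json", "04_model_rfm.joblib"]

        # 5. predict ----------------------------------------------------
        files = _stage("predict")
        preds = []
        for model in (glm, rfm):
            p = predict_status(model, kept)[DAY_KEY + ["p_hat", "cls"]]
            p.insert(0, "model", model.kind)
            p.insert(1, "variant", model.predictors.variant)
            preds.append(p)
        predictions = pd.concat(preds, ignore_index=True)
        files.append(_write(predictions, outdir / "05_predictions.csv"))

        # 6. evaluate ---------------------------------------------------
        files = _stage("evaluate")
        refs = {"milk": milk_labels, "rumen": rumen_labels, "combined": combined}
        rows = []
        for kind in ("GLM", "RFM"):
            pred = predictions[predictions["model"] == kind]
            for ref_name, ref in refs.items():
                merged = pred.merge(
                    ref[DAY_KEY + ["cls"]].rename(columns={"cls": "ref"}),
                    on=DAY_KEY,
                    how="inner",
                )
                cm = evaluate(merged["cls"], merged["ref"])
                rows.append(
                    dict(
                        comparison=f"{kind}_vs_{ref_name}",
                        variant=config.predictor_variant,
                        subgroup="all",
                        n=cm.n, tp=cm.tp, tn=cm.tn, fp=cm.fp, fn=cm.fn,
                        sensitivity=cm.sensitivity, specificity=cm.specificity,
                        ppv=cm.ppv, auc=cm.auc,
                    )
                )
            # subgroup evaluation against the configured reference
            merged = pred.merge(
                refs[config.reference][DAY_KEY + ["cls"]].rename(columns={"cls": "ref"}),
                on=DAY_KEY,
                how="inner",
            ).rename(columns={"cls": "pred"})
            sub = evaluate_subgroups(merged, herd_to_frame(herd), DEFAULT_SUBGROUPS)
            for _, s in sub.iterrows():
                rows.append(
                    dict(
                        comparison=f"{kind}_vs_{config.reference}",
                        variant=config.predictor_variant,
                        subgroup=s["subgroup"],
                        n=s["n"], tp=s["tp"], tn=s["tn"], fp=s["fp"], fn=s["fn"],
                        sensitivity=s["sensitivity"], specificity=s["specificity"],
                        ppv=s["ppv"], auc=s["auc"],
                    )
                )
        cm = milk_as_predictor(milk_labels, rumen_labels)
        rows.append(
            dict(
                comparison="milk_vs_rumen",
                variant="-",
                subgroup="all",
                n=cm.n, tp=cm.tp, tn=cm.tn, fp=cm.fp, fn=cm.fn,
                sensitivity=cm.sensitivity, specificity=cm.specificity,
                ppv=cm.ppv, auc=cm.auc,
            )
        )
        metrics_table = pd.DataFrame(rows)
        files.append(_write(metrics_table, outdir / "06_metrics.csv"))
        files.append(
            _write(positives_by_day(combined), outdir / "06_reference_positives_by_day.csv")
        )

        # 7. trends -----------------------------------------------------
        files = _stage("trends")
        fits = [
            fit_day_spline(kept, v, exclusions=config.paddock_exclusions)
            for v in BEHAVIOR_VARS
        ]
        flags = flag_relevance(fits)
        tt = trend_table(fits)
        flag_df = pd.DataFrame(
            [dict(variable=f.variable, relevant=f.relevant, direction=f.direction) for f in flags]
        )
        files.append(_write(tt, outdir / "07_trends.csv"))
        files.append(_write(flag_df, outdir / "07_relevance.csv"))
    except Exception as exc:
        manifest = {
            "status": "failed",
            "failed_stage": list(stages)[-1] if stages else None,
            "error": f"{type(exc).__name__}: {exc}",
            "stages": stages,
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "version": __version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PasturewatchError(
            f"pipeline failed in stage '{manifest['failed_stage']}': {exc}"
        ) from exc

    manifest = {
        "status": "ok",
        "stages": stages,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
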