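"""End-to-end pipeline: simulate -> impute -> grade -> derive -> evaluate.

Every stage writes its artifacts into the output directory; a manifest
records the configuration hash, seed, package version and completed stages
so a rerun with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, inject_missingness
from .derivation import (
    GAConfig,
    candidate_feature_names,
    lesion_feature_frame,
    rf_validate,
    run_ga,
    split_train_test,
)
from .evaluation import compare_grading_systems, render_severity_table, severity_table
from .grading import grades_wide
from .io import cohort_to_frame, impute_chained, write_cohort_csv

log = logging.getLogger("taigrade")

STAGES = ("simulate", "impute", "grade", "derive", "evaluate")


@dataclass
class PipelineConfig:
    """Top-level configuration gluing all stages together."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    alpha: float = 0.05
    outdir: str = "taigrade_out"
    log_level: str = "INFO"
    force_include: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # where results land does not change them
    payload.pop("log_level", None)
    if payload["cohort"].get("lesion_base_rates") is not None:
        payload["cohort"]["lesion_base_rates"] = {
            s.column: p for s, p in payload["cohort"]["lesion_base_rates"].items()
        }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all five stages; return the manifest dictionary.

    A stage failure halts the pipeline with a :class:`StageError`; the
    partially written manifest is kept with a ``.partial`` suffix.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.cohort.seed,
        "config_hash": _config_hash(config),
        "stages": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        log.info("simulating cohort (n=%d)", config.cohort.n_patients)
        cohort = generate_cohort(config.cohort)
        path = outdir / "cohort.csv"
        write_cohort_csv(cohort, path, config.cohort)
        manifest["stages"].append(stage)
        manifest["outputs"]["cohort"] = path.name

        stage = "impute"
        rng = np.random.default_rng(np.random.SeedSequence(config.cohort.seed).spawn(10)[7])
        masked = inject_missingness(cohort, config.cohort.missingness_rate, rng)
        cohort = impute_chained(masked, seed=config.cohort.seed + 1)
        path = outdir / "cohort_imputed.csv"
        write_cohort_csv(cohort, path)
        manifest["stages"].append(stage)
        manifest["outputs"]["cohort_imputed"] = path.name

        stage = "grade"
        grades = grades_wide(cohort)
        frame = cohort_to_frame(cohort).merge(grades, on="patient_id")
        path = outdir / "grades.csv"
        grades.to_csv(path, index=False)
        manifest["stages"].append(stage)
        manifest["outputs"]["grades"] = path.name

        stage = "derive"
        features = lesion_feature_frame(cohort)
        train, test = split_train_test(features, seed=config.cohort.seed + 2)
        history = run_ga(train, candidate_feature_names(), config.ga)
        selected = list(history.best.features(candidate_feature_names()))
        for forced in config.force_include:
            if forced not in selected:
                selected.append(forced)
        core = cohort_to_frame(cohort)[["patient_id", "age", "gcs", "pupils"]]
        train = train.merge(core, on="patient_id")
        test = test.merge(core, on="patient_id")
        report = rf_validate(train, test, selected, seed=config.cohort.seed + 3)
        path = outdir / "derivation.json"
        path.write_text(
            json.dumps(
                {
                    "selected_features": list(report.selected_features),
                    "best_fitness": history.best.fitness,
                    "test_auc_with_tai": report.test_auc_with_tai,
                    "test_auc_core_only": report.test_auc_core_only,
                    "gini_importances": report.gini_importances,
                },
                indent=2,
                sort_keys=True,
            )
        )
        _importance_plot(report.gini_importances, outdir / "importances.png")
        manifest["stages"].append(stage)
        manifest["outputs"]["derivation"] = path.name

        stage = "evaluate"
        comparison = compare_grading_systems(frame)
        comparison.models.to_csv(outdir / "model_comparison.csv", index=False, float_format="%.6g")
        tests = {
            "lrt": comparison.lrt.to_dict(orient="records"),
            "delong": comparison.delong.to_dict(orient="records"),
            "alpha": config.alpha,
        }
        (outdir / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))
        render_severity_table(severity_table(cohort)).to_csv(
            outdir / "severity_table.csv", index=False
        )
        _calibration_plot(frame, outdir / "calibration.png")
        manifest["stages"].append(stage)
        manifest["outputs"]["model_comparison"] = "model_comparison.csv"
        manifest["outputs"]["tests"] = "tests.json"
    except Exception as exc:
        (outdir / "manifest.json.partial").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageError(stage, exc) from exc

    blob = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _importance_plot(importances: dict[str, float], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(importances.items(), key=lambda kv: kv[1])
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * len(items))))
    ax.barh([k for k, _ in items], [v for _, v in items], color="#3b6ea5")
    ax.set_xlabel("mean decrease in Gini impurity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _calibration_plot(frame: pd.DataFrame, path: Path) -> None:
    """Decile-binned observed vs expected for the core+Stockholm model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import fit_logistic

    m = fit_logistic(frame, ["age", "gcs", "pupils", "grade_stockholm"])
    y = frame["unfavorable"].astype(int).to_numpy()
    probs = m.fitted_probs
    bins = pd.qcut(probs, 10, duplicates="drop")
    df = pd.DataFrame({"p": probs, "y": y, "bin": bins})
    g = df.groupby("bin", observed=True).agg(expected=("p", "mean"), observed=("y", "mean"))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.plot(g["expected"], g["observed"], "o-", color="#a53b3b")
    ax.set_xlabel("predicted probability of unfavorable outcome")
    ax.set_ylabel("observed fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
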