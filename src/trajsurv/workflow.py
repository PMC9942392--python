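"""Reproducible pipeline orchestration: simulate -> preprocess -> fit -> evaluate.

A single RunConfig drives every stage; artifacts are written under the run
directory and stamped with a hash of the configuration and the seed, so a
rerun with an identical config is a no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import compare_models, cross_validate
from .pipeline import DEFAULT_HORIZONS, PipelineSettings, fit_pipeline
from .preprocess import filter_eligible, process_measurements
from .simulate import CohortConfig, generate_cohort, read_cohort, write_cohort

STAGES = ("simulate", "preprocess", "fit", "evaluate")


@dataclass
class RunConfig:
    outdir: str = "run"
    n_patients: int = 300
    landmark: float = 12.0
    feature_horizon: float = 12.0
    horizons: tuple = DEFAULT_HORIZONS
    configs: tuple = ("basic", "preop_cea", "preop_3marker",
                      "postop_3marker", "longitudinal_cea",
                      "longitudinal_3marker")
    cv_folds: int = 10
    n_estimators: int = 300
    min_samples_leaf: int = 15
    k_candidates: tuple = (1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self):
        if any(h <= self.landmark for h in self.horizons):
            raise ValueError("horizons must all exceed the landmark")
        if self.feature_horizon > self.landmark:
            raise ValueError("feature horizon must be <= landmark")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def settings(self) -> PipelineSettings:
        return PipelineSettings(
            landmark=self.landmark, feature_horizon=self.feature_horizon,
            horizons=tuple(self.horizons),
            k_candidates=tuple(self.k_candidates),
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("horizons", "configs", "k_candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, stages=None, force: bool = False,
                 log=print) -> dict:
    """Execute the requested stages in dependency order.

    Returns a dict of artifact paths.  Each stage writes a manifest with the
    config hash; matching manifests short-circuit the stage unless
    ``force``.
    """
    stages = list(stages or STAGES)
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def stamp(stage):
        return outdir / f"{stage}.manifest.json"

    def fresh(stage):
        p = stamp(stage)
        if force or not p.exists():
            return True
        try:
            return json.loads(p.read_text())["config_hash"] != config.hash()
        except (KeyError, json.JSONDecodeError):
            return True

    def write_stamp(stage, extra=None):
        stamp(stage).write_text(json.dumps({
            "stage": stage, "config_hash": config.hash(),
            "seed": config.seed, "time": time.time(), **(extra or {})}))

    if "simulate" in stages:
        if fresh("simulate"):
            cohort = CohortConfig(n_patients=config.n_patients,
                                  seed=config.seed)
            patients, measurements, truth = generate_cohort(cohort)
            write_cohort(outdir, patients, measurements, truth)
            write_stamp("simulate", {"n_patients": config.n_patients})
            log(json.dumps({"stage": "simulate", "n": config.n_patients}))
        artifacts["patients"] = outdir / "patients.csv"
        artifacts["measurements"] = outdir / "measurements.csv"

    if set(stages) & {"preprocess", "fit", "evaluate"}:
        patients, measurements = read_cohort(outdir)

    if "preprocess" in stages:
        if fresh("preprocess"):
            processed = process_measurements(measurements)
            eligible, excl = filter_eligible(measurements, patients)
            processed.to_csv(outdir / "measurements_processed.csv",
                             index=False)
            excl.to_csv(outdir / "exclusions.csv", index=False)
            write_stamp("preprocess", {"n_eligible": len(eligible)})
            log(json.dumps({"stage": "preprocess",
                            "eligible": len(eligible),
                            "excluded": len(excl)}))
        artifacts["exclusions"] = outdir / "exclusions.csv"

    if "fit" in stages and fresh("fit"):
        fp = fit_pipeline(measurements, patients,
                          configs=list(config.configs),
                          settings=config.settings(), seed=config.seed)
        (outdir / "models").mkdir(exist_ok=True)
        for m, fm in fp.fpca_models.items():
            (outdir / "models" / f"fpca_{m}.json").write_text(fm.to_json())
        (outdir / "models" / "mfpca.json").write_text(
            fp.mfpca_model.to_json())
        for m, frame in fp.train_scores.items():
            frame.to_csv(outdir / "models" / f"scores_{m}.csv")
        fp.train_mfpca_scores.to_csv(outdir / "models" / "scores_mfpca.csv")
        write_stamp("fit", {"K": {m: fm.K for m, fm in
                                  fp.fpca_models.items()},
                            "M": fp.mfpca_model.M})
        log(json.dumps({"stage": "fit",
                        "K": {m: fm.K for m, fm in fp.fpca_models.items()},
                        "M": fp.mfpca_model.M}))
    if "fit" in stages:
        artifacts["models"] = outdir / "models"

    if "evaluate" in stages and fresh("evaluate"):
        cv = cross_validate(measurements, patients,
                            configs=list(config.configs),
                            n_folds=config.cv_folds, seed=config.seed,
                            settings=config.settings())
        cv.report.to_csv(outdir / "cv_metrics.csv", index=False)
        if {"preop_3marker", "longitudinal_3marker"} <= set(config.configs):
            cmp = compare_models(cv, "longitudinal_3marker",
                                 "preop_3marker", seed=config.seed)
            cmp.to_csv(outdir / "cv_reclassification.csv", index=False)
        write_stamp("evaluate")
        log(json.dumps({"stage": "evaluate",
                        "rows": int(len(cv.report))}))
    if "evaluate" in stages:
        artifacts["cv_metrics"] = outdir / "cv_metrics.csv"

    return artifacts
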