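"""End-to-end fitting and scoring: preprocessing -> FPCA -> MFPCA -> forest.

The pipeline is always fitted on the landmark risk set (patients with
observed time beyond the landmark), using only measurements within the
feature horizon; a fitted pipeline can then score any patient — including
patients never seen in training — by estimating their FPC scores under the
trained eigenstructure and passing the assembled feature row through the
trained forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forest as forest_mod
from . import mfpca as mfpca_mod
from .fpca import FpcaModel, estimate_scores_all, fit_fpca, make_grid
from .forest import CONFIGURATIONS, SurvivalModel, build_features
from .preprocess import (
    ReferenceLimits,
    apply_landmark,
    build_series,
    extract_anchor_values,
    filter_eligible,
)

DEFAULT_HORIZONS = (18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0)


@dataclass
class PipelineSettings:
    """All tunables of the analysis pipeline in one place."""

    markers: tuple = ("CEA", "CA19-9", "CA125")
    landmark: float = 12.0
    feature_horizon: float = 12.0
    horizons: tuple = DEFAULT_HORIZONS
    limits: ReferenceLimits = field(default_factory=ReferenceLimits)
    grid_lo: float = -1.0
    grid_hi: float = 12.0
    grid_size: int = 101
    k_candidates: tuple = (1, 2, 3, 4)
    mfpca_M: object = "auto"
    n_estimators: int = 1000
    min_samples_leaf: int = 15
    max_features: object = "sqrt"
    preop_window_weeks: float = 4.0
    min_postop: int = 2

    def grid(self):
        return make_grid(self.grid_lo, self.grid_hi, self.grid_size)


@dataclass
class FittedPipeline:
    settings: PipelineSettings
    fpca_models: dict                 # marker -> FpcaModel
    mfpca_model: mfpca_mod.MfpcaModel
    forests: dict                     # config name -> SurvivalModel
    train_ids: list
    train_scores: dict = None         # marker -> DataFrame (training)
    train_mfpca_scores: pd.DataFrame = None


def prepare_cohort(measurements: pd.DataFrame, patients: pd.DataFrame,
                   settings: PipelineSettings):
    """Eligibility + landmark: ids usable for training/evaluation."""
    eligible, _ = filter_eligible(
        measurements, patients, settings.preop_window_weeks,
        settings.min_postop, settings.feature_horizon,
        markers=list(settings.markers))
    at_risk = set(apply_landmark(patients, settings.landmark))
    return [pid for pid in eligible if pid in at_risk]


def score_frames(fpca_models: dict, measurements: pd.DataFrame, ids,
                 settings: PipelineSettings) -> dict:
    """Univariate FPC score matrices for the given patients."""
    frames = {}
    for m in settings.markers:
        series = build_series(measurements, m, settings.limits, ids,
                              settings.feature_horizon)
        missing = set(ids) - set(series)
        if missing:
            raise ValueError(f"no {m} measurements for patients "
                             f"{sorted(missing)[:5]}")
        series = {pid: series[pid] for pid in ids}
        pids, xis, _ = estimate_scores_all(fpca_models[m], series)
        frames[m] = pd.DataFrame(
            xis, index=pd.Index(pids, name="patient_id"),
            columns=[f"fpc_{j + 1}" for j in range(fpca_models[m].K)])
    return frames


def fit_pipeline(measurements: pd.DataFrame, patients: pd.DataFrame,
                 ids=None, configs=None, settings: PipelineSettings = None,
                 seed: int = 0) -> FittedPipeline:
    """Fit FPCA per marker, MFPCA, and one forest per configuration."""
    settings = settings or PipelineSettings()
    configs = list(configs or CONFIGURATIONS)
    if ids is None:
        ids = prepare_cohort(measurements, patients, settings)
    if not ids:
        raise ValueError("no eligible patients in the landmark risk set")
    grid = settings.grid()

    fpca_models = {}
    for m in settings.markers:
        series = build_series(measurements, m, settings.limits, ids,
                              settings.feature_horizon)
        fpca_models[m] = fit_fpca(series, m, grid=grid,
                                  k_candidates=settings.k_candidates)
    uni = score_frames(fpca_models, measurements, ids, settings)
    mf_model, mf_scores = mfpca_mod.fit_mfpca(uni, M=settings.mfpca_M)

    pts = patients[patients["patient_id"].isin(set(ids))].copy()
    anchors = extract_anchor_values(
        measurements[measurements["patient_id"].isin(set(ids))],
        settings.preop_window_weeks, settings.feature_horizon)
    forests = {}
    for name in configs:
        X = build_features(name, pts, anchors, cea_scores=uni["CEA"],
                           mfpca_scores=mf_scores, limits=settings.limits)
        X = X.loc[ids]
        model = forest_mod.fit(
            X, pts.set_index("patient_id").loc[ids, "time_months"],
            pts.set_index("patient_id").loc[ids, "event"],
            n_estimators=settings.n_estimators,
            min_samples_leaf=settings.min_samples_leaf,
            max_features=settings.max_features, seed=seed)
        model.name = name
        forests[name] = model
    return FittedPipeline(settings, fpca_models, mf_model, forests,
                          list(ids), uni, mf_scores)


def features_for(fp: FittedPipeline, measurements: pd.DataFrame,
                 patients: pd.DataFrame, ids, config_name: str) -> pd.DataFrame:
    """Feature rows for arbitrary patients under the *trained* models."""
    settings = fp.settings
    uni = score_frames(fp.fpca_models, measurements, ids, settings)
    mf_scores = mfpca_mod.transform(fp.mfpca_model, uni)
    pts = patients[patients["patient_id"].isin(set(ids))]
    anchors = extract_anchor_values(
        measurements[measurements["patient_id"].isin(set(ids))],
        settings.preop_window_weeks, settings.feature_horizon)
    X = build_features(config_name, pts, anchors, cea_scores=uni["CEA"],
                       mfpca_scores=mf_scores, limits=settings.limits)
    return X.loc[ids]


def conditional_risks(model: SurvivalModel, X: pd.DataFrame, s: float,
                      horizons) -> pd.DataFrame:
    """Risk by each horizon conditional on being alive at s: 1 - S(t)/S(s)."""
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    S = forest_mod.predict_survival(model, X, np.concatenate([[s], horizons]))
    Ss = S[:, 0]
    if np.any(Ss <= 0):
        raise ValueError("predicted survival at the landmark is zero; "
                         "conditional risk undefined")
    pi = np.clip(S[:, 1:] / Ss[:, None], 0.0, 1.0)
    return pd.DataFrame(1.0 - pi, index=X.index, columns=list(horizons))
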