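"""Personalized dynamic prediction of conditional survival.

A patient's conditional survival curve pi(s'|s) = P(T* >= s' | T* > s, Z,
scores) is the ratio S(s')/S(s) of the trained forest's predicted survival
function at the patient's current feature row — the standard landmarking
estimator.  Whenever a new marker measurement arrives (within the
12-month feature horizon), the FPC scores are re-estimated from the
augmented history, the joint scores and feature row rebuilt, and the curve
refreshed; the predicted marker trajectories are the reconstructed latent
curves under the updated scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mfpca as mfpca_mod
from .fpca import GridFunction, estimate_scores, fit_trajectory
from .forest import build_features
from .pipeline import FittedPipeline, conditional_risks
from .preprocess import cap_and_log


@dataclass
class PatientHistory:
    """One patient's covariates and raw marker history.

    ``observations``: marker -> dict {time_months: raw value}; the dict is
    the de-duplication rule — appending a (marker, time) pair that already
    exists overwrites it (last value wins).
    """

    covariates: dict
    observations: dict = field(default_factory=dict)

    def add(self, marker: str, time: float, value: float):
        if value <= 0:
            raise ValueError("marker values must be positive")
        self.observations.setdefault(marker, {})[round(float(time), 8)] = \
            float(value)

    def series(self, marker: str, limits, cutoff: float):
        obs = self.observations.get(marker, {})
        t = np.array(sorted(u for u in obs if u <= cutoff))
        if len(t) == 0:
            return t, t
        v = np.array([obs[u] for u in t])
        return t, cap_and_log(v, marker, limits)


@dataclass
class LandmarkPrediction:
    """Conditional survival curve and predicted trajectories for one patient."""

    patient_id: str
    landmark: float
    horizons: np.ndarray
    conditional_survival: np.ndarray
    cutoff: float
    scores: dict                        # marker -> univariate score vector
    mfpca_scores: np.ndarray
    trajectories: dict                  # marker -> GridFunction (log scale)
    low_information: bool = False

    def survival_at(self, horizon: float) -> float:
        i = np.flatnonzero(np.isclose(self.horizons, horizon))
        if len(i) == 0:
            raise KeyError(f"horizon {horizon} not predicted")
        return float(self.conditional_survival[i[0]])

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "landmark": self.landmark,
            "horizons": self.horizons.tolist(),
            "conditional_survival": self.conditional_survival.tolist(),
            "cutoff": self.cutoff,
            "low_information": self.low_information,
        }


def predict_for_history(fp: FittedPipeline, patient_id: str,
                        history: PatientHistory, config: str,
                        horizons=None, cutoff: float = None,
                        landmark: float = None) -> LandmarkPrediction:
    """Conditional survival for one patient from their current history."""
    settings = fp.settings
    landmark = settings.landmark if landmark is None else landmark
    cutoff = settings.feature_horizon if cutoff is None else cutoff
    if cutoff > settings.feature_horizon:
        raise ValueError(
            f"measurements after the {settings.feature_horizon}-month "
            "feature horizon are not used by the model; cutoff must be "
            f"<= {settings.feature_horizon}")
    horizons = np.atleast_1d(np.asarray(
        horizons if horizons is not None else settings.horizons, dtype=float))
    if np.any(horizons < landmark):
        raise ValueError("horizons must be >= the landmark")

    uni_scores = {}
    trajectories = {}
    low_info = False
    for m in settings.markers:
        t, y = history.series(m, settings.limits, cutoff)
        model = fp.fpca_models[m]
        if len(t) == 0:
            uni_scores[m] = np.zeros(model.K)
            low_info = True
        else:
            xi, _ = estimate_scores(model, t, y)
            uni_scores[m] = xi
            if not np.any(t > 0):
                low_info = True
        trajectories[m] = fit_trajectory(model, uni_scores[m])
    rho = mfpca_mod.transform_one(fp.mfpca_model, uni_scores)

    pts = pd.DataFrame([dict(history.covariates)],
                       index=pd.Index([patient_id], name="patient_id"))
    anchors = _anchor_frame(history, settings, pts.index)
    mf_frame = pd.DataFrame([rho], index=pts.index,
                            columns=[f"mfpc_{j + 1}"
                                     for j in range(fp.mfpca_model.M)])
    cea_frame = pd.DataFrame([uni_scores["CEA"]], index=pts.index,
                             columns=[f"fpc_{j + 1}"
                                      for j in range(len(uni_scores["CEA"]))])
    X = build_features(config, pts, anchors, cea_scores=cea_frame,
                       mfpca_scores=mf_frame, limits=settings.limits)
    risks = conditional_risks(fp.forests[config], X, landmark, horizons)
    pi = 1.0 - risks.iloc[0].to_numpy()
    return LandmarkPrediction(
        patient_id=patient_id, landmark=landmark, horizons=horizons,
        conditional_survival=pi, cutoff=cutoff, scores=uni_scores,
        mfpca_scores=rho, trajectories=trajectories,
        low_information=low_info)


def _anchor_frame(history: PatientHistory, settings, index) -> pd.DataFrame:
    window = settings.preop_window_weeks * 12.0 / 52.0
    row = {}
    for m, obs in history.observations.items():
        times = np.array(sorted(obs))
        pre = times[(times >= -window) & (times < 0)]
        if len(pre):
            row[f"preop_{m}"] = obs[pre[np.argmin(np.abs(pre))]]
        post = times[(times > 0) & (times <= settings.feature_horizon)]
        if len(post):
            row[f"postop_first_{m}"] = obs[post[0]]
    return pd.DataFrame([row], index=index)


def update_with_measurement(fp: FittedPipeline, patient_id: str,
                            history: PatientHistory, marker: str,
                            time: float, value: float, config: str,
                            horizons=None) -> LandmarkPrediction:
    """Append one measurement and refresh the prediction.

    The measurement must fall within the feature horizon; duplicate
    (marker, time) records overwrite the previous value, so repeating an
    update is idempotent.
    """
    if time > fp.settings.feature_horizon:
        raise ValueError(
            f"measurement at t={time} months is beyond the model's "
            f"{fp.settings.feature_horizon}-month feature horizon; the model "
            "only uses measurements during the 12 months after surgery")
    history.add(marker, time, value)
    return predict_for_history(fp, patient_id, history, config,
                               horizons=horizons)


def predict_marker_trajectory(fp: FittedPipeline, scores: dict,
                              marker: str) -> tuple[GridFunction, GridFunction]:
    """Reconstructed latent trajectory for one marker.

    Returns (log-scale GridFunction, original-units GridFunction); the
    original-units curve is the exponentiated reconstruction, truncated at
    the capping ceiling used in preprocessing.
    """
    model = fp.fpca_models[marker]
    logf = fit_trajectory(model, np.asarray(scores[marker], dtype=float))
    cap = fp.settings.limits.cap(marker)
    return logf, GridFunction(logf.grid, np.minimum(np.exp(logf.values), cap))


def _history_from_tables(measurements: pd.DataFrame, patients: pd.DataFrame,
                         patient_id: str) -> PatientHistory:
    """Build a PatientHistory from the cohort tables (harness utility)."""
    row = patients.set_index("patient_id").loc[patient_id]
    cov = {k: row[k] for k in row.index
           if k not in ("time_months", "event")}
    hist = PatientHistory(covariates=cov)
    sub = measurements[measurements["patient_id"] == patient_id]
    for _, r in sub.iterrows():
        hist.add(r["marker"], r["time_months"], r["value"])
    return hist


def leave_one_out_prediction(measurements: pd.DataFrame,
                             patients: pd.DataFrame, patient_id: str,
                             config: str = "longitudinal_3marker",
                             settings=None, seed: int = 0,
                             horizons=None) -> LandmarkPrediction:
    """Retrain without the target patient, then predict for them.

    Mirrors the illustrative-patient protocol: the model a target patient
    is scored under is fitted on everyone else.
    """
    from .pipeline import fit_pipeline

    rest_p = patients[patients["patient_id"] != patient_id]
    rest_m = measurements[measurements["patient_id"] != patient_id]
    fp = fit_pipeline(rest_m, rest_p, configs=[config], settings=settings,
                      seed=seed)
    hist = _history_from_tables(measurements, patients, patient_id)
    return predict_for_history(fp, patient_id, hist, config,
                               horizons=horizons)
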