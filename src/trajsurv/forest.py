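"""Random-survival-forest models over named feature configurations.

Six configurations are compared: a basic clinicopathological model; the
basic model plus preoperative CEA; plus all three preoperative markers;
plus the first postoperative values; and "longitudinal" variants that add
trajectory features (univariate CEA FPC scores, or the joint MFPCA scores
of all three markers).  The ensemble itself is scikit-survival's
RandomSurvivalForest (log-rank splitting, Nelson–Aalen leaf estimators);
this module owns the feature encoding, the out-of-bag machinery and the
permutation variable importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .preprocess import ReferenceLimits, cap_and_log

BASE_COVARIATES = [
    "age", "sex", "primary_site", "surgical_approach", "differentiation",
    "stage", "lymph_node_yield_ge12", "mucinous", "lymphovascular_invasion",
    "perineural_invasion", "adjuvant_chemo",
]

#: one-hot reference levels for the categorical covariates
REFERENCE_LEVELS = {
    "sex": "female",
    "primary_site": "colon",
    "surgical_approach": "laparoscopic",
    "differentiation": "well",
    "stage": "I",
}

CATEGORY_LEVELS = {
    "sex": ["female", "male"],
    "primary_site": ["colon", "rectum"],
    "surgical_approach": ["laparoscopic", "open"],
    "differentiation": ["well", "moderate", "poor"],
    "stage": ["I", "II", "III"],
}


@dataclass(frozen=True)
class FeatureConfiguration:
    """Named set of covariates and marker features."""

    name: str
    preop_markers: tuple = ()
    postop_markers: tuple = ()
    scores: str | None = None      # None | "cea" | "mfpca"
    covariates: tuple = tuple(BASE_COVARIATES)


CONFIGURATIONS = {
    "basic": FeatureConfiguration("basic"),
    "preop_cea": FeatureConfiguration("preop_cea", preop_markers=("CEA",)),
    "preop_3marker": FeatureConfiguration(
        "preop_3marker", preop_markers=("CEA", "CA19-9", "CA125")),
    "postop_3marker": FeatureConfiguration(
        "postop_3marker", preop_markers=("CEA", "CA19-9", "CA125"),
        postop_markers=("CEA", "CA19-9", "CA125")),
    "longitudinal_cea": FeatureConfiguration(
        "longitudinal_cea", preop_markers=("CEA",), scores="cea"),
    "longitudinal_3marker": FeatureConfiguration(
        "longitudinal_3marker", preop_markers=("CEA", "CA19-9", "CA125"),
        scores="mfpca"),
}


def encode_covariates(patients: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical covariates against fixed level sets."""
    out = pd.DataFrame(index=patients.index)
    for col in BASE_COVARIATES:
        if col not in patients:
            raise KeyError(f"missing covariate column {col!r}")
        if col in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[col]
            vals = patients[col].astype(str)
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in {col!r}")
            for lvl in levels:
                if lvl == REFERENCE_LEVELS[col]:
                    continue
                out[f"{col}_{lvl}"] = (vals == lvl).astype(float)
        else:
            out[col] = patients[col].astype(float)
    return out


def build_features(config, patients: pd.DataFrame,
                   anchors: pd.DataFrame | None = None,
                   cea_scores: pd.DataFrame | None = None,
                   mfpca_scores: pd.DataFrame | None = None,
                   limits: ReferenceLimits | None = None) -> pd.DataFrame:
    """Assemble the feature table for one configuration.

    One row per patient (indexed by patient_id); marker anchor values are
    capped and log-transformed.  Raises if any required feature is missing
    for any patient, listing the offenders.
    """
    if isinstance(config, str):
        config = CONFIGURATIONS[config]
    if patients.empty:
        raise ValueError("empty patient list")
    limits = limits or ReferenceLimits()
    pts = patients.set_index("patient_id") if "patient_id" in patients else patients
    X = encode_covariates(pts)

    def pull(frame, col, new):
        if frame is None or col not in frame:
            raise ValueError(f"{config.name}: required feature {new} "
                             "unavailable")
        s = frame[col].reindex(X.index)
        if s.isna().any():
            missing = s[s.isna()].index.tolist()
            raise ValueError(f"{config.name}: feature {new} missing for "
                             f"patients {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        return s

    for m in config.preop_markers:
        X[f"preop_log_{m}"] = cap_and_log(
            pull(anchors, f"preop_{m}", f"preop_{m}").to_numpy(), m, limits)
    for m in config.postop_markers:
        X[f"postop_log_{m}"] = cap_and_log(
            pull(anchors, f"postop_first_{m}",
                 f"postop_first_{m}").to_numpy(), m, limits)
    if config.scores == "cea":
        if cea_scores is None:
            raise ValueError("CEA score matrix required")
        for c in cea_scores.columns:
            X[f"cea_{c}"] = pull(cea_scores, c, f"cea_{c}")
    elif config.scores == "mfpca":
        if mfpca_scores is None:
            raise ValueError("MFPCA score matrix required")
        for c in mfpca_scores.columns:
            X[c] = pull(mfpca_scores, c, c)
    return X


@dataclass
class SurvivalModel:
    """Fitted survival forest plus its OOB machinery."""

    name: str
    rsf: RandomSurvivalForest
    feature_columns: list
    time: np.ndarray
    event: np.ndarray
    oob_risk: np.ndarray = field(repr=False, default=None)
    hyperparameters: dict = field(default_factory=dict)

    @property
    def oob_concordance(self) -> float:
        ok = np.isfinite(self.oob_risk)
        c = concordance_index_censored(self.event[ok].astype(bool),
                                       self.time[ok], self.oob_risk[ok])
        return float(c[0])


def fit(X: pd.DataFrame, time, event, n_estimators: int = 1000,
        min_samples_leaf: int = 15, max_features="sqrt",
        seed: int = 0, compute_oob: bool = True) -> SurvivalModel:
    """Fit the forest with a fixed seed and store OOB risk predictions."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 2:
        raise ValueError("need at least two events to fit a survival forest")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if len(np.unique(time)) < 2:
        raise ValueError("constant survival times")
    y = Surv.from_arrays(event.astype(bool), time)
    rsf = RandomSurvivalForest(
        n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
        max_features=max_features, n_jobs=1, random_state=seed)
    rsf.fit(np.asarray(X, dtype=float), y)
    model = SurvivalModel(
        name=getattr(X, "attrs", {}).get("config", ""), rsf=rsf,
        feature_columns=list(X.columns), time=time, event=event,
        hyperparameters={"n_estimators": n_estimators,
                         "min_samples_leaf": min_samples_leaf,
                         "max_features": max_features, "seed": seed})
    if compute_oob:
        model.oob_risk = _oob_risk(rsf, np.asarray(X, dtype=float))
    return model


def _oob_masks(rsf: RandomSurvivalForest, n: int):
    nb = _get_n_samples_bootstrap(n, rsf.max_samples, None)
    masks = []
    for tree in rsf.estimators_:
        idx = _generate_unsampled_indices(tree.random_state, n, nb, None)
        m = np.zeros(n, dtype=bool)
        m[idx] = True
        masks.append(m)
    return masks


def _oob_risk(rsf, X, masks=None):
    """Ensemble risk score per sample using only trees where it is OOB."""
    n = X.shape[0]
    if masks is None:
        masks = _oob_masks(rsf, n)
    total = np.zeros(n)
    count = np.zeros(n)
    for tree, m in zip(rsf.estimators_, masks):
        if m.any():
            total[m] += tree.predict(X[m])
            count[m] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def predict_risk(model: SurvivalModel, X: pd.DataFrame) -> np.ndarray:
    _check_schema(model, X)
    return model.rsf.predict(np.asarray(X, dtype=float))


def predict_survival(model: SurvivalModel, X: pd.DataFrame,
                     times) -> np.ndarray:
    """Ensemble-averaged survival probabilities at the requested times.

    Step-function evaluation: S(t) = 1 for t before the first training
    event time; constant after the last.  Returns (n_patients, n_times).
    """
    _check_schema(model, X)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    surv = model.rsf.predict_survival_function(np.asarray(X, dtype=float),
                                               return_array=True)
    ut = model.rsf.unique_times_
    pos = np.searchsorted(ut, times, side="right") - 1
    out = np.ones((surv.shape[0], len(times)))
    inside = pos >= 0
    out[:, inside] = surv[:, pos[inside]]
    return out


def _check_schema(model: SurvivalModel, X: pd.DataFrame):
    if list(X.columns) != model.feature_columns:
        raise ValueError("feature schema mismatch: expected "
                         f"{model.feature_columns}, got {list(X.columns)}")


def compute_vimp(model: SurvivalModel, X: pd.DataFrame, seed: int = 0):
    """Permutation variable importance from OOB prediction error.

    For each feature, its column is permuted and the OOB ensemble risk is
    re-computed; importance is the increase in OOB error (1 - concordance).
    Returns a DataFrame sorted by decreasing importance.
    """
    _check_schema(model, X)
    Xa = np.asarray(X, dtype=float)
    n = Xa.shape[0]
    masks = _oob_masks(model.rsf, n)
    base_risk = _oob_risk(model.rsf, Xa, masks)
    ok = np.isfinite(base_risk)
    ev = model.event.astype(bool)

    def err(risk):
        m = ok & np.isfinite(risk)
        c = concordance_index_censored(ev[m], model.time[m], risk[m])
        return 1.0 - c[0]

    base_err = err(base_risk)
    rng = np.random.default_rng(seed)
    rows = []
    for j, col in enumerate(model.feature_columns):
        perm = rng.permutation(n)
        Xp = Xa.copy()
        Xp[:, j] = Xa[perm, j]
        rows.append((col, err(_oob_risk(model.rsf, Xp, masks)) - base_err))
    out = pd.DataFrame(rows, columns=["feature", "importance"])
    out = out.sort_values("importance", ascending=False,
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
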