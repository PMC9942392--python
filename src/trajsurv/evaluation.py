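"""Model comparison: cross-validated and external metric reports.

Internal validation refits the entire pipeline (FPCA -> MFPCA -> forest)
on each training split of a tenfold stratified-on-event partition of the
landmark risk set, pools out-of-fold conditional risks, and computes
AUC(t)/BS(t) per horizon; NRI and IDI compare two configurations on the
same pooled risks.  External validation applies a trained pipeline to a
new cohort without refitting and reports metrics at a single horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .forest import CONFIGURATIONS
from .pipeline import (
    FittedPipeline,
    PipelineSettings,
    conditional_risks,
    features_for,
    fit_pipeline,
    prepare_cohort,
)


def stratified_event_folds(event, n_folds: int, seed: int = 0) -> np.ndarray:
    """Fold labels stratified on the event indicator.

    Events and non-events are shuffled separately and dealt around one
    continuing cycle of folds, so fold sizes differ by at most one overall
    and the event mix is balanced.
    """
    event = np.asarray(event).astype(int)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(len(event), dtype=int)
    cursor = 0
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            labels[j] = (cursor + i) % n_folds
        cursor += len(idx)
    return labels


@dataclass
class CrossValidationResult:
    """Pooled out-of-fold risks and the per-horizon metric table."""

    risks: dict          # config name -> DataFrame (patients x horizons)
    time: pd.Series
    event: pd.Series
    report: pd.DataFrame
    fold_labels: pd.Series


def cross_validate(measurements: pd.DataFrame, patients: pd.DataFrame,
                   configs=None, n_folds: int = 10, seed: int = 0,
                   settings: PipelineSettings = None) -> CrossValidationResult:
    """Tenfold cross-validation of the full pipeline.

    Every fold refits FPCA, MFPCA and the forests on its training split;
    out-of-fold conditional risks are pooled before metrics are computed.
    """
    settings = settings or PipelineSettings()
    configs = list(configs or CONFIGURATIONS)
    ids = prepare_cohort(measurements, patients, settings)
    if not ids:
        raise ValueError("no eligible patients")
    pts = patients.set_index("patient_id").loc[ids]
    ev = pts["event"].to_numpy()
    if ev.sum() < n_folds:
        warnings.warn("fewer events than folds; some folds lack events")
    labels = stratified_event_folds(ev, n_folds, seed)
    horizons = list(settings.horizons)
    risks = {c: pd.DataFrame(np.nan, index=pd.Index(ids, name="patient_id"),
                             columns=horizons) for c in configs}
    for f in range(n_folds):
        test_ids = [pid for pid, l in zip(ids, labels) if l == f]
        train_ids = [pid for pid, l in zip(ids, labels) if l != f]
        if pts.loc[train_ids, "event"].sum() < 2:
            warnings.warn(f"fold {f} training split lacks events; skipped")
            continue
        fp = fit_pipeline(measurements, patients, ids=train_ids,
                          configs=configs, settings=settings, seed=seed + f)
        for c in configs:
            X = features_for(fp, measurements, patients, test_ids, c)
            r = conditional_risks(fp.forests[c], X, settings.landmark,
                                  horizons)
            risks[c].loc[test_ids, :] = r.values
    rows = []
    for c in configs:
        for t in horizons:
            r = risks[c][t].to_numpy()
            ok = np.isfinite(r)
            try:
                auc = metrics_mod.td_auc(r[ok], pts["time_months"][ok],
                                         pts["event"][ok],
                                         settings.landmark, t)
                bs = metrics_mod.brier(r[ok], pts["time_months"][ok],
                                       pts["event"][ok],
                                       settings.landmark, t)
            except ValueError:
                auc, bs = np.nan, np.nan
            rows.append({"model": c, "landmark": settings.landmark,
                         "horizon": t, "auc": auc, "brier": bs,
                         "n": int(ok.sum()),
                         "n_events": int(pts["event"][ok]
                                         [pts["time_months"][ok] <= t].sum())})
    report = pd.DataFrame(rows)
    return CrossValidationResult(
        risks=risks, time=pts["time_months"], event=pts["event"],
        report=report, fold_labels=pd.Series(labels, index=pts.index))


def compare_models(cv: CrossValidationResult, new: str, old: str,
                   horizons=None, s: float = 12.0, n_boot: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """NRI and IDI of configuration ``new`` over ``old`` per horizon."""
    horizons = horizons or list(cv.risks[new].columns)
    rows = []
    for t in horizons:
        rn = cv.risks[new][t].to_numpy()
        ro = cv.risks[old][t].to_numpy()
        ok = np.isfinite(rn) & np.isfinite(ro)
        nri_res = metrics_mod.nri(rn[ok], ro[ok], cv.time[ok], cv.event[ok],
                                  s, t, n_boot=n_boot, seed=seed)
        idi_res = metrics_mod.idi(rn[ok], ro[ok], cv.time[ok], cv.event[ok],
                                  s, t, n_boot=n_boot, seed=seed)
        rows.append({
            "new": new, "old": old, "horizon": t,
            "nri_pct": nri_res.estimate,
            "nri_ci": (nri_res.ci_lower, nri_res.ci_upper),
            "events_up_pct": nri_res.detail["events_up_pct"],
            "events_down_pct": nri_res.detail["events_down_pct"],
            "nonevents_up_pct": nri_res.detail["nonevents_up_pct"],
            "nonevents_down_pct": nri_res.detail["nonevents_down_pct"],
            "idi": idi_res.estimate,
            "idi_ci": (idi_res.ci_lower, idi_res.ci_upper),
        })
    return pd.DataFrame(rows)


def external_validate(fp: FittedPipeline, measurements: pd.DataFrame,
                      patients: pd.DataFrame, horizon: float = 60.0,
                      configs=None) -> pd.DataFrame:
    """Apply a trained pipeline to an external cohort; metrics at one horizon.

    No refitting: FPC scores for external patients are conditional
    expectations under the trained eigenstructure.
    """
    configs = list(configs or fp.forests)
    settings = fp.settings
    ids = prepare_cohort(measurements, patients, settings)
    if not ids:
        raise ValueError("external cohort has no eligible patients")
    pts = patients.set_index("patient_id").loc[ids]
    rows = []
    for c in configs:
        X = features_for(fp, measurements, patients, ids, c)
        r = conditional_risks(fp.forests[c], X, settings.landmark,
                              [horizon])[horizon].to_numpy()
        auc = metrics_mod.td_auc(r, pts["time_months"], pts["event"],
                                 settings.landmark, horizon)
        bs = metrics_mod.brier(r, pts["time_months"], pts["event"],
                               settings.landmark, horizon)
        rows.append({"model": c, "landmark": settings.landmark,
                     "horizon": horizon, "auc": auc, "brier": bs,
                     "n": len(ids)})
    return pd.DataFrame(rows)
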