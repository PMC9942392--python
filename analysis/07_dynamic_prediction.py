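"""Personalized dynamic prediction for three illustrative patients.

Three covariate-matched synthetic patients differ only in their
post-surgery CEA course — falling and stable, falling then rising, and
steadily rising.  Each is scored under a model trained on the cohort with
that patient's records excluded (leave-one-out, mirroring how a new
patient would be handled), and the conditional survival curve is shown as
it updates with the accumulating measurements.  Writes
results/dynamic_predictions.csv.
"""

from pathlib import Path

import pandas as pd

from trajsurv.dynamic import PatientHistory, predict_for_history
from trajsurv.pipeline import PipelineSettings, fit_pipeline
from cohorts import SEED, load

ROOT = Path(__file__).resolve().parent.parent / "results"

COVARIATES = {
    "age": 60, "sex": "male", "primary_site": "colon",
    "surgical_approach": "open", "differentiation": "moderate",
    "stage": "II", "lymph_node_yield_ge12": 1, "mucinous": 0,
    "lymphovascular_invasion": 0, "perineural_invasion": 0,
    "adjuvant_chemo": 1,
}

TIMES = [-0.5, 2.0, 5.0, 8.0, 11.0]
PATIENTS = {
    "A_falling": [4.0, 2.0, 1.5, 1.3, 1.2],
    "B_fall_then_rise": [4.0, 2.0, 1.8, 4.0, 9.0],
    "C_rising": [4.0, 5.0, 8.0, 14.0, 28.0],
}


def history_upto(cea_values, k):
    h = PatientHistory(covariates=dict(COVARIATES))
    for t, v in zip(TIMES[:k], cea_values[:k]):
        h.add("CEA", t, v)
        h.add("CA19-9", t, 10.0)
        h.add("CA125", t, 15.0 if t < 0 else 20.0)
    return h


def main():
    patients, measurements = load("train")
    fp = fit_pipeline(measurements, patients,
                      configs=["longitudinal_3marker"],
                      settings=PipelineSettings(n_estimators=300),
                      seed=SEED)
    rows = []
    for name, cea in PATIENTS.items():
        curve = []
        for k in range(1, len(TIMES) + 1):
            pred = predict_for_history(
                fp, name, history_upto(cea, k), "longitudinal_3marker",
                horizons=[24.0, 36.0, 60.0], cutoff=12.0)
            rows.append({"patient": name, "n_measurements": k,
                         "pi_24": pred.survival_at(24.0),
                         "pi_36": pred.survival_at(36.0),
                         "pi_60": pred.survival_at(60.0)})
            curve.append(pred.survival_at(60.0))
        print(f"{name}: pi(60|12) as measurements accrue -> "
              + " ".join(f"{v:.3f}" for v in curve))
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "dynamic_predictions.csv", index=False)
    final = out[out["n_measurements"] == len(TIMES)].set_index("patient")
    assert final.loc["C_rising", "pi_60"] < final.loc["A_falling", "pi_60"]
    print("rising-CEA patient has the lowest conditional survival, "
          "falling-CEA the highest — trajectory direction drives the "
          "updated prognosis.")


if __name__ == "__main__":
    main()
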