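"""Apply eligibility and landmark rules; summarize the cohorts.

Prints cohort descriptives (preop/first-postop medians per marker, event
counts) and writes the exclusion log and eligibility summary under
results/.
"""

from pathlib import Path

import pandas as pd

from trajsurv.preprocess import (
    apply_landmark,
    extract_anchor_values,
    filter_eligible,
)
from cohorts import load

ROOT = Path(__file__).resolve().parent.parent / "results"


def summarize(name):
    patients, measurements = load(name)
    eligible, excl = filter_eligible(measurements, patients)
    at_risk = set(apply_landmark(patients, 12.0))
    risk_set = [p for p in eligible if p in at_risk]
    anchors = extract_anchor_values(measurements)
    print(f"\n== {name} ==")
    print(f"cohort {len(patients)}; eligible {len(eligible)}; "
          f"landmark risk set {len(risk_set)}; excluded {len(excl)}")
    for m in ("CEA", "CA19-9", "CA125"):
        pre = anchors[f"preop_{m}"].median()
        post = anchors[f"postop_first_{m}"].median()
        print(f"  {m}: median preop {pre:.1f}, median first postop {post:.1f}")
    excl.to_csv(ROOT / f"exclusions_{name}.csv", index=False)
    pd.Series(risk_set, name="patient_id").to_csv(
        ROOT / f"risk_set_{name}.csv", index=False)


def main():
    for name in ("train", "external"):
        summarize(name)


if __name__ == "__main__":
    main()
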