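"""Shared cohort definitions for the analysis drivers.

The training and external cohorts are fully determined by the configs
below; any driver can regenerate them on demand, so no generated data needs
to live in the repository.
"""

from pathlib import Path

from trajsurv.simulate import (
    CensoringSpec,
    CohortConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
SEED = 101

TRAIN = CohortConfig(n_patients=500, seed=101)
EXTERNAL = CohortConfig(
    n_patients=300, seed=202,
    censoring=CensoringSpec(admin_horizon_months=66.0,
                            random_rate_per_month=0.002))


def ensure_cohorts(verbose=False):
    """Generate the cohort tables if they are not on disk yet."""
    for name, cfg in (("train", TRAIN), ("external", EXTERNAL)):
        target = DATA / name / "patients.csv"
        if target.exists():
            continue
        patients, measurements, truth = generate_cohort(cfg)
        write_cohort(DATA / name, patients, measurements, truth)
        if verbose:
            print(f"{name}: n={len(patients)}, "
                  f"events={patients['event'].sum()} "
                  f"({patients['event'].mean():.1%}), "
                  f"measurements={len(measurements)}")


def load(name):
    ensure_cohorts()
    return read_cohort(DATA / name)
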