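"""Generate the synthetic training and external-validation cohorts.

Two cohorts with the same trajectory/hazard mechanism but different seeds
and censoring — a stand-in (synthetic) for the two-hospital design the
pipeline targets, since real perioperative marker cohorts are not publicly
shareable.  Writes delimited tables plus ground-truth sidecars under
results/data/.
"""

from cohorts import DATA, ensure_cohorts


def main():
    ensure_cohorts(verbose=True)
    print(f"cohort tables under {DATA}")


if __name__ == "__main__":
    main()
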