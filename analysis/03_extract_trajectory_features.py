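"""Fit sparse FPCA per marker and the joint MFPCA on the training cohort.

Reports the AIC-selected number of components, eigenvalues and error
variances per marker and the joint variance decomposition; writes model
JSON and score tables under results/models/.
"""

from pathlib import Path

from trajsurv.mfpca import fit_mfpca
from trajsurv.pipeline import PipelineSettings, prepare_cohort, score_frames
from trajsurv.preprocess import build_series
from trajsurv.fpca import fit_fpca
from cohorts import load

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "models"


def main():
    patients, measurements = load("train")
    settings = PipelineSettings()
    ids = prepare_cohort(measurements, patients, settings)
    OUT.mkdir(parents=True, exist_ok=True)

    models = {}
    for m in settings.markers:
        series = build_series(measurements, m, settings.limits, ids)
        models[m] = fit_fpca(series, m, grid=settings.grid(),
                             k_candidates=settings.k_candidates)
        fm = models[m]
        print(f"{m}: K={fm.K} (AIC), eigenvalues "
              f"{[round(float(v), 2) for v in fm.lam]}, "
              f"error variance {fm.sigma2:.3f}, "
              f"bandwidths mean {fm.bandwidth_mean:.2f} / "
              f"cov {fm.bandwidth_cov:.2f}")
        (OUT / f"fpca_{m}.json").write_text(fm.to_json())

    uni = score_frames(models, measurements, ids, settings)
    mf, scores = fit_mfpca(uni, M=settings.mfpca_M)
    explained = mf.eigvals / mf.total_variance
    print(f"MFPCA: M={mf.M} of {mf.stacked_dim} stacked dimensions, "
          f"explaining {explained.sum():.1%} of stacked score variance")
    (OUT / "mfpca.json").write_text(mf.to_json())
    for m, frame in uni.items():
        frame.to_csv(OUT / f"scores_{m}.csv")
    scores.to_csv(OUT / "scores_mfpca.csv")


if __name__ == "__main__":
    main()
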