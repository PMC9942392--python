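"""Synthetic perioperative tumor-marker cohorts with known ground truth.

The generator emulates the data structure the pipeline assumes: three
correlated serum markers (CEA ng/ml, CA19-9 U/ml, CA125 U/ml) measured once
in the four weeks before colorectal surgery and sparsely, irregularly in the
twelve months after it.  Log-scale trajectories follow a Karhunen–Loève
process (smooth mean + subject scores on orthonormal eigenfunctions +
measurement error); CEA and CA19-9 mean curves fall after resection while
CA125 rises early before declining; occasional extreme spikes mimic assay
or inflammatory outliers.  Overall-survival times come from a Weibull hazard
whose log relative risk is linear in the leading true score of each marker
and in AJCC stage, with independent random plus administrative censoring —
so every downstream estimate can be checked against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpca import make_grid, trapezoid_weights

MARKER_NAMES = ("CEA", "CA19-9", "CA125")
WEEKS_PER_MONTH = 52.0 / 12.0

#: smooth log-scale mean shapes (months relative to surgery -> log level)
MEAN_SHAPES = {
    # preop ~4 ng/ml dropping toward ~1.9 by month 2 and staying low
    "cea_decline": lambda t: 1.4 - 0.75 * _sig(t, rate=2.0),
    # preop ~12.6 U/ml easing to ~9.4
    "ca199_decline": lambda t: 2.53 - 0.30 * _sig(t, rate=1.5),
    # preop ~12.9 U/ml, early post-surgery rise toward ~24.5 then decline
    "ca125_bump": lambda t: 2.56 + 0.65 * np.exp(-0.5 * ((t - 1.5) / 1.8) ** 2)
                            * _sig(t, rate=4.0),
    "flat": lambda t: np.full_like(np.asarray(t, dtype=float), 1.0),
}


def _sig(t, rate=2.0):
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(-rate * t))


def orthonormal_poly_basis(grid: np.ndarray, n: int) -> np.ndarray:
    """First ``n`` polynomials orthonormalized under trapezoid quadrature."""
    w = trapezoid_weights(grid)
    tc = (grid - grid.mean()) / (grid[-1] - grid[0])
    basis = []
    for j in range(n):
        v = tc ** j
        for b in basis:
            v = v - (v * b * w).sum() * b
        nrm = np.sqrt((v * v * w).sum())
        if nrm < 1e-12:
            raise ValueError("degenerate basis")
        v = v / nrm
        if (v * w).sum() < 0:
            v = -v
        basis.append(v)
    return np.asarray(basis)


@dataclass
class MarkerSpec:
    """Log-scale trajectory process for one marker."""

    name: str
    ref_upper: float
    mean_shape: str
    eigenvalues: tuple = (4.0, 1.0)
    sigma2: float = 0.10

    def __post_init__(self):
        if any(ev < 0 for ev in self.eigenvalues):
            raise ValueError(f"{self.name}: eigenvalues must be >= 0")
        if self.sigma2 < 0:
            raise ValueError(f"{self.name}: error variance must be >= 0")
        if self.mean_shape not in MEAN_SHAPES:
            raise ValueError(f"unknown mean shape {self.mean_shape!r}")


@dataclass
class VisitSpec:
    """Sampling design: one preop draw plus sparse postop visits."""

    mean_postop_visits: float = 4.0
    min_postop_visits: int = 2
    preop_window_weeks: float = 4.0
    jitter_sd_months: float = 0.6
    postop_horizon_months: float = 12.0


@dataclass
class HazardSpec:
    """Weibull baseline; log-hazard linear in leading scores and stage."""

    shape: float = 1.3
    scale: float = 280.0
    score_coefs: dict = field(default_factory=lambda: {
        "CEA": 0.28, "CA19-9": 0.18, "CA125": 0.18})
    stage_coefs: dict = field(default_factory=lambda: {
        "I": 0.0, "II": 0.5, "III": 1.1})

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull parameters must be positive")


@dataclass
class CensoringSpec:
    admin_horizon_months: float = 72.0
    random_rate_per_month: float = 0.004

    def __post_init__(self):
        if self.admin_horizon_months <= 0 or self.random_rate_per_month < 0:
            raise ValueError("invalid censoring spec")


@dataclass
class SpikeSpec:
    prob: float = 0.015
    log_magnitude: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("spike probability must be in [0, 1]")


@dataclass
class CohortConfig:
    n_patients: int = 500
    markers: tuple = field(default_factory=lambda: (
        MarkerSpec("CEA", 5.0, "cea_decline"),
        MarkerSpec("CA19-9", 37.0, "ca199_decline"),
        MarkerSpec("CA125", 35.0, "ca125_bump"),
    ))
    #: correlation between the *leading* true scores of different markers
    score_correlation: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.5, 0.4],
                                          [0.5, 1.0, 0.45],
                                          [0.4, 0.45, 1.0]]))
    visits: VisitSpec = field(default_factory=VisitSpec)
    hazard: HazardSpec = field(default_factory=HazardSpec)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    spikes: SpikeSpec = field(default_factory=SpikeSpec)
    seed: int = 0
    grid_size: int = 101

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        R = np.asarray(self.score_correlation, dtype=float)
        if R.shape != (len(self.markers),) * 2 or not np.allclose(R, R.T):
            raise ValueError("score correlation must be a symmetric matrix "
                             "with one row per marker")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("score correlation matrix is not positive "
                             "semi-definite")
        self.score_correlation = R


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    scores: dict            # marker -> (n, K) true scores
    event_time: np.ndarray  # T
    censor_time: np.ndarray  # C (incl. administrative horizon)
    grid: np.ndarray
    mean_functions: dict    # marker -> values on grid
    eigenfunctions: dict    # marker -> (K, G)
    eigenvalues: dict       # marker -> (K,)

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()
        return json.dumps({
            "scores": {m: arr(v) for m, v in self.scores.items()},
            "event_time": arr(self.event_time),
            "censor_time": arr(self.censor_time),
            "grid": arr(self.grid),
            "mean_functions": {m: arr(v) for m, v in self.mean_functions.items()},
            "eigenfunctions": {m: arr(v) for m, v in self.eigenfunctions.items()},
            "eigenvalues": {m: arr(v) for m, v in self.eigenvalues.items()},
        })


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

STAGE_LEVELS = ("I", "II", "III")
DIFF_LEVELS = ("well", "moderate", "poor")

COVARIATE_COLUMNS = [
    "age", "sex", "primary_site", "surgical_approach", "differentiation",
    "stage", "lymph_node_yield_ge12", "mucinous", "lymphovascular_invasion",
    "perineural_invasion", "adjuvant_chemo",
]


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "age": np.clip(np.round(rng.normal(58, 10, n)), 25, 88).astype(int),
        "sex": rng.choice(["male", "female"], n, p=[0.59, 0.41]),
        "primary_site": rng.choice(["colon", "rectum"], n, p=[0.51, 0.49]),
        "surgical_approach": rng.choice(["open", "laparoscopic"], n,
                                        p=[0.62, 0.38]),
        "differentiation": rng.choice(DIFF_LEVELS, n, p=[0.05, 0.63, 0.32]),
        "stage": rng.choice(STAGE_LEVELS, n, p=[0.13, 0.40, 0.47]),
        "lymph_node_yield_ge12": rng.binomial(1, 0.80, n),
        "mucinous": rng.binomial(1, 0.067, n),
        "lymphovascular_invasion": rng.binomial(1, 0.085, n),
        "perineural_invasion": rng.binomial(1, 0.021, n),
        "adjuvant_chemo": rng.binomial(1, 0.86, n),
    })


def _stacked_score_cov(config: CohortConfig) -> tuple[np.ndarray, list]:
    """Covariance of the stacked true scores; leading scores correlated."""
    blocks = [np.asarray(m.eigenvalues, dtype=float) for m in config.markers]
    dims = [len(b) for b in blocks]
    D = sum(dims)
    cov = np.zeros((D, D))
    starts = np.concatenate([[0], np.cumsum(dims)])
    for i, b in enumerate(blocks):
        s = starts[i]
        cov[s:s + dims[i], s:s + dims[i]] = np.diag(b)
    R = config.score_correlation
    for i in range(len(blocks)):
        for j in range(len(blocks)):
            if i != j and dims[i] and dims[j]:
                cov[starts[i], starts[j]] = (
                    R[i, j] * np.sqrt(blocks[i][0] * blocks[j][0]))
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
        raise ValueError("implied stacked score covariance is not PSD")
    return cov, list(starts[:-1])


def _visit_times(rng: np.random.Generator, visits: VisitSpec) -> np.ndarray:
    """One preop time (months, negative) + sparse postop times in (0, 12]."""
    preop = -rng.uniform(0.0, visits.preop_window_weeks) / WEEKS_PER_MONTH
    preop = min(preop, -1e-3)
    k = max(int(rng.poisson(visits.mean_postop_visits)),
            visits.min_postop_visits)
    anchors = np.arange(1, k + 1) / k * visits.postop_horizon_months
    post = anchors + rng.normal(0.0, visits.jitter_sd_months, k)
    post = np.clip(post, 0.05, visits.postop_horizon_months)
    post = np.unique(np.round(post, 4))
    while len(post) < visits.min_postop_visits:
        post = np.unique(np.append(
            post, rng.uniform(0.05, visits.postop_horizon_months)))
    return np.concatenate([[preop], np.sort(post)])


def simulate_survival(true_scores: dict, stage, hazard: HazardSpec,
                      censoring: CensoringSpec, seed):
    """Draw observed survival data from the configured hazard.

    ``true_scores``: marker -> (n, K) arrays; the leading score of each
    marker enters the log relative risk.  Inverse-transform sampling from
    the Weibull baseline: T = scale * (E / exp(eta))^(1/shape), E ~ Exp(1).
    Returns (observed_time, event, T, C).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    stage = np.asarray(stage)
    n = len(stage)
    eta = np.array([hazard.stage_coefs[s] for s in stage], dtype=float)
    for m, coef in hazard.score_coefs.items():
        if m in true_scores and true_scores[m].shape[1] > 0:
            eta += coef * true_scores[m][:, 0]
    E = rng.exponential(1.0, n)
    T = hazard.scale * (E / np.exp(eta)) ** (1.0 / hazard.shape)
    if censoring.random_rate_per_month > 0:
        Cr = rng.exponential(1.0 / censoring.random_rate_per_month, n)
    else:
        Cr = np.full(n, np.inf)
    C = np.minimum(Cr, censoring.admin_horizon_months)
    observed = np.minimum(T, C)
    event = (T <= C).astype(int)
    observed = np.maximum(observed, 1e-6)
    return observed, event, T, C


def generate_cohort(config: CohortConfig):
    """Generate (patients, measurements, GroundTruth); reproducible from seed.

    ``patients``: one row per patient with covariates, observed survival time
    (months) and event indicator.  ``measurements``: long format with columns
    (patient_id, marker, time_months, value); values are strictly positive
    raw marker units, exp(log-scale process + error), with optional spikes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    grid = make_grid(n=config.grid_size)

    bases = {}
    means = {}
    eigvals = {}
    for spec in config.markers:
        K = len(spec.eigenvalues)
        bases[spec.name] = orthonormal_poly_basis(grid, max(K, 1))[:K]
        means[spec.name] = MEAN_SHAPES[spec.mean_shape](grid)
        eigvals[spec.name] = np.asarray(spec.eigenvalues, dtype=float)

    cov, starts = _stacked_score_cov(config)
    L = _safe_cholesky(cov)
    stacked = rng.standard_normal((n, cov.shape[0])) @ L.T
    scores = {}
    for i, spec in enumerate(config.markers):
        K = len(spec.eigenvalues)
        scores[spec.name] = stacked[:, starts[i]:starts[i] + K]

    patients = _draw_covariates(n, rng)
    patients.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])

    observed, event, T, C = simulate_survival(
        scores, patients["stage"].to_numpy(), config.hazard,
        config.censoring, rng)
    patients["time_months"] = observed
    patients["event"] = event

    rows = []
    for i in range(n):
        times = _visit_times(rng, config.visits)
        for spec in config.markers:
            mu_t = MEAN_SHAPES[spec.mean_shape](times)
            phi_t = np.array([np.interp(times, grid, b)
                              for b in bases[spec.name]])
            latent = mu_t + scores[spec.name][i] @ phi_t if len(
                spec.eigenvalues) else mu_t
            noise = (rng.normal(0.0, np.sqrt(spec.sigma2), len(times))
                     if spec.sigma2 > 0 else 0.0)
            logval = latent + noise
            if config.spikes.prob > 0:
                hit = rng.random(len(times)) < config.spikes.prob
                logval = logval + hit * config.spikes.log_magnitude
            for t, v in zip(times, np.exp(logval)):
                rows.append((patients.at[i, "patient_id"], spec.name,
                             float(t), float(v)))
    measurements = pd.DataFrame(
        rows, columns=["patient_id", "marker", "time_months", "value"])

    truth = GroundTruth(scores=scores, event_time=T, censor_time=C, grid=grid,
                        mean_functions=means, eigenfunctions=bases,
                        eigenvalues=eigvals)
    return patients, measurements, truth


def _safe_cholesky(cov):
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def write_cohort(outdir, patients: pd.DataFrame, measurements: pd.DataFrame,
                 truth: GroundTruth | None = None):
    """Write the delimited cohort files (and ground-truth JSON sidecar)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients.to_csv(outdir / "patients.csv", index=False)
    measurements.to_csv(outdir / "measurements.csv", index=False)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())


def read_cohort(indir):
    from pathlib import Path
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv")
    measurements = pd.read_csv(indir / "measurements.csv")
    return patients, measurements
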