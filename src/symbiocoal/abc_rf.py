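"""Random-forest regression ABC for theta and the per-site recombination
impact rho*l.

Training data come from the gene-conversion coalescent: parameters are drawn
from log-uniform priors on theta and rho and a uniform prior on the tract
length, each draw is simulated and summarized into the feature vector
(pi, Watterson's theta, six distance-binned four-gamete proportions), and one
regression forest per target is fitted - theta on its natural scale,
rho*l on log10. Point estimates come from the forest mean; 95% intervals from
the infinitesimal-jackknife variance of bagged predictors (Wager, Hastie &
Efron 2014), computed from the trees' bootstrap membership counts.

Empty four-gamete bins are imputed as 0 with a paired missingness indicator
appended to the feature vector.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_sample_indices

from .coalescent_gc import SimParams, simulate_coalescent_gc
from .sumstats import SummaryVector, summarize_alignment

logger = logging.getLogger(__name__)

TARGET_NAMES = ("theta", "log10_rho_l")

FEATURE_NAMES = (
    "pi",
    "watterson",
    "f4_bin1",
    "f4_bin2",
    "f4_bin3",
    "f4_bin4",
    "f4_bin5",
    "f4_bin6",
    "f4_bin1_missing",
    "f4_bin2_missing",
    "f4_bin3_missing",
    "f4_bin4_missing",
    "f4_bin5_missing",
    "f4_bin6_missing",
)


class ContractError(ValueError):
    """Observed data do not match the model's training contract."""


@dataclass(frozen=True)
class PriorSpec:
    """Log-uniform priors on per-site theta and rho; uniform on tract length."""

    theta_bounds: tuple[float, float] = (3e-5, 1e-2)
    rho_bounds: tuple[float, float] = (1e-6, 1e-2)
    tract_bounds: tuple[float, float] = (1.0, 1e5)

    def __post_init__(self) -> None:
        for lo, hi in (self.theta_bounds, self.rho_bounds, self.tract_bounds):
            if not 0 < lo < hi:
                raise ValueError("prior bounds must be positive and ordered")


@dataclass
class PriorDraw:
    """One prior draw; ``tract_length`` may exceed the simulated genome, in
    which case the simulator truncates tracts at the sequence end."""

    theta: float
    rho: float
    tract_length: int


def sample_priors(spec: PriorSpec, n_draws: int, seed: int) -> list[PriorDraw]:
    """Draw (theta, rho, l) from the priors; l is rounded to integer bp."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lt = rng.uniform(*np.log10(spec.theta_bounds), size=n_draws)
    lr = rng.uniform(*np.log10(spec.rho_bounds), size=n_draws)
    tract = rng.uniform(*spec.tract_bounds, size=n_draws)
    return [
        PriorDraw(theta=float(10**a), rho=float(10**b), tract_length=int(round(t)))
        for a, b, t in zip(lt, lr, tract)
    ]


def features_from_summary(sv: SummaryVector) -> np.ndarray:
    """Map a summary vector onto the training feature contract."""
    f4 = np.asarray(sv.f4_bins, dtype=float)
    missing = np.isnan(f4)
    return np.concatenate(
        ([sv.pi, sv.watterson], np.where(missing, 0.0, f4), missing.astype(float))
    )


@dataclass
class TrainingSet:
    features: np.ndarray        # (n_simulations, len(FEATURE_NAMES))
    targets: np.ndarray         # (n_simulations, 3): theta, log10(rho*l), l
    sample_size: int
    genome_length: int
    n_simulations: int
    n_degenerate: int = 0       # rows with no segregating sites (zero features)

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError("feature and target row counts differ")


def build_training_set(
    spec: PriorSpec,
    n_sims: int,
    sample_size: int,
    genome_length: int,
    seed: int,
) -> TrainingSet:
    """Simulate ``n_sims`` prior draws and summarize each into features.

    Degenerate replicates (no segregating sites) are retained with all-zero
    four-gamete features and their count logged, so the fitted forest sees
    the low-information regime the priors produce.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    draws = sample_priors(spec, n_sims, seed)
    rng = np.random.default_rng(seed + 1)
    feats = np.empty((n_sims, len(FEATURE_NAMES)))
    targets = np.empty((n_sims, 3))
    n_degenerate = 0
    for i, d in enumerate(draws):
        params = SimParams(
            theta=d.theta,
            rho=d.rho,
            tract_length=min(d.tract_length, genome_length),
            genome_length=genome_length,
            sample_size=sample_size,
            seed=int(rng.integers(2**31)),
        )
        try:
            rep = simulate_coalescent_gc(params)
        except Exception:
            logger.exception("simulation failed for draw %d: %s", i, d)
            raise
        sv = summarize_alignment(rep.alignment)
        if sv.watterson == 0:
            n_degenerate += 1
        feats[i] = features_from_summary(sv)
        targets[i] = (d.theta, np.log10(d.rho * d.tract_length), d.tract_length)
    if n_degenerate:
        logger.info("%d/%d training rows are degenerate (S = 0)", n_degenerate, n_sims)
    return TrainingSet(
        features=feats,
        targets=targets,
        sample_size=sample_size,
        genome_length=genome_length,
        n_simulations=n_sims,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# forest fitting and the infinitesimal jackknife
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    theta_hat: float
    rho_l_hat: float
    log10_rho_l_hat: float
    ci: dict[str, tuple[float, float]]
    oob_scores: dict[str, float]
    sample_size: int
    low_information: bool = False


@dataclass
class RFModel:
    """One regression forest per target, plus the training bookkeeping the
    infinitesimal jackknife and the feature contract need.

    ``residual_calibration`` maps each target to (prediction-bin edges,
    per-bin out-of-bag residual standard deviations); interval construction
    adds this local noise variance to the IJ estimator variance, since the
    prediction error of a regression forest is dominated by irreducible
    observation noise rather than estimator variability.
    """

    forests: dict[str, RandomForestRegressor]
    oob_scores: dict[str, float]
    sample_size: int
    genome_length: int
    n_train: int
    feature_checksum: str
    residual_calibration: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    format_version: int = 1

    def residual_sd(self, target: str, predictions: np.ndarray) -> np.ndarray:
        edges, sds = self.residual_calibration[target]
        idx = np.clip(np.searchsorted(edges, predictions) - 1, 0, len(sds) - 1)
        return sds[idx]

    def oob_predictions(self, target: str) -> np.ndarray:
        return self.forests[target].oob_prediction_


def _feature_checksum() -> str:
    return hashlib.sha256("|".join(FEATURE_NAMES).encode()).hexdigest()[:16]


def fit_rf(train: TrainingSet, n_trees: int = 500, seed: int = 0) -> RFModel:
    """Fit one forest per target (theta natural scale, rho*l log10)."""
    if train.n_simulations < 100:
        raise ValueError("need >= 100 training rows")
    if train.n_simulations < n_trees:
        logger.warning(
            "training rows (%d) fewer than trees (%d)", train.n_simulations, n_trees
        )
    forests: dict[str, RandomForestRegressor] = {}
    oob: dict[str, float] = {}
    calibration: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, name in enumerate(TARGET_NAMES):
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            oob_score=True,
            bootstrap=True,
            random_state=seed + j,
            n_jobs=1,
            min_samples_leaf=5,
            max_features=0.33,
        )
        rf.fit(train.features, train.targets[:, j])
        forests[name] = rf
        oob[name] = float(rf.oob_score_)
        # local noise calibration: oob residual sd in quantile bins of the
        # oob prediction (the targets are strongly heteroscedastic)
        oobp = rf.oob_prediction_
        res = train.targets[:, j] - oobp
        edges = np.quantile(oobp, np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        bins = np.clip(np.searchsorted(edges, oobp) - 1, 0, 9)
        sds = np.array([res[bins == k].std() for k in range(10)])
        calibration[name] = (edges, sds)
    return RFModel(
        forests=forests,
        oob_scores=oob,
        sample_size=train.sample_size,
        genome_length=train.genome_length,
        n_train=train.n_simulations,
        feature_checksum=_feature_checksum(),
        residual_calibration=calibration,
    )


def _inbag_counts(rf: RandomForestRegressor, n_train: int) -> np.ndarray:
    """(n_train, n_trees) bootstrap membership counts, replayed from each
    tree's recorded random state."""
    counts = np.empty((n_train, len(rf.estimators_)))
    for b, est in enumerate(rf.estimators_):
        idx = _generate_sample_indices(est.random_state, n_train, n_train, None)
        counts[:, b] = np.bincount(idx, minlength=n_train)
    return counts


def infinitesimal_jackknife_variance(
    rf: RandomForestRegressor,
    x: np.ndarray,
    n_train: int | None = None,
    inbag: np.ndarray | None = None,
) -> np.ndarray:
    """Bias-corrected IJ variance of forest predictions at rows of ``x``."""
    x = np.atleast_2d(x)
    if n_train is None:
        n_train = int(rf.estimators_[0].tree_.n_node_samples[0])  # bootstrap size == n
    if inbag is None:
        inbag = _inbag_counts(rf, n_train)
    tree_preds = np.stack([est.predict(x) for est in rf.estimators_], axis=0)  # (B, m)
    B = tree_preds.shape[0]
    t_c = tree_preds - tree_preds.mean(axis=0, keepdims=True)
    n_c = inbag - inbag.mean(axis=1, keepdims=True)
    cov = n_c @ t_c / B                      # (n_train, m)
    v_ij = (cov**2).sum(axis=0)
    boot_var = (t_c**2).sum(axis=0) / B
    v_unbiased = v_ij - n_train * boot_var / B
    return np.maximum(v_unbiased, 1e-12)


def estimate(model: RFModel, observed: SummaryVector, level: float = 0.95) -> FitResult:
    """Point estimates with IJ normal-theory intervals for one observation."""
    if observed.n_samples != model.sample_size:
        raise ContractError(
            f"observed sample size {observed.n_samples} does not match the "
            f"model's training sample size {model.sample_size}; train a "
            f"forest for this sample size"
        )
    if model.feature_checksum != _feature_checksum():
        raise ContractError("feature contract checksum mismatch")
    x = features_from_summary(observed)[None, :]
    low_info = bool(np.all(x[0, :8] == 0))
    if low_info:
        warnings.warn(
            "observed summary vector carries no polymorphism; the estimate "
            "reflects the prior's low-information regime",
            stacklevel=2,
        )
    z = stats.norm.ppf(0.5 + level / 2)
    point: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name, rf in model.forests.items():
        mu = float(rf.predict(x)[0])
        v_ij = infinitesimal_jackknife_variance(rf, x, n_train=model.n_train)[0]
        noise_sd = float(model.residual_sd(name, np.array([mu]))[0])
        sd = float(np.sqrt(v_ij + noise_sd**2))
        point[name] = mu
        ci[name] = (mu - z * sd, mu + z * sd)
    lo, hi = ci["log10_rho_l"]
    ci["rho_l"] = (10**lo, 10**hi)
    return FitResult(
        theta_hat=point["theta"],
        rho_l_hat=10 ** point["log10_rho_l"],
        log10_rho_l_hat=point["log10_rho_l"],
        ci=ci,
        oob_scores=dict(model.oob_scores),
        sample_size=model.sample_size,
        low_information=low_info,
    )


def save_model(model: RFModel, path: str | Path) -> None:
    import joblib

    joblib.dump(
        {
            "format_version": model.format_version,
            "feature_checksum": model.feature_checksum,
            "model": model,
        },
        path,
    )


def load_model(path: str | Path) -> RFModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("feature_checksum") != _feature_checksum():
        raise ContractError("serialized model was built under a different feature contract")
    return payload["model"]


# ---------------------------------------------------------------------------
# r/m
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateSummary:
    """rho*l together with its conversion to r/m.

    r/m = rho*l * theta_recombinant / theta_genome; when donor fragments are
    as diverse as the genome at large the two coincide and r/m = rho*l.
    """

    rho_l: float
    theta_recombinant: float
    theta_genome: float

    @property
    def r_over_m(self) -> float:
        return self.rho_l * self.theta_recombinant / self.theta_genome


def r_over_m(rho_l: float, theta_recombinant: float, theta_genome: float) -> RateSummary:
    if theta_genome <= 0:
        raise ValueError("theta_genome must be > 0")
    return RateSummary(rho_l=rho_l, theta_recombinant=theta_recombinant,
                       theta_genome=theta_genome)
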