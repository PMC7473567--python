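"""End-to-end orchestration: observed alignment -> summary statistics ->
per-sample-size forest -> estimates -> r/m report, plus a validation command
that reruns the model-consistency suites at configurable scale.

Every run writes a resolved-config JSON and a log file beside its outputs, so
any artifact can be regenerated from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import abc_rf, coalescent_gc, sumstats, transmission_model
from .io_formats import read_fasta_alignment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative parameters of one pipeline run."""

    out_dir: str
    seed: int = 0
    verbosity: int = 1
    # fit pipeline
    observed_fasta: str | None = None
    theta_recombinant: float | None = None  # defaults to the genome-wide estimate
    n_training_sims: int = 2_000
    genome_length: int = 20_000
    n_trees: int = 500
    train_cache_dir: str | None = None
    allow_training: bool = True
    # validation
    grid_size: int | None = None  # limit the agreement grid to its first k settings
    grid_replicates: int = 50
    calibration_replicates: int = 300
    recovery_sims: int = 0  # 0 skips the (slow) recovery suite
    expectation_offset: float = 0.0  # test-harness knob: perturbs the closed form

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _start_run(config: RunConfig, name: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{name}.config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    handler = logging.FileHandler(out / f"{name}.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("symbiocoal").addHandler(handler)
    level = logging.DEBUG if config.verbosity > 1 else logging.INFO
    logging.getLogger("symbiocoal").setLevel(level)
    return out


def _training_cache_key(config: RunConfig, sample_size: int) -> str:
    spec = abc_rf.PriorSpec()
    payload = json.dumps(
        [spec.theta_bounds, spec.rho_bounds, spec.tract_bounds,
         sample_size, config.genome_length, config.n_training_sims, config.seed]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def get_model(config: RunConfig, sample_size: int) -> abc_rf.RFModel:
    """Load a cached per-sample-size forest or train one."""
    cache_dir = Path(config.train_cache_dir) if config.train_cache_dir else None
    cache_path = None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_path = cache_dir / f"rf_{_training_cache_key(config, sample_size)}.joblib"
        if cache_path.exists():
            logger.info("loading cached model %s", cache_path)
            return abc_rf.load_model(cache_path)
    if not config.allow_training:
        raise abc_rf.ContractError(
            f"no trained model for sample size {sample_size} and training is "
            f"disabled; enable training or point train_cache_dir at a model"
        )
    t0 = time.time()
    logger.info("training: n_sims=%d n=%d L=%d", config.n_training_sims, sample_size,
                config.genome_length)
    train = abc_rf.build_training_set(
        abc_rf.PriorSpec(), config.n_training_sims, sample_size,
        config.genome_length, seed=config.seed,
    )
    model = abc_rf.fit_rf(train, n_trees=config.n_trees, seed=config.seed)
    logger.info("training done in %.1fs; oob=%s", time.time() - t0, model.oob_scores)
    if cache_path is not None:
        abc_rf.save_model(model, cache_path)
    return model


def run_fit_pipeline(config: RunConfig) -> Path:
    """Summarize an observed alignment, estimate theta and rho*l, report r/m.

    Returns the path of the TSV report. Fails loudly when no model matches
    the observed sample size and training is disabled.
    """
    if config.observed_fasta is None:
        raise FileNotFoundError("config.observed_fasta is required")
    if not Path(config.observed_fasta).exists():
        raise FileNotFoundError(f"observed alignment not found: {config.observed_fasta}")
    out = _start_run(config, "fit")
    aln = read_fasta_alignment(config.observed_fasta)
    sv = sumstats.summarize_alignment(aln)
    logger.info("observed: n=%d pi=%.3g thetaW=%.3g", sv.n_samples, sv.pi, sv.watterson)
    model = get_model(config, sv.n_samples)
    fit = abc_rf.estimate(model, sv)
    theta_rec = (
        config.theta_recombinant if config.theta_recombinant is not None else fit.theta_hat
    )
    rate = abc_rf.r_over_m(fit.rho_l_hat, theta_rec, fit.theta_hat)

    report = out / "fit.tsv"
    cols = [
        ("pi", sv.pi),
        ("watterson_theta", sv.watterson),
        ("rf_theta", fit.theta_hat),
        ("rf_theta_ci_low", fit.ci["theta"][0]),
        ("rf_theta_ci_high", fit.ci["theta"][1]),
        ("log10_rho_l", fit.log10_rho_l_hat),
        ("log10_rho_l_ci_low", fit.ci["log10_rho_l"][0]),
        ("log10_rho_l_ci_high", fit.ci["log10_rho_l"][1]),
        ("rho_l", fit.rho_l_hat),
        ("r_over_m", rate.r_over_m),
        ("oob_theta", fit.oob_scores["theta"]),
        ("oob_log10_rho_l", fit.oob_scores["log10_rho_l"]),
        ("n_samples", sv.n_samples),
    ]
    with open(report, "w") as fh:
        fh.write("\t".join(k for k, _ in cols) + "\n")
        fh.write("\t".join(f"{v:.6g}" for _, v in cols) + "\n")
    logger.info("fit report written to %s", report)
    return report


def run_validation(config: RunConfig) -> Path:
    """Re-run the model-consistency suites and emit a pass/fail TSV.

    Covers the transmission-model closed-form agreement grid, the coalescent
    calibration against Watterson's expectation, optionally a small
    parameter-recovery run, and the read-backed phasing threshold behavior.
    ``expectation_offset`` deliberately perturbs the closed form - a harness
    knob for verifying the report flags disagreement.
    """
    out = _start_run(config, "validate")
    rows: list[tuple[str, str, float, float, bool]] = []

    # 1. closed-form vs forward simulation over the desk grid
    t0 = time.time()
    grid = transmission_model.DEFAULT_AGREEMENT_GRID
    if config.grid_size is not None:
        grid = grid[: config.grid_size]
    results = transmission_model.run_agreement_grid(
        grid=grid, n_replicates=config.grid_replicates, seed=config.seed
    )
    max_dev = max(
        abs(r.observed_mean - (r.expected + config.expectation_offset)) for r in results
    )
    rows.append(("transmission_eq_agreement", "max|expected-observed|", max_dev, 2.0,
                 max_dev < 2.0))
    logger.info("agreement grid done in %.1fs (max dev %.3f)", time.time() - t0, max_dev)

    # 2. coalescent calibration: S against Watterson's expectation at n=2
    params = coalescent_gc.SimParams(
        theta=1e-3, rho=0.0, tract_length=1, genome_length=10_000,
        sample_size=2, seed=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    s_counts = []
    for _ in range(config.calibration_replicates):
        p = coalescent_gc.SimParams(
            theta=params.theta, rho=0.0, tract_length=1,
            genome_length=params.genome_length, sample_size=2,
            seed=int(rng.integers(2**31)),
        )
        s_counts.append(len(coalescent_gc.simulate_coalescent_gc(p).alignment.variant_positions))
    expected = coalescent_gc.expected_segregating_sites(params)
    se = np.std(s_counts) / np.sqrt(len(s_counts))
    dev = abs(np.mean(s_counts) - expected)
    rows.append(("coalescent_calibration", "|mean S - theta L| / SE", dev / se, 3.0,
                 dev <= 3 * se))

    # 3. optional small recovery run
    if config.recovery_sims >= 100:
        from scipy import stats as sps

        train = abc_rf.build_training_set(
            abc_rf.PriorSpec(), config.recovery_sims, sample_size=10,
            genome_length=config.genome_length, seed=config.seed,
        )
        model = abc_rf.fit_rf(train, n_trees=min(config.n_trees, 300), seed=config.seed)
        rho_theta = sps.spearmanr(
            train.targets[:, 0], model.oob_predictions("theta")
        ).statistic
        rows.append(("rf_theta_recovery", "oob Spearman", float(rho_theta), 0.9,
                     rho_theta >= 0.9))

    # 4. phasing threshold behavior on constructed tallies
    from .intrahost import read_pair_four_gamete
    from .synthetic_data import PhaseObservation

    obs = []
    for config_label, count in (("AB", 30), ("Ab", 30), ("aB", 30), ("ab", 30)):
        for i in range(count):
            obs.append(PhaseObservation(f"{config_label}{i}", 10,
                                        "A" if config_label[0] == "A" else "C",
                                        20, "G" if config_label[1] == "B" else "T"))
    tally = read_pair_four_gamete(obs)
    ok = len(tally.flagged()) == 1
    rows.append(("phasing_flags_balanced_mixture", "flagged pairs", float(len(tally.flagged())),
                 1.0, ok))

    report = out / "validation.tsv"
    with open(report, "w") as fh:
        fh.write("check\tmetric\tvalue\tbound\tpass\n")
        for name, metric, value, bound, passed in rows:
            fh.write(f"{name}\t{metric}\t{value:.4f}\t{bound}\t{passed}\n")
    logger.info("validation report written to %s", report)
    return report
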