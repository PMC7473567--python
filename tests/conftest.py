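import numpy as np
import pytest

from symbiocoal.abc_rf import PriorSpec, TrainingSet, build_training_set, fit_rf
from symbiocoal.synthetic_data import fixture_F1


@pytest.fixture(scope="session")
def f1_alignment():
    return fixture_F1()


@pytest.fixture(scope="session")
def trained_bundle():
    """The desk-scale training run shared by the estimator tests: 2,000 prior
    draws at n = 10 on 20 kb, a 500-tree forest per target, and 200 held-out
    simulations for interval calibration checks."""
    train = build_training_set(
        PriorSpec(), n_sims=2_000, sample_size=10, genome_length=20_000, seed=42
    )
    model = fit_rf(train, n_trees=500, seed=0)
    held = build_training_set(
        PriorSpec(), n_sims=200, sample_size=10, genome_length=20_000, seed=777
    )
    return train, model, held


def bootstrap_ci(values, n_boot=2_000, seed=0, level=95):
    """Percentile bootstrap interval for a replicate mean."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    means = rng.choice(values, size=(n_boot, values.size)).mean(axis=1)
    half = (100 - level) / 2
    return tuple(np.percentile(means, [half, 100 - half]))
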