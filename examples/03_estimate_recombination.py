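"""Estimate theta and rho*l for a synthetic observed alignment with the
random-forest regression ABC, then convert to r/m.

Uses a reduced training run (400 simulations, 200 trees) so the example
finishes in about half a minute; analyses use the package defaults
(2,000 simulations, 500 trees).

Run: python examples/03_estimate_recombination.py
"""

import numpy as np

from symbiocoal import (
    PriorSpec,
    SimParams,
    build_training_set,
    estimate,
    fit_rf,
    r_over_m,
    simulate_coalescent_gc,
    summarize_alignment,
)

TRUE_THETA, TRUE_RHO, TRUE_TRACT = 2e-3, 1e-3, 1_000

observed = simulate_coalescent_gc(SimParams(
    theta=TRUE_THETA, rho=TRUE_RHO, tract_length=TRUE_TRACT,
    genome_length=20_000, sample_size=10, seed=99,
)).alignment
sv = summarize_alignment(observed)

train = build_training_set(PriorSpec(), n_sims=400, sample_size=10,
                           genome_length=20_000, seed=1)
model = fit_rf(train, n_trees=200, seed=0)
fit = estimate(model, sv)

true_log = np.log10(TRUE_RHO * TRUE_TRACT)
print(f"true theta {TRUE_THETA:.4g}; estimate {fit.theta_hat:.4g} "
      f"(95% CI {fit.ci['theta'][0]:.4g} .. {fit.ci['theta'][1]:.4g})")
print(f"true log10(rho*l) {true_log:.2f}; estimate {fit.log10_rho_l_hat:.2f} "
      f"(95% CI {fit.ci['log10_rho_l'][0]:.2f} .. {fit.ci['log10_rho_l'][1]:.2f})")
print(f"out-of-bag scores: {fit.oob_scores}")

rate = r_over_m(fit.rho_l_hat, fit.theta_hat, fit.theta_hat)
print(f"r/m = {rate.r_over_m:.2f}: recombination introduces this many times "
      f"more nucleotide changes than mutation when donors are as diverse as "
      f"the genome at large.")
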