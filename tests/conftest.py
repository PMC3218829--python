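"""Shared fixtures.

The parameter-recovery and classification benchmarks fit the mixture on many
simulated datasets of 20,000 windows; those fits are computed once per
session and shared by every test that asserts a property of them.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from zinba.simulate import (
    evaluate_classification,
    benchmark_scenarios,
    model_design,
    simulate_dataset,
)
from zinba.zinb_mixture import fit_mixture

logging.getLogger("zinba").setLevel(logging.ERROR)

N_BENCH_SEEDS = 20
N_BENCH_WINDOWS = 20_000


@pytest.fixture(scope="session")
def high_snr_neg_fits():
    """Model-3 fits on the high-SNR, negative-G/C-effect scenario, one per seed.

    Returns a list of dicts with the simulated data, the fit, and the
    classification AUC against the latent labels.
    """
    out = []
    for seed in range(N_BENCH_SEEDS):
        cfg = benchmark_scenarios(seed=seed, n_windows=N_BENCH_WINDOWS)[("tfbs", "neg")]
        sim = simulate_dataset(cfg)
        fit = fit_mixture(model_design(sim, 3))
        auc = evaluate_classification(sim.truth, fit.posteriors.tau2).auc
        out.append({"sim": sim, "fit": fit, "auc": auc})
    return out


@pytest.fixture(scope="session")
def low_snr_neg_auc_pairs():
    """(AUC model 3, AUC model 1) per seed on the low-SNR (10% enrichment),
    negative-G/C-effect scenario."""
    pairs = []
    for seed in range(N_BENCH_SEEDS):
        cfg = benchmark_scenarios(seed=seed, n_windows=N_BENCH_WINDOWS)[("histone", "neg")]
        sim = simulate_dataset(cfg)
        auc3 = evaluate_classification(
            sim.truth, fit_mixture(model_design(sim, 3)).posteriors.tau2
        ).auc
        auc1 = evaluate_classification(
            sim.truth, fit_mixture(model_design(sim, 1)).posteriors.tau2
        ).auc
        pairs.append((auc3, auc1))
    return pairs
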