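"""Shared fixtures: small simulated datasets reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from dnvprior.bulk_model import BulkFitConfig, fit_uniform_prior
from dnvprior.core_stats import RelativeRiskParams
from dnvprior.sc_model import TrainingConfig, train_semisupervised
from dnvprior.simulators import (
    BulkScenarioConfig,
    ScScenarioConfig,
    simulate_bulk_scenario,
    simulate_sc_scenario,
    synthesize_expression_matrix,
)


@pytest.fixture(scope="session")
def rr_chd() -> RelativeRiskParams:
    """Relative-risk hyperparameters at the magnitude of a CHD-type fit."""
    return RelativeRiskParams(
        gamma_bar={"LGD": 20.0, "Dmis": 12.0},
        beta_bar={"LGD": 0.84, "Dmis": 0.90},
    )


@pytest.fixture(scope="session")
def bulk_small():
    """One bulk-scenario dataset, 4000 genes, cohort 20k (fast fits)."""
    cfg = BulkScenarioConfig(n_genes=4000, seed=7)
    return simulate_bulk_scenario(cfg, cohort_size=20_000)


@pytest.fixture(scope="session")
def sc_setup():
    """One sc-scenario dataset (6000 genes, 40 cell types) with a trained fit.

    Returns (expression, dataset, baseline_result, trained_result); shared so
    the network is trained once for all recovery/association tests.
    """
    expr, prior_labels = synthesize_expression_matrix(
        n_genes=6000, n_cell_types=40, seed=11
    )
    cfg = ScScenarioConfig(
        expression=expr,
        prior_positives=prior_labels.positives,
        prior_negatives=prior_labels.negatives,
        seed=11,
        n_label_risk=60,
        n_label_nonrisk=180,
    )
    ds = simulate_sc_scenario(cfg, replicates=[0])[0]
    base = fit_uniform_prior(ds.genes, BulkFitConfig(method="map", seed=2))
    rr0 = RelativeRiskParams(
        gamma_bar={v: base.rr.gamma_bar[v] for v in ("LGD", "Dmis")},
        beta_bar={v: base.rr.beta_bar[v] for v in ("LGD", "Dmis")},
    )
    res = train_semisupervised(
        expr, ds.genes, ds.labels, rr0, TrainingConfig(seed=3),
        pi_bar=base.params["pi_bar"],
    )
    return expr, ds, base, res
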