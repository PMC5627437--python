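"""Shared fixtures: small simulated data sets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from favsig import (TumorSimConfig, simulate_cellline_panel,
                    simulate_phenotype_panel, simulate_tumor_cohort)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted tumor cohort (n=200, 1000 genes, 25+25 planted)."""
    return simulate_tumor_cohort(TumorSimConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Pure-null cohort: no planted hazard or confounded genes."""
    cfg = TumorSimConfig(n_samples=100, n_genes=500, n_favorable=0,
                         n_unfavorable=0, n_confounded=0, seed=7)
    return simulate_tumor_cohort(cfg)


@pytest.fixture(scope="session")
def confounded_cohort():
    """Cohort with TP53-confounded genes (n=100) for filter tests."""
    cfg = TumorSimConfig(n_samples=100, n_genes=400, n_favorable=25,
                         n_unfavorable=25, n_confounded=25, seed=23)
    return simulate_tumor_cohort(cfg)


@pytest.fixture(scope="session")
def cellline_panel():
    """Planted cell-line panel: 44 lines, tau 0.4, 50 signal genes."""
    return simulate_cellline_panel(
        n_lines=44, n_genes=600, n_signal=50, target_tau=0.4, seed=5)


@pytest.fixture(scope="session")
def phenotype_panel():
    """NCI-60-like phenotype panel (60 lines, 17 drugs, 3 families)."""
    return simulate_phenotype_panel(seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
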