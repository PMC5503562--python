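"""Shared fixtures: a small synthetic multi-cancer world reused across tests."""

import pytest

from prolifindex import pipeline
from prolifindex.simulate import (SimulationConfig, simulate_cohort,
                                  simulate_mutations, simulate_drug_panels)


@pytest.fixture(scope="session")
def small_cfg():
    # 6 cancers (2 planted PICs), 80 patients each: big enough for k=18
    # dichotomization and per-gene scans, small enough to simulate in seconds.
    return SimulationConfig(n_cancers=6, n_pics=2, n_patients=80, n_genes=120,
                            n_pi_genes=30, n_second_genes=20, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    expr, cohort, truth = simulate_cohort(small_cfg)
    return expr, cohort, truth


@pytest.fixture(scope="session")
def small_analysis(small_cfg, small_sim):
    expr, cohort, truth = small_sim
    return pipeline.survival_analysis(expr, cohort, truth.pi_gene_set,
                                      shared_min_cancers=3)


@pytest.fixture(scope="session")
def small_mutations(small_cfg, small_sim):
    expr, cohort, truth = small_sim
    return simulate_mutations(truth, cohort, small_cfg)


@pytest.fixture(scope="session")
def small_panels(small_cfg, small_sim):
    expr, cohort, truth = small_sim
    return simulate_drug_panels(truth, small_cfg)
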