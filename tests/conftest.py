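"""Shared fixtures: small fitted models and the two replicate studies.

The replicate studies are expensive, so they are computed once per session
and shared between the tests that assess selection behavior under the null
and under genetic effects.
"""

from __future__ import annotations

import numpy as np
import pytest

from kernboost.boosting import kernel_boost
from kernboost.pipeline import build_base_learners, null_selection_study, power_study
from kernboost.simulate import SimulationScenario, simulate_scenario

# Study conditions: the null study keeps the 50-pathway universe of the
# original design (the false-selection rate is normalized per pathway) with
# n = 400 individuals and 20 replicates; the effect study uses RR 1.5 per
# allele at n = 1000 with 10 pathways, 2 of them causal.
NULL_STUDY_SEED = 20260
POWER_STUDY_SEED = 20261


@pytest.fixture(scope="session")
def null_study():
    return null_selection_study(
        n_replicates=20, n_pathways=50, genes_per_pathway=30, n=400,
        m_max=100, n_folds=10, seed=NULL_STUDY_SEED,
    )


@pytest.fixture(scope="session")
def effect_study():
    return power_study(
        n_replicates=20, rr_per_allele=1.5, n_cases=500, n_controls=500,
        n_pathways=10, genes_per_pathway=30, m_max=100, n_folds=10,
        seed=POWER_STUDY_SEED, compute_lkmt=True,
    )


@pytest.fixture(scope="session")
def small_effect_data():
    """One small effect-scenario dataset (n = 300, 4 pathways, 2 causal)."""
    scenario = SimulationScenario(
        n_cases=150, n_controls=150, rr_per_allele=1.5,
        n_pathways=4, genes_per_pathway=10, density=0.3,
    )
    return simulate_scenario(scenario, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_effect_data):
    """A tuned boosting fit on the small effect dataset."""
    data = small_effect_data
    learners = build_base_learners(data.genotypes, data.annotation, data.networks)
    return kernel_boost(
        data.phenotype, learners, m_max=40, n_folds=5, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
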