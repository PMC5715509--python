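"""Shared fixtures: a small simulated cohort and its derived objects.

The mini cohort (120 samples, 2,000 CpGs, 400 SNPs on 2 chromosomes) keeps
unit tests fast; desk-scale runs live in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dualtissue as dt

MINI_SEED = 20170970


@pytest.fixture(scope="session")
def mini_config() -> dt.SimulationConfig:
    return dt.SimulationConfig(
        n_samples=120,
        n_cpgs=2000,
        n_snps=400,
        n_chromosomes=2,
        n_mqtl_cpgs=30,
        n_factor_cpgs=20,
        n_panel_cpgs=60,
        seed=MINI_SEED,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config) -> dt.SimulatedCohort:
    return dt.simulate_cohort(mini_config)


@pytest.fixture(scope="session")
def mini_adjusted(mini_cohort):
    """Cell proportions, design and batch-adjusted betas for one tissue."""
    t = "cord_tissue"
    beta = mini_cohort.betas[t]
    props = dt.estimate_cell_proportions(beta, mini_cohort.panels[t])
    design = dt.build_design(mini_cohort.metadata, props, tissue=t)
    adj = dt.combat_adjust(beta.to_m(), mini_cohort.metadata["chip"], design.frame)
    return {"tissue": t, "proportions": props, "design": design,
            "m_adjusted": adj, "beta_adjusted": adj.to_beta()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2017)


@pytest.fixture()
def small_beta(rng) -> dt.BetaMatrix:
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(8, 6)),
        index=[f"cg{i:03d}" for i in range(8)],
        columns=[f"s{i}" for i in range(6)],
    )
    cpg_map = pd.DataFrame(
        {"chrom": ["1"] * 4 + ["2"] * 4, "pos": np.arange(8) * 100 + 1},
        index=values.index,
    )
    return dt.BetaMatrix(values, cpg_map=cpg_map, tissue_label="cord_tissue")
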