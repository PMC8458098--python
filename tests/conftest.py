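import numpy as np
import pandas as pd
import pytest

from rvphewas.simulate import CohortSimConfig, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortSimConfig(n_samples=400, n_genes=40, n_binary_traits=12,
                           n_quant_traits=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with one strong dominant PTV effect planted on a binary and a
    quantitative trait of a PTV-rich gene."""
    cfg = CohortSimConfig(
        n_samples=1500, n_genes=12, n_binary_traits=4, n_quant_traits=2,
        mean_variants_per_gene=30.0,
        consequence_class_probs={"synonymous": 0.2, "missense": 0.2,
                                 "ptv": 0.5, "other": 0.1},
        prevalence_range=(0.15, 0.25),
        planted_effects=(
            PlantedEffect(gene="G0001", trait="LF0001", mode="dominant",
                          effect_scale=2.0, qualifying_class="ptv"),
            PlantedEffect(gene="G0002", trait="QT01", mode="dominant",
                          effect_scale=1.0, qualifying_class="ptv"),
        ),
        seed=29,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
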