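import numpy as np
import pandas as pd
import pytest

from mmomics.containers import FeatureMatrix
from mmomics.synthetic import (CohortDesign, NoiseModel, PlantedEffect,
                               generate_lipidomics_cohort,
                               generate_proteomics_cohort,
                               generate_toy_network)


@pytest.fixture
def design_small():
    return CohortDesign.from_counts({"RRMM": 4, "NDMM": 5})


@pytest.fixture
def design_20():
    return CohortDesign.from_counts({"RRMM": 20, "NDMM": 20})


@pytest.fixture
def clean_noise():
    """No missingness, no dilution: raw intensities only."""
    return NoiseModel(sample_dilution_sd=0.0, mnar_threshold_quantile=0.0,
                      mar_rate=0.0, seed=7)


@pytest.fixture
def lipid_cohort(design_20):
    noise = NoiseModel(seed=1)
    return generate_lipidomics_cohort(
        design_20, [PlantedEffect("PC", -2.0, "RRMM")], noise)


@pytest.fixture
def protein_cohort(design_20):
    noise = NoiseModel(seed=2)
    return generate_proteomics_cohort(design_20, [], noise, n_proteins=150)


@pytest.fixture
def toy_network():
    return generate_toy_network(n_reactions=50, n_metabolites=90, n_genes=60,
                                ubiquitous_fraction=0.2, seed=3, n_chains=4,
                                chain_length=9)


@pytest.fixture
def small_log2_matrix():
    """Complete 6x6 log2 matrix with two groups, no missing values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.normal(20, 1, (6, 6)),
                          index=[f"f{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(6)])
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return FeatureMatrix(values=values, groups=groups, scale="log2")
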