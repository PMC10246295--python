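import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from burdenarch.calibration import null_calibration_config
from burdenarch.cohort import (ModyParams, RareGeneParams, SimulationConfig,
                               simulate_cohort)


@pytest.fixture(scope="session")
def signal_cohort():
    """Two-cluster cohort with common, rare and MODY-like signal."""
    cfg = SimulationConfig(
        seed=101,
        n_clusters=2,
        cases_per_cluster=250,
        controls_per_cluster=750,
        fst_per_cluster=0.1,
        prevalence=0.05,
        n_common_causal=8,
        common_or_range=(1.2, 1.5),
        n_causal_genes=4,
        rare_gene_params=(
            RareGeneParams(0.004, 8.0, 0.8),
            RareGeneParams(0.006, 5.0, 0.8),
            RareGeneParams(0.008, 3.0, 0.8),
            RareGeneParams(0.010, 2.0, 0.8),
        ),
        mody_params=ModyParams(case_carrier_rate=0.04, penetrance=0.8),
        n_null_genes=25,
        n_common_null=80,
        variants_per_gene_range=(8, 16),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort: disease independent of every genotype."""
    return simulate_cohort(
        null_calibration_config(seed=202, n_null_genes=300,
                                n_cases=500, n_controls=1000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
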