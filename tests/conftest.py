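import numpy as np
import pytest

from bprsig.io import ExpressionMatrix, PhenotypeTable
from bprsig.simulate import SimulationConfig, simulate_cohort

import pandas as pd


def make_matrix(values, feature_ids=None, sample_ids=None, annotated=True):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    feats = feature_ids or [f"g{i+1}" for i in range(n)]
    samps = sample_ids or [f"s{j+1}" for j in range(m)]
    ann = {f: {f"GENE_{f}"} for f in feats} if annotated else {}
    return ExpressionMatrix(feats, samps, values, ann)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8, 1, size=(30, 12)))


@pytest.fixture(scope="session")
def small_cohort():
    """A separable synthetic cohort shared by classifier tests."""
    cfg = SimulationConfig(n_features=600, n_diff=60, n_batch=20,
                           effect_size=2.0, within_patient_rho=0.5, seed=11)
    return simulate_cohort(cfg)


def make_pheno(rows):
    return PhenotypeTable(pd.DataFrame(rows))
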