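import logging

import numpy as np
import pandas as pd
import pytest

from switchscan import (
    ExpressionMatrix,
    SimulationConfig,
    generate_compendium,
    generate_dataset,
    make_self_activation_switch,
    make_toggle_switch,
    uniform_stimulus,
)
from switchscan.circuits import with_graded_genes

logging.getLogger("switchscan").setLevel(logging.ERROR)


def toggle_fixed_point(alpha: float = 10.0, d: float = 1.0) -> np.ndarray:
    """Independent oracle: asymmetric toggle fixed point by fixed-point iteration."""
    a, b = alpha / d, 0.0
    for _ in range(500):
        a_new = alpha / d / (1.0 + b * b)
        b_new = alpha / d / (1.0 + a * a)
        if abs(a_new - a) < 1e-12 and abs(b_new - b) < 1e-12:
            break
        a, b = a_new, b_new
    return np.array([a, b])


@pytest.fixture(scope="session")
def toggle_model():
    return make_toggle_switch()


@pytest.fixture(scope="session")
def sa_model():
    return make_self_activation_switch()


@pytest.fixture(scope="session")
def toggle_graded_dataset():
    """100-clone toggle + 3 graded genes, 20% parameter CV, inits U[0, 12]."""
    model = with_graded_genes(make_toggle_switch(), n_graded=3)
    config = SimulationConfig(
        n_clones=100, cells_per_clone=1, param_cv=0.2, init_low=0.0,
        init_high=12.0, seed=7, t_end=200.0,
    )
    return generate_dataset(model, config, uniform_stimulus(0.0, 35.0))


@pytest.fixture(scope="session")
def tiered_compendium():
    """Tiny planted compendium with one gene per signal tier.

    One type-2 switch (phenotype-locked), one type-1 switch (bimodal
    within the target block), one null gene — three clearly distinct
    information levels for ranking tests.
    """
    return generate_compendium(
        n_type2=1, n_type1=1, n_null=1, n_samples=300, n_target=100,
        n_pairs=20, seed=8,
    )


@pytest.fixture()
def gaussian_matrix():
    """Small iid-Gaussian (null) expression matrix."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(20, 60))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:03d}" for i in range(20)],
            columns=[f"s{j:03d}" for j in range(60)],
        )
    )
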