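import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pathbn.normalize import ExpressionDataset
from pathbn.pathway import parse_sif

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def chain_pathway():
    """A -> B -> C chain."""
    return parse_sif("A\tactivation\tB\nB\tactivation\tC\n", pathway_id="chain")


@pytest.fixture
def diamond_pathway():
    """A -> {B, C} -> D diamond (D has two parents)."""
    sif = "A\tactivation\tB\nA\tinhibition\tC\nB\tactivation\tD\nC\tactivation\tD\n"
    return parse_sif(sif, pathway_id="diamond")


def make_dataset(
    dataset_id="DS1",
    platform_id="P",
    n_case=5,
    n_control=5,
    genes=("A", "B", "C"),
    seed=0,
    loc=7.0,
):
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    cols = [f"{dataset_id}.s{i + 1}" for i in range(n)]
    matrix = pd.DataFrame(
        loc + rng.standard_normal((len(genes), n)), index=list(genes), columns=cols
    )
    meta = pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * n_control}, index=cols
    )
    return ExpressionDataset(dataset_id, platform_id, matrix, meta)


@pytest.fixture
def dataset_factory():
    return make_dataset
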