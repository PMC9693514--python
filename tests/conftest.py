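import numpy as np
import pandas as pd
import pytest

from epibrom.phylo_impute import impute_pipeline
from epibrom.registry import default_registry
from epibrom.synthetic import SyntheticConfig, simulate_dataset
from epibrom.trait_db import TraitTable


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: masked trait table, tree, labels, records."""
    return simulate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def imputed_dataset(default_dataset):
    """The default study after the full gap-filling chain."""
    table, tree, labels, records = default_dataset
    imputed, report = impute_pipeline(table, tree)
    return imputed, report, labels


def make_table(values: dict, genus=None, flags=None) -> TraitTable:
    """Small TraitTable from a dict of trait -> list of values."""
    vals = pd.DataFrame(values, dtype=float)
    vals.index = [f"sp{i}" for i in range(len(vals))]
    genus = genus if genus is not None else ["GenA"] * len(vals)
    gs = pd.Series(genus, index=vals.index, name="genus")
    fl = None
    if flags is not None:
        fl = pd.DataFrame(flags, index=vals.index).astype(bool)
    return TraitTable(vals, gs, default_registry(), None, fl)


@pytest.fixture
def tiny_table():
    return make_table({
        "TC": [0.0, 4.5, 99.5],
        "LW": [1.0, 2.0, 3.0],
        "LL": [30.0, 40.0, 60.0],
        "d13C": [-28.0, -15.0, np.nan],
    })
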