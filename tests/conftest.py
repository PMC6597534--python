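import numpy as np
import pytest

from probrain import allometry, synthetic


@pytest.fixture(scope="session")
def fx():
    """Packaged study fixtures: trait table, calibrated trees, exclusions."""
    return synthetic.fixtures()


@pytest.fixture(scope="session")
def eq_table(fx):
    """Trait table with recomputed brain-mass and EQ columns."""
    return allometry.compute_eq_table(fx.table)


@pytest.fixture(scope="session")
def fixture_xy(fx, eq_table):
    """(x, y, tip order) = log10 body / log10 brain aligned with the tree."""
    df = eq_table.df.set_index("specimen_id")
    order = fx.specimen_tree.tip_labels
    x = np.log10(df.loc[order, "body_g"].astype(float).to_numpy())
    y = np.log10(df.loc[order, "brain_g"].astype(float).to_numpy())
    return x, y, order
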