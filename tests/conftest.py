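"""Shared fixtures: small seeded synthetic datasets and networks."""

import numpy as np
import pandas as pd
import pytest

from dcnet.simulate import generate_paired_groups


@pytest.fixture(scope="session")
def planted_ds():
    """200-gene case/control dataset with 2% GOC + 2% LOC planted pairs."""
    ds, truth = generate_paired_groups(
        200, 100, 100, frac_goc=0.02, frac_loc=0.02, effect_delta_r=0.6, seed=1
    )
    return ds, truth


@pytest.fixture(scope="session")
def null_ds():
    """Small dataset with no planted effects."""
    ds, truth = generate_paired_groups(80, 60, 60, frac_goc=0.0, frac_loc=0.0, seed=2)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def spearman_matrix_pair(ds):
    """Case/control matrices as plain arrays."""
    return (
        ds.group_matrix("case").to_numpy(float),
        ds.group_matrix("control").to_numpy(float),
    )


@pytest.fixture(scope="session")
def planted_matrices(planted_ds):
    ds, truth = planted_ds
    case, ctrl = spearman_matrix_pair(ds)
    return case, ctrl, ds.reporters, truth
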