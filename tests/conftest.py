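import numpy as np
import pandas as pd
import pytest

import perflink as pl


@pytest.fixture(scope="session")
def bank13() -> pl.ItemBank:
    """4 fixed anchors + 9 free battery items, 5 categories each."""
    return pl.make_item_bank(4, 9, 5, slope_range=(0.9, 2.5), seed=11)


@pytest.fixture(scope="session")
def rm2000(bank13) -> pl.ResponseMatrix:
    return pl.simulate_unidimensional(bank13, 2000, seed=12)


@pytest.fixture(scope="session")
def grid() -> pl.QuadratureGrid:
    return pl.make_grid()


@pytest.fixture(scope="session")
def bank3() -> pl.ItemBank:
    """Tiny 3-item x 3-category bank for enumeration oracles."""
    return pl.ItemBank(
        [
            pl.Item("a", "new", 1.2, (-1.0, 0.5)),
            pl.Item("b", "new", 0.8, (-0.3, 1.1)),
            pl.Item("c", "new", 2.0, (0.0, 0.9)),
        ]
    )


@pytest.fixture(scope="session")
def calibration(bank13, rm2000, grid):
    """Fixed-anchor calibration from data-driven starting values (shared)."""
    anchors_only = pl.ItemBank([it for it in bank13 if it.fixed])
    free = [i for i in bank13.item_ids if not bank13[i].fixed]
    return pl.fixed_anchor_link(rm2000, anchors_only, free, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def grouped_rm(bank13, rm2000) -> pl.ResponseMatrix:
    rng = np.random.default_rng(21)
    cov = pd.DataFrame({"grp": rng.integers(0, 2, rm2000.n_persons)})
    return pl.ResponseMatrix(
        rm2000.responses, list(rm2000.item_ids), cov, rm2000.true_theta
    )
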