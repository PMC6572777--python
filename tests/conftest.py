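import numpy as np
import pytest

from flowstock import table1_fixture
from flowstock.data_model import DemographicSeries, StockTable


@pytest.fixture
def fixture4():
    """The 4-region worked-example stock pair and its demographic series."""
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_stock_pair(rng, r=5, scale=100, allow_zero=False):
    """Random integer stock pair over r regions with matched row totals.

    Row totals match (no births/deaths), as required by the accounting
    estimators after adjustment; diagonals are kept dominant so populations
    stay positive.
    """
    regions = [chr(ord("A") + i) for i in range(r)]
    s0 = rng.integers(0 if allow_zero else 1, scale, size=(r, r)).astype(float)
    s0[np.diag_indices(r)] += 5 * scale
    # redistribute each row of s0 across columns to form s1 (moves only)
    s1 = np.zeros_like(s0)
    for k in range(r):
        move = rng.uniform(0, 0.3, size=r) * s0[k]
        stay = s0[k] - move
        dest = rng.dirichlet(np.ones(r), size=r)  # where each column's movers go
        s1[k] = stay + move @ dest
    return (
        StockTable(regions, s0, "t"),
        StockTable(regions, s1, "t+1"),
    )


def zero_demo(regions, pop_start, pop_end, period="t"):
    return DemographicSeries(
        list(regions),
        births=np.zeros(len(regions)),
        deaths=np.zeros(len(regions)),
        pop_start=np.asarray(pop_start, dtype=float),
        pop_end=np.asarray(pop_end, dtype=float),
        net=np.asarray(pop_end, dtype=float) - np.asarray(pop_start, dtype=float),
        period=period,
    )
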