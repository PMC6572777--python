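"""Stock-differencing estimators.

Both estimators read the change in each bilateral stock cell directly: the
flow i -> j during the period is inferred from the stock of people born in i
who reside in j, so entry ``[i, j]`` of both tables is differenced as-is.
Neither estimator adjusts for births or deaths; they consume raw stocks.
"""

from __future__ import annotations

import numpy as np

from flowstock.data_model import FlowTable, StockTable


def _check_pair(s0: StockTable, s1: StockTable) -> None:
    if s0.regions != s1.regions:
        raise ValueError("stock tables must share the same regions in the same order")


def diff_drop_negative(s0: StockTable, s1: StockTable) -> FlowTable:
    """Difference successive stocks, setting negative differences to zero.

    y_ij = max(s1[i, j] - s0[i, j], 0) for i != j.  Decreases in a stock
    (e.g. from return migration) contribute nothing.
    """
    _check_pair(s0, s1)
    y = np.maximum(s1.values - s0.values, 0.0)
    np.fill_diagonal(y, 0.0)
    return FlowTable(s0.regions, y, "sd_drop_neg", s0.ref_time)


def diff_reverse_negative(s0: StockTable, s1: StockTable) -> FlowTable:
    """Difference successive stocks, counting stock decreases as reverse flows.

    A decline in the stock of people born in j living in i is treated as a
    migration flow from i back to j, so

        y_ij = max(s1[i, j] - s0[i, j], 0) + max(s0[j, i] - s1[j, i], 0)

    for i != j, which reproduces the four-case piecewise definition of
    Beine and Parsons: both terms positive, either alone positive, or zero.
    """
    _check_pair(s0, s1)
    d = s1.values - s0.values
    y = np.maximum(d, 0.0) + np.maximum(-d.T, 0.0)
    np.fill_diagonal(y, 0.0)
    return FlowTable(s0.regions, y, "sd_rev_neg", s0.ref_time)
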