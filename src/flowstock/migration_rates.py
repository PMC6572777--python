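"""Rate-scaling estimator (Dennett-style).

A single start-of-period stock table fixes the *shape* of the bilateral flow
matrix: each off-diagonal stock cell, divided by the global foreign-born
population, gives a flow rate.  Multiplying the rates by an estimate of the
global five-year flow total M yields flow counts.  M itself is usually
unobserved and is approximated from net-migration data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flowstock.data_model import DemographicSeries, FlowTable, StockTable


@dataclass
class GlobalFlowTotal:
    """Global one-way migration flow total for a five-year period."""

    M: float
    provenance: str = "supplied"  # supplied | from_net | from_pop_change

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("global flow total must be nonnegative")


def approximate_M(demo: DemographicSeries, mode: str = "from_net") -> GlobalFlowTotal:
    """Approximate the global flow total as a sum of absolute net flows.

    ``from_net`` sums |net_j| over regions.  ``from_pop_change`` sums
    |pop_end_j - pop_start_j|, which equals the same quantity whenever births
    and deaths cancel within every region (the textbook dummy-data case).
    """
    if mode == "from_net":
        if demo.net is None:
            raise ValueError("from_net requires net migration data")
        return GlobalFlowTotal(float(np.abs(demo.net).sum()), "from_net")
    if mode == "from_pop_change":
        return GlobalFlowTotal(
            float(np.abs(demo.pop_end - demo.pop_start).sum()), "from_pop_change"
        )
    raise ValueError(f"unknown mode {mode!r}")


def rate_flows(s0: StockTable, M: GlobalFlowTotal | float) -> FlowTable:
    """Scale off-diagonal stock shares at time t to the global flow total.

    y_ij = M * s0[i, j] / sum_{g != h} s0[g, h] for i != j.  Only the
    start-of-period table enters; flows are proportional to stocks and sum to
    M exactly.
    """
    m_total = M.M if isinstance(M, GlobalFlowTotal) else float(M)
    off = s0.values.copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum()
    if m_total == 0:
        return FlowTable(s0.regions, np.zeros_like(off), "mig_rate", s0.ref_time)
    if denom == 0:
        raise ValueError("all off-diagonal stocks are zero but M > 0")
    return FlowTable(s0.regions, m_total * off / denom, "mig_rate", s0.ref_time)
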