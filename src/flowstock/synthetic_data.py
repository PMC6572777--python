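"""Built-in fixture data and a synthetic multiregional population simulator.

:func:`table1_fixture` returns the 4-region worked example used throughout
the documentation: a pair of migrant-stock tables with matched birthplace row
totals, constructed so that births and deaths cancel in every region.

:func:`simulate_population` forward-simulates a closed multiregional
population so estimators can be tested against known true flows without any
external data.  Moves are recorded as *transitions* -- residence at the start
versus the end of a period -- matching what every estimator targets;
intermediate moves within a period are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flowstock.data_model import DemographicSeries, FlowTable, StockTable

_T1_REGIONS = ["A", "B", "C", "D"]
_T1_S0 = np.array(
    [
        [100.0, 10.0, 10.0, 0.0],
        [80.0, 180.0, 10.0, 90.0],
        [30.0, 10.0, 140.0, 40.0],
        [60.0, 70.0, 10.0, 160.0],
    ]
)
_T1_S1 = np.array(
    [
        [95.0, 5.0, 15.0, 5.0],
        [75.0, 225.0, 5.0, 55.0],
        [55.0, 0.0, 115.0, 50.0],
        [35.0, 25.0, 25.0, 215.0],
    ]
)


def table1_fixture() -> tuple[StockTable, StockTable, DemographicSeries]:
    """The hypothetical 4-region stock pair with zero births and deaths.

    Both tables have grand total 1000 and identical birthplace row sums
    (120, 360, 220, 300); resident populations shift from (270, 270, 170, 290)
    to (260, 255, 160, 325), giving net flows (-10, -15, -10, +35).
    """
    s0 = StockTable(_T1_REGIONS, _T1_S0.copy(), "t")
    s1 = StockTable(_T1_REGIONS, _T1_S1.copy(), "t+1")
    demo = DemographicSeries(
        _T1_REGIONS,
        births=np.zeros(4),
        deaths=np.zeros(4),
        pop_start=_T1_S0.sum(axis=0),
        pop_end=_T1_S1.sum(axis=0),
        net=_T1_S1.sum(axis=0) - _T1_S0.sum(axis=0),
        period="t",
    )
    return s0, s1, demo


@dataclass
class SimulationParams:
    """Demographic rates for the synthetic population, per five-year period.

    Rates are crude period probabilities: ``birth_rate`` births and
    ``death_rate`` deaths per resident, and ``move_rate`` as the fraction of
    each sending stock that relocates.  ``base_pop`` sets the scale of a
    region's population and ``foreign_share`` the initial fraction of
    residents born elsewhere.
    """

    move_rate: float = 0.03
    birth_rate: float = 0.10
    death_rate: float = 0.05
    base_pop: float = 1e5
    foreign_share: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.move_rate <= 1.0:
            raise ValueError("move_rate must lie in [0, 1]")
        if self.birth_rate < 0 or not 0.0 <= self.death_rate < 1.0:
            raise ValueError("birth_rate must be >= 0 and death_rate in [0, 1)")
        if self.base_pop <= 0 or not 0.0 <= self.foreign_share < 1.0:
            raise ValueError("base_pop must be positive and foreign_share in [0, 1)")


def simulate_population(
    R: int,
    periods: int,
    params: SimulationParams | None = None,
    seed: int = 0,
    start_year: int = 1990,
) -> tuple[list[StockTable], list[DemographicSeries], list[FlowTable]]:
    """Forward-simulate a closed multiregional population.

    Each period proceeds as deaths, then moves, then births:

    1. deaths remove a fraction ``death_rate`` of every residence column
       (identical mortality for native- and foreign-born residents);
    2. for each birthplace, regions are split at random into senders and
       receivers, and a fraction ``move_rate`` of each sending stock is
       redistributed over receivers in proportion to random positive weights
       (so the true flows follow a minimum-movers structure: within a
       birthplace no region both sends and receives);
    3. births (``birth_rate`` per start-of-period resident) are added to each
       region's native-born diagonal cell.

    Flows are expected values, so stocks hold fractional persons.  Returns
    ``periods + 1`` stock tables, one demographic series per period, and the
    true transition flows per period (tagged ``"true"``).  Deterministic for a
    given seed.
    """
    if R < 2:
        raise ValueError("need at least two regions")
    if periods < 1:
        raise ValueError("need at least one period")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)

    regions = [f"R{i:03d}" for i in range(R)]
    # diagonal-dominant initial stocks: natives plus a dispersed foreign stock
    sizes = params.base_pop * rng.uniform(0.5, 1.5, size=R)
    stocks0 = np.zeros((R, R))
    for j in range(R):
        foreign = params.foreign_share * sizes[j] * rng.dirichlet(np.ones(R - 1))
        idx = [k for k in range(R) if k != j]
        stocks0[idx, j] = foreign
        stocks0[j, j] = (1 - params.foreign_share) * sizes[j]

    stocks = [StockTable(regions, stocks0, str(start_year))]
    demos: list[DemographicSeries] = []
    true_flows: list[FlowTable] = []
    S = stocks0
    for p in range(periods):
        pop_start = S.sum(axis=0)
        deaths = params.death_rate * pop_start
        S_mid = S * (1.0 - params.death_rate)

        flows = np.zeros((R, R))
        S_moved = S_mid.copy()
        if params.move_rate > 0:
            for k in range(R):
                senders = rng.random(R) < 0.5
                if senders.all():
                    senders[rng.integers(R)] = False
                elif not senders.any():
                    senders[rng.integers(R)] = True
                receivers = ~senders
                out = np.where(senders, params.move_rate * S_mid[k], 0.0)
                if out.sum() == 0:
                    continue
                weights = np.where(receivers, rng.uniform(0.5, 1.5, size=R), 0.0)
                slice_flows = np.outer(out, weights / weights.sum())
                flows += slice_flows
                S_moved[k] = S_mid[k] - out + slice_flows.sum(axis=0)

        births = params.birth_rate * pop_start
        S_next = S_moved.copy()
        S_next[np.diag_indices(R)] += births

        pop_end = S_next.sum(axis=0)
        net = pop_end - pop_start - births + deaths
        period = str(start_year + 5 * p)
        demos.append(
            DemographicSeries(regions, births, deaths, pop_start, pop_end, net, period)
        )
        np.fill_diagonal(flows, 0.0)
        true_flows.append(FlowTable(regions, flows, "true", period))
        stocks.append(StockTable(regions, S_next, str(start_year + 5 * (p + 1))))
        S = S_next
    return stocks, demos, true_flows
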