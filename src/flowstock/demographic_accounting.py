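"""Demographic-accounting estimators of bilateral migration flows.

The accounting approach treats a pair of successive migrant-stock tables as
the known margins of an unknown array of birthplace-specific flows
m[i, j, k]: for each birthplace k, the people born in k must be redistributed
from their start-of-period residences (row k of the first table, placed on
origins) to their end-of-period residences (row k of the second table, placed
on destinations).  Because birthplace is fixed, people can only move across
residence columns; any change in row k of the stocks must be explained by
moves, births, or deaths.

Births and deaths are removed from the stocks first: deaths scale every
residence column down proportionally (mortality is assumed identical for
native- and foreign-born residents), and births to each region are subtracted
from that region's diagonal (native-born) cell of the end-of-period table.
The remaining row-total mismatch per birthplace is closed either by adding a
rest-of-world category that absorbs it (*open* system) or by rescaling both
tables so their row sums meet at the midpoint while column profiles are
preserved (*closed* system).

With matched margins, the *minimisation* estimator fixes each diagonal cell
at its maximum feasible value -- the minimum of the matching row and column
margin -- so that off-diagonal flows are the smallest consistent with the
stock changes; the off-diagonal cells follow a quasi-independence log-linear
model fitted by IPF.  The *pseudo-Bayes* estimator blends these minimum flows
with a plain independence fit of the same margins using a weight w
(default 0.87), trading the minimal-migration assumption against the
independence model's much larger gross flows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from flowstock.data_model import (
    BirthplaceFlowArray,
    DemographicSeries,
    FlowTable,
    StockTable,
)
from flowstock.ipf_engine import IPFSpec, independence_fit, ipf_fit

logger = logging.getLogger("flowstock")

#: Label of the synthetic rest-of-world category added by the open system.
OUTSIDE = "__outside__"


@dataclass
class AccountingConfig:
    """Configuration of one accounting run.

    ``system`` selects open or closed margin reconciliation; ``estimator``
    selects minimisation or the pseudo-Bayes blend (the latter only defined
    for the closed system); ``w`` is the blend weight on the minimisation
    component.
    """

    system: str = "closed"
    estimator: str = "minimisation"
    w: float = 0.87
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.system not in ("open", "closed"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.estimator not in ("minimisation", "pseudo_bayes"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.estimator == "pseudo_bayes" and self.system != "closed":
            raise ValueError("the pseudo-Bayes estimator requires a closed system")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")

    @property
    def method_tag(self) -> str:
        if self.estimator == "pseudo_bayes":
            return "da_pb_closed"
        return f"da_min_{self.system}"


def _check_regions(s0: StockTable, other) -> None:
    if s0.regions != other.regions:
        raise ValueError("inputs must share the same regions in the same order")


def adjust_for_deaths(s0: StockTable, demo: DemographicSeries) -> StockTable:
    """Scale each residence column of the start-of-period stocks for deaths.

    Column j is multiplied by (pop_start_j - deaths_j) / pop_start_j, applying
    the region's crude survival ratio to native- and foreign-born alike.
    """
    _check_regions(s0, demo)
    if np.any(demo.deaths > demo.pop_start):
        raise ValueError("deaths exceed start-of-period population")
    surv = (demo.pop_start - demo.deaths) / demo.pop_start
    return StockTable(s0.regions, s0.values * surv[None, :], s0.ref_time)


def adjust_for_births(s1: StockTable, demo: DemographicSeries) -> StockTable:
    """Subtract period births from the native-born diagonal of the end stocks.

    Only diagonal cells change.  A diagonal driven below zero is clamped to 0
    and logged (possible when reported births exceed the native-born stock).
    """
    _check_regions(s1, demo)
    values = s1.values.copy()
    diag = np.diag(values) - demo.births
    clamped = diag < 0
    if np.any(clamped):
        logger.warning(
            "births exceed native-born stock in %s; clamping diagonal to 0",
            [s1.regions[i] for i in np.flatnonzero(clamped)],
        )
    np.fill_diagonal(values, np.maximum(diag, 0.0))
    return StockTable(s1.regions, values, s1.ref_time)


def _margins_from_pair(s0: StockTable, s1: StockTable) -> tuple[np.ndarray, np.ndarray]:
    # row margins m_{i+k}: people born in k starting in residence i (row k of
    # s0, transposed onto origins); column margins m_{+jk} from row k of s1
    return s0.values.T.copy(), s1.values.T.copy()


def reconcile_open(
    s0p: StockTable, s1p: StockTable
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Close each birthplace's margin mismatch with a rest-of-world category.

    For birthplace k the origin margins come from row k of the adjusted start
    table and the destination margins from row k of the adjusted end table.
    Their difference d_k is assigned wholly to one side of an added external
    category: an external destination absorbs d_k when the start total is
    larger (people left the system), an external origin supplies -d_k when the
    end total is larger.  Returns ``(categories, birthplaces, row_margins,
    col_margins)`` with margins of shape (R + 1, R).
    """
    _check_regions(s0p, s1p)
    rows, cols = _margins_from_pair(s0p, s1p)
    d = rows.sum(axis=0) - cols.sum(axis=0)  # per-birthplace residual
    r = len(s0p.regions)
    row_m = np.vstack([rows, np.maximum(-d, 0.0)])
    col_m = np.vstack([cols, np.maximum(d, 0.0)])
    categories = list(s0p.regions) + [OUTSIDE]
    return categories, list(s0p.regions), row_m, col_m


def reconcile_closed(
    s0p: StockTable, s1p: StockTable, tol: float = 1e-6, max_iter: int = 10_000
) -> tuple[StockTable, StockTable]:
    """Rescale both adjusted tables so their row sums meet at the midpoint.

    Both grand totals are first harmonised to their mean (midpoint row targets
    must sum to a common total); each table is then biproportionally adjusted
    (IPF seeded with the table itself) to row targets equal to the midpoint of
    the harmonised row sums and to its own proportionally rescaled column
    sums, preserving column shares.  The result is a closed system: every
    person moves, stays, is born or dies within the modelled regions.
    """
    _check_regions(s0p, s1p)
    g0, g1 = s0p.values.sum(), s1p.values.sum()
    if g0 <= 0 or g1 <= 0:
        raise ValueError("grand totals must be positive")
    grand = (g0 + g1) / 2.0
    rows0 = s0p.values.sum(axis=1) * grand / g0
    rows1 = s1p.values.sum(axis=1) * grand / g1
    mid = (rows0 + rows1) / 2.0
    out = []
    for table, g in ((s0p, g0), (s1p, g1)):
        cols = table.values.sum(axis=0) * grand / g
        fitted = ipf_fit(
            IPFSpec(mid, cols, tol=tol, max_iter=max_iter, seed_table=table.values)
        )
        out.append(StockTable(table.regions, fitted, table.ref_time))
    return out[0], out[1]


def _fit_array(
    categories: list[str],
    birthplaces: list[str],
    row_m: np.ndarray,
    col_m: np.ndarray,
    model: str,
    tol: float,
    max_iter: int,
) -> BirthplaceFlowArray:
    c = len(categories)
    values = np.empty((c, c, len(birthplaces)))
    for k in range(len(birthplaces)):
        rows, cols = row_m[:, k], col_m[:, k]
        # the reconciliation step matches slice totals only to its own
        # tolerance; balance them exactly so the fit can reach full precision
        if cols.sum() > 0:
            cols = cols * (rows.sum() / cols.sum())
        if model == "independence":
            values[:, :, k] = independence_fit(rows, cols)
        else:  # quasi-independence with maximal fixed diagonal
            diag = np.minimum(rows, cols)
            fixed = {(i, i, float(diag[i])) for i in range(c)}
            values[:, :, k] = ipf_fit(
                IPFSpec(rows, cols, fixed_cells=fixed, tol=tol, max_iter=max_iter)
            )
    return BirthplaceFlowArray(categories, values, row_m, col_m, list(birthplaces))


def fit_minimisation(
    categories: list[str],
    birthplaces: list[str],
    row_margins: np.ndarray,
    col_margins: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BirthplaceFlowArray:
    """Fit the minimum-migration quasi-independence array to matched margins.

    For each birthplace slice the diagonal (stayer) cells are fixed at their
    maximum feasible value min(row margin, column margin); the off-diagonal
    cells -- the smallest flows able to absorb the remaining margin mass --
    are fitted by IPF.
    """
    return _fit_array(
        categories, birthplaces, row_margins, col_margins, "quasi", tol, max_iter
    )


def fit_independence_array(
    categories: list[str],
    birthplaces: list[str],
    row_margins: np.ndarray,
    col_margins: np.ndarray,
) -> BirthplaceFlowArray:
    """Fit the plain independence model z[i, j, k] = row_i * col_j / total per slice."""
    return _fit_array(
        categories, birthplaces, row_margins, col_margins, "independence", 0.0, 0
    )


def flows_from_array(
    m: BirthplaceFlowArray, method_tag: str = "da_min_closed", period: str = ""
) -> FlowTable:
    """Sum a fitted array over birthplaces into an origin-destination table.

    Flows through any external rest-of-world category are excluded, so the
    result is always square over the birthplace regions with a zero diagonal.
    """
    core = [m.regions.index(r) for r in m.birthplaces]
    y = m.origin_destination()[np.ix_(core, core)].copy()
    np.fill_diagonal(y, 0.0)
    return FlowTable(list(m.birthplaces), np.maximum(y, 0.0), method_tag, period)


def fit_pseudo_bayes(
    categories: list[str],
    birthplaces: list[str],
    row_margins: np.ndarray,
    col_margins: np.ndarray,
    w: float = 0.87,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    period: str = "",
) -> FlowTable:
    """Blend minimisation and independence fits: y = w * m_{ij+} + (1 - w) * z_{ij+}.

    w = 1 reproduces the minimisation flows, w = 0 the off-diagonal sums of
    the independence fits.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    m = fit_minimisation(categories, birthplaces, row_margins, col_margins, tol, max_iter)
    z = fit_independence_array(categories, birthplaces, row_margins, col_margins)
    blend = w * m.origin_destination() + (1.0 - w) * z.origin_destination()
    core = [categories.index(r) for r in birthplaces]
    y = blend[np.ix_(core, core)].copy()
    np.fill_diagonal(y, 0.0)
    return FlowTable(list(birthplaces), y, "da_pb_closed", period)


def estimate_accounting(
    s0: StockTable,
    s1: StockTable,
    demo: DemographicSeries,
    config: AccountingConfig | None = None,
) -> FlowTable:
    """Run the full accounting pipeline on one stock pair.

    Deaths are removed from the start table and births from the end table's
    diagonal; margins are reconciled per ``config.system``; the configured
    estimator is fitted and summed over birthplaces.
    """
    config = config or AccountingConfig()
    _check_regions(s0, s1)
    s0p = adjust_for_deaths(s0, demo)
    s1p = adjust_for_births(s1, demo)
    if config.system == "open":
        cats, bps, row_m, col_m = reconcile_open(s0p, s1p)
    else:
        s0pp, s1pp = reconcile_closed(s0p, s1p, config.tol, config.max_iter)
        row_m, col_m = _margins_from_pair(s0pp, s1pp)
        cats, bps = list(s0.regions), list(s0.regions)
    if config.estimator == "pseudo_bayes":
        return fit_pseudo_bayes(
            cats, bps, row_m, col_m, config.w, config.tol, config.max_iter,
            period=s0.ref_time,
        )
    m = fit_minimisation(cats, bps, row_m, col_m, config.tol, config.max_iter)
    return flows_from_array(m, config.method_tag, period=s0.ref_time)
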