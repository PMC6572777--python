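"""Core domain types and tabular readers/writers shared by all estimators.

Two kinds of square matrix run through the package.  A *stock* table counts
people by where they were born (rows) and where they live (columns) at one
point in time; its diagonal holds native-born stayers and its column sums are
resident populations.  A *flow* table counts transitions -- people resident in
origin ``i`` at the start of a five-year period and in destination ``j`` at
its end; its diagonal is identically zero.

All counts are stored as nonnegative floats: the accounting estimators
produce fractional persons, and rounding is a display concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("flowstock")

#: Canonical method tags, in output column order.
METHOD_TAGS = (
    "sd_drop_neg",
    "sd_rev_neg",
    "mig_rate",
    "da_min_open",
    "da_min_closed",
    "da_pb_closed",
)


def _as_square(values, regions: Sequence[str]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    r = len(regions)
    if arr.shape != (r, r):
        raise ValueError(f"expected a {r}x{r} matrix, got shape {arr.shape}")
    if np.any(np.isnan(arr)):
        raise ValueError("matrix contains missing values")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr


@dataclass
class StockTable:
    """Square migrant-stock table: rows = birthplace, columns = residence.

    Parameters
    ----------
    regions
        Ordered region labels, shared by rows and columns.
    values
        Nonnegative (R, R) matrix of person counts; entry ``[k, j]`` is the
        number of people born in region ``k`` resident in region ``j``.
    ref_time
        Label of the reference time point (e.g. ``"1990"`` for mid-year 1990).
    """

    regions: list[str]
    values: np.ndarray
    ref_time: str

    def __post_init__(self) -> None:
        self.regions = [str(r) for r in self.regions]
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region labels")
        self.values = _as_square(self.values, self.regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def populations(self) -> np.ndarray:
        """Resident population per region (column sums)."""
        return self.values.sum(axis=0)

    def restrict(self, regions: Sequence[str]) -> "StockTable":
        """Return the sub-table over ``regions`` (in the given order)."""
        idx = [self.regions.index(r) for r in regions]
        return StockTable(list(regions), self.values[np.ix_(idx, idx)], self.ref_time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class DemographicSeries:
    """Per-region demographic components for one period.

    ``births`` and ``deaths`` are counts over the period; ``pop_start`` and
    ``pop_end`` are populations at its endpoints; ``net`` is immigration minus
    emigration (signed), optional because only the rate-scaling estimator
    needs it.
    """

    regions: list[str]
    births: np.ndarray
    deaths: np.ndarray
    pop_start: np.ndarray
    pop_end: np.ndarray
    net: np.ndarray | None = None
    period: str = ""

    def __post_init__(self) -> None:
        self.regions = [str(r) for r in self.regions]
        r = len(self.regions)
        for name in ("births", "deaths", "pop_start", "pop_end"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (r,):
                raise ValueError(f"{name} must have length {r}")
            setattr(self, name, vec)
        if np.any(self.births < 0) or np.any(self.deaths < 0):
            raise ValueError("births and deaths must be nonnegative")
        if np.any(self.pop_start <= 0) or np.any(self.pop_end <= 0):
            raise ValueError("populations must be positive")
        if self.net is not None:
            self.net = np.asarray(self.net, dtype=float)
            if self.net.shape != (r,):
                raise ValueError(f"net must have length {r}")

    def restrict(self, regions: Sequence[str]) -> "DemographicSeries":
        idx = [self.regions.index(r) for r in regions]
        return DemographicSeries(
            list(regions),
            self.births[idx],
            self.deaths[idx],
            self.pop_start[idx],
            self.pop_end[idx],
            None if self.net is None else self.net[idx],
            self.period,
        )


@dataclass
class FlowTable:
    """Square origin-destination flow table with an identically-zero diagonal."""

    regions: list[str]
    values: np.ndarray
    method_tag: str
    period: str = ""

    def __post_init__(self) -> None:
        self.regions = [str(r) for r in self.regions]
        self.values = _as_square(self.values, self.regions)
        if np.any(np.diag(self.values) != 0):
            raise ValueError("flow-table diagonal must be exactly zero")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class BirthplaceFlowArray:
    """Birthplace-specific flows: ``values[i, j, k]`` = flow i -> j of people born in k.

    ``row_margins[i, k]`` and ``col_margins[j, k]`` are the known slice margins
    coming from the start- and end-of-period stock tables respectively.  The
    matched-margin precondition of the accounting estimators requires
    ``row_margins[:, k].sum() == col_margins[:, k].sum()`` for each k.

    ``regions`` lists the origin/destination categories; under an open
    accounting system it carries one extra rest-of-world category beyond the
    ``birthplaces`` (which default to ``regions`` in the closed, square case).
    """

    regions: list[str]
    values: np.ndarray
    row_margins: np.ndarray
    col_margins: np.ndarray
    birthplaces: list[str] | None = None

    def __post_init__(self) -> None:
        self.regions = [str(r) for r in self.regions]
        if self.birthplaces is None:
            self.birthplaces = list(self.regions)
        c, k = len(self.regions), len(self.birthplaces)
        self.values = np.asarray(self.values, dtype=float)
        self.row_margins = np.asarray(self.row_margins, dtype=float)
        self.col_margins = np.asarray(self.col_margins, dtype=float)
        if self.values.shape != (c, c, k):
            raise ValueError(f"values must have shape ({c}, {c}, {k})")
        if self.row_margins.shape != (c, k) or self.col_margins.shape != (c, k):
            raise ValueError(f"margins must have shape ({c}, {k})")
        if np.any(self.values < -1e-9):
            raise ValueError("flows must be nonnegative")
        sums_r = self.row_margins.sum(axis=0)
        sums_c = self.col_margins.sum(axis=0)
        if not np.allclose(sums_r, sums_c, rtol=0, atol=1e-6 * (1 + sums_r.max())):
            raise ValueError("row and column margins must match per birthplace")

    def origin_destination(self) -> np.ndarray:
        """Sum over birthplaces: the matrix m_{ij+} over all categories."""
        return self.values.sum(axis=2)

    def margin_discrepancy(self) -> float:
        """Largest absolute deviation of fitted slice margins from targets."""
        rows = self.values.sum(axis=1)  # (C, K)
        cols = self.values.sum(axis=0)  # (C, K)
        return float(
            max(
                np.abs(rows - self.row_margins).max(initial=0.0),
                np.abs(cols - self.col_margins).max(initial=0.0),
            )
        )


@dataclass
class ValidationSet:
    """Paired estimated/reported flows for correlation-based validation.

    Wraps a long DataFrame with columns ``origin``, ``destination``,
    ``period``, ``estimated``, ``reported``, ``side`` (``sending`` or
    ``receiving``), and optionally ``dev_orig`` / ``dev_dest`` development
    levels.  Both flow columns must already be on the same five-year basis.
    """

    records: pd.DataFrame = field(repr=False)

    REQUIRED = ("origin", "destination", "period", "estimated", "reported", "side")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = set(self.records["side"]) - {"sending", "receiving"}
        if bad:
            raise ValueError(f"unknown reporting side(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _stock_from_long(df: pd.DataFrame, ref_time: str) -> StockTable:
    sub = df[df["ref_time"].astype(str) == ref_time]
    if sub.duplicated(["birthplace", "residence"]).any():
        raise ValueError(f"duplicate (birthplace, residence) keys at {ref_time}")
    regions = sorted(set(sub["birthplace"]) | set(sub["residence"]))
    wide = sub.pivot(index="birthplace", columns="residence", values="count")
    wide = wide.reindex(index=regions, columns=regions)
    if wide.isna().any().any():
        raise ValueError(f"missing cells in stock table at {ref_time}")
    return StockTable(regions, wide.to_numpy(), ref_time)


def read_stocks(path: str | Path, layout: str = "long") -> list[StockTable]:
    """Read one or more stock tables from a delimited text file.

    ``long`` layout: a CSV with header ``birthplace,residence,ref_time,count``
    (row order irrelevant).  ``wide`` layout: one square block per time point,
    blocks separated by blank lines; the top-left header cell carries the
    reference-time label and the remaining header cells the region labels.

    Returns tables sorted by their reference-time label.
    """
    path = Path(path)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"birthplace", "residence", "ref_time", "count"}
        if not required <= set(df.columns):
            raise ValueError(f"long stock file must have columns {sorted(required)}")
        df = df.astype({"birthplace": str, "residence": str})
        if (df["count"] < 0).any():
            raise ValueError("negative stock counts")
        times = sorted(df["ref_time"].astype(str).unique())
        return [_stock_from_long(df, t) for t in times]
    if layout == "wide":
        tables = []
        block: list[str] = []
        for line in path.read_text().splitlines() + [""]:
            if line.strip():
                block.append(line)
                continue
            if not block:
                continue
            header = [c.strip() for c in block[0].split(",")]
            ref_time, regions = header[0], header[1:]
            rows, labels = [], []
            for row in block[1:]:
                cells = [c.strip() for c in row.split(",")]
                labels.append(cells[0])
                rows.append([float(c) for c in cells[1:]])
            if labels != regions or any(len(r) != len(regions) for r in rows):
                raise ValueError(f"non-square or mislabelled block at {ref_time}")
            tables.append(StockTable(regions, np.array(rows), ref_time))
            block = []
        if not tables:
            raise ValueError(f"no stock blocks found in {path}")
        return sorted(tables, key=lambda t: t.ref_time)
    raise ValueError(f"unknown layout {layout!r}")


def read_demographics(path: str | Path) -> list[DemographicSeries]:
    """Read per-region demographic period data from a long CSV.

    Columns: ``region, period, births, deaths, pop_start, pop_end`` and
    optionally ``net``.  Returns one series per period, sorted by its label.
    Missing values are preserved as NaN so :func:`align_regions` can drop the
    affected regions.
    """
    df = pd.read_csv(path)
    required = {"region", "period", "births", "deaths", "pop_start", "pop_end"}
    if not required <= set(df.columns):
        raise ValueError(f"demographic file must have columns {sorted(required)}")
    out = []
    for period, sub in df.groupby(df["period"].astype(str), sort=True):
        sub = sub.set_index(sub["region"].astype(str)).sort_index()
        numeric = ["births", "deaths", "pop_start", "pop_end"]
        complete = sub[numeric].notna().all(axis=1)
        if not complete.all():
            # keep incomplete rows out of the constructor but remember the
            # regions so alignment can report them
            dropped = sorted(sub.index[~complete])
            logger.warning("period %s: incomplete demographics for %s", period, dropped)
            sub = sub[complete]
        net = sub["net"].to_numpy(dtype=float) if "net" in sub.columns else None
        out.append(
            DemographicSeries(
                list(sub.index),
                sub["births"].to_numpy(dtype=float),
                sub["deaths"].to_numpy(dtype=float),
                sub["pop_start"].to_numpy(dtype=float),
                sub["pop_end"].to_numpy(dtype=float),
                net,
                period,
            )
        )
    return out


def write_flows(flows: Iterable[FlowTable], path: str | Path | None) -> pd.DataFrame:
    """Write flow tables to a long-format CSV, one column per method tag.

    One row per (origin, destination, period), diagonal pairs included with
    value 0, so R regions over P periods yield exactly R*R*P rows.  The method
    columns use the canonical tag names; all tables within a period must share
    the same region set.

    Returns the assembled DataFrame (also written to ``path`` unless None).
    """
    flows = list(flows)
    if not flows:
        raise ValueError("no flow tables to write")
    ref = flows[0].regions
    for ft in flows:
        if ft.regions != ref:
            raise ValueError("all flow tables must share the same region set")
        if ft.method_tag not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {ft.method_tag!r}")
    periods = sorted({ft.period for ft in flows})
    tags = [t for t in METHOD_TAGS if any(ft.method_tag == t for ft in flows)]
    r = len(ref)
    orig = np.repeat(ref, r)
    dest = np.tile(ref, r)
    frames = []
    for period in periods:
        data = {"origin": orig, "destination": dest, "period": period}
        for tag in tags:
            matches = [f for f in flows if f.period == period and f.method_tag == tag]
            if len(matches) != 1:
                raise ValueError(f"need exactly one {tag} table for period {period!r}")
            data[tag] = matches[0].values.ravel()
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def align_regions(
    stocks: Sequence[StockTable], demo: Sequence[DemographicSeries]
) -> tuple[list[StockTable], list[DemographicSeries]]:
    """Restrict all inputs to the regions with complete data everywhere.

    Mirrors the real-data practice of excluding any country lacking complete
    demographic information.  Dropped regions are logged.  Raises if the
    intersection is empty.
    """
    common: set[str] | None = None
    for st in stocks:
        common = set(st.regions) if common is None else common & set(st.regions)
    for ds in demo:
        common = set(ds.regions) if common is None else common & set(ds.regions)
    if not common:
        raise ValueError("no regions with complete data in every input")
    keep = sorted(common)
    everything = set().union(*(set(s.regions) for s in stocks), *(set(d.regions) for d in demo))
    dropped = sorted(everything - common)
    if dropped:
        logger.warning("dropping regions without complete data: %s", dropped)
    if not dropped and all(s.regions == keep for s in stocks) and all(
        d.regions == keep for d in demo
    ):
        return list(stocks), list(demo)
    return [s.restrict(keep) for s in stocks], [d.restrict(keep) for d in demo]
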