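"""Validation measures and correlation reporting.

Estimated five-year flows cannot be validated by accuracy against reported
flows: reporting countries use incompatible migrant definitions, so levels
differ even when patterns agree.  Validity is therefore measured by Pearson
correlation between estimates and reports on six migration measures -- the
count, its natural log, the proportion of a region's in- or outflow, crude
emigration and immigration rates, and the net count -- exploiting the
invariance of correlation under positive rescaling of either variable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from flowstock.data_model import DemographicSeries, FlowTable, ValidationSet

MEASURES = ("count", "log", "prop", "emi_rate", "imm_rate", "net")


def to_quinquennial(annual_flows: Iterable[float]) -> float:
    """Convert reported annual flows in one corridor-period to a five-year total.

    Five times the mean of the available annual observations; years without a
    report are simply absent from the mean rather than counted as zero.
    """
    values = [v for v in annual_flows if v is not None and not np.isnan(v)]
    if not values:
        raise ValueError("no annual observations in the five-year window")
    return 5.0 * float(np.mean(values))


def measures(flows: FlowTable, demo: DemographicSeries) -> dict:
    """Compute the six validation measures for one flow table.

    Returns a dict with a per-corridor DataFrame (count, log count, sending-
    and receiving-side proportions) and a per-region DataFrame (emigration and
    immigration rates against start-of-period populations, and net counts).
    Log counts are NaN for zero corridors; proportions are NaN where a
    region's total in- or outflow is zero.
    """
    if flows.regions != demo.regions:
        raise ValueError("flow table and demographic series must share regions")
    if np.any(demo.pop_start <= 0):
        raise ValueError("start-of-period populations must be positive")
    y = flows.values
    outflow = y.sum(axis=1)
    inflow = y.sum(axis=0)
    r = len(flows.regions)
    orig = np.repeat(flows.regions, r)
    dest = np.tile(flows.regions, r)
    counts = y.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_counts = np.where(counts > 0, np.log(np.where(counts > 0, counts, 1.0)), np.nan)
        prop_send = np.where(
            np.repeat(outflow, r) > 0, counts / np.repeat(outflow, r), np.nan
        )
        prop_recv = np.where(np.tile(inflow, r) > 0, counts / np.tile(inflow, r), np.nan)
    corridor = pd.DataFrame(
        {
            "origin": orig,
            "destination": dest,
            "count": counts,
            "log": log_counts,
            "prop_sending": prop_send,
            "prop_receiving": prop_recv,
        }
    )
    corridor = corridor[corridor["origin"] != corridor["destination"]].reset_index(drop=True)
    region = pd.DataFrame(
        {
            "region": flows.regions,
            "emi_rate": outflow / demo.pop_start,
            "imm_rate": inflow / demo.pop_start,
            "net": inflow - outflow,
        }
    )
    return {"corridor": corridor, "region": region}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return np.nan
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan  # correlation undefined under zero variance
    return float(stats.pearsonr(x, y)[0])


def correlate(
    v: ValidationSet,
    measure: str = "count",
    group_by: str = "none",
    dev_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation between estimated and reported flows, by group.

    ``measure`` is ``count``, ``log`` (corridors with a zero on either side
    are excluded, since log 0 is undefined), or ``prop`` (each flow divided by
    its region's total outflow for sending-side records, total inflow for
    receiving-side records, computed within each period and side).
    ``group_by`` is ``none``, ``period``, or ``dev_level`` (requires a
    region -> development-level mapping unless ``dev_orig``/``dev_dest``
    columns are already present).  Groups with fewer than three pairs or zero
    variance get a NaN correlation, never a fabricated zero.

    Returns a DataFrame with columns ``group``, ``n``, ``correlation``.
    """
    df = v.records.copy()
    if measure not in ("count", "log", "prop"):
        raise ValueError(f"unsupported corridor measure {measure!r}")
    if measure == "log":
        df = df[(df["estimated"] > 0) & (df["reported"] > 0)].copy()
        df["estimated"] = np.log(df["estimated"])
        df["reported"] = np.log(df["reported"])
    elif measure == "prop":
        for col in ("estimated", "reported"):
            key = np.where(df["side"] == "sending", df["origin"], df["destination"])
            totals = df.groupby([key, df["period"], df["side"]])[col].transform("sum")
            df[col] = df[col] / totals.replace(0, np.nan)
        df = df.dropna(subset=["estimated", "reported"])

    if group_by == "none":
        groups = [("all", df)]
    elif group_by == "period":
        groups = list(df.groupby("period"))
    elif group_by == "dev_level":
        if "dev_orig" not in df.columns or "dev_dest" not in df.columns:
            if dev_levels is None:
                raise ValueError("dev_level grouping needs a region metadata mapping")
            df["dev_orig"] = df["origin"].map(dev_levels)
            df["dev_dest"] = df["destination"].map(dev_levels)
        df["group"] = df["dev_orig"].astype(str) + "->" + df["dev_dest"].astype(str)
        groups = list(df.groupby("group"))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for name, sub in groups:
        x = sub["estimated"].to_numpy(dtype=float)
        yv = sub["reported"].to_numpy(dtype=float)
        rows.append({"group": name, "n": len(sub), "correlation": _pearson(x, yv)})
    return pd.DataFrame(rows)
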