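"""Iterative proportional fitting with fixed cells and structural zeros.

The accounting estimators reduce to two log-linear designs on a square table:
the independence model (cell = row effect x column effect), which has the
closed form r_i * c_j / N, and a quasi-independence model in which diagonal
cells are held at externally fixed values and only the off-diagonal cells are
scaled to the margins.  Both are solved here by classical two-way IPF:
alternately rescale rows and columns of a seed table until both margin sets
are met.

Fixed cells are removed from the problem by subtracting their values from the
target margins; structural zeros are cells pinned at 0 throughout.  IPF
preserves the seed's interaction structure, so passing an observed table as
``seed_table`` performs a biproportional adjustment of that table to new
margins (used by the closed-system stock reconciliation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class IPFConvergenceError(RuntimeError):
    """IPF failed to meet the margin tolerance within the iteration cap."""

    def __init__(self, message: str, discrepancy: float):
        super().__init__(message)
        self.discrepancy = discrepancy


@dataclass
class IPFSpec:
    """Specification of a single two-way IPF problem.

    ``fixed_cells`` is a set of ``(i, j, value)`` triples held constant;
    ``structural_zeros`` a set of ``(i, j)`` cells pinned at 0.  ``tol`` is the
    maximum absolute margin discrepancy (in persons) accepted as converged.
    """

    target_row_margins: np.ndarray
    target_col_margins: np.ndarray
    fixed_cells: set = field(default_factory=set)
    structural_zeros: set = field(default_factory=set)
    tol: float = 1e-6
    max_iter: int = 10_000
    seed_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.target_row_margins = np.asarray(self.target_row_margins, dtype=float)
        self.target_col_margins = np.asarray(self.target_col_margins, dtype=float)
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if np.any(self.target_row_margins < 0) or np.any(self.target_col_margins < 0):
            raise ValueError("target margins must be nonnegative")


def ipf_fit(spec: IPFSpec, full_output: bool = False) -> np.ndarray:
    """Fit a nonnegative table to the margins of ``spec``.

    Free cells start from ``seed_table`` (default all ones) and are alternately
    row- and column-scaled until every margin is met to within ``spec.tol``.
    Returns the fitted table; with ``full_output=True`` also a dict with the
    iteration count and the margin-discrepancy history.

    Raises
    ------
    ValueError
        If a fixed cell exceeds its row or column target (infeasible margins)
        or the two margin totals disagree after fixed-cell accounting.
    IPFConvergenceError
        If the tolerance is not reached within ``max_iter`` sweeps.
    """
    rows = spec.target_row_margins.copy()
    cols = spec.target_col_margins.copy()
    nr, nc = len(rows), len(cols)

    free = np.ones((nr, nc), dtype=bool)
    fixed = np.zeros((nr, nc))
    for i, j, v in spec.fixed_cells:
        if v < 0:
            raise ValueError(f"fixed cell ({i}, {j}) has negative value {v}")
        fixed[i, j] = v
        free[i, j] = False
    for i, j in spec.structural_zeros:
        free[i, j] = False

    # remove fixed mass from the targets; the residual problem is pure IPF
    res_rows = rows - fixed.sum(axis=1)
    res_cols = cols - fixed.sum(axis=0)
    scale = 1.0 + max(rows.sum(), cols.sum())
    if np.any(res_rows < -1e-9 * scale) or np.any(res_cols < -1e-9 * scale):
        raise ValueError("infeasible margins: fixed cells exceed a row or column target")
    res_rows = np.maximum(res_rows, 0.0)
    res_cols = np.maximum(res_cols, 0.0)
    if abs(res_rows.sum() - res_cols.sum()) > 1e-6 * scale:
        raise ValueError(
            f"margin totals disagree: rows {res_rows.sum():g} vs cols {res_cols.sum():g}"
        )

    # zero residual margins pin all their free cells at 0
    free &= (res_rows > 0)[:, None]
    free &= (res_cols > 0)[None, :]

    if spec.seed_table is not None:
        table = np.asarray(spec.seed_table, dtype=float).copy()
        if table.shape != (nr, nc):
            raise ValueError("seed_table shape does not match margins")
        if np.any(table[free] < 0):
            raise ValueError("seed_table must be nonnegative")
    else:
        table = np.ones((nr, nc))
    table[~free] = 0.0

    history: list[float] = []
    converged = False
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(spec.max_iter):
            rsum = table.sum(axis=1)
            rfac = np.where(rsum > 0, res_rows / np.where(rsum > 0, rsum, 1.0), 0.0)
            if np.any((rsum == 0) & (res_rows > 0)):
                raise IPFConvergenceError(
                    "a row target is positive but has no admissible cells",
                    float("inf"),
                )
            table *= rfac[:, None]
            csum = table.sum(axis=0)
            cfac = np.where(csum > 0, res_cols / np.where(csum > 0, csum, 1.0), 0.0)
            if np.any((csum == 0) & (res_cols > 0)):
                raise IPFConvergenceError(
                    "a column target is positive but has no admissible cells",
                    float("inf"),
                )
            table *= cfac[None, :]
            disc = max(
                np.abs(table.sum(axis=1) - res_rows).max(initial=0.0),
                np.abs(table.sum(axis=0) - res_cols).max(initial=0.0),
            )
            history.append(float(disc))
            if disc < spec.tol:
                converged = True
                break
    if not converged:
        raise IPFConvergenceError(
            f"IPF did not converge in {spec.max_iter} iterations "
            f"(final discrepancy {history[-1]:g})",
            history[-1],
        )
    out = table + fixed
    if full_output:
        return out, {"iterations": len(history), "history": history}
    return out


def independence_fit(row_margins, col_margins) -> np.ndarray:
    """Closed-form independence table: cell (i, j) = row_i * col_j / total.

    Equivalent to :func:`ipf_fit` with no fixed cells or structural zeros.
    """
    rows = np.asarray(row_margins, dtype=float)
    cols = np.asarray(col_margins, dtype=float)
    if np.any(rows < 0) or np.any(cols < 0):
        raise ValueError("margins must be nonnegative")
    total = rows.sum()
    if abs(total - cols.sum()) > 1e-6 * (1.0 + total):
        raise ValueError("margin totals disagree")
    if total == 0:
        if np.any(rows > 0) or np.any(cols > 0):
            raise ValueError("zero total with nonzero margins")
        return np.zeros((len(rows), len(cols)))
    return np.outer(rows, cols) / total
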