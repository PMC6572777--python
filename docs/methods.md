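# Methods

## Data model

A migrant-stock table is a square contingency table: rows index birthplace,
columns place of residence, the diagonal holds native-born stayers, and
column sums are resident populations at the reference time. Flows are
*transitions*: a person counted in `y_ij` was resident in `i` at the start of
the five-year interval and in `j` at its end, regardless of intermediate
moves. All counts are nonnegative floats — the accounting estimators produce
fractional persons, and rounding (1 decimal in the printed examples) is
purely a display choice.

Region labels are opaque strings; ISO3 or UN codes work but are not required.
Long-format keys are (origin, destination, period label), periods half-open
`[t, t+5)`.

## Stock differencing

`sd_drop_neg` takes the positive part of each off-diagonal stock change.
`sd_rev_neg` additionally counts a *decline* in the stock of people born in
`j` living in `i` as a return flow `i → j`; the implementation uses the
identity

    y_ij = max(Δ_ij, 0) + max(−Δ_ji, 0),   Δ_ij = s_ij^{t+1} − s_ij^t,

which is equivalent to the four-branch piecewise definition and makes the
oracle identity `Σ y_ij = Σ |Δ_ij|` (off-diagonal) immediate. Ties (no
change) contribute zero. Neither estimator adjusts for deaths or births: a
migrant dying abroad looks like a return move, which is a known bias of this
family.

## Migration rates

With `M` the global one-way flow total for the period, flows are allocated
proportionally to start-of-period stock shares. `M` is approximated as
`Σ_j |net_j|` from supplied net-migration data (default), or as
`Σ_j |Δpop_j|`, which coincides with the former exactly when births equal
deaths in every region. The sum is deliberately *not* halved even though each
move enters two regions' nets; this matches the convention of the method's
source and of the worked example. Flows conserve `M` exactly and are
invariant to rescaling the stock table.

## Demographic accounting

People cannot change their birthplace, so row `k` of the two stock tables
gives the start and end residence distributions of the cohort born in `k`:
the margins of an unknown flow table `m[i, j, k]`. Preprocessing:

1. **Deaths** — each residence column of the start table is multiplied by
   `(pop_start_j − deaths_j)/pop_start_j`. Mortality is assumed identical for
   native- and foreign-born residents (no global mortality-by-nativity data
   exist to do better).
2. **Births** — `births_j` is subtracted from the native-born diagonal cell
   `(j, j)` of the end table only. A negative result is clamped to 0 and
   logged; clamping keeps margins nonnegative where reported births exceed
   the native-born stock.

The per-birthplace row/column totals still differ slightly; two
reconciliations close the gap:

- **Open system** (`da_min_open`): one aggregate rest-of-world category is
  appended. For each birthplace the entire residual goes to one side — an
  external destination when the system lost members of that cohort, an
  external origin when it gained them. Flows through the external category
  are excluded from the final table. A single aggregate category (rather
  than a per-country allocation of external moves) is the minimal structure
  that satisfies the residual constraint.
- **Closed system** (`da_min_closed`, `da_pb_closed`): both adjusted tables
  are biproportionally rescaled (IPF seeded with the table itself, preserving
  its interaction structure) so that their row sums meet at the midpoint.
  Because midpoint row targets must sum to a common grand total, both grand
  totals are first harmonised to their mean and column targets are the
  tables' own column sums rescaled proportionally — column *shares* are
  preserved exactly, column totals only up to the common-total factor. The
  closure forces every region's implied net flow to equal the net change in
  the reconciled stocks, which is why closed estimates correlate perfectly
  with accounting-equation net counts.

**Minimisation fit.** Per birthplace slice, diagonal (stayer) cells are fixed
at their maximum feasible value `min(row_i, col_i)`; off-diagonal cells
follow a quasi-independence log-linear model fitted by IPF with the diagonal
held fixed. Fixing the diagonal at the minimum of the margins makes the
off-diagonal mass per slice exactly `Σ_i max(row_i − col_i, 0)`, the smallest
total flow any nonnegative array with those margins can achieve (verified
against a linear-programming oracle in the tests). Origin–destination flows
are the array summed over birthplaces, diagonal zeroed.

**Pseudo-Bayes blend.** The minimisation flows are averaged with a plain
independence fit `z[i, j, k] = row_i · col_j / total` of the same margins:
`y_ij = w·m_{ij+} + (1−w)·z_{ij+}`, default `w = 0.87`. The weight is a
configurable constant, not re-estimated here. The blend deliberately breaks
the "minimum required flow" property: the independence component assigns
mass to every corridor, so even a completely static stock pair yields
positive pseudo-Bayes flows of `(1−w)` times the independence off-diagonal
mass. The blend is only defined for the closed system.

## IPF engine

Classical two-way IPF: alternate row and column proportional scaling of a
seed table (default all ones). Fixed cells are removed by subtracting their
values from the target margins; a negative residual margin is reported as
infeasible rather than clamped. Zero residual margins pin their free cells at
0, avoiding 0/0 scaling. Convergence is declared when the maximum absolute
margin discrepancy falls below `tol` (default 1e-6 persons, an absolute
tolerance chosen so that 1-decimal table output is unaffected); the iteration
cap defaults to 10,000 cheap sweeps, and hitting it raises an error carrying
the final discrepancy. Because the closed-system reconciliation itself only
matches slice totals to this tolerance, the array fitters first rescale each
slice's column margins exactly onto its row total (an adjustment bounded by
the reconciliation tolerance) so the downstream fit is feasible to full
precision.

With the diagonal fixed at `min(row, col)`, every region has a zero residual
on at least one side, so the free cells form a complete bipartite block
between net senders and net receivers; the fit then equals the independence
table on that block and IPF converges in a handful of sweeps.

## Validation measures

Six measures per method: count, log count, proportion of a region's total
in-/outflow, emigration rate `Σ_j y_ij / p_i`, immigration rate
`Σ_i y_ij / p_j` (denominators are start-of-period populations), and net
count `Σ_i y_ij − Σ_j y_ji`. Validity is Pearson correlation against
reported flows, never absolute error: reported annual flows are converted to
five-year equivalents as 5 × the mean of available years (a simple mean, as
no principled weighting of partial coverage exists), and correlation is
invariant to that multiplier. Corridors with a zero on either side are
excluded from the log-count correlation (log 0 undefined; the exclusion
count is visible in the output's `n` column). Corridors reported by both the
sending and the receiving country enter as two records. Groups with fewer
than three pairs or zero variance report a missing correlation, not zero.

## Synthetic data generator

`table1_fixture()` is the 4-region desk example: matched row totals,
births = deaths = 0, so every preprocessing step is the identity and the
open and closed systems coincide.

`simulate_population(R, periods, params, seed)` forward-simulates a closed
multiregional population as deaths → moves → births per period:

- deaths remove `death_rate` of every residence column (default 0.05 per
  five years, roughly a crude death rate of 10 per 1000 per year);
- for each birthplace, regions are split at random into senders and
  receivers and `move_rate` (default 0.03) of each sending stock is
  redistributed over receivers proportionally to random weights;
- births add `birth_rate` (default 0.10, ~20 per 1000 per year) per
  start-of-period resident to each region's native diagonal.

Initial populations are `base_pop` (default 1e5) scaled by ±50% uniform
noise, with `foreign_share` (default 0.10) of each region's residents born
elsewhere. Flows are expected values (no sampling noise), which makes
parameter-recovery tests exact: the sender/receiver split means no region
both sends and receives within a birthplace slice, so the true flows satisfy
the minimum-movers structure and the closed minimisation estimator inverts
the simulation to numerical precision. This is also what the simulator does
*not* emulate: measurement error in stocks, mortality differentials by
nativity, flows violating the quasi-independence structure, and integer
sampling noise. Passing recovery tests therefore demonstrates correctness of
the pipeline's algebra, not robustness of the estimators on real data —
estimator disagreement on noisy inputs is expected and is the reason the
validation module exists.

## Problem sizes and determinism

The test suite and the acceptance script run the full six-method pipeline at
200 regions × 5 periods (200,000 corridor-period rows, a few seconds) and use
3–10-region instances elsewhere; all randomness flows through explicit seeds
(`numpy.random.default_rng`), and identical inputs and configuration produce
byte-identical output files.

## Known limitations

- No age or sex disaggregation; no uncertainty intervals.
- The open-system residual is assigned wholly to one side per birthplace;
  simultaneous in- and out-residuals for one cohort cannot be represented.
- `reconcile_closed` requires strictly positive row sums in both adjusted
  tables (IPF cannot grow a zero row); degenerate inputs raise rather than
  silently redistribute.
- Stocks recorded off mid-year grid points must be interpolated upstream.
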