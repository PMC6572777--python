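import numpy as np
import pytest
from scipy.optimize import linprog

from flowstock import (
    AccountingConfig,
    adjust_for_births,
    adjust_for_deaths,
    estimate_accounting,
    fit_independence_array,
    fit_minimisation,
    fit_pseudo_bayes,
    flows_from_array,
    reconcile_closed,
    reconcile_open,
    simulate_population,
)
from flowstock.data_model import DemographicSeries, StockTable
from flowstock.demographic_accounting import OUTSIDE, _margins_from_pair
from flowstock.synthetic_data import SimulationParams

from conftest import random_stock_pair, zero_demo

# printed worked-example tables, 1-decimal display precision:
# birthplace-specific quasi-independence arrays (origin x destination, per birthplace)
TABLE4 = {
    "A": [[95, 0, 2.5, 2.5], [0, 5, 2.5, 2.5], [0, 0, 10, 0], [0, 0, 0, 0]],
    "B": [[75, 5, 0, 0], [0, 180, 0, 0], [0, 5, 5, 0], [0, 35, 0, 55]],
    "C": [[30, 0, 0, 0], [7.1, 0, 0, 2.9], [17.9, 0, 115, 7.1], [0, 0, 0, 40]],
    "D": [[35, 0, 5.4, 19.6], [0, 25, 9.6, 35.4], [0, 0, 10, 0], [0, 0, 0, 160]],
}
# birthplace-specific independence arrays
TABLE6 = {
    "A": [[79.2, 4.2, 12.5, 4.2], [7.9, 0.4, 1.3, 0.4], [7.9, 0.4, 1.3, 0.4], [0, 0, 0, 0]],
    "B": [[16.7, 50, 1.1, 12.2], [37.5, 112.5, 2.5, 27.5], [2.1, 6.3, 0.1, 1.5], [18.8, 56.3, 1.3, 13.8]],
    "C": [[7.5, 0, 15.7, 6.8], [2.5, 0, 5.2, 2.3], [35, 0, 73.2, 31.8], [10, 0, 20.9, 9.1]],
    "D": [[7, 5, 5, 43], [8.2, 5.8, 5.8, 50.2], [1.2, 0.8, 0.8, 7.2], [18.7, 13.3, 13.3, 114.7]],
}
# origin-destination flow estimates summed over birthplaces
TABLE5_MIN = np.array(
    [[0, 5, 7.9, 22.1], [7.1, 0, 12.1, 40.7], [17.9, 5, 0, 7.1], [0, 35, 0, 0]]
)
TABLE5_PB = np.array(
    [[0, 12, 11.3, 27.9], [13.5, 0, 12.5, 45.9], [21.5, 5.3, 0, 11.5], [6.2, 39.5, 4.6, 0]]
)


class TestAdjustments:
    def test_zero_deaths_leave_stocks_unchanged(self, fixture4):
        s0, _, demo = fixture4
        np.testing.assert_array_equal(adjust_for_deaths(s0, demo).values, s0.values)

    def test_half_the_population_dying_halves_the_column(self, fixture4):
        s0, _, demo = fixture4
        demo = zero_demo(demo.regions, demo.pop_start, demo.pop_end)
        demo.deaths = demo.pop_start / 2
        adj = adjust_for_deaths(s0, demo)
        np.testing.assert_allclose(adj.values, s0.values / 2)

    def test_adjusted_column_sums_equal_survivors(self, rng):
        s0, _ = random_stock_pair(rng, r=6)
        pop = s0.populations()
        demo = zero_demo(s0.regions, pop, pop)
        demo.deaths = rng.uniform(0, 0.3, size=6) * pop
        adj = adjust_for_deaths(s0, demo)
        np.testing.assert_allclose(adj.populations(), pop - demo.deaths)

    def test_deaths_exceeding_population_rejected(self, fixture4):
        s0, _, demo = fixture4
        demo = zero_demo(demo.regions, demo.pop_start, demo.pop_end)
        demo.deaths = demo.pop_start + 1
        with pytest.raises(ValueError):
            adjust_for_deaths(s0, demo)

    def test_births_touch_only_the_diagonal(self, fixture4):
        _, s1, demo = fixture4
        demo = zero_demo(demo.regions, demo.pop_start, demo.pop_end)
        demo.births = np.array([10.0, 0.0, 5.0, 0.0])
        adj = adjust_for_births(s1, demo)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(adj.values[off], s1.values[off])
        np.testing.assert_allclose(np.diag(adj.values), np.diag(s1.values) - demo.births)

    def test_births_exceeding_native_stock_clamp_to_zero(self, fixture4, caplog):
        import logging

        _, s1, demo = fixture4
        demo = zero_demo(demo.regions, demo.pop_start, demo.pop_end)
        demo.births = np.array([1e6, 0.0, 0.0, 0.0])
        with caplog.at_level(logging.WARNING, logger="flowstock"):
            adj = adjust_for_births(s1, demo)
        assert adj.values[0, 0] == 0.0
        assert any("clamp" in rec.message for rec in caplog.records)


class TestReconcile:
    def test_open_system_zero_residual_on_matched_rows(self, fixture4):
        s0, s1, _ = fixture4
        cats, bps, row_m, col_m = reconcile_open(s0, s1)
        assert cats[-1] == OUTSIDE and bps == s0.regions
        assert np.all(row_m[-1] == 0) and np.all(col_m[-1] == 0)
        np.testing.assert_allclose(row_m.sum(axis=0), col_m.sum(axis=0))

    def test_open_system_residual_bookkeeping(self, fixture4):
        s0, s1, _ = fixture4
        bumped = s1.values.copy()
        bumped[2, 0] += 12.0  # born-C row total now exceeds the start total
        s1b = StockTable(s1.regions, bumped, s1.ref_time)
        cats, _, row_m, col_m = reconcile_open(s0, s1b)
        assert row_m[-1, 2] == pytest.approx(12.0)  # external origin supplies it
        assert col_m[-1, 2] == 0.0
        np.testing.assert_allclose(row_m.sum(axis=0), col_m.sum(axis=0))

    def test_open_system_global_residual_conservation(self, rng):
        s0, s1 = random_stock_pair(rng, r=5)
        noisy = StockTable(
            s1.regions, s1.values * rng.uniform(0.9, 1.1, size=(5, 5)), s1.ref_time
        )
        _, _, row_m, col_m = reconcile_open(s0, noisy)
        inflow, outflow = row_m[-1].sum(), col_m[-1].sum()
        mismatch = (noisy.values.sum(axis=1) - s0.values.sum(axis=1)).sum()
        assert inflow - outflow == pytest.approx(mismatch, abs=1e-8)

    def test_closed_system_is_a_fixed_point_on_matched_rows(self, fixture4):
        s0, s1, _ = fixture4
        a, b = reconcile_closed(s0, s1)
        np.testing.assert_allclose(a.values, s0.values, atol=1e-5)
        np.testing.assert_allclose(b.values, s1.values, atol=1e-5)

    def test_closed_system_matches_row_sums_and_grand_totals(self, rng):
        s0, s1 = random_stock_pair(rng, r=5)
        noisy = StockTable(
            s1.regions, s1.values * rng.uniform(0.85, 1.15, size=(5, 5)), s1.ref_time
        )
        a, b = reconcile_closed(s0, noisy)
        np.testing.assert_allclose(
            a.values.sum(axis=1), b.values.sum(axis=1), atol=1e-4
        )
        assert a.values.sum() == pytest.approx(b.values.sum(), abs=1e-4)
        # column shares preserved
        np.testing.assert_allclose(
            a.populations() / a.values.sum(), s0.populations() / s0.values.sum(),
            atol=1e-6,
        )


class TestMinimisation:
    def fit_fixture(self, fixture4):
        s0, s1, _ = fixture4
        row_m, col_m = _margins_from_pair(s0, s1)
        return fit_minimisation(list(s0.regions), list(s0.regions), row_m, col_m)

    def test_birthplace_arrays_match_worked_example(self, fixture4):
        m = self.fit_fixture(fixture4)
        for k, name in enumerate(m.birthplaces):
            np.testing.assert_allclose(
                m.values[:, :, k], np.array(TABLE4[name], dtype=float), atol=0.06
            )

    def test_flows_match_worked_example(self, fixture4):
        ft = flows_from_array(self.fit_fixture(fixture4))
        np.testing.assert_allclose(ft.values, TABLE5_MIN, atol=0.06)
        assert ft.total == pytest.approx(160, abs=1e-3)

    def test_single_region_system(self):
        m = fit_minimisation(["A"], ["A"], np.array([[7.0]]), np.array([[7.0]]))
        assert m.values[0, 0, 0] == 7.0
        assert flows_from_array(m).total == 0

    def test_offdiagonal_mass_identity(self, rng):
        s0, s1 = random_stock_pair(rng, r=5)
        row_m, col_m = _margins_from_pair(s0, s1)
        m = fit_minimisation(list(s0.regions), list(s0.regions), row_m, col_m)
        for k in range(5):
            mass = m.values[:, :, k].sum() - np.trace(m.values[:, :, k])
            expected = (row_m[:, k] - np.minimum(row_m[:, k], col_m[:, k])).sum()
            assert mass == pytest.approx(expected, abs=1e-6)

    def test_fitted_margins_meet_targets(self, rng):
        s0, s1 = random_stock_pair(rng, r=6)
        row_m, col_m = _margins_from_pair(s0, s1)
        m = fit_minimisation(list(s0.regions), list(s0.regions), row_m, col_m)
        assert m.margin_discrepancy() < 1e-5

    def test_minimality_against_linear_programming_oracle(self, rng):
        """The fitted off-diagonal mass per slice is the smallest achievable by
        ANY nonnegative array with the same margins (checked by an LP)."""
        for _ in range(5):
            rows = rng.uniform(0, 50, size=3)
            cols = rng.uniform(0, 50, size=3)
            cols *= rows.sum() / max(cols.sum(), 1e-9)
            m = fit_minimisation(
                ["A", "B", "C"], ["A"], rows[:, None], cols[:, None]
            )
            fitted_mass = m.values[:, :, 0].sum() - np.trace(m.values[:, :, 0])
            c = (1.0 - np.eye(3)).ravel()  # minimise off-diagonal mass
            a_eq, b_eq = [], []
            for i in range(3):
                sel = np.zeros((3, 3))
                sel[i, :] = 1
                a_eq.append(sel.ravel())
                b_eq.append(rows[i])
            for j in range(3):
                sel = np.zeros((3, 3))
                sel[:, j] = 1
                a_eq.append(sel.ravel())
                b_eq.append(cols[j])
            res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                          bounds=[(0, None)] * 9)
            assert res.success
            assert fitted_mass == pytest.approx(res.fun, abs=1e-6)


class TestIndependenceArray:
    def test_matches_worked_example(self, fixture4):
        s0, s1, _ = fixture4
        row_m, col_m = _margins_from_pair(s0, s1)
        z = fit_independence_array(list(s0.regions), list(s0.regions), row_m, col_m)
        for k, name in enumerate(z.birthplaces):
            np.testing.assert_allclose(
                z.values[:, :, k], np.array(TABLE6[name], dtype=float), atol=0.06
            )


class TestPseudoBayes:
    def test_matches_worked_example(self, fixture4):
        s0, s1, demo = fixture4
        ft = estimate_accounting(
            s0, s1, demo, AccountingConfig("closed", "pseudo_bayes", w=0.87)
        )
        np.testing.assert_allclose(ft.values, TABLE5_PB, atol=0.06)
        assert ft.total == pytest.approx(211.7, abs=0.05)

    def test_blend_endpoints(self, fixture4):
        s0, s1, _ = fixture4
        cats = list(s0.regions)
        row_m, col_m = _margins_from_pair(s0, s1)
        at_one = fit_pseudo_bayes(cats, cats, row_m, col_m, w=1.0)
        minim = flows_from_array(fit_minimisation(cats, cats, row_m, col_m))
        np.testing.assert_allclose(at_one.values, minim.values, atol=1e-6)
        at_zero = fit_pseudo_bayes(cats, cats, row_m, col_m, w=0.0)
        z = fit_independence_array(cats, cats, row_m, col_m).origin_destination()
        np.fill_diagonal(z, 0.0)
        np.testing.assert_allclose(at_zero.values, z, atol=1e-9)

    def test_pseudo_bayes_requires_closed_system(self):
        with pytest.raises(ValueError):
            AccountingConfig(system="open", estimator="pseudo_bayes")


class TestEstimateAccounting:
    def test_open_equals_closed_on_matched_fixture(self, fixture4):
        s0, s1, demo = fixture4
        open_ft = estimate_accounting(s0, s1, demo, AccountingConfig("open"))
        closed_ft = estimate_accounting(s0, s1, demo, AccountingConfig("closed"))
        np.testing.assert_allclose(open_ft.values, closed_ft.values, atol=1e-4)
        assert open_ft.method_tag == "da_min_open"
        assert closed_ft.method_tag == "da_min_closed"

    def test_closed_nets_match_reconciled_stock_nets_exactly(self, rng):
        """A closed accounting system forces every region's implied net flow
        (inflow - outflow) to equal the population change implied by the
        reconciled stocks, so the two vectors correlate perfectly."""
        s0, s1 = random_stock_pair(rng, r=6)
        noisy = StockTable(
            s1.regions, s1.values * rng.uniform(0.9, 1.1, size=(6, 6)), s1.ref_time
        )
        pop0 = s0.populations()
        demo = zero_demo(s0.regions, pop0, noisy.populations())
        demo.deaths = 0.05 * pop0
        demo.births = 0.08 * pop0
        ft = estimate_accounting(s0, noisy, demo, AccountingConfig("closed"))
        est_net = ft.values.sum(axis=0) - ft.values.sum(axis=1)
        s0pp, s1pp = reconcile_closed(
            adjust_for_deaths(s0, demo), adjust_for_births(noisy, demo)
        )
        stock_net = s1pp.populations() - s0pp.populations()
        np.testing.assert_allclose(est_net, stock_net, atol=1e-4)
        assert np.corrcoef(est_net, stock_net)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_on_minimum_movers_population(self):
        """Flows generated under the minimum-movers structure (no region both
        sends and receives within a birthplace) are recovered exactly by the
        closed minimisation estimator."""
        params = SimulationParams(move_rate=0.05, birth_rate=0.08, death_rate=0.04)
        stocks, demos, true_flows = simulate_population(6, 2, params, seed=42)
        for s0, s1, demo, truth in zip(stocks[:-1], stocks[1:], demos, true_flows):
            ft = estimate_accounting(s0, s1, demo, AccountingConfig("closed"))
            np.testing.assert_allclose(ft.values, truth.values, atol=1e-3)

    def test_all_estimators_nonnegative_zero_diagonal(self, rng):
        from flowstock.pipeline import estimate_period

        s0, s1 = random_stock_pair(rng, r=5)
        noisy = StockTable(
            s1.regions, s1.values * rng.uniform(0.95, 1.05, size=(5, 5)), s1.ref_time
        )
        pop0 = s0.populations()
        demo = zero_demo(s0.regions, pop0, noisy.populations())
        demo.deaths = 0.02 * pop0
        demo.births = 0.05 * pop0
        for ft in estimate_period(s0, noisy, demo):
            assert np.all(ft.values >= 0)
            assert np.all(np.diag(ft.values) == 0)
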