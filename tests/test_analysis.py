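"""Simulation protocols: growth media, overflow scans, trade-off, metrics."""

import math

import numpy as np
import pytest

from ecgem import (
    build_ec_model,
    energy_enzyme_cost,
    estimation_error,
    max_growth_on_carbon_source,
    minimize_enzyme_usage,
    normalized_flux_error,
    optimize,
    overflow_scan,
    tradeoff_scan,
)
from ecgem.analysis import growth_comparison_table, secretion_flux, uptake_flux


class TestMetrics:
    def test_estimation_error_identities(self):
        assert estimation_error(0.6, 0.6) == 0.0
        assert estimation_error(0.66, 0.60) == pytest.approx(0.1)
        assert estimation_error(0.0, 0.5) == 1.0

    def test_estimation_error_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            estimation_error(0.5, 0.0)

    def test_normalized_flux_error_identities(self):
        assert normalized_flux_error([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert normalized_flux_error([1.0, 1.0], [1.0, 2.0]) == pytest.approx(
            math.sqrt(1 / 5)
        )

    def test_normalized_flux_error_scale_invariance(self):
        sim, exp = [0.3, 0.7, 1.1], [0.4, 0.6, 1.0]
        assert normalized_flux_error(
            [10 * s for s in sim], [10 * e for e in exp]
        ) == pytest.approx(normalized_flux_error(sim, exp), rel=1e-12)

    def test_normalized_flux_error_validates_input(self):
        with pytest.raises(ValueError, match="length"):
            normalized_flux_error([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="experimental"):
            normalized_flux_error([1.0], [0.0])


class TestCarbonSourceGrowth:
    def test_sole_substrate_equals_plain_optimum(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        sol = max_growth_on_carbon_source(ec, "EX_glc__D_e", uptake_ub=10.0)
        assert sol.fluxes["BIOMASS"] == pytest.approx(
            optimize(ec).objective_value, rel=1e-6
        )

    def test_uptake_bound_is_respected(self, toy_ec_factory, toy_params):
        ec = toy_ec_factory(1000.0)  # enzyme non-binding: substrate-limited
        sol = max_growth_on_carbon_source(ec, "EX_glc__D_e", uptake_ub=3.0)
        assert uptake_flux(ec, sol, "EX_glc__D_e") <= 3.0 + 1e-9
        assert sol.fluxes["BIOMASS"] == pytest.approx(
            toy_params.fba_max_growth(3.0), rel=1e-6
        )

    def test_closed_exchange_carries_no_flux(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        sol = max_growth_on_carbon_source(
            ec, "EX_o2_e", uptake_ub=10.0, closed_exchanges=["EX_glc__D_e"]
        )
        # no carbon: no growth, no glucose uptake
        assert uptake_flux(ec, sol, "EX_glc__D_e") == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["BIOMASS"] == pytest.approx(0.0, abs=1e-9)

    def test_comparison_table_reports_errors(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        mu = optimize(ec).objective_value
        table = growth_comparison_table(ec, {"EX_glc__D_e": mu * 1.25})
        assert len(table) == 1
        assert table[0].estimation_error == pytest.approx(0.2)


class TestOverflowScan:
    def test_switch_point_matches_closed_form(self, toy_ec_factory, toy_params):
        pool = 0.02
        ec = toy_ec_factory(pool)
        switch = toy_params.overflow_switch_growth(pool)
        grid = [0.1, 0.25, switch * 0.999, switch, switch + 5e-5, 0.45, 0.49]
        scan = overflow_scan(ec, grid, "EX_glc__D_e", ["EX_ac_e"], "EX_o2_e")
        assert scan.switch_point == pytest.approx(switch, abs=1e-4)
        for row in scan.rows:
            if row["growth"] <= switch:
                assert row["secretion_EX_ac_e"] <= 1e-9

    def test_uptake_matches_closed_form_above_and_below_switch(
        self, toy_ec_factory, toy_params
    ):
        pool = 0.02
        ec = toy_ec_factory(pool)
        grid = [0.1, 0.3, 0.45, 0.49]
        scan = overflow_scan(ec, grid, "EX_glc__D_e", ["EX_ac_e"], "EX_o2_e")
        for row in scan.rows:
            expected_uptake, _, ferm = toy_params.min_uptake_at_growth(row["growth"], pool)
            assert row["substrate_uptake"] == pytest.approx(expected_uptake, rel=1e-6)
            assert row["secretion_EX_ac_e"] == pytest.approx(
                toy_params.acetate_per_glc_ferm * ferm, abs=1e-6
            )

    def test_huge_pool_never_secretes(self, toy_ec_factory):
        scan = overflow_scan(
            toy_ec_factory(1000.0), [0.1, 0.3, 0.5], "EX_glc__D_e", ["EX_ac_e"], "EX_o2_e"
        )
        assert scan.switch_point is None
        assert all(r["secretion_EX_ac_e"] <= 1e-9 for r in scan.rows)

    def test_uptake_nondecreasing_in_growth(self, toy_ec_factory):
        grid = list(np.linspace(0.05, 0.49, 8))
        scan = overflow_scan(toy_ec_factory(0.02), grid, "EX_glc__D_e", ["EX_ac_e"])
        uptakes = [r["substrate_uptake"] for r in scan.rows]
        assert all(b >= a - 1e-9 for a, b in zip(uptakes, uptakes[1:]))

    def test_infeasible_grid_point_is_recorded_not_raised(self, toy_ec_factory, toy_params):
        pool = 0.02
        ceiling = toy_params.max_growth_unlimited_substrate(pool)
        scan = overflow_scan(
            toy_ec_factory(pool), [0.1, ceiling * 2], "EX_glc__D_e", ["EX_ac_e"]
        )
        assert scan.rows[0]["status"] == "optimal"
        assert scan.rows[1]["status"] == "infeasible"

    def test_oxphos_ratio_definition(self, toy_ec_factory, toy_params):
        ec = toy_ec_factory(0.02)
        scan = overflow_scan(ec, [0.2], "EX_glc__D_e", ["EX_ac_e"], "EX_o2_e")
        row = scan.rows[0]
        # pure respiration: o2/glc = stoichiometric ratio
        assert row["oxphos_ratio"] == pytest.approx(toy_params.o2_per_glc_resp, rel=1e-6)

    def test_grid_must_increase(self, toy_ec_factory):
        with pytest.raises(ValueError, match="increasing"):
            overflow_scan(toy_ec_factory(0.02), [0.3, 0.2], "EX_glc__D_e", ["EX_ac_e"])


class TestEnergyEnzymeCost:
    def test_single_reaction_arithmetic(self, toy_ec_factory, toy_params):
        # substrate-limited regime: all flux goes through respiration
        ec = toy_ec_factory(1000.0)
        sol = minimize_enzyme_usage(ec)
        breakdown = energy_enzyme_cost(ec, sol, ["RESP"], "atp_c", label="respiration")
        v = sol.fluxes["RESP"]
        assert breakdown.net_atp_flux == pytest.approx(toy_params.atp_per_glc_resp * v)
        assert breakdown.cost_per_atp == pytest.approx(
            sol.enzyme_costs["RESP"] / (toy_params.atp_per_glc_resp * v)
        )

    def test_per_mol_reporting_scales_by_1000(self, toy_ec_factory):
        ec = toy_ec_factory(1000.0)
        sol = minimize_enzyme_usage(ec)
        per_mmol = energy_enzyme_cost(ec, sol, ["RESP"], "atp_c")
        per_mol = energy_enzyme_cost(ec, sol, ["RESP"], "atp_c", per_mol=True)
        assert per_mol.cost_per_atp == pytest.approx(1000 * per_mmol.cost_per_atp)

    def test_fermentation_cheaper_per_atp_than_respiration(self, toy_ec_factory, toy_params):
        """The overflow driver: at high growth the fermentation route costs
        less enzyme per unit ATP than respiration."""
        from ecgem import solve_lp

        pool = 0.02
        ec = toy_ec_factory(pool)
        # min-uptake state at a growth above the switch: both routes active
        overrides = {"BIOMASS": (0.49, 0.49), "EX_glc__D_e_reverse": (0.0, 1e6)}
        scan_sol = solve_lp(ec, {"EX_glc__D_e_reverse": 1.0}, "min",
                            bound_overrides=overrides)
        assert scan_sol.optimal
        assert scan_sol.fluxes["RESP"] > 1e-6  # respiration still running
        resp = energy_enzyme_cost(ec, scan_sol, ["RESP"], "atp_c", label="respiration")
        ferm = energy_enzyme_cost(
            ec, scan_sol, ["FERM_num1", "FERM_num2", "NADHOX"], "atp_c", label="fermentation"
        )
        assert resp.defined and ferm.defined
        assert ferm.cost_per_atp < resp.cost_per_atp
        # closed forms: c_r/y_r and c_ferm_chain/y_f
        assert resp.cost_per_atp == pytest.approx(
            toy_params.cost_resp / toy_params.atp_per_glc_resp, rel=1e-6
        )
        assert ferm.cost_per_atp == pytest.approx(
            toy_params.cost_ferm_chain / toy_params.atp_per_glc_ferm, rel=1e-6
        )

    def test_zero_flux_pathway_is_flagged_undefined(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        sol = minimize_enzyme_usage(
            ec, bound_overrides={"EX_glc__D_e_reverse": (0.0, 0.0)}
        )
        breakdown = energy_enzyme_cost(ec, sol, ["RESP"], "atp_c")
        assert not breakdown.defined
        assert breakdown.cost_per_atp is None

    def test_unknown_pathway_reaction_raises(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        sol = minimize_enzyme_usage(ec)
        with pytest.raises(KeyError, match="GHOST"):
            energy_enzyme_cost(ec, sol, ["GHOST"], "atp_c")


class TestTradeoffScan:
    def test_yield_constant_before_binding_then_decreasing(self, toy_ec_factory, toy_params):
        pool = 0.02
        # respiration saturates the pool at uptake P/c_r = 0.2
        binding_uptake = pool / toy_params.cost_resp
        grid = [0.25 * binding_uptake, 0.5 * binding_uptake, binding_uptake,
                1.5 * binding_uptake, 2.5 * binding_uptake]
        result = tradeoff_scan(toy_ec_factory(pool), grid, "EX_glc__D_e")
        yields = [r["biomass_yield"] for r in result.rows]
        assert yields[0] == pytest.approx(yields[1], rel=1e-6)
        assert yields[1] == pytest.approx(yields[2], rel=1e-6)
        assert yields[3] < yields[2] - 1e-9
        assert yields[4] < yields[3] - 1e-9

    def test_efficiency_rises_while_yield_falls(self, toy_ec_factory, toy_params):
        pool = 0.02
        binding_uptake = pool / toy_params.cost_resp
        grid = [binding_uptake, 2 * binding_uptake, 4 * binding_uptake]
        rows = tradeoff_scan(toy_ec_factory(pool), grid, "EX_glc__D_e").rows
        for a, b in zip(rows, rows[1:]):
            assert b["biomass_yield"] <= a["biomass_yield"] + 1e-9
            assert b["enzyme_efficiency"] >= a["enzyme_efficiency"] - 1e-9

    def test_emin_nondecreasing_while_growth_increases(self, toy_ec_factory):
        grid = list(np.linspace(0.05, 0.6, 6))
        rows = tradeoff_scan(toy_ec_factory(0.02), grid, "EX_glc__D_e").rows
        emins = [r["e_min"] for r in rows]
        growths = [r["growth"] for r in rows]
        assert all(b >= a - 1e-9 for a, b in zip(emins, emins[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(growths, growths[1:]))

    def test_nonbinding_pool_yield_constant_everywhere(self, toy_ec_factory):
        """With the pool slack the LP is substrate-limited and linear, so
        the yield is identical at every uptake bound."""
        rows = tradeoff_scan(
            toy_ec_factory(1000.0), [1.0, 2.0, 4.0, 8.0], "EX_glc__D_e"
        ).rows
        yields = [r["biomass_yield"] for r in rows]
        assert all(y == pytest.approx(yields[0], rel=1e-6) for y in yields[1:])

    def test_grid_validation(self, toy_ec_factory):
        with pytest.raises(ValueError, match="positive"):
            tradeoff_scan(toy_ec_factory(0.02), [-1.0, 2.0], "EX_glc__D_e")


class TestSecretionAccounting:
    def test_secretion_and_uptake_are_nonnegative(self, toy_ec_factory):
        ec = toy_ec_factory(0.02)
        sol = minimize_enzyme_usage(ec)
        for ex in ("EX_glc__D_e", "EX_ac_e", "EX_o2_e"):
            assert uptake_flux(ec, sol, ex) >= 0.0
            assert secretion_flux(ec, sol, ex) >= 0.0
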