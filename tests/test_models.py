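"""Flux-inference models: entropy program, SPOT, FBA+min-l2."""

import numpy as np
import pandas as pd
import pytest

import entroflux as ef
from entroflux.models import FEASIBILITY_RTOL

V = 1000.0


def rx_for(split, values):
    """ReactionExpression from per-gene values (toy-style g1..gN GPRs)."""
    return ef.map_expression(split, ef.ExpressionProfile(values))


class TestPheflux:
    def test_two_reaction_chain_forced_solution(self):
        """On uptake -> A -> secretion with sum(v) = V, steady state forces
        v = (V/2, V/2) regardless of expression."""
        chain = ef.chain_network(2)
        split = ef.split_reversible(chain)
        rx = rx_for(split, {"g1": 9.0, "g2": 0.5})
        sol = ef.solve_pheflux(split, rx, V_total=V)
        assert sol.ok
        np.testing.assert_allclose(sol.v.values, [V / 2, V / 2],
                                   atol=1e-4 * V)

    def test_equal_expression_keeps_exchange_open(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        sol = ef.solve_pheflux(toy_split, rx, V_total=V)
        assert sol.ok
        assert sol.net["v1"] > 1e-3 * V
        assert sol.net["v4"] > 1e-3 * V

    def test_tenfold_cycle_expression_keeps_exchange_open(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 10, "g4": 1})
        sol = ef.solve_pheflux(toy_split, rx, V_total=V)
        assert sol.ok
        assert sol.net["v1"] > 1e-3 * V
        assert sol.net["v4"] > 1e-3 * V
        # the cycle still dominates the fluxome
        assert sol.net["v2"] > sol.net["v1"]

    def test_solution_satisfies_polytope_invariants(self, toy_split):
        rx = rx_for(toy_split, {"g1": 2, "g2": 1, "g3": 5, "g4": 1})
        sol = ef.solve_pheflux(toy_split, rx, V_total=V)
        assert sol.ok
        v = sol.v.values
        assert np.abs(toy_split.S_split @ v).max() <= FEASIBILITY_RTOL * V
        assert np.all(v >= toy_split.lb_split - FEASIBILITY_RTOL * V)
        assert np.all(v <= toy_split.ub_split + FEASIBILITY_RTOL * V)
        assert abs(v.sum() - V) <= FEASIBILITY_RTOL * V

    def test_entropy_and_kl_formulations_agree(self, parallel_split):
        rx = rx_for(parallel_split,
                    {"g1": 1, "g2": 3, "g3": 2, "g4": 1, "g5": 7})
        a = ef.solve_pheflux(parallel_split, rx, V_total=V)
        b = ef.solve_pheflux_kl(parallel_split, rx, V_total=V)
        assert a.ok and b.ok
        np.testing.assert_allclose(a.v.values, b.v.values, atol=1e-4 * V)

    def test_expression_scale_invariance(self, toy_split):
        base = {"g1": 1, "g2": 2, "g3": 4, "g4": 0.5}
        sol1 = ef.solve_pheflux(
            toy_split, rx_for(toy_split, base), V_total=V)
        sol2 = ef.solve_pheflux(
            toy_split,
            rx_for(toy_split, {k: 1000.0 * x for k, x in base.items()}),
            V_total=V)
        np.testing.assert_allclose(sol1.v.values, sol2.v.values,
                                   atol=1e-4 * V)

    def test_start_independence(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 2, "g3": 4, "g4": 0.5})
        ref = ef.solve_pheflux(toy_split, rx, V_total=V)
        rng = np.random.default_rng(11)
        for _ in range(3):
            x0 = rng.uniform(0, V / 4, toy_split.n_split)
            alt = ef.solve_pheflux(toy_split, rx, V_total=V, x0=x0)
            np.testing.assert_allclose(alt.v.values, ref.v.values,
                                       atol=1e-4 * V)

    def test_proportional_point_attained_when_feasible(self):
        """If v proportional to g lies inside the polytope, the KL optimum
        is that point (divergence zero)."""
        chain = ef.chain_network(3)
        split = ef.split_reversible(chain)
        rx = rx_for(split, {"g1": 5.0, "g2": 5.0, "g3": 5.0})
        sol = ef.solve_pheflux_kl(split, rx, V_total=V)
        np.testing.assert_allclose(sol.v.values, np.full(3, V / 3),
                                   atol=1e-4 * V)
        assert ef.kl_objective(sol.v.values, rx.g) < 1e-8

    def test_infeasible_polytope_is_status_not_exception(self, toy_network):
        choked = ef.apply_medium(toy_network,
                                 {rid: (0.0, 0.0)
                                  for rid in toy_network.reaction_ids})
        split = ef.split_reversible(choked)
        rx = rx_for(split, {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        sol = ef.solve_pheflux(split, rx, V_total=V)
        assert sol.status == "infeasible"
        assert sol.v is None

    def test_objective_reported_in_nats(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        sol = ef.solve_pheflux(toy_split, rx, V_total=V)
        assert sol.objective_value == pytest.approx(
            ef.entropy_objective(sol.v.values, rx.g, V, 1e-8), rel=1e-9)

    def test_summary_smoke(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        text = ef.Pheflux(toy_split, rx).fit().summary()
        assert "pheflux" in text and "optimal" in text

    def test_accepts_raw_network_and_profile(self, toy_network):
        model = ef.Pheflux(toy_network, ef.tic_expression_preset("equal"))
        sol = model.fit()
        assert sol.ok


class TestSpot:
    def test_tenfold_cycle_kills_exchange(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 10, "g4": 1})
        sol = ef.solve_spot(toy_split, rx, V_total=V)
        assert sol.ok
        assert abs(sol.net["v1"]) < 1e-3 * V
        assert abs(sol.net["v4"]) < 1e-3 * V
        assert sol.net["v2"] > 100

    def test_equal_expression_keeps_exchange_open(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 1, "g3": 1, "g4": 1})
        sol = ef.solve_spot(toy_split, rx, V_total=V)
        assert sol.net["v1"] > 1e-3 * V
        assert sol.net["v4"] > 1e-3 * V

    def test_chain_closed_form(self):
        """On a 2-reaction chain the feasible ray is v = t(1,1); the norm
        constraint binds at t = 1/sqrt(2), and rescaling restores sum = V."""
        chain = ef.chain_network(2)
        split = ef.split_reversible(chain)
        rx = rx_for(split, {"g1": 3.0, "g2": 1.0})
        sol = ef.solve_spot(split, rx, V_total=V)
        np.testing.assert_allclose(sol.v.values, [V / 2, V / 2],
                                   atol=1e-3 * V)
        # unnormalized objective at the unit-ball optimum: g . v/||v||
        expected = np.dot(rx.g, [1, 1]) / np.sqrt(2.0)
        assert sol.objective_value == pytest.approx(expected, rel=1e-4)

    def test_spot_objective_dominates_pheflux_point(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 2, "g3": 5, "g4": 1})
        spot = ef.solve_spot(toy_split, rx, V_total=V)
        ph = ef.solve_pheflux(toy_split, rx, V_total=V)

        def unit_ball_objective(sol):
            v = sol.v.values
            return float(rx.g @ v) / np.linalg.norm(v)

        assert unit_ball_objective(spot) >= unit_ball_objective(ph) - 1e-6


class TestFBAMinL2:
    @pytest.fixture
    def fba_toy(self, toy_network):
        net = ef.apply_medium(toy_network, {"v1": (0.0, 10.0)})
        net.biomass_reaction = "v4"
        return net

    def test_biomass_at_lp_optimum_and_cycle_removed(self, fba_toy):
        sol = ef.solve_fba_min_l2(fba_toy)
        assert sol.ok
        assert sol.diagnostics["biomass_flux"] == pytest.approx(10.0)
        np.testing.assert_allclose(sol.net.values, [10, 10, 0, 10],
                                   atol=1e-6)

    def test_zero_biomass_optimum_gives_zero_flux(self, toy_network):
        net = ef.apply_medium(toy_network, {"v1": (0.0, 0.0),
                                            "v4": (0.0, 0.0)})
        net.biomass_reaction = "v4"
        sol = ef.solve_fba_min_l2(net)
        np.testing.assert_allclose(sol.net.values, 0.0, atol=1e-6)

    def test_branched_network_matches_kkt_oracle(self):
        """Two parallel routes A -> B; min-l2 splits flux equally (KKT of
        min v2^2 + v3^2 s.t. v2 + v3 = 10)."""
        S = np.array([
            [1., -1., -1., 0.],
            [0., 1., 1., -1.],
        ])
        net = ef.MetabolicNetwork(
            metabolite_ids=["A", "B"],
            reaction_ids=["up", "path1", "path2", "bio"],
            S=S,
            lower_bound=np.zeros(4),
            upper_bound=np.array([10., 1000., 1000., 1000.]),
            biomass_reaction="bio",
        )
        sol = ef.solve_fba_min_l2(net)
        np.testing.assert_allclose(sol.net.values, [10, 5, 5, 10],
                                   atol=1e-5)

    def test_unbounded_biomass_raises(self):
        S = np.array([[1., -1.]])
        net = ef.MetabolicNetwork(
            metabolite_ids=["A"], reaction_ids=["up", "bio"], S=S,
            lower_bound=np.zeros(2),
            upper_bound=np.array([np.inf, np.inf]),
            biomass_reaction="bio",
        )
        with pytest.raises(ef.UnboundedProblemError):
            ef.solve_fba_min_l2(net)

    def test_missing_biomass_raises(self, toy_network):
        with pytest.raises(ef.ValidationError):
            ef.FBAMinL2(toy_network)

    def test_expression_never_read(self, fba_toy):
        a = ef.solve_fba_min_l2(fba_toy)
        b = ef.solve_fba_min_l2(fba_toy)
        pd.testing.assert_series_equal(a.net, b.net)


class TestFluxTable:
    def test_to_frame_columns_and_expression(self, toy_split):
        rx = rx_for(toy_split, {"g1": 1, "g2": 2, "g3": 4, "g4": 8})
        table = ef.solve_pheflux(toy_split, rx).to_frame()
        assert list(table.columns) == [
            "reaction_id", "net_flux", "forward_flux", "reverse_flux",
            "expression_g", "imputed"]
        assert table.loc[table.reaction_id == "v3",
                         "expression_g"].item() == 4.0
        assert not table["imputed"].any()
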