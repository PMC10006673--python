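"""Polytope sampling, synthetic transcriptomes and the lambda sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import entroflux as ef


class TestSampleFluxomes:
    def test_deterministic_given_seed(self, toy_network):
        a = ef.sample_fluxomes(toy_network, 10, thinning=10, seed=5)
        b = ef.sample_fluxomes(toy_network, 10, thinning=10, seed=5)
        assert (a.values == b.values).all()

    def test_different_seed_differs(self, toy_network):
        a = ef.sample_fluxomes(toy_network, 10, thinning=10, seed=5)
        b = ef.sample_fluxomes(toy_network, 10, thinning=10, seed=6)
        assert not (a.values == b.values).all()

    def test_samples_satisfy_steady_state_and_bounds(self, toy_network):
        samples = ef.sample_fluxomes(toy_network, 50, thinning=10, seed=1)
        resid = np.abs(toy_network.S @ samples.values.T)
        assert resid.max() < 1e-6
        assert (samples.values >= toy_network.lower_bound - 1e-9).all()
        assert (samples.values <= toy_network.upper_bound + 1e-9).all()

    def test_n_zero_gives_empty_frame(self, toy_network):
        out = ef.sample_fluxomes(toy_network, 0, seed=1)
        assert len(out) == 0
        assert list(out.columns) == toy_network.reaction_ids

    def test_chain_marginal_uniform(self):
        """On a chain the polytope is the segment v1=v2 in [0, ub]; the
        marginal of v1 is exactly uniform (KS test)."""
        chain = ef.chain_network(2)
        samples = ef.sample_fluxomes(chain, 400, thinning=50, seed=3)
        u = samples["v1"].to_numpy() / chain.upper_bound[0]
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_toy_triangle_marginal_mean(self, toy_network):
        """Eliminating steady state leaves the triangle
        {v1, v3 >= 0, v1 + v3 <= 1000}; the v1 marginal is triangular with
        mean 1000/3."""
        samples = ef.sample_fluxomes(toy_network, 600, thinning=50, seed=9)
        mean = samples["v1"].mean()
        se = samples["v1"].std() / np.sqrt(len(samples))
        assert abs(mean - 1000.0 / 3) < 6 * se + 20

    def test_unbounded_polytope_rejected(self):
        net = ef.MetabolicNetwork(
            metabolite_ids=["A"], reaction_ids=["r1", "r2"],
            S=np.array([[1.0, -1.0]]),
            lower_bound=np.zeros(2),
            upper_bound=np.array([np.inf, np.inf]),
        )
        with pytest.raises(ef.UnboundedProblemError):
            ef.sample_fluxomes(net, 5)


@pytest.fixture(scope="module")
def reference(flow_network):
    return ef.sample_fluxomes(flow_network, 1, thinning=20, seed=2).iloc[0]


@pytest.fixture(scope="module")
def sweep(flow_network):
    return ef.run_lambda_sweep(flow_network, [0.0, 0.5, 1.0], 4,
                               methods=["pheflux", "fba_min_l2"],
                               seed=7, thinning=20)


class TestGenerateExpression:
    def test_lambda_one_perfect_correlation(self, flow_network, reference):
        prof = ef.generate_expression(reference, flow_network, 1.0, seed=0)
        g = np.array([prof.values[f"G_{rid}"]
                      for rid in flow_network.reaction_ids])
        r = stats.pearsonr(g, reference.abs().to_numpy()).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_lambda_zero_random_everywhere(self, flow_network, reference):
        prof = ef.generate_expression(reference, flow_network, 0.0, seed=0)
        g = np.array([prof.values[f"G_{rid}"]
                      for rid in flow_network.reaction_ids])
        assert not np.allclose(np.corrcoef(
            g, reference.abs().to_numpy())[0, 1], 1.0)

    def test_correlated_count_rounds(self, flow_network, reference):
        n = flow_network.n_reactions
        bench = ef.make_benchmark(flow_network, 0.5, 1, seed=0,
                                  samples=reference.to_frame().T)
        assert len(bench.correlated_set) == round(0.5 * n)

    def test_lambda_out_of_range_rejected(self, flow_network, reference):
        with pytest.raises(ValueError):
            ef.generate_expression(reference, flow_network, 1.5)

    def test_deterministic_given_seed(self, flow_network, reference):
        a = ef.generate_expression(reference, flow_network, 0.4, seed=11)
        b = ef.generate_expression(reference, flow_network, 0.4, seed=11)
        assert a.values == b.values


class TestScorePrediction:
    def test_identity_scores_one(self):
        ref = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert ef.score_prediction(ref, ref) == pytest.approx(1.0)

    def test_sign_flip_scores_minus_one(self):
        ref = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert ef.score_prediction(-ref, ref) == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        ref = pd.Series([2.0, 4.0, 6.0, 9.0], index=list("abcd"))
        pred = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        x, y = pred.to_numpy(), ref.to_numpy()
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert ef.score_prediction(pred, ref) == pytest.approx(
            expected, rel=1e-12)

    def test_constant_vector_undefined(self):
        ref = pd.Series([1.0, 1.0], index=["a", "b"])
        pred = pd.Series([1.0, 2.0], index=["a", "b"])
        assert np.isnan(ef.score_prediction(pred, ref))

    def test_empty_subset_rejected(self):
        ref = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ef.score_prediction(ref, ref, subset=[])


class TestFixtures:
    def test_toy_dimensions(self, toy_network):
        assert toy_network.n_metabolites == 2
        assert toy_network.n_reactions == 4

    def test_presets_ratios(self):
        equal = ef.tic_expression_preset("equal").values
        double = ef.tic_expression_preset("g3_double").values
        tenfold = ef.tic_expression_preset("g3_tenfold").values
        assert len(set(equal.values())) == 1
        assert double["g3"] / double["g1"] == 2.0
        assert tenfold["g3"] / tenfold["g1"] == 10.0

    def test_core_set_from_subsystems(self, flow_network):
        core = ef.core_reaction_set(flow_network)
        assert core
        subs = dict(zip(flow_network.reaction_ids, flow_network.subsystems))
        assert all(subs[rid] in ("Glycolysis", "Citric acid cycle")
                   for rid in core)

    def test_flow_network_size_in_range(self, flow_network):
        assert 30 <= flow_network.n_reactions <= 60
        assert all(rule.startswith("G_")
                   for rule in flow_network.gpr_rules)


class TestLambdaSweep:
    def test_row_count(self, sweep):
        # 3 lambdas x 2 methods x 2 scales
        assert len(sweep) == 12

    def test_fba_rows_identical_across_lambda(self, sweep):
        fba = sweep[sweep.method == "fba_min_l2"]
        for scale in ("core", "genome"):
            vals = fba[fba.scale == scale]["mean_r"].to_numpy()
            assert np.allclose(vals, vals[0], equal_nan=True)

    def test_pheflux_improves_with_lambda(self, sweep):
        ph = sweep.query("method == 'pheflux' and scale == 'genome'")
        ph = ph.sort_values("lambda")
        assert ph["mean_r"].iloc[-1] > ph["mean_r"].iloc[0]

    def test_seed_determinism(self, flow_network, sweep):
        again = ef.run_lambda_sweep(flow_network, [0.0, 0.5, 1.0], 4,
                                    methods=["pheflux", "fba_min_l2"],
                                    seed=7, thinning=20)
        pd.testing.assert_frame_equal(sweep, again)

    def test_unknown_method_rejected(self, flow_network):
        with pytest.raises(ValueError):
            ef.run_lambda_sweep(flow_network, [0.0], 2,
                                methods=["made_up"], seed=0)
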