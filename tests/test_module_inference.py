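"""RNN dynamics, RMSE objective, PSO fitting and the GA cluster search."""

import math

import numpy as np
import pytest

from trnmotif.clustering import ClusterSet
from trnmotif.data_io import InteractionNetwork
from trnmotif.module_inference import (GAConfig, MotifTopology, OptimConfig,
                                       PSOConfig, RNNParams, _Compiled,
                                       ga_search, pso_fit, rmse, rnn_simulate,
                                       topology_from_instance)

SINGLE = MotifTopology(tf_roles=("TF",), cluster_roles=("C1",),
                       edges=(("TF", "C1", "pdi"),))


def _quick(iters=150, swarm=24, stop=0.0):
    return OptimConfig(ga=GAConfig(population=24, generations=40),
                       pso=PSOConfig(swarm=swarm, iterations=iters),
                       rmse_stop=stop)


class TestTopology:
    def test_requires_tf_and_cluster_roles(self):
        with pytest.raises(ValueError):
            MotifTopology(tf_roles=(), cluster_roles=("C1",), edges=())

    def test_requires_connectivity(self):
        with pytest.raises(ValueError, match="connected"):
            MotifTopology(tf_roles=("TF",), cluster_roles=("C1", "C2"),
                          edges=(("TF", "C1", "pdi"),))

    def test_param_edges_exclude_tf_to_tf(self):
        top = MotifTopology(tf_roles=("TF", "TF2"), cluster_roles=("C1",),
                            edges=(("TF", "TF2", "ppi"), ("TF", "C1", "pdi"),
                                   ("TF2", "C1", "pdi")))
        assert ("TF", "TF2", "ppi") not in top.param_edges
        assert len(top.param_edges) == 2

    def test_from_instance_roles_and_edges(self):
        net = InteractionNetwork({"t", "p", "g"}, {("g", "p")},
                                 {("t", "g"), ("t", "p")})
        top, role_genes = topology_from_instance(
            net, ("g", "p", "t"), focal="t", tf_genes={"t"},
            profile_genes={"t", "p", "g"})
        assert top.tf_roles == ("TF",)
        assert sorted(top.cluster_roles) == ["C1", "C2"]
        assert role_genes["TF"] == "t"
        kinds = sorted(k for _, _, k in top.edges)
        assert kinds == ["pdi", "pdi", "ppi"]


class TestSimulate:
    def test_zero_parameters_give_zero_trajectory(self):
        params = RNNParams(w={("TF", "C1", "pdi"): 0.0}, beta={"C1": 0.0},
                           tau={"C1": 1.0})
        out = rnn_simulate(SINGLE, params, {"TF": np.ones(10)})
        assert np.allclose(out["C1"], 0.0)

    def test_clamped_regulator_closed_form(self):
        # w=2, beta=0, tau=dt -> x(t) = tanh(2) for every t >= 2
        params = RNNParams(w={("TF", "C1", "pdi"): 2.0}, beta={"C1": 0.0},
                           tau={"C1": 1.0})
        out = rnn_simulate(SINGLE, params, {"TF": np.ones(8)})
        assert out["C1"][0] == 0.0
        assert np.allclose(out["C1"][1:], math.tanh(2.0))

    def test_matches_hand_iteration_of_update_rule(self):
        rng = np.random.default_rng(0)
        top = MotifTopology(tf_roles=("TF",), cluster_roles=("C1", "C2"),
                            edges=(("TF", "C1", "pdi"), ("C1", "C2", "pdi"),
                                   ("TF", "C2", "pdi")))
        w = {e: float(rng.normal()) for e in top.param_edges}
        beta = {r: float(rng.normal()) for r in ("C1", "C2")}
        tau = {"C1": 2.0, "C2": 2.0}  # dt/tau = 0.5
        params = RNNParams(w=w, beta=beta, tau=tau)
        reg = rng.normal(size=6)
        out = rnn_simulate(top, params, {"TF": reg},
                           x0={"C1": 0.1, "C2": -0.2})
        x1, x2 = 0.1, -0.2
        for t in range(5):
            n1 = 0.5 * math.tanh(w[("TF", "C1", "pdi")] * reg[t]
                                 + beta["C1"]) + 0.5 * x1
            n2 = 0.5 * math.tanh(w[("C1", "C2", "pdi")] * x1
                                 + w[("TF", "C2", "pdi")] * reg[t]
                                 + beta["C2"]) + 0.5 * x2
            x1, x2 = n1, n2
            assert out["C1"][t + 1] == pytest.approx(x1)
            assert out["C2"][t + 1] == pytest.approx(x2)

    def test_bounded_given_bounded_initial_state(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            params = RNNParams(w={("TF", "C1", "pdi"): float(rng.uniform(-5, 5))},
                               beta={"C1": float(rng.uniform(-5, 5))},
                               tau={"C1": float(rng.uniform(1, 10))})
            out = rnn_simulate(SINGLE, params,
                               {"TF": rng.uniform(-1, 1, size=30)},
                               x0={"C1": float(rng.uniform(-1, 1))})
            assert np.all(np.abs(out["C1"]) <= 1.0 + 1e-12)

    def test_batch_simulation_matches_single(self):
        rng = np.random.default_rng(2)
        comp = _Compiled(SINGLE)
        thetas = rng.uniform(-2, 2, size=(7, comp.n_params))
        thetas[:, -1] = rng.uniform(1, 5, size=7)  # tau
        regs = rng.uniform(-1, 1, size=(1, 12))
        batch = comp.simulate(thetas, regs, np.zeros(1))
        for i in range(7):
            single = comp.simulate(thetas[i:i + 1], regs, np.zeros(1))
            np.testing.assert_allclose(batch[i], single[0])

    def test_non_finite_parameter_rejected(self):
        with pytest.raises(ValueError):
            RNNParams(w={("TF", "C1", "pdi"): float("nan")},
                      beta={"C1": 0.0}, tau={"C1": 1.0})


class TestRMSE:
    def test_identity_and_constant_offset(self):
        x = np.random.default_rng(0).normal(size=(2, 10))
        assert rmse(x, x) == 0.0
        assert rmse(x + 0.1, x) == pytest.approx(0.1)

    def test_first_time_point_excluded(self):
        a = np.zeros((1, 5))
        b = np.zeros((1, 5))
        b[0, 0] = 100.0  # initial condition differs; ignored
        assert rmse(a, b) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        p, o = rng.normal(size=(2, 10)), rng.normal(size=(2, 10))
        expected = math.sqrt(np.mean((p[:, 1:] - o[:, 1:]) ** 2))
        assert rmse(p, o) == pytest.approx(expected)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((1, 5)), np.zeros((1, 6)))


class TestPSO:
    def test_zero_target_solved_quickly(self):
        T = 12
        res = pso_fit(SINGLE, {"TF": np.zeros(T)}, {"C1": np.zeros(T)},
                      _quick(iters=50), seed=0)
        assert res.rmse <= 1e-2

    def test_trace_monotone_for_any_seed(self):
        rng = np.random.default_rng(5)
        tgt = rng.uniform(-1, 1, size=20)
        for seed in range(5):
            res = pso_fit(SINGLE, {"TF": np.sin(np.arange(20))},
                          {"C1": tgt}, _quick(iters=60), seed=seed)
            assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))

    def test_noiseless_self_consistency_most_seeds(self):
        """Parameters generating the data are recovered to low RMSE in at
        least 8 of 10 seeds (PSO may occasionally stall in a local optimum)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            T = 47
            reg = np.sin(2 * np.pi * np.arange(T) / 23.5
                         + rng.uniform(0, 2 * np.pi))
            params = RNNParams(
                w={("TF", "C1", "pdi"): float(rng.choice([-1, 1])
                                              * rng.uniform(1.8, 2.8))},
                beta={"C1": float(rng.uniform(-0.25, 0.25))},
                tau={"C1": float(rng.uniform(1, 2))})
            target = rnn_simulate(SINGLE, params, {"TF": reg})["C1"]
            res = pso_fit(SINGLE, {"TF": reg}, {"C1": target},
                          _quick(iters=400, swarm=30), seed=seed)
            hits += res.rmse <= 0.02
        assert hits >= 8

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        tgt = rng.uniform(-1, 1, size=15)
        r1 = pso_fit(SINGLE, {"TF": np.cos(np.arange(15))}, {"C1": tgt},
                     _quick(iters=40), seed=11)
        r2 = pso_fit(SINGLE, {"TF": np.cos(np.arange(15))}, {"C1": tgt},
                     _quick(iters=40), seed=11)
        assert r1.rmse == r2.rmse
        assert r1.params.w == r2.params.w


def _decoy_clusters(rng, traj, n_decoys=10):
    from scipy.ndimage import gaussian_filter1d
    profiles = {0: traj}
    for d in range(1, n_decoys + 1):
        x = gaussian_filter1d(rng.normal(size=traj.size), 2.0)
        profiles[d] = 2 * (x - x.min()) / (x.max() - x.min()) - 1
    labels = {f"g{i}": i for i in profiles}
    return ClusterSet(labels, profiles)


class TestGASearch:
    def test_single_candidate_returned_in_one_generation(self):
        T = 15
        rng = np.random.default_rng(0)
        cs = ClusterSet({"g0": 0}, {0: rng.uniform(-1, 1, size=T)})
        res = ga_search("tf", SINGLE, cs, {"tf": np.sin(np.arange(T))},
                        _quick(iters=40), seed=0)
        assert len(res.ranked) == 1
        assert len(res.trace) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_cluster_ranked_first_among_decoys(self, seed):
        rng = np.random.default_rng(300 + seed)
        T = 47
        reg = np.sin(2 * np.pi * np.arange(T) / 23.5
                     + rng.uniform(0, 2 * np.pi))
        params = RNNParams(
            w={("TF", "C1", "pdi"): float(rng.choice([-1, 1])
                                          * rng.uniform(1.8, 2.8))},
            beta={"C1": float(rng.uniform(-0.25, 0.25))},
            tau={"C1": float(rng.uniform(1, 2))})
        traj = rnn_simulate(SINGLE, params, {"TF": reg})["C1"]
        cs = _decoy_clusters(rng, traj)
        res = ga_search("tf", SINGLE, cs, {"tf": reg}, _quick(), seed=seed)
        assert res.ranked[0].cluster_map["C1"] == 0

    def test_trace_non_increasing(self):
        rng = np.random.default_rng(7)
        T = 20
        reg = np.sin(np.arange(T))
        traj = np.tanh(1.5 * reg)
        cs = _decoy_clusters(rng, traj, n_decoys=30)
        cfg = OptimConfig(ga=GAConfig(population=8, generations=6),
                          pso=PSOConfig(swarm=10, iterations=30),
                          rmse_stop=0.0)
        res = ga_search("tf", SINGLE, cs, {"tf": reg}, cfg, seed=1)
        assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))

    def test_two_cluster_roles_must_differ(self):
        top = MotifTopology(tf_roles=("TF",), cluster_roles=("C1", "C2"),
                            edges=(("TF", "C1", "pdi"), ("TF", "C2", "pdi"),
                                   ("C1", "C2", "ppi")))
        rng = np.random.default_rng(8)
        cs = _decoy_clusters(rng, np.sin(np.arange(20)), n_decoys=3)
        res = ga_search("tf", top, cs, {"tf": np.cos(np.arange(20))},
                        _quick(iters=30), seed=0)
        for trnm in res.ranked:
            assert trnm.cluster_map["C1"] != trnm.cluster_map["C2"]

    def test_more_cluster_roles_than_clusters_is_error(self):
        top = MotifTopology(tf_roles=("TF",), cluster_roles=("C1", "C2"),
                            edges=(("TF", "C1", "pdi"), ("TF", "C2", "pdi"),
                                   ("C1", "C2", "ppi")))
        cs = ClusterSet({"g0": 0}, {0: np.zeros(10)})
        with pytest.raises(ValueError):
            ga_search("tf", top, cs, {"tf": np.zeros(10)}, _quick(), seed=0)
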