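import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from neqcycle import (
    AffinityNetwork,
    Edge,
    compare_stats,
    kT,
    ki_to_dG,
    mle_absolute,
    p2y1_bptu_benchmark,
    sample_network,
    sign_concordance,
)

RT = kT(298.15)


class TestKiConversion:
    def test_one_molar_is_zero(self):
        assert ki_to_dG(1.0) == 0.0

    def test_e_inverse_molar_gives_rt(self):
        assert ki_to_dG(math.exp(-1)) == pytest.approx(RT, abs=1e-12)
        assert ki_to_dG(math.exp(-1)) == pytest.approx(0.59248, abs=1e-5)

    def test_nonpositive_ki_rejected(self):
        for ki in (0.0, -1e-9):
            with pytest.raises(ValueError):
                ki_to_dG(ki)

    def test_pairwise_differences_equal_in_magnitude_across_conventions(self):
        ki_a, ki_b = 3e-9, 8e-8
        dd_printed = ki_to_dG(ki_b) - ki_to_dG(ki_a)
        dd_binding = (ki_to_dG(ki_b, convention="binding")
                      - ki_to_dG(ki_a, convention="binding"))
        assert abs(dd_printed) == pytest.approx(abs(dd_binding), abs=1e-12)


def _oracle_mle(nodes, edges, errs):
    """Independent solve: parametrize all nodes, fix the mean to zero."""
    idx = {n: i for i, n in enumerate(nodes)}

    def resid(x):
        r = [(x[idx[b]] - x[idx[a]] - d) / e for (a, b, d), e in zip(edges, errs)]
        r.append(x.sum() * 1e6)  # enforce mean-zero gauge strongly
        return np.array(r)

    sol = least_squares(resid, np.zeros(len(nodes)), method="lm", xtol=1e-15)
    return dict(zip(nodes, sol.x - sol.x.mean()))


class TestMle:
    def test_star_graph_path_sums_then_mean_centered(self):
        net = AffinityNetwork.from_edges(
            [Edge("h", "a", -2.0, 0.3), Edge("h", "b", 1.0, 0.3)])
        est = mle_absolute(net)
        assert est.values["h"] == pytest.approx(1 / 3, abs=1e-9)
        assert est.values["a"] == pytest.approx(-5 / 3, abs=1e-9)
        assert est.values["b"] == pytest.approx(4 / 3, abs=1e-9)

    def test_consistent_triangle_recovered_exactly(self):
        net = AffinityNetwork.from_edges(
            [Edge("a", "b", 1.0, 0.2), Edge("b", "c", 1.0, 0.2),
             Edge("a", "c", 2.0, 0.2)])
        est = mle_absolute(net)
        truth = {"a": 0.0, "b": 1.0, "c": 2.0}
        shift = np.mean(list(truth.values()))
        for n, t in truth.items():
            assert est.values[n] == pytest.approx(t - shift, abs=1e-9)

    def test_inconsistent_triangle_matches_normal_equation_oracle(self):
        edges = [("a", "b", 1.3), ("b", "c", 0.4), ("a", "c", 2.5)]
        errs = [0.2, 0.7, 0.4]
        net = AffinityNetwork.from_edges(
            [Edge(a, b, d, e) for (a, b, d), e in zip(edges, errs)])
        est = mle_absolute(net)
        oracle = _oracle_mle(["a", "b", "c"], edges, errs)
        for n in oracle:
            assert est.values[n] == pytest.approx(oracle[n], abs=1e-8)

    def test_random_graphs_match_oracle(self, rng):
        for trial in range(5):
            n = int(rng.integers(4, 7))
            nodes = [f"n{i}" for i in range(n)]
            edges, errs = [], []
            for i in range(1, n):  # spanning tree + extra cycles
                j = int(rng.integers(0, i))
                edges.append((nodes[j], nodes[i], float(rng.normal(0, 2))))
                errs.append(float(rng.uniform(0.1, 0.8)))
            for _ in range(2):
                i, j = rng.choice(n, 2, replace=False)
                edges.append((nodes[i], nodes[j], float(rng.normal(0, 2))))
                errs.append(float(rng.uniform(0.1, 0.8)))
            net = AffinityNetwork.from_edges(
                [Edge(a, b, d, e) for (a, b, d), e in zip(edges, errs)])
            est = mle_absolute(net)
            oracle = _oracle_mle(nodes, edges, errs)
            for nd in nodes:
                assert est.values[nd] == pytest.approx(oracle[nd], abs=1e-7)

    def test_tree_equals_path_summation(self):
        net, truth = sample_network(8, topology="random_tree",
                                    edge_noise_sd=0.0, seed=5)
        est = mle_absolute(net)
        centered = {k: v - np.mean(list(truth.values())) for k, v in truth.items()}
        for n in truth:
            assert est.values[n] == pytest.approx(centered[n], abs=1e-6)

    def test_gauge_invariance_of_experimental_anchors(self):
        net, truth = sample_network(6, topology="star", edge_noise_sd=0.2, seed=9)
        exp = {k: v for k, v in list(truth.items())[:4]}
        base = mle_absolute(AffinityNetwork(net.nodes, net.edges, exp))
        shifted = mle_absolute(AffinityNetwork(
            net.nodes, net.edges, {k: v + 5.0 for k, v in exp.items()}))
        for n in net.nodes:
            assert shifted.values[n] == pytest.approx(base.values[n] + 5.0, abs=1e-9)

    def test_disconnected_components_anchored_independently(self):
        edges = [Edge("a", "b", 1.0, 0.2), Edge("c", "d", -1.0, 0.2)]
        net = AffinityNetwork.from_edges(edges, {"a": -8.0, "b": -7.0})
        est = mle_absolute(net)
        assert est.component["a"] == est.component["b"]
        assert est.component["c"] != est.component["a"]
        # anchored component matches its experimental mean
        assert np.mean([est.values["a"], est.values["b"]]) == pytest.approx(-7.5)
        # unanchored component stays mean-zero
        assert est.values["c"] + est.values["d"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_errors_replaced_by_minimum_positive(self, caplog):
        net = AffinityNetwork.from_edges(
            [Edge("a", "b", 1.0, 0.0), Edge("b", "c", 1.0, 0.5)])
        est = mle_absolute(net)  # must not produce infinite weight
        assert all(np.isfinite(v) for v in est.values.values())

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mle_absolute(AffinityNetwork(("a",), (), {}))

    def test_weighted_residual_never_increases_when_err_grows(self, rng):
        def residual(net, est):
            return sum(((est.values[e.ligand_to] - est.values[e.ligand_from]
                         - e.ddG) / e.err) ** 2 for e in net.edges)

        for trial in range(3):
            net, _ = sample_network(5, topology="cyclic",
                                    edge_noise_sd=0.5, seed=trial)
            base = residual(net, mle_absolute(net))
            bigger = list(net.edges)
            e0 = bigger[0]
            bigger[0] = Edge(e0.ligand_from, e0.ligand_to, e0.ddG, e0.err * 3)
            net2 = AffinityNetwork(net.nodes, tuple(bigger), {})
            assert residual(net2, mle_absolute(net2)) <= base + 1e-9


class TestCompareStats:
    def test_identity_pairs(self):
        v = [1.0, 2.0, 3.5, -1.0]
        s = compare_stats(v, v, n_bootstrap=50)
        assert s["rmsd"] == 0 and s["mue"] == 0
        assert s["r2"] == pytest.approx(1.0) and s["tau"] == pytest.approx(1.0)

    def test_anti_monotone_pairs(self):
        s = compare_stats([1, 2, 3, 4], [8, 6, 4, 2], n_bootstrap=50)
        assert s["tau"] == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_stats([1, 2], [1, 2, 3])

    def test_pair_order_invariance_and_rmsd_dominates_mue(self, rng):
        p = rng.normal(0, 2, 15)
        r = p + rng.normal(0, 1, 15)
        s1 = compare_stats(p, r, n_bootstrap=0)
        perm = rng.permutation(15)
        s2 = compare_stats(p[perm], r[perm], n_bootstrap=0)
        for k in ("rmsd", "mue", "r2", "tau"):
            assert s1[k] == pytest.approx(s2[k], abs=1e-12)
        assert s1["rmsd"] >= s1["mue"]

    def test_benchmark_agreement_with_equilibrium_fep_values(self):
        df = p2y1_bptu_benchmark()
        s = compare_stats(df.ddG_obs_D, df.ddG_obs, n_bootstrap=200)
        assert round(s["r2"], 2) == 0.57

    def test_bootstrap_cis_bracket_point_estimates(self):
        df = p2y1_bptu_benchmark()
        s = compare_stats(df.ddG_obs_D, df.ddG_obs, n_bootstrap=500, seed=4)
        lo, hi = s["ci95"]["rmsd"]
        assert lo <= s["rmsd"] <= hi


class TestSignConcordance:
    def test_benchmark_6a_group(self):
        df = p2y1_bptu_benchmark()
        sub = df[df.group == "6a"]
        frac = sign_concordance(list(zip(sub.ddG_obs, sub.ddG_exp)))
        assert frac == pytest.approx(0.875, abs=1e-12)

    def test_all_matched(self):
        assert sign_concordance([(1.0, 2.0), (-1.0, -0.5)]) == 1.0

    def test_infinite_zero_band_is_degenerate(self):
        assert sign_concordance([(1.0, -5.0), (-1.0, 5.0)],
                                zero_band=np.inf) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_concordance([])
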