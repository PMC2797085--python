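import numpy as np
import pytest

from conftest import random_network
from prince.netio import AssociationTable, DiseaseSimilarityMatrix, WeightedNetwork
from prince.propagation import (
    CipherUndefinedError,
    cipher_dn,
    cipher_dn_scores,
    normalize,
    propagate_exact,
    propagate_iterative,
    random_walk_restart,
    smoothness_objective,
)


class TestNormalize:
    def test_single_edge_normalizes_to_one(self):
        for w in (0.1, 0.5, 1.0):
            net = WeightedNetwork({("a", "b"): w})
            Wn = normalize(net).Wn.toarray()
            assert Wn[0, 1] == pytest.approx(1.0)

    def test_path_degrees(self, path_abc):
        Wn = normalize(path_abc).Wn.toarray()
        i = path_abc.index
        assert Wn[i["a"], i["b"]] == pytest.approx(1 / np.sqrt(2))
        assert Wn[i["b"], i["c"]] == pytest.approx(1 / np.sqrt(2))

    def test_uniform_weight_scaling_invariance(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 30)
        scaled = WeightedNetwork({(u, v): w * 0.1 for u, v, w in net.edges()})
        a = normalize(net).Wn.toarray()
        b = normalize(scaled).Wn.toarray()
        assert np.allclose(a, b, atol=1e-12)

    def test_spectrum_within_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            net = random_network(rng, 30, 0.2)
            eig = np.linalg.eigvalsh(normalize(net).Wn.toarray())
            assert np.all(np.abs(eig) <= 1 + 1e-9)


class TestPropagate:
    def test_exact_two_node_closed_form(self, pair):
        F = propagate_exact(normalize(pair), np.array([1.0, 0.0]), alpha=0.5).scores
        assert F == pytest.approx([2 / 3, 1 / 3])

    def test_alpha_zero_returns_prior(self, triangle):
        y = np.array([0.3, 0.0, 0.7])
        for fn in (propagate_exact, propagate_iterative):
            assert np.array_equal(fn(normalize(triangle), y, alpha=0.0).scores, y)

    def test_zero_prior_gives_zero_scores(self, triangle):
        norm = normalize(triangle)
        assert np.all(propagate_iterative(norm, np.zeros(3), 0.9).scores == 0.0)
        assert np.all(propagate_exact(norm, np.zeros(3), 0.9).scores == 0.0)

    def test_high_alpha_spreads_to_all_nodes(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 25, 0.15)
        y = np.zeros(net.n)
        y[0] = 1.0
        F = propagate_exact(normalize(net), y, alpha=0.999).scores
        assert np.all(F > 0)

    def test_invalid_alpha_rejected(self, triangle):
        for alpha in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                propagate_exact(normalize(triangle), np.zeros(3), alpha)

    def test_iterative_matches_exact(self):
        rng = np.random.default_rng(6)
        for alpha in (0.5, 0.75, 0.9):
            net = random_network(rng, 50, 0.1)
            y = rng.random(net.n) * (rng.random(net.n) < 0.1)
            norm = normalize(net)
            ex = propagate_exact(norm, y, alpha).scores
            it = propagate_iterative(norm, y, alpha, max_iter=5000, tol=1e-13).scores
            assert np.max(np.abs(ex - it)) < 1e-8

    def test_residual_decays_geometrically(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 40, 0.15)
        norm = normalize(net)
        y = rng.random(net.n)
        alpha = 0.8
        residuals = []
        F = y.copy()
        for _ in range(30):
            F_new = alpha * (norm.Wn @ F) + (1 - alpha) * y
            residuals.append(np.max(np.abs(F_new - F)))
            F = F_new
        ratios = np.array(residuals[1:]) / np.array(residuals[:-1])
        assert np.all(ratios <= alpha + 1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, 20, 0.3)
        renamed = WeightedNetwork({(f"z{u}", f"z{v}"): w for u, v, w in net.edges()})
        y = rng.random(net.n)
        F1 = propagate_exact(normalize(net), y, 0.9).scores
        y2 = np.empty(net.n)
        for p in net.proteins:
            y2[renamed.index[f"z{p}"]] = y[net.index[p]]
        F2 = propagate_exact(normalize(renamed), y2, 0.9).scores
        for p in net.proteins:
            assert F2[renamed.index[f"z{p}"]] == pytest.approx(F1[net.index[p]], abs=1e-12)

    def test_fixed_point_smoother_than_prior(self):
        rng = np.random.default_rng(9)
        net = random_network(rng, 40, 0.15)
        norm = normalize(net)
        y = rng.random(net.n) * (rng.random(net.n) < 0.2)
        alpha = 0.9
        F = propagate_exact(norm, y, alpha).scores
        assert smoothness_objective(norm, F, y, alpha) <= smoothness_objective(norm, y, y, alpha) + 1e-12

    def test_ten_iterations_recover_exact_ranking(self):
        """Ranking stabilizes after ~10 sweeps on planted benchmarks."""
        from prince.prior import build_prior
        from prince.synthetic import gen_disease_world, gen_network

        rng = np.random.default_rng(10)
        agree = 0
        trials = 20
        for _ in range(trials):
            net, mods = gen_network(100, 4, 6, 1.0, 0.02, seed=int(rng.integers(2**31)))
            sims, assoc, _ = gen_disease_world(net, mods, 3, 3, 2, seed=int(rng.integers(2**31)))
            prior = build_prior(sims.diseases[0], assoc, sims, net)
            norm = normalize(net)
            ex = propagate_exact(norm, prior, 0.9).scores
            it = propagate_iterative(norm, prior, 0.9, max_iter=10, tol=0.0).scores
            agree += set(np.argsort(-ex)[:5]) == set(np.argsort(-it)[:5])
        assert agree / trials >= 0.95


class TestRandomWalkRestart:
    def test_two_node_closed_form(self, pair):
        p = random_walk_restart(pair, np.array([1.0, 0.0]), restart=0.5).scores
        assert p == pytest.approx([2 / 3, 1 / 3])

    def test_probability_mass_conserved(self):
        rng = np.random.default_rng(11)
        net = random_network(rng, 30, 0.2)
        y = rng.random(net.n)
        p = random_walk_restart(net, y, 0.3).scores
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_restart_one_returns_start_distribution(self, triangle):
        y = np.array([2.0, 0.0, 2.0])
        p = random_walk_restart(triangle, y, restart=1.0).scores
        assert p == pytest.approx([0.5, 0.0, 0.5])

    def test_zero_prior_stays_zero(self, triangle):
        assert np.all(random_walk_restart(triangle, np.zeros(3), 0.5).scores == 0.0)


class TestCipherDN:
    @pytest.fixture
    def toy(self):
        # candidate x adjacent (w=1) to the sole gene g1 of the most similar
        # disease; decoy y unconnected to any disease gene
        net = WeightedNetwork(
            {
                ("g1", "x"): 1.0,
                ("g2", "u"): 1.0,
                ("g3", "u"): 1.0,
                ("x", "u"): 0.2,
                ("y", "u"): 0.2,
            }
        )
        S = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.2, 0.1],
                [0.2, 0.2, 1.0, 0.1],
                [0.1, 0.1, 0.1, 1.0],
            ]
        )
        sims = DiseaseSimilarityMatrix(("q", "d1", "d2", "d3"), S)
        assoc = AssociationTable(frozenset({("d1", "g1"), ("d2", "g2"), ("d3", "g3")}))
        return net, sims, assoc

    def test_neighbor_of_similar_disease_gene_scores_highest(self, toy):
        net, sims, assoc = toy
        scores = cipher_dn_scores(net, "q", sims, assoc, ["x", "y", "u"])
        assert np.argmax(scores) == 0
        assert scores[0] == cipher_dn(net, "q", sims, assoc, "x") > 0

    def test_known_gene_scores_itself(self, toy):
        net, sims, assoc = toy
        # g1's closeness to d1 includes the self-contribution of 1
        assert cipher_dn(net, "q", sims, assoc, "g1") > 0

    def test_isolated_candidate_has_undefined_correlation(self, toy):
        net, sims, assoc = toy
        with pytest.raises(CipherUndefinedError):
            cipher_dn(net, "q", sims, assoc, "y")
        scores = cipher_dn_scores(net, "q", sims, assoc, ["y"])
        assert scores[0] == -np.inf

    def test_fewer_than_two_diseases_rejected(self, toy):
        net, sims, _ = toy
        one = AssociationTable(frozenset({("d1", "g1")}))
        with pytest.raises(CipherUndefinedError):
            cipher_dn(net, "q", sims, one, "x")

    def test_matches_brute_force_correlation(self, toy):
        net, sims, assoc = toy
        diseases = sorted(assoc.diseases)
        svec = [sims.similarity("q", d) for d in diseases]
        gene_of = {d: next(iter(assoc.proteins_for(d))) for d in diseases}

        def closeness(cand, d):
            g = gene_of[d]
            return 1.0 if g == cand else net.weight(cand, g)

        cvec = [closeness("x", d) for d in diseases]
        expected = np.corrcoef(svec, cvec)[0, 1]
        assert cipher_dn(net, "q", sims, assoc, "x") == pytest.approx(expected)
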