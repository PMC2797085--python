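import math
from itertools import combinations

import numpy as np
import pytest

from conftest import random_network
from prince.complexes import (
    ComplexCandidate,
    ComplexModelParams,
    complex_score,
    filter_complexes,
    grow_from_seeds,
    infer_complexes,
    null_edge_prob,
    refine,
    tune_beta_to_size,
)
from prince.netio import WeightedNetwork
from prince.propagation import PropagationResult, normalize, propagate_exact


def brute_force_score(C, network, gamma=0.9, eps=1e-6):
    """Independent pairwise-sum reference implementation."""
    d = {p: 0.0 for p in network.proteins}
    for u, v, w in network.edges():
        d[u] += w
        d[v] += w
    two_m = 2.0 * network.total_edge_weight()
    total = 0.0
    for u, v in combinations(sorted(C), 2):
        p = min(max(d[u] * d[v] / two_m, eps), 1 - eps)
        r = network.weight(u, v)
        if r > 0:
            total += math.log((0.9 * r + 0.1 * (1 - r)) / (p * r + (1 - p) * (1 - r)))
        else:
            total += math.log(0.1 / (1 - p))
    return total


class TestNullEdgeProb:
    def test_triangle(self, triangle):
        assert null_edge_prob(triangle, "a", "b") == pytest.approx(2 / 3)

    def test_star_leaves(self):
        star = WeightedNetwork({("hub", "a"): 1.0, ("hub", "b"): 1.0, ("hub", "c"): 1.0})
        assert null_edge_prob(star, "a", "b") == pytest.approx(1 / 6)

    def test_hub_pair_clamped(self):
        star = WeightedNetwork({("hub", f"x{i}"): 1.0 for i in range(10)})
        big = WeightedNetwork(
            {("h1", "h2"): 1.0, **{("h1", f"a{i}"): 1.0 for i in range(5)},
             **{("h2", f"b{i}"): 1.0 for i in range(5)}}
        )
        # d(h1) = d(h2) = 6, total weight 11 -> 36/22 > 1, clamped
        assert null_edge_prob(big, "h1", "h2") == pytest.approx(1 - 1e-6)

    def test_self_pair_rejected(self, triangle):
        with pytest.raises(ValueError):
            null_edge_prob(triangle, "a", "a")


class TestComplexScore:
    def test_unit_triangle_closed_form(self, triangle):
        # each pair: log(gamma / p) = log(0.9 / (2/3)) = log(1.35)
        assert complex_score({"a", "b", "c"}, triangle) == pytest.approx(
            3 * math.log(1.35), rel=1e-12
        )

    def test_unobserved_pair_penalty(self):
        # d(u)=d(v)=1, total weight 5 -> p(u,v) = 0.1; no edge between u and v
        net = WeightedNetwork(
            {("u", "a"): 1.0, ("v", "b"): 1.0, ("a", "b"): 1.0,
             ("c", "d"): 1.0, ("e", "f"): 1.0}
        )
        assert complex_score({"u", "v"}, net) == pytest.approx(math.log(0.1 / 0.9))

    def test_identical_models_score_zero(self):
        # pair graph weight w: p = w/2; choosing gamma = p makes both models equal
        net = WeightedNetwork({("a", "b"): 0.8})
        params = ComplexModelParams(gamma=0.4)
        assert complex_score({"a", "b"}, net, params) == pytest.approx(0.0, abs=1e-12)

    def test_too_small_set_rejected(self, triangle):
        with pytest.raises(ValueError):
            complex_score({"a"}, triangle)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, 30, 0.2)
        for _ in range(200):
            size = int(rng.integers(2, 9))
            C = set(rng.choice(net.proteins, size=size, replace=False))
            assert complex_score(C, net) == pytest.approx(
                brute_force_score(C, net), abs=1e-12
            )

    def test_planted_clique_outscores_random_sets(self):
        rng = np.random.default_rng(22)
        wins = 0
        trials = 200
        from prince.synthetic import gen_network

        net, mods = gen_network(120, 3, 6, 1.0, 0.03, seed=9)
        clique = mods[0]
        for _ in range(trials):
            rand = set(rng.choice(net.proteins, size=len(clique), replace=False))
            wins += complex_score(clique, net) > complex_score(rand, net)
        assert wins / trials >= 0.99


def scores_result(network, values):
    F = np.zeros(network.n)
    for p, v in values.items():
        F[network.index[p]] = v
    return PropagationResult("dX", F, 0.9, 0, True, 0.0)


class TestGrowRefineFilter:
    @pytest.fixture
    def clique_world(self):
        edges = {}
        members = [f"m{i}" for i in range(6)]
        for u, v in combinations(members, 2):
            edges[(u, v)] = 0.9
        # low-scoring periphery
        for i, d in enumerate(f"x{j}" for j in range(8)):
            edges[(members[i % 6], d)] = 0.3
        net = WeightedNetwork(edges)
        F = {m: 0.5 for m in members}
        F.update({f"x{j}": 0.01 for j in range(8)})
        return net, scores_result(net, F), set(members)

    def test_planted_clique_grown_exactly(self, clique_world):
        net, res, members = clique_world
        params = ComplexModelParams(beta=0.1, seed_count=20)
        grown = grow_from_seeds(res, net, params)
        assert len(grown) == 1
        assert set(grown[0].members) == members

    def test_all_below_beta_gives_nothing(self, clique_world):
        net, res, _ = clique_world
        assert grow_from_seeds(res, net, ComplexModelParams(beta=0.9)) == []

    def test_interval_constraint_discards(self, clique_world):
        from prince.netio import CandidateInterval

        net, res, members = clique_world
        params = ComplexModelParams(beta=0.1, seed_count=20)
        outside = CandidateInterval("dX", ("x0", "x1"))
        assert grow_from_seeds(res, net, params, outside) == []
        inside = CandidateInterval("dX", ("m0",))
        assert len(grow_from_seeds(res, net, params, inside)) == 1

    def test_refine_removes_net_negative_pendant(self, clique_world):
        net, _, members = clique_world
        cand_members = members | {"x0"}
        cand = ComplexCandidate(
            frozenset(cand_members), "m0", complex_score(cand_members, net), "dX"
        )
        refined = refine(cand, net)
        assert set(refined.members) == members
        assert refined.score >= cand.score

    def test_refine_idempotent_and_fixed_on_triangle(self, triangle):
        cand = ComplexCandidate(
            frozenset({"a", "b", "c"}), "a", complex_score({"a", "b", "c"}, triangle)
        )
        once = refine(cand, triangle)
        assert once == cand  # dense triangle is already optimal
        assert refine(once, triangle) == once

    def test_refine_preserves_connectivity_and_score(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 40, 0.15)
        for _ in range(100):
            size = int(rng.integers(4, 12))
            start = net.proteins[int(rng.integers(net.n))]
            # grow a connected random candidate by BFS
            members = {start}
            frontier = [net.index[start]]
            while len(members) < size and frontier:
                i = frontier.pop(0)
                for j in net.neighbors(i).tolist():
                    if len(members) >= size:
                        break
                    if net.proteins[j] not in members:
                        members.add(net.proteins[j])
                        frontier.append(j)
            if len(members) < 3:
                continue
            cand = ComplexCandidate(
                frozenset(members), start, complex_score(members, net)
            )
            refined = refine(cand, net)
            assert refined.score >= cand.score
            assert refine(refined, net) == refined
            # connectivity oracle: BFS on the induced subgraph
            mem = sorted(refined.members)
            idx = {net.index[p] for p in mem}
            seen = {next(iter(idx))}
            stack = [next(iter(idx))]
            while stack:
                i = stack.pop()
                for j in net.neighbors(i).tolist():
                    if j in idx and j not in seen:
                        seen.add(j)
                        stack.append(j)
            assert len(seen) == len(idx)

    def test_filter_size_and_overlap(self):
        a = ComplexCandidate(frozenset("abcdef"), "a", 5.0)
        b = ComplexCandidate(frozenset("abcdef"), "b", 4.0)
        c = ComplexCandidate(frozenset("uvwxyz"), "u", 1.0)
        small = ComplexCandidate(frozenset("abc"), "a", 9.0)
        kept = filter_complexes([small, b, c, a])
        assert kept == [a, c]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ComplexModelParams(gamma=1.5)
        with pytest.raises(ValueError):
            ComplexModelParams(min_size=1)
        with pytest.raises(ValueError):
            ComplexModelParams(min_size=10, max_size=5)


class TestInferComplexes:
    def test_planted_modules_recovered(self, small_bundle):
        b = small_bundle
        norm = normalize(b.network)
        params = ComplexModelParams(beta=0.05, seed_count=100)
        for d in b.sims.diseases[:4]:
            from prince.prior import build_prior

            prior = build_prior(d, b.associations, b.sims, b.network)
            res = propagate_exact(norm, prior, 0.9)
            found = infer_complexes(res, b.network, params)
            module = set(b.modules[b.truth["diseases"][d]["module"]])
            best = max(
                (len(set(c.members) & module) / len(set(c.members) | module) for c in found),
                default=0.0,
            )
            assert best >= 0.8
            for c in found:
                assert params.min_size <= len(c) <= params.max_size

    def test_beta_above_max_score_gives_nothing(self, small_bundle):
        b = small_bundle
        from prince.prior import build_prior

        d = b.sims.diseases[0]
        prior = build_prior(d, b.associations, b.sims, b.network)
        res = propagate_exact(normalize(b.network), prior, 0.9)
        hi = float(res.scores.max()) + 1.0
        assert infer_complexes(res, b.network, ComplexModelParams(beta=hi)) == []

    def test_insensitive_to_seed_count(self, small_bundle):
        b = small_bundle
        from prince.prior import build_prior

        d = b.sims.diseases[0]
        prior = build_prior(d, b.associations, b.sims, b.network)
        res = propagate_exact(normalize(b.network), prior, 0.9)
        outputs = []
        for sc in (50, 100, 150):
            found = infer_complexes(
                res, b.network, ComplexModelParams(beta=0.05, seed_count=sc)
            )
            outputs.append(sorted(c.sorted_members() for c in found))
        assert outputs[0] == outputs[1] == outputs[2]

    def test_tune_beta_tracks_reference_size(self, small_bundle):
        b = small_bundle
        from prince.prior import build_prior

        norm = normalize(b.network)
        results = [
            propagate_exact(norm, build_prior(d, b.associations, b.sims, b.network), 0.9)
            for d in b.sims.diseases[:3]
        ]
        beta = tune_beta_to_size(
            results, b.network, 6.0, beta_grid=np.linspace(0.01, 0.2, 10)
        )
        params = ComplexModelParams(beta=beta)
        sizes = [len(c) for r in results for c in infer_complexes(r, b.network, params)]
        assert sizes and abs(np.mean(sizes) - 6.0) <= 2.0
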