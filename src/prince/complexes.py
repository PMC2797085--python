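"""Disease-associated protein complex inference.

Starting from the top-scoring proteins of a propagation run, each seed greedily
grows by repeatedly absorbing the network neighbor with the highest propagation
score, as long as that score exceeds a membership threshold beta and the set
holds at most ``max_size`` proteins. Candidates are then refined by removing
proteins whose removal raises a log-likelihood-ratio score while keeping the
induced interaction subgraph connected, and finally filtered by size and
mutual overlap.

The score contrasts a complex model — every pair of members interacts with a
high probability gamma, independently of all other pairs — against a random
background in which an edge between u and v appears with probability
proportional to the product of their (weighted) degrees,
p(u,v) = d(u) d(v) / (2 * total edge weight). Edge confidences enter as noisy
observations: a pair observed with reliability r contributes

    log[ (gamma * r + (1-gamma)(1-r)) / (p * r + (1-p)(1-r)) ],

an unobserved pair contributes log[(1-gamma) / (1-p)]. Null probabilities are
clamped away from {0, 1} to keep every term finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .netio import CandidateInterval, WeightedNetwork
from .propagation import PropagationResult

__all__ = [
    "ComplexModelParams",
    "ComplexCandidate",
    "null_edge_prob",
    "complex_score",
    "grow_from_seeds",
    "refine",
    "filter_complexes",
    "infer_complexes",
    "tune_beta_to_size",
]


@dataclass(frozen=True)
class ComplexModelParams:
    """Tunables of the complex model.

    gamma: assumed within-complex interaction probability.
    beta: minimum propagation score for a protein to join a complex; the
        useful scale tracks the score distribution of the data set (see
        :func:`tune_beta_to_size`).
    seed_count: how many top-scoring proteins seed the growth phase; results
        are typically insensitive across 50-150.
    min_size/max_size: size window for reported complexes.
    overlap_threshold: maximum allowed |A∩B|/min(|A|,|B|) against any
        higher-scoring kept complex.
    eps: clamp for null edge probabilities.
    """

    gamma: float = 0.9
    beta: float = 0.1
    max_size: int = 20
    seed_count: int = 100
    min_size: int = 4
    overlap_threshold: float = 0.8
    eps: float = 1e-6

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if not (self.max_size >= self.min_size >= 2):
            raise ValueError("need max_size >= min_size >= 2")
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.seed_count < 1:
            raise ValueError("seed_count must be >= 1")


@dataclass(frozen=True)
class ComplexCandidate:
    """A candidate complex: member set, its seed, and its likelihood-ratio score."""

    members: frozenset[str]
    seed: str
    score: float
    disease: str = ""

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError("a complex candidate needs at least 2 members")
        if not math.isfinite(self.score):
            raise ValueError("complex score must be finite")

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def null_edge_prob(network: WeightedNetwork, u: str, v: str, eps: float = 1e-6) -> float:
    """Background edge probability p(u,v) = d(u) d(v) / (2 * total edge weight).

    Uses weighted degrees; clamped to [eps, 1 - eps].
    """
    if u == v:
        raise ValueError("null probability undefined for a self-pair")
    d = network.degrees()
    du, dv = d[network.index[u]], d[network.index[v]]
    p = du * dv / float(network.W.sum())
    return float(min(max(p, eps), 1.0 - eps))


def _pair_term(w: float, p: float, gamma: float) -> float:
    if w > 0.0:
        return math.log((gamma * w + (1.0 - gamma) * (1.0 - w)) / (p * w + (1.0 - p) * (1.0 - w)))
    return math.log((1.0 - gamma) / (1.0 - p))


def complex_score(
    C: Iterable[str], network: WeightedNetwork, params: ComplexModelParams = ComplexModelParams()
) -> float:
    """Log-likelihood ratio of the complex model vs. the degree null over all pairs."""
    members = sorted(set(C))
    if len(members) < 2:
        raise ValueError("complex score needs at least 2 proteins")
    d = network.degrees()
    two_m = float(network.W.sum())
    total = 0.0
    for i, u in enumerate(members):
        du = d[network.index[u]]
        for v in members[i + 1 :]:
            p = du * d[network.index[v]] / two_m
            p = min(max(p, params.eps), 1.0 - params.eps)
            total += _pair_term(network.weight(u, v), p, params.gamma)
    return total


def grow_from_seeds(
    result: PropagationResult,
    network: WeightedNetwork,
    params: ComplexModelParams = ComplexModelParams(),
    interval: CandidateInterval | None = None,
) -> list[ComplexCandidate]:
    """Greedy growth from the top-scoring proteins.

    Seeds are the ``seed_count`` proteins with the highest propagation score,
    processed in descending score order (ties broken lexicographically).
    Seeds scoring below beta, or already members of a previously grown complex
    for this disease, are skipped. Growth repeatedly adds the neighbor of the
    current set with the highest score while that score exceeds beta and the
    set stays within ``max_size``. When an interval is given, a grown complex
    containing no interval member is discarded.
    """
    F = np.asarray(result.scores, dtype=np.float64)
    order = sorted(range(network.n), key=lambda i: (-F[i], network.proteins[i]))
    seeds = order[: params.seed_count]
    claimed: set[int] = set()
    out: list[ComplexCandidate] = []
    interval_idx = (
        {network.index[p] for p in interval.members if p in network}
        if interval is not None
        else None
    )
    for s in seeds:
        if F[s] < params.beta or s in claimed:
            continue
        members = {s}
        while len(members) < params.max_size:
            neigh: set[int] = set()
            for m in members:
                neigh.update(network.neighbors(m).tolist())
            neigh -= members
            if not neigh:
                break
            best = min(neigh, key=lambda i: (-F[i], network.proteins[i]))
            if F[best] <= params.beta:
                break
            members.add(best)
        if len(members) < 2:
            continue
        if interval_idx is not None and not (members & interval_idx):
            continue
        names = frozenset(network.proteins[i] for i in members)
        out.append(
            ComplexCandidate(
                names, network.proteins[s], complex_score(names, network, params), result.disease
            )
        )
        claimed |= members
    return out


def _is_connected(members: Sequence[str], network: WeightedNetwork) -> bool:
    """BFS connectivity over the induced observed-edge subgraph."""
    members = list(members)
    if len(members) <= 1:
        return True
    idx = {network.index[p] for p in members}
    start = next(iter(idx))
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for i in frontier:
            for j in network.neighbors(i).tolist():
                if j in idx and j not in seen:
                    seen.add(j)
                    nxt.append(j)
        frontier = nxt
    return len(seen) == len(idx)


def refine(
    candidate: ComplexCandidate,
    network: WeightedNetwork,
    params: ComplexModelParams = ComplexModelParams(),
) -> ComplexCandidate:
    """Remove members to maximize the score while preserving connectivity.

    Each step removes the protein yielding the largest strict score increase
    among connectivity-preserving removals (ties go to the lexicographically
    smallest protein); stops when no removal improves the score. Idempotent
    and monotone in score.
    """
    members = set(candidate.members)
    score = candidate.score
    while len(members) > 2:
        best_protein, best_score = None, score
        for p in sorted(members):
            rest = members - {p}
            if not _is_connected(sorted(rest), network):
                continue
            s = complex_score(rest, network, params)
            if s > best_score:
                best_protein, best_score = p, s
        if best_protein is None:
            break
        members.remove(best_protein)
        score = best_score
    if members == candidate.members:
        return candidate
    return replace(candidate, members=frozenset(members), score=score)


def _overlap(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / min(len(a), len(b))


def filter_complexes(
    candidates: Sequence[ComplexCandidate],
    params: ComplexModelParams = ComplexModelParams(),
) -> list[ComplexCandidate]:
    """Drop undersized candidates; greedily resolve overlaps by score.

    Candidates are sorted by descending score (ties by member list); a
    candidate is kept only if its overlap with every kept higher-scoring
    candidate stays below ``overlap_threshold``.
    """
    sized = [c for c in candidates if len(c) >= params.min_size]
    sized.sort(key=lambda c: (-c.score, c.sorted_members()))
    kept: list[ComplexCandidate] = []
    for cand in sized:
        if all(_overlap(cand.members, k.members) < params.overlap_threshold for k in kept):
            kept.append(cand)
    return kept


def infer_complexes(
    result: PropagationResult,
    network: WeightedNetwork,
    params: ComplexModelParams = ComplexModelParams(),
    interval: CandidateInterval | None = None,
) -> list[ComplexCandidate]:
    """Full pipeline: grow from seeds, refine each candidate, filter. Deterministic."""
    grown = grow_from_seeds(result, network, params, interval)
    refined = [refine(c, network, params) for c in grown]
    return filter_complexes(refined, params)


def tune_beta_to_size(
    results: Sequence[PropagationResult],
    network: WeightedNetwork,
    target_mean_size: float,
    params: ComplexModelParams = ComplexModelParams(),
    beta_grid: Sequence[float] | None = None,
) -> float:
    """Pick beta so the mean inferred complex size tracks a reference collection.

    Mirrors calibrating the membership threshold against the mean size of a
    curated complex collection: for each beta on the grid, complexes are
    inferred for every propagation result and the beta whose mean complex size
    is closest to ``target_mean_size`` is returned (diseases yielding no
    complex contribute nothing; a beta yielding no complexes at all is
    skipped). Ties prefer the smaller beta.
    """
    if beta_grid is None:
        hi = max(float(np.max(r.scores)) for r in results)
        beta_grid = np.linspace(0.005, max(hi, 0.01), 40)
    best_beta, best_err = None, np.inf
    for beta in beta_grid:
        p = replace(params, beta=float(beta))
        sizes = [len(c) for r in results for c in infer_complexes(r, network, p)]
        if not sizes:
            continue
        err = abs(float(np.mean(sizes)) - target_mean_size)
        if err < best_err:
            best_beta, best_err = float(beta), err
    if best_beta is None:
        raise ValueError("no beta on the grid produced any complex")
    return best_beta
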