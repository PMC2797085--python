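"""Cross-validation harness and precision-recall metrics.

Each trial hides one (disease, protein) association together with every other
association of that protein — otherwise a protein associated with several very
similar diseases would make the trial trivially easy — rebuilds the prior with
those pairs excluded, reruns the scorer and records the rank of the hidden
protein among the candidates. Candidates are either an artificial linkage
interval of fixed size around the protein in a given genome ordering, or the
whole network. Ranks use pessimistic competition ranking with lexicographic
tie-breaks, so ties never flatter a method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netio import (
    AssociationTable,
    CandidateInterval,
    DiseaseSimilarityMatrix,
    WeightedNetwork,
)
from .prior import LogisticParams, build_prior
from .propagation import (
    CipherUndefinedError,
    PropagationResult,
    cipher_dn_scores,
    exact_solver,
    normalize,
    random_walk_restart,
)

log = logging.getLogger(__name__)

__all__ = [
    "CVTrial",
    "PRCurve",
    "make_artificial_interval",
    "rank_of",
    "run_cv",
    "precision_recall",
    "METHODS",
]

METHODS = ("prince", "rwr", "cipher-dn")


@dataclass(frozen=True)
class CVTrial:
    """One cross-validation trial: a hidden association and the achieved rank."""

    disease: str
    protein: str
    hidden: frozenset[tuple[str, str]]
    n_candidates: int
    rank: int
    flagged: bool = False


@dataclass(frozen=True)
class PRCurve:
    """(k, precision, recall) triples for increasing rank thresholds k."""

    points: tuple[tuple[int, float, float], ...]

    def recall_at(self, k: int) -> float:
        for kk, _, r in self.points:
            if kk == k:
                return r
        raise KeyError(f"no point for k={k}")


def make_artificial_interval(
    protein: str, genome_order: Sequence[str], size: int = 100
) -> CandidateInterval:
    """A window of ``size`` genes centered on the protein in genome order.

    Truncation at either end of the list is compensated by extending the other
    side, so the interval has exactly ``size`` members whenever the genome is
    long enough; otherwise the whole list is returned with a warning.
    """
    if size < 1:
        raise ValueError("interval size must be >= 1")
    order = list(genome_order)
    try:
        pos = order.index(protein)
    except ValueError:
        raise KeyError(f"protein {protein!r} not in genome order") from None
    if len(order) < size:
        log.warning("genome order shorter than interval size; using the whole list")
        return CandidateInterval("", tuple(order))
    start = pos - (size - 1) // 2
    start = max(0, min(start, len(order) - size))
    return CandidateInterval("", tuple(order[start : start + size]))


def rank_of(
    scores: PropagationResult | Mapping[str, float] | np.ndarray,
    candidates: CandidateInterval | Sequence[str],
    target: str,
    network: WeightedNetwork | None = None,
) -> int:
    """Pessimistic competition rank of the target among the candidates.

    rank = 1 + #{candidates scoring strictly higher}
             + #{equal-scored candidates with lexicographically smaller ID}.
    """
    members = list(candidates.members if isinstance(candidates, CandidateInterval) else candidates)
    if target not in members:
        raise KeyError(f"target {target!r} not among candidates")
    if isinstance(scores, PropagationResult):
        if network is None:
            raise ValueError("network required to index a PropagationResult")
        lookup = {p: float(scores.scores[network.index[p]]) for p in members if p in network}
    elif isinstance(scores, Mapping):
        lookup = {p: float(scores[p]) for p in members if p in scores}
    else:
        arr = np.asarray(scores, dtype=np.float64)
        if len(arr) != len(members):
            raise ValueError("score array length does not match candidate count")
        lookup = dict(zip(members, (float(x) for x in arr)))
    # candidates without a score compete with -inf
    st = lookup.get(target, -np.inf)
    rank = 1
    for p in members:
        if p == target:
            continue
        s = lookup.get(p, -np.inf)
        if s > st or (s == st and p < target):
            rank += 1
    return rank


def _fold_partition(pairs: list[tuple[str, str]], folds, seed: int) -> list[list[tuple[str, str]]]:
    if folds in ("loo", None) or folds == len(pairs):
        return [[p] for p in pairs]
    k = int(folds)
    if not (2 <= k <= len(pairs)):
        raise ValueError(f"folds must be 'loo' or in [2, {len(pairs)}]")
    rng = np.random.default_rng(seed)
    order = list(pairs)
    rng.shuffle(order)
    return [order[i::k] for i in range(k)]


def run_cv(
    network: WeightedNetwork,
    sims: DiseaseSimilarityMatrix,
    associations: AssociationTable,
    genome_order: Sequence[str] | None = None,
    *,
    method: str = "prince",
    folds="loo",
    interval_size: int = 100,
    seed: int = 0,
    alpha: float = 0.9,
    restart: float = 0.5,
    logistic: LogisticParams = LogisticParams(),
    tol: float = 1e-6,
) -> list[CVTrial]:
    """Cross-validate one scorer over every known association.

    ``folds='loo'`` hides one association per trial; integer folds partition
    the (seed-shuffled) association list and hide a whole fold at a time. In
    both cases the trial additionally hides every association of the trial's
    protein. ``genome_order=None`` ranks against the whole network instead of
    an artificial interval. Deterministic given the seed.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    pairs = sorted(associations.pairs)
    partition = _fold_partition(pairs, folds, seed)
    norm = normalize(network) if method == "prince" else None
    solver = exact_solver(norm, alpha) if method == "prince" else None

    trials: list[CVTrial] = []
    for fold in partition:
        fold_set = frozenset(fold)
        for disease, protein in fold:
            if protein not in network:
                continue
            hidden = fold_set | associations.pairs_of_protein(protein)
            if genome_order is not None:
                interval = make_artificial_interval(protein, genome_order, interval_size)
                candidates = list(interval.members)
            else:
                candidates = list(network.proteins)
            # proteins with a surviving association to the query are not
            # candidates: the task is to prioritize proteins not already
            # known to be associated with the query disease
            surviving = associations.pairs - hidden
            candidates = [
                q for q in candidates if q == protein or (disease, q) not in surviving
            ]
            flagged = False
            if method == "cipher-dn":
                try:
                    scores = cipher_dn_scores(
                        network, disease, sims, associations.excluding(hidden), candidates
                    )
                    rank = rank_of(scores, candidates, protein)
                except CipherUndefinedError:
                    rank, flagged = len(candidates), True
            else:
                prior = build_prior(
                    disease, associations, sims, network, logistic, exclude=hidden
                )
                if prior.y.sum() == 0.0:
                    rank, flagged = len(candidates), True
                else:
                    if method == "prince":
                        F = solver(prior.y)
                        result = PropagationResult(disease, F, alpha, 0, True, 0.0)
                    else:
                        result = random_walk_restart(network, prior, restart, tol=tol)
                    rank = rank_of(result, candidates, protein, network)
            trials.append(
                CVTrial(disease, protein, hidden, len(candidates), rank, flagged)
            )
    return trials


def precision_recall(trials: Sequence[CVTrial], ks: Iterable[int]) -> PRCurve:
    """Precision/recall at each rank threshold k.

    Recall at k is the fraction of trials whose hidden association was
    recovered within the top k. With a single hidden association per trial the
    association-level precision coincides with recall; both are reported.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    ranks = np.array([t.rank for t in trials])
    points = []
    for k in sorted(set(int(k) for k in ks)):
        if k < 1:
            raise ValueError("rank thresholds must be >= 1")
        recall = float(np.mean(ranks <= k))
        points.append((k, recall, recall))
    return PRCurve(tuple(points))
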