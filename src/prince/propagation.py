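"""Degree-normalized network propagation and the two baseline scorers.

The prioritization function F solves

    F = alpha * W' * F + (1 - alpha) * Y,

where W' = D^{-1/2} W D^{-1/2} is the degree-normalized adjacency and Y the
prior vector. Equivalently F minimizes a combination of a smoothness penalty
over the network (adjacent proteins should score similarly) and a fit-to-prior
penalty, with alpha trading the two off. Because W' is similar to the
row-stochastic matrix D^{-1} W its spectrum lies in [-1, 1], so for
alpha < 1 the system has a unique solution and the fixed-point iteration
F_t = alpha W' F_{t-1} + (1 - alpha) Y converges geometrically (ratio <= alpha).

Also implemented here: the random-walk-with-restart baseline (column-stochastic
walk matrix W D^{-1}, restart to the normalized prior) and the direct-neighbor
correlation baseline that scores a candidate by the Pearson correlation between
its phenotype-similarity profile and its network closeness to each disease's
known genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import pearsonr

from .netio import AssociationTable, DiseaseSimilarityMatrix, WeightedNetwork
from .prior import PriorVector

__all__ = [
    "NormalizedNetwork",
    "PropagationResult",
    "normalize",
    "propagate_iterative",
    "propagate_exact",
    "exact_solver",
    "random_walk_restart",
    "cipher_dn",
    "cipher_dn_scores",
    "CipherUndefinedError",
]


@dataclass(frozen=True)
class NormalizedNetwork:
    """A network together with its degree-normalized adjacency W'."""

    base: WeightedNetwork
    Wn: sp.csr_matrix


@dataclass(frozen=True)
class PropagationResult:
    """Converged score vector for one query disease."""

    disease: str
    scores: np.ndarray
    alpha: float
    iterations: int
    converged: bool
    residual: float
    method: str = "prince"

    def score_of(self, network: WeightedNetwork, protein: str) -> float:
        return float(self.scores[network.index[protein]])


def normalize(network: WeightedNetwork) -> NormalizedNetwork:
    """W'[u,v] = w(u,v) / sqrt(d(u) d(v)) with weighted degrees d.

    Invariant under uniform rescaling of all edge weights; symmetric; spectrum
    in [-1, 1]. Raises ``ValueError`` on zero-degree nodes (these should have
    been dropped at load time).
    """
    d = network.degrees()
    if np.any(d <= 0):
        raise ValueError("zero-degree node encountered; drop isolated proteins at load")
    inv_sqrt = 1.0 / np.sqrt(d)
    Dinv = sp.diags(inv_sqrt)
    Wn = (Dinv @ network.W @ Dinv).tocsr()
    return NormalizedNetwork(network, Wn)


def _prior_array(Y: PriorVector | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(Y, PriorVector):
        return np.asarray(Y.y, dtype=np.float64), Y.disease
    return np.asarray(Y, dtype=np.float64), ""


def propagate_iterative(
    norm: NormalizedNetwork,
    Y: PriorVector | np.ndarray,
    alpha: float = 0.9,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> PropagationResult:
    """Fixed-point iteration F_t = alpha W' F_{t-1} + (1-alpha) Y, F_0 = Y.

    Stops when the max-abs change drops below ``tol`` or after ``max_iter``
    sweeps. ``alpha = 0`` is admitted as the closed prior-only limit (F = Y).
    """
    y, disease = _prior_array(Y)
    if alpha == 0.0:
        return PropagationResult(disease, y.copy(), alpha, 0, True, 0.0)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1) (got {alpha})")
    F = y.copy()
    base = (1.0 - alpha) * y
    residual = np.inf
    for it in range(1, max_iter + 1):
        F_new = alpha * (norm.Wn @ F) + base
        residual = float(np.max(np.abs(F_new - F)))
        F = F_new
        if residual < tol:
            return PropagationResult(disease, F, alpha, it, True, residual)
    return PropagationResult(disease, F, alpha, max_iter, False, residual)


def exact_solver(norm: NormalizedNetwork, alpha: float) -> Callable[[np.ndarray], np.ndarray]:
    """Prefactorized solver for (I - alpha W') F = (1-alpha) Y.

    Factorizing once lets cross-validation reuse the operator across trials.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1) (got {alpha})")
    n = norm.base.n
    A = (sp.identity(n, format="csc") - alpha * norm.Wn).tocsc()
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # pragma: no cover - cannot occur for alpha < 1
        raise ValueError(f"singular propagation system: {exc}") from exc

    def solve(y: np.ndarray) -> np.ndarray:
        return lu.solve((1.0 - alpha) * np.asarray(y, dtype=np.float64))

    return solve


def propagate_exact(
    norm: NormalizedNetwork, Y: PriorVector | np.ndarray, alpha: float = 0.9
) -> PropagationResult:
    """Exact solution of the propagation linear system.

    Since the spectrum of W' is within [-1, 1], I - alpha W' is invertible for
    alpha < 1. ``alpha = 0`` returns F = Y.
    """
    y, disease = _prior_array(Y)
    if alpha == 0.0:
        return PropagationResult(disease, y.copy(), alpha, 0, True, 0.0)
    F = exact_solver(norm, alpha)(y)
    return PropagationResult(disease, F, alpha, 0, True, 0.0)


def smoothness_objective(norm: NormalizedNetwork, F: np.ndarray, Y: np.ndarray, alpha: float) -> float:
    """The quadratic objective the propagation fixed point minimizes.

    alpha * sum_{(u,v) in E} w'(u,v) (F_u - F_v)^2-style smoothness term plus
    (1-alpha) * ||F - Y||^2 fit term, written in its matrix form
    alpha * F^T (I - W') F + (1-alpha) ||F - Y||^2.
    """
    F = np.asarray(F, dtype=np.float64)
    smooth = float(F @ F - F @ (norm.Wn @ F))
    fit = float(np.sum((F - Y) ** 2))
    return alpha * smooth + (1.0 - alpha) * fit


# ---------------------------------------------------------------------------
# Baseline 1: random walk with restart
# ---------------------------------------------------------------------------


def random_walk_restart(
    network: WeightedNetwork,
    Y: PriorVector | np.ndarray,
    restart: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10000,
) -> PropagationResult:
    """Steady state of p_t = (1-r) M p_{t-1} + r p0 with M = W D^{-1}.

    M is column-stochastic, p0 = Y / sum(Y); the result is a probability
    vector (sums to 1). An all-zero prior yields an all-zero result.
    ``restart = 1`` returns p0 exactly.
    """
    y, disease = _prior_array(Y)
    if not (0.0 < restart <= 1.0):
        raise ValueError(f"restart probability must lie in (0, 1] (got {restart})")
    total = y.sum()
    if total == 0.0:
        return PropagationResult(disease, np.zeros_like(y), restart, 0, True, 0.0, "rwr")
    p0 = y / total
    if restart == 1.0:
        return PropagationResult(disease, p0, restart, 0, True, 0.0, "rwr")
    d = network.degrees()
    M = (network.W @ sp.diags(1.0 / d)).tocsr()  # column-stochastic
    p = p0.copy()
    base = restart * p0
    residual = np.inf
    for it in range(1, max_iter + 1):
        p_new = (1.0 - restart) * (M @ p) + base
        residual = float(np.max(np.abs(p_new - p)))
        p = p_new
        if residual < tol:
            return PropagationResult(disease, p, restart, it, True, residual, "rwr")
    return PropagationResult(disease, p, restart, max_iter, False, residual, "rwr")


# ---------------------------------------------------------------------------
# Baseline 2: direct-neighbor similarity/closeness correlation
# ---------------------------------------------------------------------------


class CipherUndefinedError(ValueError):
    """The correlation score is undefined (fewer than 2 diseases with genes)."""


def _closeness(network: WeightedNetwork, candidate: str, genes: frozenset[str]) -> float:
    """Direct-neighbor closeness of a candidate to a disease's gene set.

    Each known gene g' contributes 1 when the candidate is g' itself, the edge
    confidence w(candidate, g') when adjacent, and 0 otherwise.
    """
    total = 0.0
    for g in genes:
        if g == candidate:
            total += 1.0
        else:
            total += network.weight(candidate, g)
    return total


def cipher_dn(
    network: WeightedNetwork,
    query: str,
    sims: DiseaseSimilarityMatrix,
    associations: AssociationTable,
    candidate: str,
) -> float:
    """Direct-neighbor correlation score of one candidate for the query disease.

    Correlates, over all diseases with at least one known gene in the network,
    the phenotype similarity to the query with the candidate's closeness to the
    disease's gene set. Raises :class:`CipherUndefinedError` when fewer than
    two diseases have known genes or the closeness profile is constant.
    """
    if query not in sims:
        raise KeyError(f"query disease {query!r} absent from similarity matrix")
    if candidate not in network:
        raise KeyError(f"candidate {candidate!r} absent from network")
    gene_sets = _disease_gene_sets(network, sims, associations)
    if len(gene_sets) < 2:
        raise CipherUndefinedError("need at least 2 diseases with known genes")
    sims_vec, close_vec = _profiles(network, query, sims, gene_sets, candidate)
    if np.ptp(close_vec) == 0.0 or np.ptp(sims_vec) == 0.0:
        raise CipherUndefinedError("constant profile: correlation undefined")
    r, _ = pearsonr(sims_vec, close_vec)
    return float(r)


def _disease_gene_sets(
    network: WeightedNetwork,
    sims: DiseaseSimilarityMatrix,
    associations: AssociationTable,
) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for d in sorted(associations.diseases):
        if d not in sims:
            continue
        genes = frozenset(p for p in associations.proteins_for(d) if p in network)
        if genes:
            out[d] = genes
    return out


def _profiles(network, query, sims, gene_sets, candidate):
    diseases = sorted(gene_sets)
    qrow = sims.S[sims.index[query]]
    sims_vec = np.array([qrow[sims.index[d]] for d in diseases])
    close_vec = np.array([_closeness(network, candidate, gene_sets[d]) for d in diseases])
    return sims_vec, close_vec


def cipher_dn_scores(
    network: WeightedNetwork,
    query: str,
    sims: DiseaseSimilarityMatrix,
    associations: AssociationTable,
    candidates: list[str],
) -> np.ndarray:
    """Score many candidates; undefined correlations become -inf for ranking."""
    gene_sets = _disease_gene_sets(network, sims, associations)
    if len(gene_sets) < 2:
        raise CipherUndefinedError("need at least 2 diseases with known genes")
    scores = np.full(len(candidates), -np.inf)
    for i, cand in enumerate(candidates):
        if cand not in network:
            continue
        sims_vec, close_vec = _profiles(network, query, sims, gene_sets, cand)
        if np.ptp(close_vec) == 0.0 or np.ptp(sims_vec) == 0.0:
            continue
        scores[i] = pearsonr(sims_vec, close_vec)[0]
    return scores
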