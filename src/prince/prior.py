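"""Prior-knowledge vector construction from phenotype similarity.

The confidence that two diseases share causal genes is modeled with a logistic
transform L(x) = 1 / (1 + exp(c*x + d)) of the raw phenotype similarity
x in [0, 1], with c < 0 so that L increases with similarity. Low similarities
(below ~0.3) are mapped to near-zero confidence, reflecting the empirical
finding that only high phenotype similarity is informative about shared gene
function. The prior Y assigns each protein the confidence of its most similar
associated disease and zero to unassociated proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .netio import (
    AssociationTable,
    DiseaseSimilarityMatrix,
    WeightedNetwork,
    _fmt,
)

__all__ = ["LogisticParams", "PriorVector", "logistic_confidence", "build_prior", "write_prior"]

#: Default slope/offset: L(0) = 1e-4 and L(0.3) ~ 0.009, i.e. similarities in
#: the uninformative zone receive near-zero confidence.
DEFAULT_C = -15.0
DEFAULT_D = math.log(9999.0)


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the similarity-confidence transform L(x) = 1/(1+exp(c*x+d))."""

    c: float = DEFAULT_C
    d: float = DEFAULT_D

    def __post_init__(self):
        if not self.c < 0:
            raise ValueError(f"logistic slope c must be negative (got {self.c})")


def logistic_confidence(similarity: float, params: LogisticParams = LogisticParams()) -> float:
    """Confidence that two diseases are related, given their phenotype similarity.

    Strictly increasing in similarity (c < 0), bounded in (0, 1).
    Raises ``ValueError`` when the similarity is outside [0, 1].
    """
    if not (0.0 <= similarity <= 1.0):
        raise ValueError(f"similarity {similarity} outside [0, 1]")
    return float(1.0 / (1.0 + np.exp(params.c * similarity + params.d)))


def _logistic_vec(x: np.ndarray, params: LogisticParams) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(params.c * x + params.d))


@dataclass(frozen=True)
class PriorVector:
    """Prior evidence Y over proteins, aligned to a network's protein order.

    ``provenance`` maps each protein with positive prior to the disease that
    produced it (the associated disease most similar to the query) and the raw
    similarity value used.
    """

    disease: str
    y: np.ndarray
    proteins: tuple[str, ...]
    provenance: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "y", y)
        if y.shape != (len(self.proteins),):
            raise ValueError("prior vector length does not match protein order")
        if y.min() < 0.0 or y.max() > 1.0:
            raise ValueError("prior values must lie in [0, 1]")


def build_prior(
    query: str,
    associations: AssociationTable,
    sims: DiseaseSimilarityMatrix,
    network: WeightedNetwork,
    params: LogisticParams = LogisticParams(),
    exclude: Iterable[tuple[str, str]] = (),
) -> PriorVector:
    """Build the prior vector Y for a query disease.

    For every network protein p with at least one surviving association, the
    source disease is the associated disease most similar to the query (ties
    broken by lexicographic disease ID) and Y[p] = L(similarity). All other
    proteins get Y[p] = 0. ``exclude`` hides (disease, protein) pairs, which
    supports cross-validation; a protein whose associations are all excluded
    contributes nothing even if it is associated with the query itself.
    """
    if query not in sims:
        raise KeyError(f"query disease {query!r} absent from similarity matrix")
    excluded = frozenset(exclude)
    y = np.zeros(network.n, dtype=np.float64)
    provenance: dict[str, tuple[str, float]] = {}
    qrow = sims.S[sims.index[query]]
    by_protein: dict[str, list[str]] = {}
    for d, p in associations.pairs:
        if (d, p) in excluded or p not in network or d not in sims:
            continue
        by_protein.setdefault(p, []).append(d)
    for p, diseases in by_protein.items():
        # argmax similarity; ties resolved toward the lexicographically
        # smallest disease ID for determinism
        best_d = min(diseases, key=lambda d: (-qrow[sims.index[d]], d))
        s = float(qrow[sims.index[best_d]])
        y[network.index[p]] = logistic_confidence(s, params)
        provenance[p] = (best_d, s)
    return PriorVector(query, y, network.proteins, provenance)


def write_prior(prior: PriorVector, path, header: str | None = None) -> None:
    """Serialize as 2-column TSV (protein, Y)."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p, v in zip(prior.proteins, prior.y):
            fh.write(f"{p}\t{_fmt(v)}\n")
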