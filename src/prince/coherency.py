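"""Coherency statistics for protein complex collections.

Three per-complex statistics quantify whether the members of an inferred
complex look like a real functional unit:

* functional — the minimal hypergeometric upper-tail probability over all
  annotation terms (annotations must arrive pre-propagated up the term
  hierarchy; :func:`propagate_annotations` helps);
* expression — the mean pairwise Pearson correlation of the members'
  expression profiles across conditions;
* conservation — the mean pairwise Jaccard similarity of the members' binary
  phylogenetic profiles across a panel of genomes.

Each raw statistic is compared against the same statistic for random protein
sets of the same size drawn from the proteins that carry the relevant data
type, giving an empirical p-value with the add-one estimator
(1 + #{null at least as extreme}) / (1 + n_null). Per-measure p-values are
corrected across the collection with Benjamini-Hochberg, and a complex counts
as coherent when its corrected q falls below the significance threshold
(default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netio import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "CoherencyReport",
    "hypergeom_term_p",
    "functional_coherency",
    "expression_coherency",
    "conservation_coherency",
    "fdr_bh",
    "coherency_report",
    "propagate_annotations",
    "mean_pairwise_pearson",
    "mean_pairwise_jaccard",
]

MEASURES = ("functional", "expression", "conservation")


def hypergeom_term_p(complex_members: set, term_members: set, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), k = |complex ∩ term|."""
    if not complex_members:
        raise ValueError("empty complex")
    k = len(set(complex_members) & set(term_members))
    return float(hypergeom.sf(k - 1, universe, len(set(term_members)), len(set(complex_members))))


def _empirical_p(n_as_extreme: int, n_null: int) -> float:
    return (1 + n_as_extreme) / (1 + n_null)


def _check_n_null(n_null: int) -> None:
    if n_null < 100:
        raise ValueError(f"n_null must be >= 100 (got {n_null})")


def propagate_annotations(
    annotations: GeneSetCollection, parents: Mapping[str, Sequence[str]]
) -> GeneSetCollection:
    """Add every gene of a term to all its ancestor terms.

    ``parents`` maps a term to its parent term(s); ancestors absent from the
    collection are created. Cycle-safe via memoized ancestor closure.
    """
    def ancestors(t: str) -> set[str]:
        # iterative closure; a term inside a parent cycle is its own ancestor,
        # which is harmless (self-union)
        out: set[str] = set()
        frontier = list(parents.get(t, ()))
        while frontier:
            p = frontier.pop()
            if p in out:
                continue
            out.add(p)
            frontier.extend(parents.get(p, ()))
        return out

    sets: dict[str, set[str]] = {name: set(m) for name, m in annotations.sets.items()}
    for name in list(annotations.sets):
        for anc in ancestors(name):
            sets.setdefault(anc, set()).update(annotations.sets[name])
    return GeneSetCollection({k: frozenset(v) for k, v in sets.items()}, annotations.descriptions)


class _TermTable:
    """Precomputed term-membership structure for fast minimal-p queries."""

    def __init__(self, annotations: GeneSetCollection, universe: Sequence[str]):
        self.universe = tuple(universe)
        self.N = len(self.universe)
        idx = {p: i for i, p in enumerate(self.universe)}
        self.terms = annotations.names()
        self.M = np.zeros((len(self.terms), self.N), dtype=bool)
        self.term_sizes = np.zeros(len(self.terms), dtype=int)
        for t, name in enumerate(self.terms):
            mem = annotations.members(name)
            for p in mem:
                if p in idx:
                    self.M[t, idx[p]] = True
            self.term_sizes[t] = len(mem & set(self.universe))
        self.annotated = tuple(
            self.universe[i] for i in range(self.N) if self.M[:, i].any()
        )
        self.idx = idx

    def sf_table(self, set_size: int) -> np.ndarray:
        """sf[t, k] = P(X >= k) for term t when drawing ``set_size`` proteins."""
        kmax = set_size
        ks = np.arange(0, kmax + 1)
        table = np.empty((len(self.terms), kmax + 1))
        for t in range(len(self.terms)):
            table[t] = hypergeom.sf(ks - 1, self.N, self.term_sizes[t], set_size)
        return table

    def min_p(self, members: Sequence[int], table: np.ndarray) -> tuple[int, float]:
        """(best term index, minimal raw p) for a set of universe indices."""
        if len(members) == 0:
            return -1, 1.0
        overlaps = self.M[:, list(members)].sum(axis=1)
        ps = table[np.arange(len(self.terms)), overlaps]
        t = int(np.argmin(ps))
        return t, float(ps[t])


def functional_coherency(
    complex_members: set,
    annotations: GeneSetCollection,
    universe: Sequence[str],
    n_null: int = 10000,
    seed: int = 0,
) -> tuple[str | None, float, float]:
    """(best term, raw minimal hypergeometric p, empirical p) for one complex.

    The empirical p compares the observed minimal raw p against minimal raw
    p-values of ``n_null`` random same-size sets drawn from annotated
    proteins. A complex with no annotated member is flagged with empirical
    p = 1.
    """
    _check_n_null(n_null)
    tt = _TermTable(annotations, universe)
    members = [tt.idx[p] for p in complex_members if p in tt.idx]
    annotated_members = [i for i in members if tt.M[:, i].any()]
    if not annotated_members:
        log.warning("complex has no annotated member; empirical p = 1")
        return None, 1.0, 1.0
    table = tt.sf_table(len(members))
    t, raw = tt.min_p(members, table)
    rng = np.random.default_rng(seed)
    pool = np.array([tt.idx[p] for p in tt.annotated])
    hits = 0
    for _ in range(n_null):
        draw = rng.choice(pool, size=len(members), replace=False)
        _, p = tt.min_p(draw, table)
        if p <= raw:
            hits += 1
    return tt.terms[t], raw, _empirical_p(hits, n_null)


def mean_pairwise_pearson(profiles: np.ndarray) -> float:
    """Mean Pearson r over unordered row pairs; constant rows yield undefined
    correlations and those pairs are excluded (NaN when no pair is valid)."""
    X = np.asarray(profiles, dtype=np.float64)
    if X.shape[0] < 2:
        return float("nan")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    iu = np.triu_indices(X.shape[0], k=1)
    vals = R[iu]
    bad = (sd[iu[0]] == 0) | (sd[iu[1]] == 0)
    if bad.any():
        log.info("excluding %d pair(s) with constant profiles from the mean", int(bad.sum()))
    vals = vals[~bad]
    return float(np.mean(vals)) if vals.size else float("nan")


def mean_pairwise_jaccard(profiles: np.ndarray) -> float:
    """Mean Jaccard |A∩B|/|A∪B| over unordered row pairs of a binary matrix.

    A pair of all-zero profiles counts as 0.
    """
    X = np.asarray(profiles, dtype=bool)
    n = X.shape[0]
    if n < 2:
        return float("nan")
    inter = (X.astype(np.int64) @ X.T.astype(np.int64)).astype(np.float64)
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    iu = np.triu_indices(n, k=1)
    return float(np.mean(J[iu]))


def _profile_coherency(
    complex_members: set,
    data: pd.DataFrame,
    statistic,
    n_null: int,
    seed: int,
) -> tuple[float, float]:
    _check_n_null(n_null)
    profiled = data.index
    members = sorted(set(complex_members) & set(profiled))
    if len(members) < 2:
        log.warning("fewer than 2 profiled members; empirical p = 1")
        return float("nan"), 1.0
    obs = statistic(data.loc[members].to_numpy())
    if np.isnan(obs):
        return float("nan"), 1.0
    rng = np.random.default_rng(seed)
    pool = np.array(sorted(profiled))
    hits = 0
    for _ in range(n_null):
        draw = rng.choice(pool, size=len(members), replace=False)
        s = statistic(data.loc[draw].to_numpy())
        if not np.isnan(s) and s >= obs:
            hits += 1
    return float(obs), _empirical_p(hits, n_null)


def expression_coherency(
    complex_members: set, expression: pd.DataFrame, n_null: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """(mean pairwise Pearson r, empirical p) against random profiled sets."""
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 conditions for expression coherency")
    return _profile_coherency(complex_members, expression, mean_pairwise_pearson, n_null, seed)


def conservation_coherency(
    complex_members: set, profiles: pd.DataFrame, n_null: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """(mean pairwise Jaccard, empirical p) against random profiled sets."""
    return _profile_coherency(complex_members, profiles, mean_pairwise_jaccard, n_null, seed)


def fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CoherencyReport:
    """Per-complex coherency statistics and collection-level summaries.

    ``table`` holds one row per complex with, per measure, the raw statistic,
    the empirical p and the BH-corrected q. ``percent_coherent`` is the
    percentage of complexes with q below the threshold per measure;
    ``percent_raw`` uses the uncorrected empirical p instead (the quantity
    whose null calibration is exactly the nominal level).
    """

    table: pd.DataFrame
    threshold: float
    percent_coherent: dict[str, float]
    percent_raw: dict[str, float]


def coherency_report(
    complexes: GeneSetCollection,
    annotations: GeneSetCollection,
    expression: pd.DataFrame,
    profiles: pd.DataFrame,
    universe: Sequence[str],
    threshold: float = 0.05,
    n_null: int = 10000,
    seed: int = 0,
) -> CoherencyReport:
    """Evaluate a complex collection on all three coherency measures."""
    if len(complexes) == 0:
        raise ValueError("empty complex collection")
    names = complexes.names()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(3 * len(names)).astype(np.uint32)
    rows = []
    for i, name in enumerate(names):
        members = set(complexes.members(name))
        term, raw_f, p_f = functional_coherency(
            members, annotations, universe, n_null, int(child_seeds[3 * i])
        )
        r, p_e = expression_coherency(members, expression, n_null, int(child_seeds[3 * i + 1]))
        j, p_c = conservation_coherency(members, profiles, n_null, int(child_seeds[3 * i + 2]))
        rows.append(
            {
                "complex": name,
                "size": len(members),
                "best_term": term,
                "functional_raw": raw_f,
                "functional_p": p_f,
                "expression_stat": r,
                "expression_p": p_e,
                "conservation_stat": j,
                "conservation_p": p_c,
            }
        )
    table = pd.DataFrame(rows).set_index("complex")
    percent_q: dict[str, float] = {}
    percent_raw: dict[str, float] = {}
    for measure in MEASURES:
        p = table[f"{measure}_p"].to_numpy()
        q = fdr_bh(p)
        table[f"{measure}_q"] = q
        percent_q[measure] = 100.0 * float(np.mean(q < threshold))
        percent_raw[measure] = 100.0 * float(np.mean(p < threshold))
    return CoherencyReport(table, threshold, percent_q, percent_raw)
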