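"""Data model and I/O for networks, similarity matrices, associations, intervals and gene sets.

All containers are plain in-memory objects backed by numpy / scipy.sparse with
opaque, case-sensitive string identifiers. File formats are deliberately simple
text standards: TSV edge lists, square TSV matrices, two-column TSV association
tables, GMT gene-set files and one-ID-per-line interval files. Every reader has
a writer counterpart and the pair round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "WeightedNetwork",
    "DiseaseSimilarityMatrix",
    "AssociationTable",
    "CandidateInterval",
    "GeneSetCollection",
    "read_network",
    "write_network",
    "read_similarity",
    "write_similarity",
    "read_associations",
    "write_associations",
    "read_interval",
    "write_interval",
    "read_gene_sets",
    "write_gene_sets",
    "read_id_list",
    "write_id_list",
]


class FormatError(ValueError):
    """Raised for malformed input files or invariant violations."""


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips through float()."""
    return repr(float(x))


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# WeightedNetwork
# ---------------------------------------------------------------------------


class WeightedNetwork:
    """Undirected protein network with edge confidences in (0, 1].

    Proteins are kept in sorted order so that loading is insensitive to the
    order of input rows. The adjacency matrix ``W`` is symmetric with a zero
    diagonal; weighted degrees (row sums) are strictly positive because
    isolated proteins are dropped at construction.
    """

    def __init__(self, edges: Mapping[tuple[str, str], float]):
        if not edges:
            raise FormatError("no edges: a network needs at least one edge")
        canon: dict[tuple[str, str], float] = {}
        for (u, v), w in edges.items():
            if u == v:
                raise FormatError(f"self-loop on {u!r}")
            if not (0.0 < w <= 1.0):
                raise FormatError(f"edge weight {w} for ({u!r}, {v!r}) outside (0, 1]")
            key = (u, v) if u < v else (v, u)
            prev = canon.get(key)
            canon[key] = w if prev is None else max(prev, w)
        self.proteins: tuple[str, ...] = tuple(sorted({p for e in canon for p in e}))
        self.index: dict[str, int] = {p: i for i, p in enumerate(self.proteins)}
        n = len(self.proteins)
        rows, cols, vals = [], [], []
        for (u, v), w in canon.items():
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        self.W: sp.csr_matrix = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n, n), dtype=np.float64
        )
        self._edges = canon

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.proteins)

    def degrees(self) -> np.ndarray:
        """Weighted degrees d(u) = sum_v w(u, v)."""
        return np.asarray(self.W.sum(axis=1)).ravel()

    def total_edge_weight(self) -> float:
        """Sum of edge weights over undirected edges."""
        return float(self.W.sum()) / 2.0

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for (u, v), w in sorted(self._edges.items()):
            yield u, v, w

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def weight(self, u: str, v: str) -> float:
        """Edge weight, 0.0 if the pair is not connected."""
        key = (u, v) if u < v else (v, u)
        return self._edges.get(key, 0.0)

    def has_edge(self, u: str, v: str) -> bool:
        key = (u, v) if u < v else (v, u)
        return key in self._edges

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of neighbors of protein index ``i``."""
        return self.W.indices[self.W.indptr[i] : self.W.indptr[i + 1]]

    def __contains__(self, protein: str) -> bool:
        return protein in self.index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedNetwork)
            and self.proteins == other.proteins
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return f"WeightedNetwork(n={self.n}, edges={self.n_edges})"


def read_network(path, min_weight: float = 0.0) -> WeightedNetwork:
    """Load a 3-column TSV edge list (protein_a, protein_b, confidence).

    '#'-comment lines are skipped; self-loops are dropped with a warning;
    duplicate pairs keep the maximum weight; rows with weight < ``min_weight``
    are dropped; isolated proteins cannot occur (every retained protein sits on
    an edge). Raises :class:`FormatError` on malformed rows, weights outside
    (0, 1], or an empty edge set.
    """
    edges: dict[tuple[str, str], float] = {}
    n_self, n_dup, n_filtered = 0, 0, 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
        u, v, ws = parts
        try:
            w = float(ws)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: weight {ws!r} is not a number") from None
        if not (0.0 < w <= 1.0):
            raise FormatError(f"{path}: line {lineno}: weight {w} outside (0, 1]")
        if u == v:
            n_self += 1
            continue
        if w < min_weight:
            n_filtered += 1
            continue
        key = (u, v) if u < v else (v, u)
        if key in edges:
            n_dup += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if n_self:
        log.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        log.info("%s: merged %d duplicate pair(s), keeping the max weight", path, n_dup)
    if n_filtered:
        log.info("%s: dropped %d edge(s) below min_weight=%g", path, n_filtered, min_weight)
    if not edges:
        raise FormatError(f"{path}: no edges")
    return WeightedNetwork(edges)


def write_network(network: WeightedNetwork, path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{_fmt(w)}\n")


# ---------------------------------------------------------------------------
# DiseaseSimilarityMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseSimilarityMatrix:
    """Symmetric phenotype-similarity matrix with entries in [0, 1], unit diagonal."""

    diseases: tuple[str, ...]
    S: np.ndarray
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        S = np.asarray(self.S, dtype=np.float64)
        object.__setattr__(self, "S", S)
        m = len(self.diseases)
        if len(set(self.diseases)) != m:
            raise FormatError("duplicate disease IDs")
        if S.shape != (m, m):
            raise FormatError(f"similarity matrix shape {S.shape} does not match {m} diseases")
        if not np.array_equal(S, S.T):
            raise FormatError("similarity matrix is not symmetric")
        if S.min() < 0.0 or S.max() > 1.0:
            raise FormatError("similarity values outside [0, 1]")
        if not np.allclose(np.diag(S), 1.0, atol=1e-12):
            raise FormatError("similarity diagonal must be 1")
        object.__setattr__(self, "index", {d: i for i, d in enumerate(self.diseases)})

    def similarity(self, a: str, b: str) -> float:
        return float(self.S[self.index[a], self.index[b]])

    def __contains__(self, disease: str) -> bool:
        return disease in self.index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DiseaseSimilarityMatrix)
            and self.diseases == other.diseases
            and np.array_equal(self.S, other.S)
        )


def read_similarity(path) -> DiseaseSimilarityMatrix:
    """Load a square TSV matrix with disease IDs as header row and first column."""
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        if len(parts) != len(header) + 1:
            raise FormatError(f"{path}: line {lineno}: expected {len(header) + 1} columns")
        try:
            rows[parts[0]] = [float(x) for x in parts[1:]]
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric similarity value") from None
    if header is None or not rows:
        raise FormatError(f"{path}: empty similarity matrix")
    if set(rows) != set(header):
        raise FormatError(f"{path}: row IDs do not match header IDs")
    order = tuple(sorted(header))
    col = {d: i for i, d in enumerate(header)}
    S = np.array([[rows[a][col[b]] for b in order] for a in order], dtype=np.float64)
    return DiseaseSimilarityMatrix(order, S)


def write_similarity(sims: DiseaseSimilarityMatrix, path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("disease\t" + "\t".join(sims.diseases) + "\n")
        for i, d in enumerate(sims.diseases):
            fh.write(d + "\t" + "\t".join(_fmt(x) for x in sims.S[i]) + "\n")


# ---------------------------------------------------------------------------
# AssociationTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationTable:
    """Known (disease, protein) associations with set semantics."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def proteins_for(self, disease: str) -> frozenset[str]:
        return frozenset(p for d, p in self.pairs if d == disease)

    def diseases_for(self, protein: str) -> frozenset[str]:
        return frozenset(d for d, p in self.pairs if p == protein)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for _, p in self.pairs)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    def pairs_of_protein(self, protein: str) -> frozenset[tuple[str, str]]:
        return frozenset((d, p) for d, p in self.pairs if p == protein)

    def excluding(self, hidden: Iterable[tuple[str, str]]) -> "AssociationTable":
        return AssociationTable(self.pairs - frozenset(hidden))

    def __len__(self) -> int:
        return len(self.pairs)


def validate_associations(
    table: AssociationTable,
    network: WeightedNetwork | None = None,
    sims: DiseaseSimilarityMatrix | None = None,
    policy: str = "warn",
) -> AssociationTable:
    """Check referential integrity against companion objects.

    ``policy='warn'`` drops offending pairs with a log warning; ``'strict'``
    raises :class:`FormatError`.
    """
    if policy not in ("warn", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    bad = set()
    for d, p in table.pairs:
        if network is not None and p not in network:
            bad.add((d, p))
        elif sims is not None and d not in sims:
            bad.add((d, p))
    if bad:
        if policy == "strict":
            raise FormatError(f"{len(bad)} association(s) reference unknown protein/disease")
        log.warning("dropping %d association(s) referencing unknown protein/disease", len(bad))
        return AssociationTable(table.pairs - bad)
    return table


def read_associations(
    path,
    network: WeightedNetwork | None = None,
    sims: DiseaseSimilarityMatrix | None = None,
    policy: str = "warn",
) -> AssociationTable:
    """Load a 2-column TSV (disease, protein); duplicates collapse silently."""
    pairs = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        pairs.add((parts[0], parts[1]))
    table = AssociationTable(frozenset(pairs))
    return validate_associations(table, network, sims, policy)


def write_associations(table: AssociationTable, path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for d, p in sorted(table.pairs):
            fh.write(f"{d}\t{p}\n")


# ---------------------------------------------------------------------------
# CandidateInterval
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateInterval:
    """An ordered candidate gene list (genomic order) tied to one disease."""

    disease: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise FormatError("interval must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise FormatError("interval members must be unique")

    def __contains__(self, protein: str) -> bool:
        return protein in self.members

    def __len__(self) -> int:
        return len(self.members)


def read_interval(path) -> CandidateInterval:
    """One protein ID per line; the disease ID comes from a '# disease=ID' header."""
    disease = ""
    members: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("disease="):
                    disease = body[len("disease="):].strip()
                continue
            members.append(line)
    return CandidateInterval(disease, tuple(members))


def write_interval(interval: CandidateInterval, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# disease={interval.disease}\n")
        for p in interval.members:
            fh.write(p + "\n")


def read_id_list(path) -> tuple[str, ...]:
    """Plain one-ID-per-line list (e.g. a synthetic genome ordering)."""
    out = []
    for _, line in _data_lines(path):
        out.append(line.strip())
    if not out:
        raise FormatError(f"{path}: empty ID list")
    return tuple(out)


def write_id_list(ids: Iterable[str], path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p in ids:
            fh.write(p + "\n")


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named protein sets (annotation terms, complex collections)."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "sets", {name: frozenset(m) for name, m in dict(self.sets).items()}
        )
        object.__setattr__(self, "descriptions", dict(self.descriptions))

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.sets.values():
            out |= m
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and dict(self.sets) == dict(other.sets)


def read_gene_sets(path) -> GeneSetCollection:
    """GMT format: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, frozenset[str]] = {}
    descr: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT rows need name, description, >=1 member")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(parts[2:])
        descr[name] = parts[1]
    if not sets:
        raise FormatError(f"{path}: empty gene-set file")
    return GeneSetCollection(sets, descr)


def write_gene_sets(collection: GeneSetCollection, path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for name in collection.names():
            desc = collection.descriptions.get(name, "na") or "na"
            members = "\t".join(sorted(collection.members(name)))
            fh.write(f"{name}\t{desc}\t{members}\n")
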