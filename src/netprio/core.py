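"""Domain types shared across the package.

A gene network is an undirected weighted graph over an ordered *gene
universe*; every matrix in the package (adjacency, kernel Gram, score
vector) is indexed by the position of a gene in that universe.  Matrices
are stored dense: the workloads this package targets stay well below
n ~ 10^4 genes, and q-step kernel powers densify regardless of the input
sparsity.  An absent edge is an exact zero entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GeneUniverse",
    "WeightedNetwork",
    "BipartiteAssociation",
    "KernelMatrix",
    "GeneSetCollection",
    "ScoreVector",
]


class GeneUniverse:
    """Ordered collection of unique gene identifiers.

    Defines the row/column indexing (0-based) of every matrix built over
    it.  Identifiers are opaque, case-sensitive strings.
    """

    __slots__ = ("genes", "index")

    def __init__(self, genes: Iterable[str]):
        genes = tuple(str(g) for g in genes)
        index = {g: i for i, g in enumerate(genes)}
        if len(index) != len(genes):
            seen: set[str] = set()
            dup = next(g for g in genes if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        self.genes = genes
        self.index = index

    @property
    def n(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneUniverse) and self.genes == other.genes

    def __hash__(self) -> int:
        return hash(self.genes)

    def __repr__(self) -> str:
        return f"GeneUniverse(n={self.n})"

    def indices_of(self, genes: Iterable[str]) -> np.ndarray:
        """Integer positions of ``genes``; raises KeyError on foreign ids."""
        return np.fromiter((self.index[g] for g in genes), dtype=np.intp)

    @classmethod
    def union(cls, *gene_iterables: Iterable[str]) -> "GeneUniverse":
        """Universe over the union of identifiers, first-seen order."""
        seen: dict[str, None] = {}
        for it in gene_iterables:
            for g in it:
                seen.setdefault(str(g), None)
        return cls(seen)


def _check_square_symmetric(m: np.ndarray, n: int, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"{what} must be {n}x{n}, got {m.shape}")
    if not np.allclose(m, m.T, rtol=0.0, atol=1e-8):
        raise ValueError(f"{what} must be symmetric")
    return m


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative adjacency matrix over a gene universe.

    ``coverage`` marks which genes the original data source actually
    contained; after zero-fill alignment a gene can be *present* in the
    matrix yet uncovered by the source, which matters for per-edge
    averaging during integration.
    """

    universe: GeneUniverse
    weights: np.ndarray
    name: str = ""
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = _check_square_symmetric(self.weights, self.universe.n, "adjacency")
        if (self.weights < 0).any():
            raise ValueError("adjacency weights must be nonnegative")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=bool)
            if self.coverage.shape != (self.universe.n,):
                raise ValueError("coverage mask length must equal universe size")

    @property
    def n(self) -> int:
        return self.universe.n

    @property
    def coverage_mask(self) -> np.ndarray:
        """Boolean per-gene presence mask (all True if never aligned)."""
        if self.coverage is None:
            return np.ones(self.n, dtype=bool)
        return self.coverage

    def edge_weights(self) -> np.ndarray:
        """Weights of the distinct edges (upper triangle, nonzero)."""
        iu, ju = np.triu_indices(self.n, k=1)
        w = self.weights[iu, ju]
        return w[w > 0]

    @property
    def n_edges(self) -> int:
        return int(self.edge_weights().size)

    def replace_weights(self, weights: np.ndarray, name: str | None = None) -> "WeightedNetwork":
        return WeightedNetwork(
            self.universe, weights, self.name if name is None else name, self.coverage
        )

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class BipartiteAssociation:
    """Gene x entity incidence table (entities: modules, chemicals, genes...)."""

    top: GeneUniverse
    bottom: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.bottom = tuple(str(b) for b in self.bottom)
        if len(set(self.bottom)) != len(self.bottom):
            raise ValueError("duplicate bottom entity identifiers")
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.shape != (self.top.n, len(self.bottom)):
            raise ValueError(
                f"incidence must be {self.top.n}x{len(self.bottom)}, got {self.incidence.shape}"
            )
        if (self.incidence < 0).any():
            raise ValueError("incidence entries must be nonnegative")


@dataclass
class KernelMatrix:
    """Symmetric Gram matrix of a (q-step) random-walk kernel.

    ``a`` is the diagonal-shift parameter of the one-step kernel
    K = (a-1) I + D^{-1/2} W D^{-1/2} (a > 1; a >= 2 guarantees positive
    semidefiniteness) and ``q`` the number of walk steps.
    """

    universe: GeneUniverse
    gram: np.ndarray
    a: float = 2.0
    q: int = 1

    def __post_init__(self) -> None:
        self.gram = _check_square_symmetric(self.gram, self.universe.n, "gram matrix")
        if self.a <= 1:
            raise ValueError(f"kernel parameter a must be > 1, got {self.a}")
        if self.q < 1:
            raise ValueError(f"step count q must be >= 1, got {self.q}")

    @property
    def n(self) -> int:
        return self.universe.n


class GeneSetCollection(Mapping[str, frozenset]):
    """Mapping from disease identifier to its non-empty seed gene set.

    Every member gene must resolve in the reference universe.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: GeneUniverse):
        self.universe = universe
        clean: dict[str, frozenset] = {}
        for disease, genes in sets.items():
            members = frozenset(str(g) for g in genes)
            if not members:
                raise ValueError(f"gene set {disease!r} is empty")
            foreign = members - set(universe.index)
            if foreign:
                raise ValueError(
                    f"gene set {disease!r} has members outside the universe: "
                    f"{sorted(foreign)[:5]}"
                )
            clean[str(disease)] = members
        self.sets = clean

    def __getitem__(self, disease: str) -> frozenset:
        return self.sets[disease]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {d: len(g) for d, g in self.sets.items()}

    def indices_of(self, disease: str) -> np.ndarray:
        """Sorted universe indices of the disease's seed genes."""
        return np.sort(self.universe.indices_of(self.sets[disease]))

    def label_vector(self, disease: str) -> np.ndarray:
        """Boolean positive-label vector over the universe."""
        y = np.zeros(self.universe.n, dtype=bool)
        y[self.indices_of(disease)] = True
        return y

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets over {self.universe!r})"


@dataclass
class ScoreVector:
    """One real-valued prioritization score per gene of the universe."""

    universe: GeneUniverse
    disease_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.universe.n,):
            raise ValueError("score vector length must equal universe size")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def ranking(self) -> list[tuple[str, float]]:
        """Genes sorted by descending score, ties broken lexicographically."""
        order = sorted(
            range(self.universe.n),
            key=lambda i: (-self.scores[i], self.universe.genes[i]),
        )
        return [(self.universe.genes[i], float(self.scores[i])) for i in order]
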