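"""Gene ranking algorithms.

Two families:

* *Kernelized score functions* read similarities off a (q-step random
  walk) kernel Gram matrix K and score every gene against the seed set
  V_M: nearest neighbour S_NN(i) = max_{j in V_M} K(i,j); k-nearest
  neighbours S_kNN(i) = sum of the k largest K(i,j) over the seeds;
  average score S_AV(i) = -K(i,i)/2 + mean_{j in V_M} K(i,j) (the self
  term can be dropped when kernel diagonals are constant — ranking is
  then unchanged).

* *Label propagation*: random walk p <- Q^T p with Q = D^{-1} W from the
  uniform seed distribution (RW), its restarting variant
  p <- (1-theta) Q^T p + theta p0 iterated to the steady state (RWR),
  and the guilt-by-association baseline scoring a gene by its heaviest
  edge to a seed.

Seeds are scored alongside every other gene; masking them is the
evaluation protocol's job, because seed status depends on the
cross-validation fold.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .core import GeneUniverse, KernelMatrix, ScoreVector, WeightedNetwork

__all__ = [
    "score_nn",
    "score_knn",
    "score_av",
    "rw",
    "rwr",
    "gba",
    "transition_matrix",
    "build_scorer",
    "KERNEL_METHODS",
    "NETWORK_METHODS",
]

KERNEL_METHODS = ("sav", "sknn", "snn")
NETWORK_METHODS = ("rw", "rwr", "gba")


def _seed_indices(universe: GeneUniverse, seeds: Iterable[str]) -> np.ndarray:
    idx = universe.indices_of(set(seeds))
    if idx.size == 0:
        raise ValueError("seed set must be non-empty")
    return np.sort(idx)


# ---------------------------------------------------------------------------
# kernelized score functions — index-based kernels shared with evaluation

def _nn_scores(gram: np.ndarray, seed_idx: np.ndarray) -> np.ndarray:
    return gram[:, seed_idx].max(axis=1)


def _knn_scores(gram: np.ndarray, seed_idx: np.ndarray, k: int) -> np.ndarray:
    sub = gram[:, seed_idx]
    if k >= seed_idx.size:
        return sub.sum(axis=1)
    part = np.partition(sub, sub.shape[1] - k, axis=1)
    return part[:, -k:].sum(axis=1)


def _av_scores(gram: np.ndarray, seed_idx: np.ndarray, drop_self_term: bool) -> np.ndarray:
    s = gram[:, seed_idx].mean(axis=1)
    if not drop_self_term:
        s = s - 0.5 * np.diag(gram)
    return s


def score_nn(kernel: KernelMatrix, seeds: Iterable[str]) -> ScoreVector:
    """Nearest-neighbour score: similarity to the closest seed gene."""
    idx = _seed_indices(kernel.universe, seeds)
    return ScoreVector(kernel.universe, "", _nn_scores(kernel.gram, idx))


def score_knn(kernel: KernelMatrix, seeds: Iterable[str], k: int = 19) -> ScoreVector:
    """k-nearest-neighbour score: summed similarity to the k closest seeds.

    With k >= |seeds| the sum runs over the whole seed set; k = 1 reduces
    to the nearest-neighbour score.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    idx = _seed_indices(kernel.universe, seeds)
    return ScoreVector(kernel.universe, "", _knn_scores(kernel.gram, idx, k))


def score_av(
    kernel: KernelMatrix, seeds: Iterable[str], drop_self_term: bool = False
) -> ScoreVector:
    """Average score: mean similarity to the seeds minus half the self-similarity.

    ``drop_self_term`` omits the -K(i,i)/2 term; when the kernel diagonal
    is constant this shifts every score equally and the ranking is
    identical.  q-step kernel diagonals are generally unequal, so the
    full form is the default.
    """
    idx = _seed_indices(kernel.universe, seeds)
    return ScoreVector(kernel.universe, "", _av_scores(kernel.gram, idx, drop_self_term))


# ---------------------------------------------------------------------------
# label propagation

def transition_matrix(net: WeightedNetwork) -> np.ndarray:
    """Row-stochastic transition matrix Q = D^{-1} W.

    Zero-degree genes get a self-transition of 1 so that every row sums
    to one and probability mass is conserved even on disconnected or
    heavily filtered networks.
    """
    d = net.degrees()
    q = np.zeros_like(net.weights)
    nz = d > 0
    q[nz] = net.weights[nz] / d[nz, None]
    zero = np.flatnonzero(~nz)
    q[zero, zero] = 1.0
    return q


def _seed_distribution(n: int, seed_idx: np.ndarray) -> np.ndarray:
    p0 = np.zeros(n)
    p0[seed_idx] = 1.0 / seed_idx.size
    return p0


def rw(net: WeightedNetwork, seeds: Iterable[str], steps: int = 5) -> ScoreVector:
    """Random-walk propagation for a fixed number of steps.

    Starts from the uniform distribution over the seeds and applies
    p <- Q^T p ``steps`` times.  Run for only a few steps: iterated too
    long the walk forgets the seed information and drifts toward the
    stationary distribution of the graph.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    idx = _seed_indices(net.universe, seeds)
    qt = transition_matrix(net).T
    p = _seed_distribution(net.n, idx)
    for _ in range(steps):
        p = qt @ p
    return ScoreVector(net.universe, "", p)


def rwr(
    net: WeightedNetwork,
    seeds: Iterable[str],
    theta: float = 0.6,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ScoreVector:
    """Random walk with restart, iterated to its steady state.

    At every step the walker restarts from the seed distribution with
    probability ``theta``; iteration stops when the L1 change drops below
    ``tol`` (or after ``max_iter`` sweeps).
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"restart probability theta must be in (0, 1], got {theta}")
    idx = _seed_indices(net.universe, seeds)
    qt = transition_matrix(net).T
    p0 = _seed_distribution(net.n, idx)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - theta) * (qt @ p) + theta * p0
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    return ScoreVector(net.universe, "", p)


def gba(net: WeightedNetwork, seeds: Iterable[str]) -> ScoreVector:
    """Guilt by association: heaviest edge weight to any seed gene (0 if none)."""
    idx = _seed_indices(net.universe, seeds)
    return ScoreVector(net.universe, "", net.weights[:, idx].max(axis=1))


# ---------------------------------------------------------------------------
# scorer factory used by the evaluation protocol and CLI

def build_scorer(
    method: str,
    *,
    kernel: KernelMatrix | None = None,
    network: WeightedNetwork | None = None,
    k: int = 19,
    drop_self_term: bool = False,
    steps: int = 5,
    theta: float = 0.6,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> Callable[[np.ndarray], np.ndarray]:
    """Bind a method name and its data to a seed-indices -> scores callable.

    Kernel methods ('sav', 'sknn', 'snn') require ``kernel``; propagation
    methods ('rw', 'rwr', 'gba') require ``network``.  The returned
    callable takes an integer array of seed indices, which is what the
    cross-validation loop manipulates.
    """
    method = method.lower()
    if method in KERNEL_METHODS:
        if kernel is None:
            raise ValueError(f"method {method!r} needs a kernel matrix")
        gram = kernel.gram
        if method == "sav":
            return lambda idx: _av_scores(gram, idx, drop_self_term)
        if method == "snn":
            return lambda idx: _nn_scores(gram, idx)
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        return lambda idx: _knn_scores(gram, idx, k)
    if method in NETWORK_METHODS:
        if network is None:
            raise ValueError(f"method {method!r} needs a network")
        if method == "gba":
            w = network.weights
            return lambda idx: w[:, idx].max(axis=1)
        qt = transition_matrix(network).T
        n = network.n
        if method == "rw":
            if steps < 0:
                raise ValueError("steps must be >= 0")

            def _rw(idx: np.ndarray) -> np.ndarray:
                p = _seed_distribution(n, idx)
                for _ in range(steps):
                    p = qt @ p
                return p

            return _rw
        if not 0.0 < theta <= 1.0:
            raise ValueError(f"restart probability theta must be in (0, 1], got {theta}")

        def _rwr(idx: np.ndarray) -> np.ndarray:
            p0 = _seed_distribution(n, idx)
            p = p0.copy()
            for _ in range(max_iter):
                p_next = (1.0 - theta) * (qt @ p) + theta * p0
                if np.abs(p_next - p).sum() < tol:
                    return p_next
                p = p_next
            return p

        return _rwr
    raise ValueError(f"unknown method {method!r}; choose from {KERNEL_METHODS + NETWORK_METHODS}")
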