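"""Combining multiple gene networks (or kernel matrices) into one.

Unweighted operators depend only on the edge weights themselves:

  UA   mean over all networks, zeros included
  PUA  mean over only the networks that contain *both* genes of the pair
  MAX  elementwise maximum (union of evidence)
  MIN  elementwise minimum — "drastic" (a single zero kills the edge) or
       "soft" (minimum over the nonzero weights only)

Weighted operators first learn a per-network weight gamma from how well a
ranking method performs on each network alone (measured e.g. by AUC per
disease), then average:

  WAP  per-disease weights gamma^d(k), one integrated network per disease
  WA   class-averaged weights gamma^d = mean_k gamma^d(k), one network
       for all diseases (a regularized WAP, less prone to overfitting)

Every operator is elementwise, so it applies unchanged to kernel Gram
matrices in place of adjacencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import GeneUniverse, KernelMatrix, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkCollection",
    "GammaWeights",
    "integrate_ua",
    "integrate_pua",
    "integrate_max",
    "integrate_min",
    "compute_gamma",
    "integrate_wap",
    "integrate_wa",
]

Member = Union[WeightedNetwork, KernelMatrix]


class NetworkCollection:
    """Networks (or kernel matrices) aligned to one shared gene universe."""

    def __init__(self, members: Sequence[Member]):
        if not members:
            raise ValueError("collection must contain at least one member")
        self.members = list(members)
        self.universe: GeneUniverse = members[0].universe
        for m in members[1:]:
            if m.universe != self.universe:
                raise ValueError("all members must share the same gene universe")
        kinds = {type(m) for m in members}
        if len(kinds) > 1:
            raise ValueError("cannot mix adjacency networks and kernel matrices")
        names = [self._name(i) for i in range(len(members))]
        if len(set(names)) != len(names):
            raise ValueError(f"member names must be unique, got {names}")
        self.names = names

    def _name(self, i: int) -> str:
        m = self.members[i]
        name = getattr(m, "name", "") or f"net{i}"
        return name

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_kernel(self) -> bool:
        return isinstance(self.members[0], KernelMatrix)

    def matrices(self) -> np.ndarray:
        """Stacked (n_members, n, n) array of the member matrices."""
        return np.stack(
            [m.gram if isinstance(m, KernelMatrix) else m.weights for m in self.members]
        )

    def coverage(self) -> np.ndarray:
        """(n_members, n) boolean per-member gene-presence masks."""
        return np.stack(
            [
                m.coverage_mask if isinstance(m, WeightedNetwork) else np.ones(m.n, dtype=bool)
                for m in self.members
            ]
        )

    def wrap(self, matrix: np.ndarray, name: str) -> Member:
        """Package an integrated matrix as the collection's member type."""
        if self.is_kernel:
            first: KernelMatrix = self.members[0]  # type: ignore[assignment]
            return KernelMatrix(self.universe, matrix, a=first.a, q=first.q)
        return WeightedNetwork(self.universe, matrix, name=name)


def integrate_ua(col: NetworkCollection) -> Member:
    """Unweighted average; absent edges contribute zeros to the mean."""
    return col.wrap(col.matrices().mean(axis=0), "UA")


def integrate_pua(col: NetworkCollection) -> Member:
    """Per-edge unweighted average over the networks covering both genes.

    A network "contains" the pair (i, j) iff its coverage mask holds both
    genes; pairs covered by no network get weight 0.
    """
    mats = col.matrices()
    cov = col.coverage().astype(float)
    pair_counts = np.einsum("di,dj->ij", cov, cov)
    total = mats.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pair_counts > 0, total / np.maximum(pair_counts, 1.0), 0.0)
    return col.wrap(out, "PUA")


def integrate_max(col: NetworkCollection) -> Member:
    """Elementwise maximum: the union of all sources of evidence."""
    return col.wrap(col.matrices().max(axis=0), "MAX")


def integrate_min(col: NetworkCollection, mode: str = "drastic") -> Member:
    """Elementwise minimum: the intersection of the networks.

    ``drastic``: plain minimum, so a single zero weight removes the edge.
    ``soft``: minimum over the nonzero weights only; the edge is 0 only
    when every network misses it.
    """
    mats = col.matrices()
    if mode == "drastic":
        return col.wrap(mats.min(axis=0), "MIN-drastic")
    if mode != "soft":
        raise ValueError(f"mode must be 'drastic' or 'soft', got {mode!r}")
    masked = np.where(mats != 0, mats, np.inf)
    out = masked.min(axis=0)
    out[~np.isfinite(out)] = 0.0
    return col.wrap(out, "MIN-soft")


# ---------------------------------------------------------------------------
# weighted integration

@dataclass
class GammaWeights:
    """Per-network integration weights derived from an accuracy metric.

    ``per_class`` holds gamma^d(k): rows are disease classes, columns are
    networks, each row summing to 1.  ``metrics`` keeps the raw metric
    values M^d(k) (e.g. per-network AUCs) the weights derive from.
    """

    per_class: pd.DataFrame
    metrics: pd.DataFrame
    transform: str = "linear"
    b: float = 0.99

    def __post_init__(self) -> None:
        sums = self.per_class.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-class gamma rows must each sum to 1")
        if (self.per_class.values < 0).any():
            raise ValueError("gamma weights must be nonnegative")

    def averaged(self) -> pd.Series:
        """Class-averaged weights gamma^d = mean_k gamma^d(k) (sum to 1)."""
        return self.per_class.mean(axis=0)

    def for_class(self, disease: str) -> pd.Series:
        return self.per_class.loc[disease]


def compute_gamma(
    metrics: pd.DataFrame | Mapping[str, Mapping[str, float]],
    transform: str = "linear",
    b: float = 0.99,
) -> GammaWeights:
    """Turn per-disease, per-network accuracy metrics into gamma weights.

    ``metrics`` rows are diseases, columns are networks, values in [0, 1]
    (AUC, precision at a recall, ...).  ``linear`` normalizes each row to
    sum 1; ``log`` uses log(1 - min(M, b)) / sum_j log(1 - min(M_j, b)),
    which emphasizes the most informative networks — the upper bound
    b < 1 keeps the logarithm finite when a metric reaches 1.
    """
    m = pd.DataFrame(metrics).astype(float)
    if m.empty:
        raise ValueError("metrics table is empty")
    if (m.values < 0).any() or (m.values > 1).any():
        raise ValueError("metric values must lie in [0, 1]")
    if transform == "linear":
        raw = m.values.copy()
    elif transform == "log":
        if not b < 1:
            raise ValueError(f"upper bound b must be < 1, got {b}")
        raw = np.log1p(-np.minimum(m.values, b))
    else:
        raise ValueError(f"transform must be 'linear' or 'log', got {transform!r}")
    sums = raw.sum(axis=1, keepdims=True)
    degenerate = np.abs(sums[:, 0]) < 1e-300
    if degenerate.any():
        logger.warning(
            "%d disease(s) with an all-degenerate metric row; using uniform weights",
            int(degenerate.sum()),
        )
        raw[degenerate] = 1.0
        sums = raw.sum(axis=1, keepdims=True)
    gamma = pd.DataFrame(raw / sums, index=m.index, columns=m.columns)
    return GammaWeights(gamma, m, transform=transform, b=b)


def _weighted_sum(col: NetworkCollection, gamma: pd.Series, name: str) -> Member:
    missing = set(col.names) - set(gamma.index)
    if missing:
        raise ValueError(f"gamma weights missing for network(s): {sorted(missing)}")
    g = gamma.reindex(col.names).to_numpy(dtype=float)
    out = np.tensordot(g, col.matrices(), axes=(0, 0))
    return col.wrap(out, name)


def integrate_wap(col: NetworkCollection, gamma: GammaWeights, disease: str) -> Member:
    """Weighted average per class: the integrated network for one disease."""
    return _weighted_sum(col, gamma.for_class(disease), f"WAP[{disease}]")


def integrate_wa(col: NetworkCollection, gamma: GammaWeights) -> Member:
    """Weighted average with class-averaged weights: one network for all diseases."""
    return _weighted_sum(col, gamma.averaged(), "WA")
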