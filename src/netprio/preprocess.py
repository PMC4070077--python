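"""Network pre-processing and bipartite projections.

Pre-processing makes heterogeneous networks comparable before they are
combined: weak edges are filtered at a per-network threshold chosen so
that no gene loses its last connection, surviving weights are linearly
rescaled to [0, 1], and every network is aligned (zero-filled) to a
shared gene universe.  Bipartite gene-entity tables are collapsed to
gene-gene networks through shared-neighbour projections.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import BipartiteAssociation, GeneUniverse, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "select_threshold",
    "filter_edges",
    "linear_rescale",
    "align_to_universe",
    "binary_projection",
    "sum_projection",
    "binarize",
]


def select_threshold(net: WeightedNetwork) -> float:
    """Largest edge-filter threshold that leaves every gene connected.

    For each gene take the maximum weight over its incident edges; the
    threshold is the minimum of those per-gene maxima.  Filtering with an
    inclusive keep at this value is then guaranteed to leave every gene
    with at least one edge.
    """
    col_max = net.weights.max(axis=1)
    if (col_max <= 0).any():
        isolated = [g for g, m in zip(net.universe.genes, col_max) if m <= 0]
        raise ValueError(
            f"threshold undefined: {len(isolated)} isolated gene(s), e.g. {isolated[:3]}"
        )
    return float(col_max.min())


def filter_edges(net: WeightedNetwork, threshold: float) -> WeightedNetwork:
    """Drop edges with weight strictly below ``threshold`` (inclusive keep)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = np.where(net.weights >= threshold, net.weights, 0.0)
    return net.replace_weights(w)


def linear_rescale(net: WeightedNetwork) -> WeightedNetwork:
    """Affinely map the surviving edge weights onto [0, 1].

    min and max are taken over the *present* edges only — a zero entry
    means "no evidence", not "evidence of weight zero", and including
    structural zeros would pin the minimum at 0 for every sparse network
    and defeat cross-network comparability.  If all surviving edges share
    one weight the map is degenerate and they are all set to 1, so binary
    networks pass through unchanged.
    """
    w = net.weights
    mask = w > 0
    if not mask.any():
        raise ValueError("cannot rescale a network with no edges")
    lo = w[mask].min()
    hi = w[mask].max()
    out = np.zeros_like(w)
    if hi == lo:
        out[mask] = 1.0
    else:
        out[mask] = (w[mask] - lo) / (hi - lo)
    return net.replace_weights(out)


def align_to_universe(net: WeightedNetwork, universe: GeneUniverse) -> WeightedNetwork:
    """Embed the network into ``universe``, zero-filling missing genes.

    Genes of the network absent from the target universe are dropped with
    a warning.  The returned network carries a coverage mask recording
    which universe genes the source network actually contained; per-edge
    averaging (PUA) needs it to know which networks "contain" a gene pair.
    """
    src = net.universe
    kept = [g for g in src.genes if g in universe]
    if len(kept) < src.n:
        logger.warning(
            "%s: dropping %d gene(s) not in the target universe", net.name, src.n - len(kept)
        )
    w = np.zeros((universe.n, universe.n))
    src_idx = src.indices_of(kept)
    dst_idx = universe.indices_of(kept)
    w[np.ix_(dst_idx, dst_idx)] = net.weights[np.ix_(src_idx, src_idx)]
    coverage = np.zeros(universe.n, dtype=bool)
    coverage[dst_idx] = True
    return WeightedNetwork(universe, w, name=net.name, coverage=coverage)


def sum_projection(bip: BipartiteAssociation) -> WeightedNetwork:
    """Project a bipartite table to genes: w(i,j) = number of shared neighbours."""
    inc = (bip.incidence > 0).astype(float)
    w = inc @ inc.T
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(bip.top, w, name="sum_projection")


def binary_projection(bip: BipartiteAssociation) -> WeightedNetwork:
    """Project to genes with w(i,j) = 1 iff i and j share >= 1 neighbour."""
    net = binarize(sum_projection(bip), cutoff=1.0)
    net.name = "binary_projection"
    return net


def binarize(net: WeightedNetwork, cutoff: float) -> WeightedNetwork:
    """Set w(i,j) to 1 where w(i,j) >= cutoff, else 0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    w = (net.weights >= cutoff).astype(float)
    np.fill_diagonal(w, 0.0)
    return net.replace_weights(w)


def preprocess_network(
    net: WeightedNetwork,
    universe: GeneUniverse,
    threshold: float | str = "auto",
    rescale: bool = True,
) -> WeightedNetwork:
    """Full pipeline: threshold-filter, rescale, align to the universe."""
    if threshold == "auto":
        threshold = select_threshold(net)
    if threshold:
        net = filter_edges(net, float(threshold))
    if rescale:
        net = linear_rescale(net)
    return align_to_universe(net, universe)


__all__.append("preprocess_network")
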