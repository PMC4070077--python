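"""Synthetic multi-network benchmarks with planted disease structure.

The generator emulates the study design the package targets: several
heterogeneous functional networks over one shared gene universe, each
with its own "informativeness" for a collection of overlapping disease
gene sets.  Diseases are random gene subsets (a planted-*set* model —
sets may overlap, as real disease annotations do).  In network d with
informativeness iota_d, a gene pair sharing at least one disease gets an
edge with probability p_in * iota_d + p_out * (1 - iota_d); all other
pairs with probability p_out.  iota = 1 gives a maximally informative
network, iota = 0 pure noise.  Edge weights are 1 times multiplicative
lognormal jitter so that [0, 1] rescaling is non-trivial, and a coverage
fraction < 1 removes random genes from a network to exercise zero-fill
alignment and per-edge averaging.

Everything is driven by one integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneSetCollection, GeneUniverse, WeightedNetwork
from .integration import NetworkCollection
from . import io as npio

__all__ = ["FixtureSpec", "generate", "write_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic benchmark.

    Defaults are sized for desk experiments: 500 genes, 20 diseases of
    5-40 genes, three networks of decreasing informativeness
    (0.9, 0.5, 0.0 — strong signal, weak signal, pure noise), within-set
    edge probability 0.3 against a 0.02 background, and lognormal weight
    jitter with sigma 0.25.
    """

    n_genes: int = 500
    n_diseases: int = 20
    set_size: tuple[int, int] = (5, 40)
    p_in: float = 0.3
    p_out: float = 0.02
    informativeness: tuple[float, ...] = (0.9, 0.5, 0.0)
    weight_noise: float = 0.25
    coverage: tuple[float, ...] | float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid set size range {self.set_size}")
        if hi > self.n_genes:
            raise ValueError(f"set size {hi} exceeds n_genes={self.n_genes}")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        for iota in self.informativeness:
            if not 0.0 <= iota <= 1.0:
                raise ValueError(f"informativeness must be in [0, 1], got {iota}")
        if isinstance(self.coverage, (int, float)):
            self.coverage = (float(self.coverage),) * len(self.informativeness)
        if len(self.coverage) != len(self.informativeness):
            raise ValueError("one coverage fraction per network required")
        for c in self.coverage:
            if not 0.0 < c <= 1.0:
                raise ValueError(f"coverage must be in (0, 1], got {c}")


def generate(
    spec: FixtureSpec,
) -> tuple[NetworkCollection, GeneSetCollection, pd.DataFrame]:
    """Draw a benchmark: networks, disease sets and the ground-truth table.

    The truth table records, per network, its planted informativeness,
    the resulting within-set edge probability and the coverage fraction
    — the quantities a parameter-recovery experiment tries to get back.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    width = len(str(n - 1))
    universe = GeneUniverse(f"g{i:0{width}d}" for i in range(n))

    lo, hi = spec.set_size
    membership = np.zeros((n, spec.n_diseases), dtype=bool)
    sets = {}
    for k in range(spec.n_diseases):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(n, size=size, replace=False)
        membership[idx, k] = True
        sets[f"D{k:03d}"] = [universe.genes[i] for i in idx]
    gene_sets = GeneSetCollection(sets, universe)

    share = (membership.astype(np.int32) @ membership.T.astype(np.int32)) > 0
    iu, ju = np.triu_indices(n, k=1)
    shared_pair = share[iu, ju]

    members = []
    truth_rows = []
    for d, (iota, cov) in enumerate(zip(spec.informativeness, spec.coverage)):
        p_within = spec.p_in * iota + spec.p_out * (1.0 - iota)
        probs = np.where(shared_pair, p_within, spec.p_out)
        drawn = rng.random(iu.size) < probs
        weights = np.zeros((n, n))
        if spec.weight_noise > 0:
            vals = rng.lognormal(mean=0.0, sigma=spec.weight_noise, size=int(drawn.sum()))
        else:
            vals = np.ones(int(drawn.sum()))
        weights[iu[drawn], ju[drawn]] = vals
        weights += weights.T
        coverage_mask = np.ones(n, dtype=bool)
        if cov < 1.0:
            n_present = max(1, int(round(cov * n)))
            present = rng.choice(n, size=n_present, replace=False)
            coverage_mask = np.zeros(n, dtype=bool)
            coverage_mask[present] = True
            weights[~coverage_mask, :] = 0.0
            weights[:, ~coverage_mask] = 0.0
        name = f"net{d + 1}"
        members.append(WeightedNetwork(universe, weights, name=name, coverage=coverage_mask))
        truth_rows.append(
            {
                "network": name,
                "informativeness": iota,
                "p_within": p_within,
                "p_background": spec.p_out,
                "coverage": cov,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("network")
    return NetworkCollection(members), gene_sets, truth


def write_fixture(
    col: NetworkCollection,
    sets: GeneSetCollection,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the benchmark as edge-list TSVs, a GMT and a truth TSV."""
    if len(col) == 0:
        raise ValueError("empty network collection")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, member in zip(col.names, col.members):
        path = out_dir / f"{name}.tsv"
        npio.write_edge_list(member, path)
        written.append(path)
    gmt = out_dir / "disease_sets.gmt"
    npio.write_gmt(sets, gmt)
    written.append(gmt)
    if truth is not None:
        tpath = out_dir / "truth.tsv"
        truth.to_csv(tpath, sep="\t")
        written.append(tpath)
    return written
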