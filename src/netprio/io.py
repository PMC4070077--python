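"""Readers and writers for the plain-text interchange formats.

Formats:
  * edge list  — TSV ``geneA geneB weight``; ``#`` comment lines skipped
  * bipartite  — TSV ``gene entity [weight]``
  * gene sets  — GMT (``set-id  description  gene ...``)
  * ranking    — TSV ``rank gene score annotated``
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import (
    BipartiteAssociation,
    GeneSetCollection,
    GeneUniverse,
    ScoreVector,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_bipartite",
    "read_gmt",
    "write_gmt",
    "write_ranking",
    "read_ranking",
    "write_kernel_tsv",
    "read_kernel_tsv",
]


def _data_lines(path: str | Path):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, universe: GeneUniverse | None = None) -> WeightedNetwork:
    """Read a weighted undirected network from a 3-column TSV edge list.

    Duplicate records for the same gene pair keep the *maximum* weight
    (conservative union of evidence); self-edges are dropped.  When
    ``universe`` is given, it fixes the matrix indexing and edges whose
    genes fall outside it are dropped with a warning; otherwise the
    universe is built from the genes seen in the file, in file order.
    """
    path = Path(path)
    records: dict[tuple[str, str], float] = {}
    order: dict[str, None] = {}
    n_self = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
        ga, gb, wtxt = parts[0], parts[1], parts[2]
        try:
            w = float(wtxt)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable weight {wtxt!r}") from None
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"{path}:{lineno}: negative or non-finite weight {wtxt!r}")
        order.setdefault(ga, None)
        order.setdefault(gb, None)
        if ga == gb:
            n_self += 1
            continue
        key = (ga, gb) if ga < gb else (gb, ga)
        prev = records.get(key)
        if prev is None or w > prev:
            records[key] = w
    if n_self:
        logger.warning("%s: dropped %d self-edge record(s)", path.name, n_self)

    if universe is None:
        universe = GeneUniverse(order)
        dropped = 0
    else:
        foreign = [g for g in order if g not in universe]
        dropped = 0
        if foreign:
            for key in list(records):
                if key[0] not in universe or key[1] not in universe:
                    del records[key]
                    dropped += 1
            logger.warning(
                "%s: %d gene(s) outside the given universe; %d edge(s) dropped",
                path.name, len(foreign), dropped,
            )

    w = np.zeros((universe.n, universe.n))
    for (ga, gb), val in records.items():
        i, j = universe.index[ga], universe.index[gb]
        w[i, j] = w[j, i] = val
    return WeightedNetwork(universe, w, name=path.stem)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write the nonzero upper-triangle edges as a 3-column TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# geneA\tgeneB\tweight\n")
        iu, ju = np.triu_indices(net.n, k=1)
        for i, j in zip(iu, ju):
            w = net.weights[i, j]
            if w > 0:
                fh.write(f"{net.universe.genes[i]}\t{net.universe.genes[j]}\t{float(w)!r}\n")


def read_bipartite(path: str | Path, universe: GeneUniverse | None = None) -> BipartiteAssociation:
    """Read a gene-entity incidence table (TSV: gene, entity[, weight])."""
    path = Path(path)
    records: dict[tuple[str, str], float] = {}
    gene_order: dict[str, None] = {}
    entity_order: dict[str, None] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
        gene, entity = parts[0], parts[1]
        w = 1.0
        if len(parts) >= 3 and parts[2] != "":
            try:
                w = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable weight {parts[2]!r}") from None
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight")
        gene_order.setdefault(gene, None)
        entity_order.setdefault(entity, None)
        key = (gene, entity)
        records[key] = max(records.get(key, 0.0), w)
    if universe is None:
        universe = GeneUniverse(gene_order)
    else:
        foreign = [g for g in gene_order if g not in universe]
        if foreign:
            logger.warning("%s: dropped %d gene(s) outside the universe", path.name, len(foreign))
            records = {k: v for k, v in records.items() if k[0] in universe}
    bottom = tuple(entity_order)
    entity_index = {b: j for j, b in enumerate(bottom)}
    inc = np.zeros((universe.n, len(bottom)))
    for (gene, entity), w in records.items():
        inc[universe.index[gene], entity_index[entity]] = w
    return BipartiteAssociation(universe, bottom, inc)


def read_gmt(path: str | Path, universe: GeneUniverse) -> GeneSetCollection:
    """Read a GMT gene-set collection, resolving genes in ``universe``.

    Genes absent from the universe are dropped (count logged); sets left
    empty after the drop are removed.  A file yielding zero parseable
    sets is rejected.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    n_dropped = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
        set_id = parts[0]
        members = {g for g in parts[2:] if g}
        kept = {g for g in members if g in universe}
        n_dropped += len(members) - len(kept)
        if kept:
            sets.setdefault(set_id, set()).update(kept)
        else:
            logger.warning("%s:%d: set %r has no resolvable genes", path.name, lineno, set_id)
    if n_dropped:
        logger.warning("%s: dropped %d gene(s) not in the universe", path.name, n_dropped)
    if not sets and n_dropped == 0:
        raise ValueError(f"{path}: no parseable gene sets")
    return GeneSetCollection(sets, universe)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for disease in sets:
            genes = "\t".join(sorted(sets[disease]))
            fh.write(f"{disease}\t{description}\t{genes}\n")


def write_kernel_tsv(kernel, path: str | Path) -> None:
    """Write a Gram matrix as dense TSV: header = a, q and the gene ids."""
    from .core import KernelMatrix  # local to avoid a cycle in type-only use

    assert isinstance(kernel, KernelMatrix)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# a={float(kernel.a)!r}\tq={kernel.q}\n")
        fh.write("gene\t" + "\t".join(kernel.universe.genes) + "\n")
        for i, gene in enumerate(kernel.universe.genes):
            row = "\t".join(repr(float(v)) for v in kernel.gram[i])
            fh.write(f"{gene}\t{row}\n")


def read_kernel_tsv(path: str | Path):
    """Read a Gram matrix written by :func:`write_kernel_tsv`."""
    from .core import KernelMatrix

    path = Path(path)
    a, q = 2.0, 1
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            for tok in first.lstrip("#").split("\t"):
                key, _, val = tok.strip().partition("=")
                if key == "a":
                    a = float(val)
                elif key == "q":
                    q = int(val)
            header = fh.readline()
        else:
            header = first + "\n"
        genes = header.rstrip("\n").split("\t")[1:]
        universe = GeneUniverse(genes)
        gram = np.empty((len(genes), len(genes)))
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if parts[0] != genes[i]:
                raise ValueError(f"{path}: row order does not match header at row {i}")
            gram[i] = [float(v) for v in parts[1:]]
    return KernelMatrix(universe, gram, a=a, q=q)


def write_ranking(
    scores: ScoreVector,
    path: str | Path,
    positives: Iterable[str] | None = None,
) -> None:
    """Write the descending-score gene ranking as a 4-column TSV.

    Columns: rank, gene, score, annotated flag (1/0, or NA when no label
    set is given).  Ties are broken lexicographically on the gene id so
    the output is deterministic.
    """
    pos = None if positives is None else set(positives)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("rank\tgene\tscore\tannotated\n")
        for rank, (gene, score) in enumerate(scores.ranking(), start=1):
            flag = "NA" if pos is None else str(int(gene in pos))
            fh.write(f"{rank}\t{gene}\t{float(score)!r}\t{flag}\n")


def read_ranking(path: str | Path):
    """Read a ranking TSV back into (genes, scores, annotated) arrays.

    ``annotated`` is a boolean array, or None when the file was written
    without a label set (NA column).
    """
    genes: list[str] = []
    scores: list[float] = []
    flags: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["rank", "gene", "score", "annotated"]:
            raise ValueError(f"{path}: not a ranking file")
        for line in fh:
            _, gene, score, flag = line.rstrip("\n").split("\t")[:4]
            genes.append(gene)
            scores.append(float(score))
            flags.append(flag)
    annotated = None if (flags and flags[0] == "NA") else np.array([f == "1" for f in flags])
    return genes, np.array(scores), annotated
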