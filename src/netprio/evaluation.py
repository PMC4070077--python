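"""Evaluation protocol for gene prioritization.

The protocol is node-wise cross-validation: the genes (not the diseases)
are randomly partitioned into f folds; in turn one fold is the test
fold, its labels are hidden, the seed genes of the training folds drive
the scorer, and only the test-fold scores are retained.  After all folds
every gene has been scored exactly once without seeing its own label,
and the assembled score vector is evaluated per disease by AUC
(Mann-Whitney, ties credited 1/2) and precision at fixed recall levels.

Robustness is assessed by a label-shuffling test: draw ``n_shuffles``
random gene sets of the same size as the positives, recompute the AUC of
the *fixed* score vector against each, and report p = m/n_shuffles where
m counts shuffles whose AUC exceeds the true one.

Weighted integration estimates its per-network weights inside each
external training split (internal cross-validation or exact
leave-one-out over training genes only), so test labels never leak into
the weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import GeneSetCollection, GeneUniverse, KernelMatrix, ScoreVector
from .integration import (
    GammaWeights,
    NetworkCollection,
    compute_gamma,
    integrate_wa,
    integrate_wap,
)
from .kernels import random_walk_kernel
from .prioritizers import KERNEL_METHODS, build_scorer

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "filter_diseases",
    "auc",
    "precision_at_recall",
    "cross_validate",
    "estimate_internal_weights",
    "cross_validate_weighted",
    "permutation_test",
    "add_permutation_pvalues",
    "candidate_analysis",
    "DEFAULT_RECALL_LEVELS",
]

DEFAULT_RECALL_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))

Scorer = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# gene-set size filter

def filter_diseases(
    sets: GeneSetCollection, min_size: int = 5, max_size: int = 200
) -> GeneSetCollection:
    """Keep disease sets with min_size <= |set| <= max_size (inclusive).

    Small sets carry too little prior information for a ranking task;
    very large ones are too heterogeneous to be a meaningful class.
    """
    kept = {d: g for d, g in sets.items() if min_size <= len(g) <= max_size}
    return GeneSetCollection(kept, sets.universe)


# ---------------------------------------------------------------------------
# ranking metrics

def _as_score_array(scores) -> np.ndarray:
    if isinstance(scores, ScoreVector):
        return scores.scores
    return np.asarray(scores, dtype=float)


def _as_label_array(positives, n: int, universe: GeneUniverse | None) -> np.ndarray:
    if isinstance(positives, np.ndarray) and positives.dtype == bool:
        return positives
    pos = list(positives)
    if pos and isinstance(pos[0], str):
        if universe is None:
            raise ValueError("gene-name positives need a universe")
        idx = universe.indices_of(pos)
    else:
        idx = np.asarray(pos, dtype=np.intp)
    y = np.zeros(n, dtype=bool)
    y[idx] = True
    return y


def auc(scores, positives, universe: GeneUniverse | None = None) -> float:
    """Area under the ROC curve of a score vector against a positive set.

    Computed as the Mann-Whitney statistic via average ranks: the
    fraction of (positive, negative) pairs where the positive outscores
    the negative, ties counted 1/2.  Returns NaN when either class is
    empty (the statistic is undefined).
    """
    s = _as_score_array(scores)
    if isinstance(scores, ScoreVector) and universe is None:
        universe = scores.universe
    y = _as_label_array(positives, s.size, universe)
    n_pos = int(y.sum())
    n_neg = s.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s, method="average")
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _ranking_order(s: np.ndarray, universe: GeneUniverse | None) -> np.ndarray:
    """Descending-score order with a deterministic lexicographic tiebreak."""
    if universe is not None:
        tie = np.argsort(np.argsort(universe.genes))
    else:
        tie = np.arange(s.size)
    return np.lexsort((tie, -s))


def precision_at_recall(
    scores,
    positives,
    recall_levels: Sequence[float] = DEFAULT_RECALL_LEVELS,
    universe: GeneUniverse | None = None,
) -> list[float]:
    """Precision at the smallest ranking cutoff reaching each recall level."""
    s = _as_score_array(scores)
    if isinstance(scores, ScoreVector) and universe is None:
        universe = scores.universe
    y = _as_label_array(positives, s.size, universe)
    n_pos = int(y.sum())
    if n_pos == 0:
        return [float("nan")] * len(recall_levels)
    order = _ranking_order(s, universe)
    tp = np.cumsum(y[order])
    k = np.arange(1, s.size + 1)
    recall = tp / n_pos
    precision = tp / k
    out = []
    for r in recall_levels:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"recall level must be in [0, 1], got {r}")
        hit = np.flatnonzero(recall >= r - 1e-12)
        out.append(float(precision[hit[0]]) if hit.size else float("nan"))
    return out


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVPlan:
    """Random partition of the universe's genes into f disjoint folds."""

    fold_of: np.ndarray  # fold id per gene, values in 0..f-1
    f: int
    seed: int

    def __post_init__(self) -> None:
        if self.f < 2:
            raise ValueError("fold count must be >= 2")
        present = np.unique(self.fold_of)
        if present.min() < 0 or present.max() >= self.f:
            raise ValueError("fold ids out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_cv_plan(
    universe: GeneUniverse,
    f: int = 5,
    seed: int = 0,
    stratify_for: GeneSetCollection | None = None,
) -> CVPlan:
    """Randomly partition the genes into f folds of near-equal size.

    The default partition is unstratified.  With ``stratify_for`` the
    positives of each disease are spread round-robin over the folds
    (useful when sets have as few as 5 genes, at the price of folds that
    are no longer simple uniform draws).
    """
    rng = np.random.default_rng(seed)
    n = universe.n
    fold_of = np.empty(n, dtype=np.intp)
    perm = rng.permutation(n)
    fold_of[perm] = np.arange(n) % f
    if stratify_for is not None:
        taken = np.zeros(n, dtype=bool)
        for disease in stratify_for:
            idx = stratify_for.indices_of(disease)
            idx = idx[~taken[idx]]
            rng.shuffle(idx)
            start = int(rng.integers(f))
            fold_of[idx] = (start + np.arange(idx.size)) % f
            taken[idx] = True
    return CVPlan(fold_of=fold_of, f=f, seed=seed)


def _cv_scores_for_disease(
    scorer: Scorer, pos_idx: np.ndarray, plan: CVPlan, disease: str
) -> np.ndarray:
    """Assemble the full out-of-fold score vector for one disease."""
    n = plan.fold_of.size
    assembled = np.zeros(n)
    pos_mask = np.zeros(n, dtype=bool)
    pos_mask[pos_idx] = True
    for fold in range(plan.f):
        train_mask = plan.fold_of != fold
        seeds = np.flatnonzero(pos_mask & train_mask)
        test = np.flatnonzero(~train_mask)
        if seeds.size == 0:
            logger.warning(
                "disease %s: fold %d holds every positive; scoring its test genes 0",
                disease, fold,
            )
            assembled[test] = 0.0
            continue
        assembled[test] = scorer(seeds)[test]
    return assembled


def cross_validate(
    scorer: Scorer,
    sets: GeneSetCollection,
    plan: CVPlan,
    recall_levels: Sequence[float] = DEFAULT_RECALL_LEVELS,
    return_scores: bool = False,
):
    """Node-wise cross-validated evaluation of one scorer on every disease.

    ``scorer`` maps an integer array of seed indices to a score for every
    gene (see :func:`netprio.prioritizers.build_scorer`).  Returns a
    per-disease report DataFrame (n_pos, auc, precision columns), and
    optionally the assembled out-of-fold score vectors.
    """
    universe = sets.universe
    if plan.fold_of.size != universe.n:
        raise ValueError("CV plan does not match the gene universe")
    rows = {}
    assembled: dict[str, np.ndarray] = {}
    for disease in sets:
        pos_idx = sets.indices_of(disease)
        s = _cv_scores_for_disease(scorer, pos_idx, plan, disease)
        y = sets.label_vector(disease)
        row = {"n_pos": int(y.sum()), "auc": auc(s, y, universe)}
        for r, p in zip(recall_levels, precision_at_recall(s, y, recall_levels, universe)):
            row[f"prec@{r:g}"] = p
        rows[disease] = row
        if return_scores:
            assembled[disease] = s
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "disease"
    if return_scores:
        return report, assembled
    return report


# ---------------------------------------------------------------------------
# internal weight estimation (for weighted integration)

def _internal_auc(
    scorer: Scorer,
    pos_idx: np.ndarray,
    train_idx: np.ndarray,
    sub_fold: np.ndarray | None,
) -> float:
    """AUC of a scorer estimated strictly within the training genes.

    ``sub_fold`` is the internal fold id per training gene, drawn once
    per disease so that every network is measured on the same split;
    None runs exact leave-one-out (only seed removals change the scorer
    input, so it costs |positives|+1 calls).
    """
    pos_set = set(pos_idx.tolist())
    train_pos = np.array([i for i in train_idx if i in pos_set], dtype=np.intp)
    if train_pos.size == 0 or train_pos.size == train_idx.size:
        return 0.5
    scores = np.zeros(train_idx.size)
    if sub_fold is None:
        full = scorer(train_pos)
        for t, g in enumerate(train_idx):
            if g in pos_set:
                if train_pos.size == 1:
                    scores[t] = 0.0  # no seeds left once g is held out
                else:
                    scores[t] = scorer(train_pos[train_pos != g])[g]
            else:
                scores[t] = full[g]
    else:
        pos_local = np.isin(train_idx, train_pos)
        for fold in range(sub_fold.max() + 1):
            tr = train_idx[(sub_fold != fold) & pos_local]
            te = sub_fold == fold
            if tr.size == 0:
                scores[te] = 0.0
                continue
            scores[te] = scorer(tr)[train_idx[te]]
    y_local = np.isin(train_idx, train_pos)
    value = auc(scores, y_local)
    return 0.5 if np.isnan(value) else float(value)


def estimate_internal_weights(
    scorers: Mapping[str, Scorer],
    sets: GeneSetCollection,
    train_idx: np.ndarray,
    internal_folds=5,
    seed: int = 0,
    transform: str = "linear",
    b: float = 0.99,
) -> GammaWeights:
    """Per-network gamma weights from AUCs measured on training genes only.

    ``scorers`` maps network name -> scorer built on that single network.
    For every disease and network the AUC is estimated by internal
    cross-validation (or exact leave-one-out) restricted to ``train_idx``;
    the resulting metric table is turned into weights by
    :func:`netprio.integration.compute_gamma`.  Test-fold labels are
    never read, by construction.
    """
    train_idx = np.asarray(train_idx, dtype=np.intp)
    rng = np.random.default_rng(seed)
    if internal_folds != "loo" and int(internal_folds) < 2:
        raise ValueError("internal fold count must be >= 2 (or 'loo')")
    rows = {}
    for disease in sets:
        pos_idx = sets.indices_of(disease)
        pos_train = pos_idx[np.isin(pos_idx, train_idx)]
        if internal_folds == "loo":
            sub_fold = None
        else:
            # one split per disease, shared by all networks, so the
            # comparison between networks is not confounded by split noise
            sub_fold = np.empty(train_idx.size, dtype=np.intp)
            perm = rng.permutation(train_idx.size)
            sub_fold[perm] = np.arange(train_idx.size) % int(internal_folds)
        rows[disease] = {
            name: _internal_auc(scorer, pos_train, train_idx, sub_fold)
            for name, scorer in scorers.items()
        }
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    return compute_gamma(metrics, transform=transform, b=b)


def _single_network_scorers(
    method: str, col: NetworkCollection, a: float, q: int, **params
) -> dict[str, Scorer]:
    scorers: dict[str, Scorer] = {}
    for name, member in zip(col.names, col.members):
        if method in KERNEL_METHODS:
            kernel = (
                member
                if isinstance(member, KernelMatrix)
                else random_walk_kernel(member, a=a, q=q)
            )
            scorers[name] = build_scorer(method, kernel=kernel, **params)
        else:
            if isinstance(member, KernelMatrix):
                raise ValueError(f"method {method!r} needs adjacency networks, not kernels")
            scorers[name] = build_scorer(method, network=member, **params)
    return scorers


def cross_validate_weighted(
    method: str,
    col: NetworkCollection,
    sets: GeneSetCollection,
    plan: CVPlan,
    integration: str = "wa",
    transform: str = "linear",
    b: float = 0.99,
    internal_folds=5,
    a: float = 2.0,
    q: int = 5,
    recall_levels: Sequence[float] = DEFAULT_RECALL_LEVELS,
    return_scores: bool = False,
    **method_params,
):
    """Nested cross-validation of WA / WAP weighted network integration.

    Per external fold: gamma weights are estimated from the training
    genes (internal CV per network and disease), the member matrices are
    combined with those weights, and the seed genes of the training
    folds score the test fold.  When the members are adjacency networks
    the *adjacencies* are integrated and kernel methods build their
    kernel on the integrated network — walks may then alternate between
    sources of evidence; a collection of kernel Gram matrices is instead
    integrated elementwise as it stands.
    Returns (report, gamma_per_fold[, assembled scores]).
    """
    if integration not in ("wa", "wap"):
        raise ValueError("integration must be 'wa' or 'wap'")
    single_scorers = _single_network_scorers(method, col, a=a, q=q, **method_params)

    def _scorer_for(member) -> Scorer:
        if method in KERNEL_METHODS:
            kernel = (
                member
                if isinstance(member, KernelMatrix)
                else random_walk_kernel(member, a=a, q=q)
            )
            return build_scorer(method, kernel=kernel, **method_params)
        return build_scorer(method, network=member, **method_params)

    universe = sets.universe
    n = universe.n
    assembled = {d: np.zeros(n) for d in sets}
    gammas: list[GammaWeights] = []
    for fold in range(plan.f):
        train_idx = plan.train_indices(fold)
        test = plan.test_indices(fold)
        gamma = estimate_internal_weights(
            single_scorers, sets, train_idx,
            internal_folds=internal_folds,
            seed=plan.seed * (plan.f + 1) + fold,
            transform=transform, b=b,
        )
        gammas.append(gamma)
        if integration == "wa":
            integrated = integrate_wa(col, gamma)
            scorer = _scorer_for(integrated)
            scorers_by_disease = {d: scorer for d in sets}
        else:
            scorers_by_disease = {
                d: _scorer_for(integrate_wap(col, gamma, d)) for d in sets
            }
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
        for disease in sets:
            pos_idx = sets.indices_of(disease)
            seeds = pos_idx[train_mask[pos_idx]]
            if seeds.size == 0:
                logger.warning(
                    "disease %s: fold %d holds every positive; test genes scored 0",
                    disease, fold,
                )
                assembled[disease][test] = 0.0
                continue
            assembled[disease][test] = scorers_by_disease[disease](seeds)[test]
    rows = {}
    for disease in sets:
        y = sets.label_vector(disease)
        s = assembled[disease]
        row = {"n_pos": int(y.sum()), "auc": auc(s, y, universe)}
        for r, p in zip(recall_levels, precision_at_recall(s, y, recall_levels, universe)):
            row[f"prec@{r:g}"] = p
        rows[disease] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "disease"
    if return_scores:
        return report, gammas, assembled
    return report, gammas


# ---------------------------------------------------------------------------
# permutation test

def permutation_test(
    scores,
    positives,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    universe: GeneUniverse | None = None,
    add_one: bool = False,
) -> tuple[int, float]:
    """Label-shuffling robustness test at fixed predictions.

    Draws ``n_shuffles`` uniformly random gene sets of the same size as
    the positives, recomputes the AUC of the same score vector against
    each, and counts how many times m the shuffled AUC exceeds the true
    one.  Returns (m, p) with p = m/n_shuffles (``add_one`` switches to
    the (m+1)/(n+1) estimator).
    """
    s = _as_score_array(scores)
    if isinstance(scores, ScoreVector) and universe is None:
        universe = scores.universe
    y = _as_label_array(positives, s.size, universe)
    n_pos = int(y.sum())
    n_neg = s.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("permutation test needs both positives and negatives")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranks = rankdata(s, method="average")
    offset = n_pos * (n_pos + 1) / 2.0
    denom = n_pos * n_neg
    true_auc = (ranks[y].sum() - offset) / denom
    m = 0
    for _ in range(n_shuffles):
        idx = rng.choice(s.size, size=n_pos, replace=False)
        if (ranks[idx].sum() - offset) / denom > true_auc:
            m += 1
    if add_one:
        return m, (m + 1) / (n_shuffles + 1)
    return m, m / n_shuffles


def add_permutation_pvalues(
    report: pd.DataFrame,
    assembled_scores: Mapping[str, np.ndarray],
    sets: GeneSetCollection,
    n_shuffles: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> pd.DataFrame:
    """Append m and p-value columns (one shuffle test per disease) to a report."""
    rng = np.random.default_rng(seed)
    ms, ps = [], []
    for disease in report.index:
        m, p = permutation_test(
            assembled_scores[disease], sets[disease],
            n_shuffles=n_shuffles, seed=rng,
            universe=sets.universe, add_one=add_one,
        )
        ms.append(m)
        ps.append(p)
    out = report.copy()
    out["m"] = ms
    out["p_value"] = ps
    return out


# ---------------------------------------------------------------------------
# candidate-gene percentile analysis

def candidate_analysis(
    assembled_scores: Mapping[str, np.ndarray],
    sets: GeneSetCollection,
    report: pd.DataFrame,
    auc_min: float = 0.975,
    p_max: float = 0.01,
    top: int = 3,
) -> pd.DataFrame:
    """ECDF percentiles of the top unannotated genes for the best diseases.

    Diseases passing ``auc >= auc_min`` and ``p_value < p_max`` are
    selected.  Per disease: c is the lowest score among annotated genes;
    the ECDF is taken over the multiset of *all* gene scores >= c
    (annotated and unannotated); each of the ``top`` highest-ranked
    unannotated genes is reported with its percentile
    100 * #(support <= score) / #support.  A top gene scoring below c
    falls outside the support and is assigned percentile 0 with the
    ``below_support`` flag set.
    """
    universe = sets.universe
    selected = report.index[
        (report["auc"] >= auc_min) & (report["p_value"] < p_max)
    ]
    if len(selected) == 0:
        logger.warning("no disease passes auc >= %g and p < %g", auc_min, p_max)
    records = []
    for disease in selected:
        s = np.asarray(assembled_scores[disease], dtype=float)
        y = sets.label_vector(disease)
        c = s[y].min()
        support = np.sort(s[s >= c])
        order = _ranking_order(s, universe)
        unannotated = [i for i in order if not y[i]][:top]
        for rank, i in enumerate(unannotated, start=1):
            below = s[i] < c
            pct = 0.0 if below else 100.0 * np.searchsorted(support, s[i], side="right") / support.size
            records.append(
                {
                    "disease": disease,
                    "rank": rank,
                    "gene": universe.genes[i],
                    "score": float(s[i]),
                    "percentile": float(pct),
                    "below_support": bool(below),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["disease", "rank", "gene", "score", "percentile", "below_support"]
    )
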