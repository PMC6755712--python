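"""Degree-constrained cross-validation and mean percentile ranking (MPR).

Known links are split into *k* folds; each fold's training matrix is the full
matrix with that fold's test links zeroed.  Because the data are one-class
(a zero means "untested"), evaluation is recall-based: for each test target
the drugs are ranked by decreasing score over the whole drug axis, and the
percentile rank of a held-out true pair is its normalized list position --
0% for the top of the list, 100% for the bottom.  Per-target ranks average
to R_i, and R_i averages over test targets to the MPR.  Uniformly random
scores give an expected MPR of 50%; lower is better.

The degree constraint -- every drug and every target keeps at least one
training link in every fold -- is enforced greedily: links are shuffled, each
is assigned to the least-filled fold whose training matrix can spare it, and
links that no fold can spare (e.g. the only link of a degree-1 drug) are
pinned to training everywhere and excluded from all test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .data import AuxSimilarityPair, DataError, InteractionMatrix
from .predict import (
    DEFAULT_BLEND,
    DEFAULT_RANK,
    ScoreMatrix,
    Strategy,
    predict,
)
from .similarity import CoMode, Metric

logger = logging.getLogger("nbcfdti")

TieRule = Literal["average", "min"]

#: scorer signature: (train, fold_seed) -> ScoreMatrix
Scorer = Callable[[InteractionMatrix, int], ScoreMatrix]


@dataclass(frozen=True)
class CVFold:
    """One fold: training matrix with test links zeroed, plus the test pairs."""

    train: InteractionMatrix
    test_pairs: tuple[tuple[int, int], ...]
    fold_id: int
    seed: int


@dataclass(frozen=True)
class MPRReport:
    """Per-target mean percentile ranks and their aggregate MPR."""

    per_target: tuple[tuple[int, float], ...]
    mpr: float
    n_test_targets: int
    config: dict = field(default_factory=dict)


def make_folds(full: InteractionMatrix, k: int = 10, seed: int = 0) -> list[CVFold]:
    """Partition the link set into *k* degree-constrained folds.

    Links are shuffled with ``seed`` and assigned greedily to the currently
    smallest fold whose training matrix keeps both endpoints at degree >= 1
    after removal.  Unassignable links are pinned to training in every fold
    (with a logged warning) and appear in no test set.
    """
    if k < 2:
        raise DataError(f"need k >= 2 folds, got {k}")
    links = list(zip(*np.nonzero(full.values)))
    n_links = len(links)
    if n_links == 0:
        raise DataError("interaction matrix has no links to cross-validate")
    if k > n_links:
        raise DataError(f"k={k} folds exceed {n_links} links")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_links)
    t_deg = full.target_degrees().copy()
    d_deg = full.drug_degrees().copy()
    # removed[f][node]: links of this node already in fold f's test set
    removed_t = np.zeros((k, full.n_targets), dtype=np.int64)
    removed_d = np.zeros((k, full.n_drugs), dtype=np.int64)
    fold_members: list[list[tuple[int, int]]] = [[] for _ in range(k)]
    n_pinned = 0
    for idx in order:
        i, j = links[idx]
        candidates = [
            f
            for f in range(k)
            if t_deg[i] - removed_t[f, i] >= 2 and d_deg[j] - removed_d[f, j] >= 2
        ]
        if not candidates:
            n_pinned += 1
            continue
        f = min(candidates, key=lambda f: (len(fold_members[f]), f))
        fold_members[f].append((int(i), int(j)))
        removed_t[f, i] += 1
        removed_d[f, j] += 1
    if n_pinned:
        logger.warning(
            "%d of %d links pinned to training in all folds (degree constraint)",
            n_pinned,
            n_links,
        )
    folds = []
    for f in range(k):
        train_values = full.values.copy()
        for i, j in fold_members[f]:
            train_values[i, j] = 0
        folds.append(
            CVFold(
                train=full.replace_values(train_values),
                test_pairs=tuple(sorted(fold_members[f])),
                fold_id=f,
                seed=seed,
            )
        )
    return folds


def percentile_ranks(
    scores: ScoreMatrix,
    fold: CVFold,
    tie_rule: TieRule = "average",
) -> dict[tuple[int, int], float]:
    """Percentile rank of each held-out pair among all N drugs for its target.

    Drugs are sorted by decreasing score; a pair in position p (1-based) gets
    rank (p - 1) / (N - 1), so a strict top hit scores exactly 0 and a strict
    bottom hit exactly 1.  Ties share the average (default) or minimum
    position.  With a single drug the rank is defined as 0.
    """
    if tie_rule not in ("average", "min"):
        raise DataError(f"unknown tie rule {tie_rule!r}")
    n = scores.values.shape[1]
    out: dict[tuple[int, int], float] = {}
    by_target: dict[int, list[int]] = {}
    for i, j in fold.test_pairs:
        by_target.setdefault(i, []).append(j)
    for i, drugs in by_target.items():
        if n == 1:
            for j in drugs:
                out[(i, j)] = 0.0
            continue
        pos = rankdata(-scores.values[i], method=tie_rule)
        for j in drugs:
            out[(i, j)] = (pos[j] - 1.0) / (n - 1.0)
    return out


def mpr(ranks: dict[tuple[int, int], float], fold: CVFold, config: dict | None = None) -> MPRReport:
    """Aggregate per-pair percentile ranks into per-target R_i and the MPR.

    R_i averages the ranks of the drugs tested for target i; the MPR averages
    R_i over the fold's test targets.
    """
    if not fold.test_pairs:
        raise DataError("no test pairs")
    missing = [p for p in fold.test_pairs if p not in ranks]
    if missing or len(ranks) != len(fold.test_pairs):
        raise DataError("ranks do not cover exactly the fold's test pairs")
    by_target: dict[int, list[float]] = {}
    for (i, _j), r in ranks.items():
        by_target.setdefault(i, []).append(r)
    per_target = tuple(sorted((i, float(np.mean(rs))) for i, rs in by_target.items()))
    return MPRReport(
        per_target=per_target,
        mpr=float(np.mean([r for _i, r in per_target])),
        n_test_targets=len(per_target),
        config=dict(config or {}),
    )


@dataclass(frozen=True)
class ExperimentSummary:
    """MPR across repeated cross-validation trials."""

    mpr_mean: float
    mpr_sd: float
    trial_mprs: tuple[float, ...]
    fold_mprs: tuple[tuple[float, ...], ...]
    per_target: tuple[tuple[int, float], ...]  # pooled over the last trial
    config: dict = field(default_factory=dict)


def random_scorer(train: InteractionMatrix, seed: int) -> ScoreMatrix:
    """Baseline scorer: i.i.d. uniform scores for every target-drug pair."""
    rng = np.random.default_rng(seed)
    return ScoreMatrix(rng.random(train.values.shape), "random", "random", {"seed": seed})


def run_experiment(
    full: InteractionMatrix,
    strategy: Strategy = "s1",
    metric: Metric = "ppmi",
    rank: int = DEFAULT_RANK,
    alpha: float = DEFAULT_BLEND[0],
    beta: float = DEFAULT_BLEND[1],
    gamma: float = DEFAULT_BLEND[2],
    aux: Optional[AuxSimilarityPair] = None,
    n_trials: int = 5,
    k: int = 10,
    seeds: Optional[Sequence[int]] = None,
    tie_rule: TieRule = "average",
    co_mode: CoMode = "shared-ones",
    scorer: Optional[Scorer] = None,
) -> ExperimentSummary:
    """Repeated k-fold cross-validation of a prediction strategy.

    Each trial draws fresh folds from its seed, scores every fold's training
    matrix, and pools R_i over all test targets of all folds into one trial
    MPR; the summary is the mean and standard deviation over trials.  Fold-
    level MPRs are reported alongside.  ``scorer`` overrides the built-in
    pipeline (used for the random baseline).
    """
    if seeds is None:
        seeds = list(range(1, n_trials + 1))
    seeds = list(seeds)
    if len(seeds) != n_trials:
        raise DataError(f"need {n_trials} seeds, got {len(seeds)}")
    config = {
        "strategy": strategy,
        "metric": metric,
        "rank": rank,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "n_trials": n_trials,
        "k": k,
        "seeds": seeds,
        "tie_rule": tie_rule,
        "co_mode": co_mode,
        "scorer": "custom" if scorer is not None else "pipeline",
    }
    trial_mprs: list[float] = []
    fold_mprs: list[tuple[float, ...]] = []
    pooled_last: tuple[tuple[int, float], ...] = ()
    for trial, seed in enumerate(seeds):
        folds = make_folds(full, k=k, seed=seed)
        per_fold: list[float] = []
        pooled: list[tuple[int, float]] = []
        for fold in folds:
            if not fold.test_pairs:
                continue
            if scorer is not None:
                scores = scorer(fold.train, seed * 1000 + fold.fold_id)
            else:
                scores = predict(
                    fold.train,
                    strategy=strategy,
                    metric=metric,
                    rank=rank,
                    alpha=alpha,
                    beta=beta,
                    gamma=gamma,
                    aux=aux,
                    co_mode=co_mode,
                )
            ranks = percentile_ranks(scores, fold, tie_rule)
            report = mpr(ranks, fold)
            per_fold.append(report.mpr)
            pooled.extend(report.per_target)
        if not pooled:
            raise DataError("no test pairs in any fold")
        # trial MPR pools R_i over all (fold, target) pairs of the trial
        trial_mprs.append(float(np.mean([r for _i, r in pooled])))
        fold_mprs.append(tuple(per_fold))
        pooled_last = tuple(pooled)
    return ExperimentSummary(
        mpr_mean=float(np.mean(trial_mprs)),
        mpr_sd=float(np.std(trial_mprs, ddof=1)) if len(trial_mprs) > 1 else 0.0,
        trial_mprs=tuple(trial_mprs),
        fold_mprs=tuple(fold_mprs),
        per_target=pooled_last,
        config=config,
    )


def mpr_boxplot(summaries: dict[str, ExperimentSummary], dest: str) -> None:
    """Minimal boxplot of trial MPRs per labelled configuration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(summaries)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(labels), 4))
    ax.boxplot([summaries[l].trial_mprs for l in labels], tick_labels=labels)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=1, label="random baseline")
    ax.set_ylabel("MPR")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)
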