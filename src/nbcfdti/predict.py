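"""Neighbor-based collaborative filtering scores and noise-mitigation strategies.

The core score for target *i* and query drug *j* sums the similarities between
*j* and the drugs already known to hit *i*:

    score[i, j] = sum over k in known(i) of S[j, k]

which in matrix form is ``Y_train @ S`` for symmetric S.  Three strategies
produce the final score matrix:

* **s1** -- the raw neighbor score, the headline configuration when paired
  with PPMI similarity;
* **s2** -- a truncated-SVD low-rank reconstruction of the raw scores
  (default rank 100), suppressing noise carried over from a sparse network
  through cosine/tanimoto-style similarities;
* **s3** -- blending in auxiliary target-sequence and drug-structure
  similarities: ``alpha * S_T @ Y^t + beta * Y^t + gamma * Y^t @ S_D`` with
  defaults (0.025, 0.95, 0.025).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .data import AuxSimilarityPair, DataError, InteractionMatrix
from .similarity import CoMode, DrugSimilarityMatrix, Metric, compute_similarity

Strategy = Literal["s1", "s2", "s3"]

STRATEGIES: tuple[str, ...] = ("s1", "s2", "s3")

#: default truncation rank for the low-rank approximation (strategy s2)
DEFAULT_RANK = 100
#: default smoothing coefficients (alpha, beta, gamma) for strategy s3
DEFAULT_BLEND = (0.025, 0.95, 0.025)


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued M x N predicted interaction scores with provenance."""

    values: np.ndarray
    strategy: str
    metric: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise DataError(f"score matrix must be 2-D, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise DataError("score matrix contains non-finite entries")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class SVDFactorization:
    """Thin SVD triplet U, s, V with singular values in nonincreasing order."""

    left: np.ndarray
    singular: np.ndarray
    right: np.ndarray
    rank_used: int

    def reconstruct(self) -> np.ndarray:
        return (self.left * self.singular) @ self.right.T


def nbcf_score(
    train: InteractionMatrix,
    sim: DrugSimilarityMatrix,
    mask_self: bool = False,
) -> ScoreMatrix:
    """Sum similarities between the query drug and each target's known drugs.

    ``mask_self`` drops the k = j term (a drug's self-similarity) from the
    sum; it is off by default because in cross-validation the query pair is
    absent from training anyway.
    """
    if sim.drug_ids != train.drug_ids:
        raise DataError(
            f"similarity matrix drugs ({sim.n_drugs}) do not match "
            f"training matrix drugs ({train.n_drugs})"
        )
    y = train.values.astype(float)
    scores = y @ sim.values  # sim is symmetric: (Y @ S)[i,j] = sum_k Y_ik S_jk
    if mask_self:
        scores = scores - y * np.diag(sim.values)[None, :]
    return ScoreMatrix(scores, "s1", sim.metric, {"mask_self": mask_self})


def svd_factorize(values: np.ndarray, rank: int) -> SVDFactorization:
    """Deterministic thin SVD truncated to ``min(rank, M, N)`` components."""
    if rank < 1:
        raise DataError(f"rank must be >= 1, got {rank}")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    r = min(rank, len(s))
    return SVDFactorization(u[:, :r], s[:r], vt[:r].T, r)


def lra_denoise(scores: ScoreMatrix, rank: int = DEFAULT_RANK) -> ScoreMatrix:
    """Best rank-R approximation (Frobenius norm) of the score matrix.

    The requested rank is clamped to ``min(M, N)``; both requested and
    effective ranks are recorded in the provenance.
    """
    fact = svd_factorize(scores.values, rank)
    prov = dict(scores.provenance)
    prov.update({"rank_requested": rank, "rank_effective": fact.rank_used})
    return ScoreMatrix(fact.reconstruct(), "s2", scores.metric, prov)


def auxiliary_blend(
    scores: ScoreMatrix,
    aux: AuxSimilarityPair,
    alpha: float = DEFAULT_BLEND[0],
    beta: float = DEFAULT_BLEND[1],
    gamma: float = DEFAULT_BLEND[2],
) -> ScoreMatrix:
    """Smooth scores with auxiliary similarities.

    ``Y_hat = alpha * S_T @ Y^t + beta * Y^t + gamma * Y^t @ S_D``.  The
    coefficients are not renormalized when they do not sum to one.
    """
    for name, value in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not np.isfinite(value):
            raise DataError(f"{name} must be finite, got {value}")
    yt = scores.values
    m, n = yt.shape
    if aux.target_sim.shape[0] != m or aux.drug_sim.shape[0] != n:
        raise DataError(
            f"auxiliary shapes {aux.target_sim.shape}/{aux.drug_sim.shape} "
            f"do not match score matrix {yt.shape}"
        )
    blended = alpha * (aux.target_sim @ yt) + beta * yt + gamma * (yt @ aux.drug_sim)
    prov = dict(scores.provenance)
    prov.update({"alpha": alpha, "beta": beta, "gamma": gamma})
    return ScoreMatrix(blended, "s3", scores.metric, prov)


def predict(
    train: InteractionMatrix,
    strategy: Strategy = "s1",
    metric: Metric = "ppmi",
    rank: int = DEFAULT_RANK,
    alpha: float = DEFAULT_BLEND[0],
    beta: float = DEFAULT_BLEND[1],
    gamma: float = DEFAULT_BLEND[2],
    aux: Optional[AuxSimilarityPair] = None,
    co_mode: CoMode = "shared-ones",
    mask_self: bool = False,
) -> ScoreMatrix:
    """Full pipeline: profile similarity, neighbor scores, optional denoising.

    ``s1`` returns the raw neighbor scores, ``s2`` reconstructs them at low
    rank, ``s3`` blends in the auxiliary similarity pair (required for s3).
    ``s1`` with ``metric='ppmi'`` is the recommended configuration.
    """
    if strategy not in STRATEGIES:
        raise DataError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy == "s3":
        if aux is None:
            raise DataError("strategy s3 requires auxiliary similarity matrices")
        aux.check_shapes(train)
    sim = compute_similarity(train, metric, co_mode)
    scores = nbcf_score(train, sim, mask_self)
    if strategy == "s1":
        return scores
    if strategy == "s2":
        return lra_denoise(scores, rank)
    return auxiliary_blend(scores, aux, alpha, beta, gamma)
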