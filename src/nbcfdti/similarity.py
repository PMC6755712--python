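"""Drug-drug similarity from interaction profiles.

Each drug is described by its interaction profile (DIP): the binary column of
the adjacency matrix recording which targets it is known to hit.  Four metrics
turn pairs of profiles into an N x N similarity matrix:

* ``cosine``   -- inner product over the product of Euclidean norms,
* ``tanimoto`` -- intersection over union of the binary profiles,
* ``dice``     -- twice the intersection over the sum of profile sizes,
* ``ppmi``     -- positive pointwise mutual information of the empirical
  co-occurrence distribution, in base-2 logs, clamped at zero.

PPMI is the sparsity-robust choice: on a network where only ~0.6-1% of pairs
are observed, raw overlap counts are noisy, and PPMI discounts co-occurrence
that is no more frequent than chance.  Degenerate all-zero profiles yield
similarity 0 to every drug, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import DataError, InteractionMatrix

Metric = Literal["cosine", "tanimoto", "dice", "ppmi"]
CoMode = Literal["shared-ones", "shared-ones-and-zeros"]

METRICS: tuple[str, ...] = ("cosine", "tanimoto", "dice", "ppmi")


@dataclass(frozen=True)
class DrugSimilarityMatrix:
    """Symmetric N x N drug-drug similarity with the metric that produced it."""

    values: np.ndarray
    metric: str
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DataError(f"similarity matrix must be square, got {arr.shape}")
        if arr.shape[0] != len(self.drug_ids):
            raise DataError(
                f"{len(self.drug_ids)} drug ids for a {arr.shape[0]}x{arr.shape[1]} matrix"
            )
        if not np.isfinite(arr).all():
            raise DataError("similarity matrix contains non-finite entries")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]


def _profiles(m: InteractionMatrix) -> np.ndarray:
    return m.values.astype(float)


def cosine_similarity(m: InteractionMatrix) -> DrugSimilarityMatrix:
    """Cosine similarity between drug interaction profiles.

    ``S[j,j'] = sum_i Y_ij Y_ij' / (||Y_.j|| ||Y_.j'||)``; on binary profiles
    this lies in [0, 1].  Pairs involving an all-zero profile score 0.
    """
    y = _profiles(m)
    dot = y.T @ y
    norm = np.sqrt(np.diag(dot))
    denom = np.outer(norm, norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    return DrugSimilarityMatrix(s, "cosine", m.drug_ids)


def tanimoto_similarity(m: InteractionMatrix) -> DrugSimilarityMatrix:
    """Tanimoto (Jaccard) similarity: intersection over union of profiles.

    ``S[j,j'] = a.b / (a.a + b.b - a.b)`` for binary columns a, b; in [0, 1].
    """
    y = _profiles(m)
    dot = y.T @ y
    sq = np.diag(dot)
    denom = sq[:, None] + sq[None, :] - dot
    s = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    return DrugSimilarityMatrix(s, "tanimoto", m.drug_ids)


def dice_similarity(m: InteractionMatrix) -> DrugSimilarityMatrix:
    """Dice coefficient: ``2 a.b / (a.a + b.b)`` for binary profiles; in [0, 1]."""
    y = _profiles(m)
    dot = y.T @ y
    sq = np.diag(dot)
    denom = sq[:, None] + sq[None, :]
    s = np.where(denom > 0, 2.0 * dot / np.where(denom > 0, denom, 1.0), 0.0)
    return DrugSimilarityMatrix(s, "dice", m.drug_ids)


def cooccurrence(m: InteractionMatrix, co_mode: CoMode = "shared-ones") -> np.ndarray:
    """Drug-pair co-occurrence counts over targets.

    ``shared-ones`` counts targets hit by both drugs (the column dot product,
    standard PPMI practice on occurrence data).  ``shared-ones-and-zeros``
    additionally counts targets hit by neither, i.e. positions where the two
    profiles agree.  The diagonal is included.
    """
    y = _profiles(m)
    co = y.T @ y
    if co_mode == "shared-ones-and-zeros":
        z = 1.0 - y
        co = co + z.T @ z
    elif co_mode != "shared-ones":
        raise DataError(f"unknown co_mode {co_mode!r}")
    return co


def ppmi_similarity(m: InteractionMatrix, co_mode: CoMode = "shared-ones") -> DrugSimilarityMatrix:
    """Positive pointwise mutual information between drug profiles.

    Joint probabilities are the co-occurrence counts normalized by the grand
    total over all ordered drug pairs (diagonal included); marginals are the
    corresponding row sums.  ``S[j,j'] = max(log2(P(j,j') / (P(j) P(j'))), 0)``,
    with pairs of zero joint or zero marginal probability scored 0.
    """
    if m.n_interactions == 0:
        raise DataError("no interactions: PPMI undefined")
    co = cooccurrence(m, co_mode)
    total = co.sum()
    if total <= 0:
        raise DataError("no interactions: PPMI undefined")
    p_joint = co / total
    p_marg = co.sum(axis=1) / total
    denom = np.outer(p_marg, p_marg)
    ok = (p_joint > 0) & (denom > 0)
    s = np.zeros_like(p_joint)
    s[ok] = np.log2(p_joint[ok] / denom[ok])
    np.maximum(s, 0.0, out=s)
    return DrugSimilarityMatrix(s, "ppmi", m.drug_ids)


_METRIC_FUNCS = {
    "cosine": cosine_similarity,
    "tanimoto": tanimoto_similarity,
    "dice": dice_similarity,
    "ppmi": ppmi_similarity,
}


def compute_similarity(
    m: InteractionMatrix, metric: Metric, co_mode: CoMode = "shared-ones"
) -> DrugSimilarityMatrix:
    """Dispatch to one of the four profile-similarity metrics."""
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise DataError(f"unknown similarity metric {metric!r}; choose from {METRICS}") from None
    if metric == "ppmi":
        return func(m, co_mode)
    return func(m)
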