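# Methods

## Model and assumptions

The package treats DTI prediction as one-class ranking on a bipartite graph.
The working assumption is chemical-similarity transfer: if a target is known
to interact with drugs similar to a query drug, the query drug is a plausible
interactor.  Similarity is computed from interaction profiles (columns of the
adjacency matrix), not from chemical structure, so the model is only as
informative as the network's co-occurrence structure.  Known limitations
follow directly: activity cliffs (structurally or profile-wise similar drugs
with different pharmacology) violate the assumption; drugs or targets with no
training links cannot be scored meaningfully (cold-start is out of scope, as
is the symmetric problem of ranking targets for a query drug).

Zeros in the adjacency matrix are untested pairs, never verified
non-interactions.  This motivates both the one-class scoring rule and the
recall-based evaluation metric: precision against the 0 class would be
meaningless.

## Similarity metrics

Cosine, Tanimoto and Dice are standard overlap measures on binary profiles;
on such profiles all three lie in [0, 1], and entrywise
`tanimoto ≤ dice ≤ 1` and `tanimoto ≤ cosine` hold.  Columns with no links
score 0 against every drug (never NaN); that case arises only in synthetic or
degenerate inputs, since the cross-validation splitter preserves positive
degree.

PPMI treats the profile pair as a co-occurrence table: `co(j, j')` counts
targets shared by drugs j and j' (the column dot product, diagonal included),
joint probabilities normalize `co` by its grand total over all ordered pairs,
marginals are row sums of the same table, and the score is
`max(log₂(P_joint / (P_j P_j')), 0)`.  Pairs with zero joint or marginal
probability score 0, and an all-zero network is rejected (PPMI is undefined
without co-occurrence mass).

Two co-occurrence conventions exist for binary data: counting shared 1s only,
or counting every position where two profiles agree (shared 1s and shared 0s).
On data this sparse the second convention is dominated by shared zeros and
compresses all scores toward zero.  The default is `shared-ones`, the standard
PPMI practice on occurrence data; the agreement-counting variant is available
via `co_mode="shared-ones-and-zeros"` for exploration.  No row normalization
or other post-processing is applied to the similarity matrix before scoring.

## Scoring strategies

`nbcf_score` computes `Y_train · S` (S symmetric).  The drug's self-similarity
term is included by default: during cross-validation the query pair is absent
from the training matrix, so no information leaks; a `mask_self` flag exists
for sensitivity analysis.

Strategy s2 reconstructs the score matrix from its top R singular triplets
(deterministic LAPACK SVD, no randomized solver).  The default R = 100 is
clamped to `min(M, N)`, since a rank above the matrix dimensions is not
meaningful; provenance records both requested and effective rank.  The
truncation is the Frobenius-optimal denoiser, which is the point: similarity
noise from a sparse network propagates into the raw scores, and the dominant
singular subspace retains the systematic structure.

Strategy s3 computes `α S_T Ŷᵗ + β Ŷᵗ + γ Ŷᵗ S_D` exactly in that form, with
defaults (0.025, 0.95, 0.025).  Coefficients are not renormalized when they
do not sum to 1 — the blend is a linear smoother, not a convex combination by
contract.  User-supplied auxiliary matrices are validated for shape, symmetry
(tolerance 1e-9) and finiteness only; negative entries pass through.

## Cross-validation and MPR

Links are partitioned into k folds (default 10) under the constraint that
every drug and every target keeps at least one training link in every fold.
The splitter shuffles links with the trial seed and greedily assigns each to
the currently smallest fold whose training matrix can spare it; links that no
fold can spare — any link with a degree-1 endpoint — are pinned to training in
all folds, excluded from every test set, and counted in a logged warning.
At benchmark sparsity a third of the links can be pinned; the evaluated MPR
is therefore conditional on testable links, which is the only consistent
choice under the degree constraint.

Percentile ranks use the whole drug axis (training positives for the target
included) sorted by decreasing score, normalized as `(position − 1)/(N − 1)`
so that 0% and 100% are exactly attainable.  Ties take the average position by
default — the unbiased choice, which makes random scores give MPR 50% exactly
in expectation; a `min` rule is available.  With a single drug the rank is
defined as 0.

A target appearing in several folds' test sets contributes one `R_i` per
fold; a trial's MPR pools `R_i` over all (fold, target) pairs, and the
experiment summary reports mean ± standard deviation over trials (default 5),
plus the per-fold MPRs.  Fold-level and pooled values coincide up to weighting
by test-target counts; both are exposed rather than asserting one convention.

## Synthetic networks

The generator is a bipartite degree-corrected stochastic block model tuned to
the regime of public DTI benchmarks: 733 targets × 829 drugs at sparsity
0.006 by default (the dimensions of a DrugBank-derived benchmark), four
latent blocks standing in for coarse target-family/drug-class structure, a
within-block rate boost of 20 (≈87% of links within blocks), and Pareto(1)
per-node propensities truncated so that no node's expected degree exceeds 10%
of the opposite axis — reproducing the observed min-degree 1, max-degree
~50–100 spread.  The truncation solves the fixed point
`cap = max_degree · Σ min(a, cap) / n_links`, which is exact for balanced
blocks.  A repair pass gives each zero-degree node one link drawn from its
link-probability row; sampling (rather than taking the argmax) matters,
because deterministic repair funnels hundreds of links onto the single
largest hub, breaking both the degree cap and the boost = 1 null (spurious
popularity signal).  Realized sparsity stays within ~20% of the target, most
of the excess coming from repair links.

Auxiliary matrices are block indicators mixed with symmetric uniform noise
(`(1 − ε)·indicator + ε·noise`, default ε = 0.1), so strategy s3 receives
auxiliary information consistent with the planted structure.

What the generator does not emulate: overlapping target families, correlated
drug scaffolds within and across classes, and the fine biclustering of real
pharmacology.  Passing tests on these networks demonstrate that the
implementation recovers plantable structure and that the evaluation protocol
is calibrated (random scores → MPR 0.50); they do not certify the MPR levels
achievable on curated benchmark data, where profile correlations are stronger
and the metrics' relative ordering can differ.

## Numerical and design notes

- All similarity computations are dense; at benchmark scale (≲10³ per axis)
  dense BLAS is faster and simpler than sparse paths.
- Degenerate inputs: all-zero profiles give similarity 0; an all-zero network
  is a validation error for PPMI and for fold-making.
- Reproducibility: every stochastic component (generator, fold shuffling,
  random-baseline scorer) takes an explicit seed; the CLI requires `--seed`
  for `simulate` and `evaluate` and echoes the full configuration as JSON next
  to every output.
- Test and evaluation problem sizes (networks of 150×100 to 733×829, five
  trials of tenfold CV) were chosen so the whole suite completes in well
  under a minute while keeping the benchmark-regime defaults for the headline
  checks.
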