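# nbcfdti

Neighbor-based collaborative filtering (NBCF) for drug–target interaction
(DTI) prediction.

Experimentally validated DTIs form a very sparse bipartite network: hundreds
of protein targets and drugs, with well under 1% of all target–drug pairs
tested.  The data are one-class — a 0 means *untested*, never "does not
interact".  `nbcfdti` ranks candidate drugs for a target of interest using
only this network (plus, optionally, auxiliary target-sequence and
drug-structure similarities), in the style of item-based recommender systems.
It is aimed at chemogenomics and drug-repositioning researchers who want a
fast, model-free ranking of untested pairs, and at method developers who need
a clean reference implementation of the evaluation protocol.

## Method

Let `Y ∈ {0,1}^{M×N}` be the adjacency matrix of the DTI network (M targets,
N drugs).  Drug *j* is described by its interaction profile, the column
`Y_.j`.  A drug–drug similarity `S ∈ R^{N×N}` is computed from profiles under
one of four metrics:

- **cosine**  `S_jj' = Σ_i Y_ij Y_ij' / (‖Y_.j‖ ‖Y_.j'‖)`
- **tanimoto**  `S_jj' = Σ_i Y_ij Y_ij' / (Σ_i Y_ij² + Σ_i Y_ij'² − Σ_i Y_ij Y_ij')`
- **dice**  `S_jj' = 2 Σ_i Y_ij Y_ij' / (Σ_i Y_ij² + Σ_i Y_ij'²)`
- **ppmi**  `S_jj' = max(log₂ P(Y_.j, Y_.j') / (P(Y_.j) P(Y_.j')), 0)`, with the
  probabilities estimated from empirical profile co-occurrence counts.  PPMI
  discounts co-occurrence that is no more frequent than chance, which makes it
  robust to the noise that plain overlap counts pick up on very sparse data.

The neighbor score of an untested pair sums the similarities between the query
drug and the target's known drugs:

    Ŷ_ij = Σ_{k ∈ known(i)} S_jk

Three strategies produce the final scores:

1. **s1** — the raw neighbor score; `s1` + `ppmi` is the recommended
   configuration.
2. **s2** — truncated-SVD low-rank reconstruction of the raw scores (default
   rank 100), which suppresses similarity noise for cosine/tanimoto/dice.
3. **s3** — blending in auxiliary similarities:
   `Ŷ = α S_T Ŷᵗ + β Ŷᵗ + γ Ŷᵗ S_D`, default `(α, β, γ) = (0.025, 0.95, 0.025)`.

Performance is measured by **mean percentile ranking (MPR)**: for each test
target, all N drugs are ranked by decreasing score; a held-out true pair at
list position p contributes percentile rank `(p−1)/(N−1)` (0% = top, 100% =
bottom); per-target means `R_i` average to the MPR.  Random scores give an
expected MPR of 50%; lower is better.  Cross-validation removes 10% of the
links per fold while guaranteeing every drug and target keeps at least one
training link.

## Worked example

Generate a synthetic benchmark-regime network (planted block structure,
heavy-tailed degrees, sparsity ≈ 0.006) and cross-validate the strategies:

```sh
nbcfdti simulate --seed 1 --outdir demo
nbcfdti stats --interactions demo/interactions.tsv
```

```
n_targets       733
n_drugs         829
n_interactions  3919
mean_targets_per_drug   4.72738
mean_drugs_per_target   5.34652
min_deg_drug    1
max_deg_drug    71
min_deg_target  1
max_deg_target  80
sparsity        0.00644936
```

```sh
nbcfdti evaluate --interactions demo/interactions.tsv \
    --strategy s1 --metric ppmi --seed 1 --outdir demo/eval
```

```
MPR 0.2387 +/- 0.0033 (5 trials of 10-fold CV)
```

Held-out interactions are ranked, on average, in the top 24% of each target's
candidate list — far better than the 50% a random ranking would achieve.
Other configurations on the same network, same seeds:

| configuration | MPR |
|---|---|
| s1 / ppmi | 0.2387 ± 0.0033 |
| s1 / cosine | 0.1936 ± 0.0021 |
| s2 / cosine (rank 100) | 0.2013 ± 0.0037 |
| s3 / cosine (block-structured auxiliaries) | 0.1240 ± 0.0010 |
| random baseline | 0.5036 ± 0.0057 |

(`s3` used `--aux-target-sim demo/target_sim.tsv --aux-drug-sim
demo/drug_sim.tsv`; on this synthetic network the auxiliaries encode the
planted blocks almost perfectly, so blending them in helps more than it
typically does on real data.)

Scoring without evaluation writes a dense score matrix plus a JSON config
echo:

```sh
nbcfdti predict --interactions demo/interactions.tsv \
    --strategy s1 --metric ppmi --outdir demo/scores
```

The same functionality is available as a library: `read_interactions`,
`compute_similarity`, `nbcf_score`, `lra_denoise`, `auxiliary_blend`,
`predict`, `make_folds`, `percentile_ranks`, `run_experiment`,
`SyntheticSpec`/`generate`.

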