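# kronlink

Link prediction on bipartite association networks (e.g. ncRNA–disease) with
Kronecker-product-kernel regularized least squares. The pipeline:

1. **GIP kernels** — Gaussian interaction-profile similarity for both entity
   sets, computed from the binary association matrix with a bandwidth equal to
   the reciprocal mean squared profile norm.
2. **DAG semantic similarity** — disease similarity from decayed shared-ancestor
   contributions on an ontology DAG (layer factor Δ), integrated with the
   disease GIP kernel as their elementwise mean.
3. **Weighted-kNN cold start** — entities with an all-zero profile receive
   initial scores from a similarity-weighted average of their neighbors'
   labels, with the neighbor count controlled by ε.
4. **Kron-RLS solver** — `vec(Ŷᵀ) = K (K + σI)⁻¹ vec(Yᵀ)` with `K = K_c ⊗ K_d`,
   solved through the per-side eigendecompositions and an elementwise spectral
   filter λ/(λ+σ); an explicit-Kronecker solver serves as a small-instance
   oracle.
5. **Evaluation harness** — repeated 5-/10-fold and leave-one-out CV over known
   positives, rank-based AUC with mid-rank ties, held-out positives ranked
   against all never-associated pairs.
6. **Baselines** — `rls-avg`, `rls-kron`, `netlaprls`, `katz`, `nbi`, `wp`
   behind the same predictor interface.
7. **Synthetic generator** — seeded block-model associations plus a
   block-correlated random DAG, so everything is testable without downloads.

## CLI

```sh
# generate a synthetic dataset (edge list, DAG, disease->term mapping)
kronlink simulate --n-circ 60 --n-disease 40 --seed 0 -o data/

# rank all candidate pairs after training on every known positive
kronlink predict data/associations.tsv --dag data/dag.tsv \
    --mapping data/mapping.tsv --disease-sim mean -o predictions.tsv

# cross-validated AUC for any method
kronlink cv data/associations.tsv --method wknn-kronrls --scheme 10CV \
    --repeats 10 --seed 0 -o cv.tsv

# parameter sweep with shared fold assignments across grid values
kronlink sweep data/associations.tsv --param sigma \
    --grid 0.1,0.2,0.5,1.0 --scheme 10CV --repeats 5 -o sweep.tsv
```

Defaults: ε = 1.0, σ = 0.2, Δ = 0.5. A YAML config mirroring those fields can
be passed with `--config`; explicit flags override it. Logs go to stderr,
results to files/stdout.

## File formats

- associations: TSV edge list (`row_id<TAB>col_id`, optional header) or dense
  0/1 TSV with a header row and label column;
- DAG: TSV `child<TAB>parent` edge list (validated acyclic);
- mapping: TSV `disease<TAB>term`, repeated lines accumulate multiple terms;
- predictions: TSV `row_id, col_id, score, rank`, score-descending with
  lexicographic tie breaks.

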