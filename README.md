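# scmnmf

Joint dimensionality reduction and clustering for **multi-block single-cell
omics data** (CITE-seq RNA+ADT, 10x multiome RNA+ATAC, ...) by graph-regularized
non-negative matrix factorization.

Most pipelines reduce each modality and cluster in two separate steps, which
can lock in a poor embedding before clustering ever sees the data. Here both
happen in one optimization: feature selection, the shared low-dimensional cell
embedding, and the cluster assignment all influence each other at every
iteration. The package is aimed at computational biologists who have aligned
cell-by-feature count matrices for the same cells and want hard cluster
labels plus interpretable non-negative factors.

## The model

Given M non-negative blocks X_k ∈ ℝ^{n×J_k} over the same n cells, the model
couples two factorizations through a shared basis W:

    X_k ≈ W H_k                (shared n×p cell embedding, per-block loadings)
    W   ≈ B F                  (B: n×k₁ cluster evidence, F: k₁×p map)

and minimizes

    O = Σ_k ‖X_k − W H_k‖²_F + Σ_k λ_k ‖H_k‖₁ + μ Σ_i ‖w_i·‖₁
        + ‖W − B F‖²_F + α Tr(Bᵀ L B),        W, H_k, B, F ≥ 0,

where L = D − A is the Laplacian of a kNN heat-kernel graph over cells
(A_ij = exp(−‖c_i − c_j‖²/σ) for mutual-or-directed kNN pairs). The ℓ1
penalties make H_k select features and keep W sparse; the Laplacian term
makes the rows of B — each cell's cluster evidence — vary smoothly over the
cell graph, preserving local geometry. Optimization is by alternating
multiplicative updates whose per-iteration objective trace is provably
non-increasing; hard labels come from the row-wise argmax of B (with a
seeded k-means fallback if a cluster would come out empty).

The package also ships the four standard external agreement metrics
(ACC via Hungarian mapping, ARI, NMI = 2·MI/(h(P)+h(Q)), AMI with the exact
hypergeometric expected-MI correction), a planted-cluster negative-binomial
simulator with known labels, single-cell preprocessing defaults, 10x-style
MTX/CSV readers and writers, and a CLI.

## Worked example

```python
from scmnmf import ScMNMF, SyntheticSpec, simulate

spec = SyntheticSpec(n_cells=300, k_types=3, block_features=[500, 800], seed=0)
data = simulate(spec)                       # two count blocks + true labels

res = ScMNMF(data, n_clusters=3, p=20, max_iter=150, tol=1e-5).fit(seed=0)
print(res.summary())
print(res.score().to_json())                # agreement with the true labels
```

which prints

```
scMNMF joint factorization results
==========================================
cells:              300
blocks:             2 (omics_0=500, omics_1=800)
latent dim p:       20
clusters k1:        3
lambda (l1 on H):   0.01
mu (l1 on W):       0.01
alpha (graph):      1.0
iterations:         150 (max_iter reached)
final objective:    767093
assignment:         argmax
cluster sizes:      1:104, 2:92, 3:104
seed:               0

{
  "acc": 0.9966666666666667,
  "ami": 0.9827636851031871,
  "ari": 0.9901984703756908,
  "n": 300,
  "nmi": 0.9830371146822586
}
```

The three planted cell types are recovered almost perfectly (ARI 0.99; ACC
is the best one-to-one relabeling agreement, here 299/300 cells). The
objective trace is available as `res.objective_trace` and is monotone
non-increasing; `res.embedding` holds the n×k₁ cluster-evidence matrix B.

The same pipeline from the shell:

```bash
scmnmf simulate --preset sim1 --out data/      # writes MTX blocks + labels + config.yaml
scmnmf cluster  --config data/config.yaml --out run/
scmnmf evaluate --pred run/labels.csv --truth data/labels.csv
```

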