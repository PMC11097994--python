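# Methods

## Model

The package fits M aligned non-negative cell-by-feature blocks
X_k ∈ ℝ^{n×J_k} with a two-level non-negative factorization. A shared basis
W ∈ ℝ^{n×p} links the blocks (X_k ≈ W H_k with per-block loadings
H_k ∈ ℝ^{p×J_k}); a secondary factorization W ≈ B F splits the embedding
into per-cell cluster evidence B ∈ ℝ^{n×k₁} and a cluster-to-factor map
F ∈ ℝ^{k₁×p}. The joint objective is

O = Σ_k ‖X_k − W H_k‖²_F + Σ_k λ_k‖H_k‖₁ + μ Σ_i ‖w_i·‖₁
    + γ‖W − B F‖²_F + α Tr(Bᵀ L B),  subject to W, H_k, B, F ≥ 0,

with L = D − A the Laplacian of a kNN heat-kernel affinity over cells.
γ (the coupling weight) is fixed at 1 in the model proper; it is exposed so
that γ = λ = μ = α = 0 reduces the solver to classical two-factor NMF, which
is used as a diagnostic cross-check against an independent NMF
implementation.

Assumptions: blocks are non-negative and share the cell axis exactly; the
number of clusters k₁ and the latent dimension p are supplied by the user
(no automatic selection; a small grid over k₁ with the silhouette of B or
prior biological knowledge is the intended practice); cluster structure is
expressed consistently across modalities, since a single W must explain all
blocks.

Note on the smoothness term: for B with cells in rows, the dimensionally
consistent trace form is Tr(Bᵀ L B); this is the quadratic form that equals
½ Σ_ij A_ij‖b_i − b_j‖², and it is what the package computes.

## Graph construction

The affinity is built once, before optimization, on the preprocessed blocks
concatenated along features with each block scaled to unit Frobenius norm
(so no modality dominates the distances). For each cell the `n_neighbors`
(default 15) exact nearest neighbours by Euclidean distance are found; ties
are broken toward the lower cell index so the graph is deterministic. An
edge (i, j) exists when either cell is in the other's neighbour set, with
weight exp(−‖c_i − c_j‖²/σ). By default σ resolves to the mean squared
distance over retained edges, which is scale-invariant and parameter-free;
if all points coincide, σ falls back to 1 with a logged warning. Fixing the
graph a priori (rather than rebuilding it from the current W each iteration)
keeps the B update's monotonicity guarantee intact; a W-adaptive graph is a
possible extension but changes the convergence argument.

## Optimization

Alternating multiplicative updates, one pass per iteration in the order
W → H_1..H_M → B → F:

* W ← W ⊙ (Σ_k X_k H_kᵀ + γBF + ε) ⊘ (W(Σ_k H_k H_kᵀ + γI) + μ/2 + ε)
* H_k ← H_k ⊙ (Wᵀ X_k + ε) ⊘ (WᵀW H_k + λ_k/2 + ε)
* B ← B ⊙ (W Fᵀ + α A B + ε) ⊘ (B F Fᵀ + α D B + ε)
* F ← F ⊙ (Bᵀ W + ε) ⊘ (BᵀB F + ε)

Each rule is the exact minimizer of the standard quadratic auxiliary
function of its sub-problem, splitting the gradient into positive and
negative parts (the graph term contributes +αDB to the positive and +αAB to
the negative part). The ℓ1 weights therefore enter the denominators as
λ_k/2 and μ/2 — the factor ½ comes from the gradient of the squared
Frobenius terms carrying a factor 2, and is required for the guaranteed
monotone descent; un-halved weights would merely correspond to doubled
penalties without the guarantee. The same small ε (default 1e−10) is added
to numerator and denominator: this keeps the update on the segment between
the current iterate and the auxiliary minimizer (so descent is preserved),
and turns exact 0/0 stalls (e.g. the F row of an all-zero B column) into
no-ops rather than hard zeros. Consequently the objective trace is
non-increasing across every full cycle up to floating-point noise; the test
suite asserts this with 1e−8 relative slack.

Initialization draws all factors uniform on (0, 1] from a seeded generator,
then rescales H_k and F so the initial reconstructions match the data's mean
magnitude — this avoids the early plateau that badly scaled multiplicative
updates exhibit. Convergence is declared when
|O_t − O_{t−1}| / max(O_{t−1}, ε) < tol.

Hard labels: rows of B are ℓ1-normalized and each cell takes its argmax
column (ties → lowest index; an all-zero row maps to cluster 1). If any of
the k₁ clusters would be empty, labels are recomputed by seeded k-means on
the rows of B and the results object records which path ran
(`assignment_method`). Argmax is the natural reading of B as cluster
evidence; the k-means fallback guarantees k₁ populated clusters whenever
the embedding supports them.

## Hyperparameters

| name | meaning | default | notes |
|---|---|---|---|
| k₁ | number of clusters | — (required, ≥ 2) | no automatic selection |
| p | latent dimension | 50 | capped at min(n, min_k J_k) − 1, floored at k₁ |
| λ_k | ℓ1 on H_k | 0.01 | scalar broadcast or per-block list |
| μ | ℓ1 on rows of W | 0.01 | scalar broadcast to all cells |
| α | graph penalty weight | 1.0 | 0 disables the graph entirely |
| n_neighbors | kNN size | 15 | clipped to n − 1 on tiny data |
| σ | heat-kernel bandwidth | "auto" | mean squared kNN-edge distance |
| max_iter / tol | stopping | 500 / 1e−6 | relative objective change |
| ε | denominator guard | 1e−10 | also the 0/0-stall guard |

The sparsity defaults are light-touch (about 1% of a typical residual
gradient on library-normalized log counts); they bias toward sparse,
interpretable loadings without distorting the reconstruction.

## Preprocessing

Defaults follow common single-cell practice and are fully overridable:
features detected in < 3 cells are dropped; cells with no detected feature
in any block are dropped jointly across blocks (alignment is never broken);
each cell is scaled to a library size of 1e4 per block; log1p; the 2000
most variable features are kept per block. Every step preserves
non-negativity and cell order. No batch correction, doublet removal or
ADT-specific CLR transform is attempted.

## Synthetic data generator

The generator emulates K planted cell types expressed consistently across
blocks. Labels follow the requested proportions (each type guaranteed at
least one cell). Per block, baseline feature means are lognormal
(median 2, σ_log = 0.8 — a right-skewed mean distribution typical of count
data); 10% of features are markers, each owned by one type, whose mean is
multiplied by e^signal in cells of that type. Counts are negative-binomial
with size r = 2 (var = m + m²/2, moderate overdispersion), then thinned by
independent dropout with probability 0.3. `signal = 2` (≈ 7.4-fold marker
change) is the generator's notion of strong, cleanly separated types;
`signal = 0` is an exact null in which all types share one mean vector.
Defaults were chosen once as realistic for well-separated cell types and are
not tuned per experiment.

Presets `sim1` (530 cells, 3 types, blocks of 2000 and 5000 features) and
`sim2` (250 cells, 5 types, 2500 and 5000) reproduce the *shapes* of the
simulated benchmark datasets only; the underlying generative process of
those published simulations is not reproduced here, so scores on the presets
characterize this generator, not the published data.

`make_manifold_pair` places each type on a noisy arc of a common latent
circle (arc length ∝ `curvature`, span 0.7·π/k per unit curvature, latent
noise 0.03) and lets marker log-means follow the latent position through
random unit loadings, producing elongated, curved clusters where within-type
variation is continuous — the regime where the graph-smoothness penalty on B
is expected to help. `curvature = 0` degenerates exactly to the plain
generator.

What passing tests on this generator do *not* show: robustness to batch
effects, doublets, ambient contamination, modality-specific noise models
(e.g. ADT background), or cluster sizes/shapes beyond NB-with-dropout
blobs and one-dimensional manifolds.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so each
fit carries a clear signal: recovery and ablation conditions use 300 cells,
3 types, blocks of 500 and 800 features (≈ 43 markers per type per block),
p = 20, 150 iterations at tol = 1e−5; the presets run at their published
shapes with default hyperparameters and 300 iterations. Exact kNN and dense
factor algebra are used throughout — the implementation targets datasets up
to a few thousand cells; no approximate-NN index, mini-batching or GPU path
is provided.

Ties: kNN distance ties break toward the lower cell index; argmax label
ties toward the lower cluster id; top-variance feature selection is stable
in the original feature order. Degenerate inputs: identical points give a
σ = 1 heat kernel (all weights 1); all-zero B rows are assigned cluster 1;
zero-library cells stay zero under scaling. The graph penalty clips
rounding-level negative values of the PSD quadratic form at 0.

## Metrics

ACC pads the contingency table square and maximizes matched counts with the
Hungarian algorithm — equivalent to the best one-to-one mapping between
cluster ids and class ids. ARI uses the Hubert–Arabie contingency-table
binomial form. NMI is 2·MI/(h(P)+h(Q)) with natural logs. AMI is
(MI − E[MI]) / (max(h(P), h(Q)) − E[MI]) with E[MI] computed by the exact
hypergeometric summation over feasible cell counts (log-gamma arithmetic for
stability). Degenerate zero-entropy or zero-denominator cases return 1 when
the two partitions induce the same grouping and 0 otherwise. The tests pin
all four against brute-force oracles (exhaustive mapping enumeration,
pair-category counting, full-permutation expected MI) and an independent
reference implementation.

## Known limitations

* The objective is non-convex; different seeds can reach different local
  minima. Labels, not factor values, are the stable output; for critical
  analyses run several seeds and keep the best-objective fit.
* k₁ and p are user inputs; a mis-specified k₁ forces the k-means fallback
  or merged clusters.
* Multiplicative updates stall on exact zeros (a zero entry stays zero);
  the strictly positive initialization avoids spurious zero locking, but
  warm starts containing zeros inherit their support.
* The cell graph is built from the preprocessed data once; if preprocessing
  obscures the geometry (e.g. too few variable features), the Laplacian
  term regularizes toward the wrong neighbourhoods.
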