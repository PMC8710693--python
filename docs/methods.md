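# Methods

`pmgae` predicts links in a bipartite pseudogene–miRNA association network.
The pipeline has three stages: (1) per-node-set similarity profiles are
computed from node attributes and fused; (2) the bipartite graph is embedded
with a graph auto-encoder (GAE); (3) node-pair embeddings are classified
with gradient-boosted trees. This note records the model, the defaults, the
numerical choices, and what the synthetic benchmark does and does not show.

## Similarity profiles

miRNAs are described by 3-mer frequency vectors of their sequences
(`count(w) / (L − k + 1)` over the 4³ = 64 k-mers in lexicographic A<C<G<U
order), pseudogenes by tissue expression min–max scaled per tissue to
[0, 1] (constant tissues map to 0; min–max rather than z-scoring keeps the
features non-negative, which the generalised Jaccard measure requires).

Three similarity measures are computed per node set over these feature
rows:

* **Generalised (Ruzicka) Jaccard** `Σ min(x_k, y_k) / Σ max(x_k, y_k)` —
  reduces to set Jaccard on binary data; a pair of all-zero rows scores 1.
* **Cosine** `x·y / (‖x‖‖y‖)`, zero rows score raw 0 off-diagonal.
* **Pearson correlation**, zero-variance rows score raw 0 off-diagonal.

Cosine and Pearson can be negative, so both are rescaled `s → (s+1)/2` to
share the [0, 1] range the fusion and zero-filling stages assume. Every
finalised similarity matrix is symmetric with unit diagonal and entries in
[0, 1].

Exact zeros in each similarity matrix are replaced by the Gaussian
interaction-profile (GIP) kernel of the binary association matrix,
`G(i,j) = exp(−γ‖IP(i) − IP(j)‖²)` with bandwidth `γ = 1 / mean_i ‖IP(i)‖²`
(γ = 1 when all profiles are empty) — the standard interaction-profile
convention. Because the GIP kernel reads the association matrix, the whole
feature path is recomputed from *training* associations in every
evaluation split (see Leakage control).

## Similarity network fusion

The three views per node set are merged by non-linear cross-diffusion. Each
view contributes a full-kernel transition matrix `P` (off-diagonal mass
halved, diagonal 1/2, rows summing to 1) and a KNN-restricted local
transition matrix `L` (each row renormalised over its K most similar
neighbours, self excluded). One round updates every view as

    P_v ← L_v · (mean of the other views' P) · L_vᵀ

followed by re-application of the weight normalisation (rows to 1, diagonal
to 1/2) and symmetrisation. The renormalisation step follows the
established SNF convention; without it the diffusion loses contrast between
within-module and between-module similarity. Defaults: `K = min(20, n−1)`,
at most 20 rounds with early stop when the largest entry change falls below
1e-6. The fused matrix is the view average with its diagonal set to 1.

Ties in the KNN selection are broken by lower row index (stable argsort),
making runs bit-reproducible.

## Auto-encoder reduction and standardisation

The fused profile rows are compressed with a symmetric stacked auto-encoder
(n → 256 → d → 256 → n, ReLU hidden units, squared-error reconstruction,
Adam, 200 epochs, seed-controlled initialisation; `d` = 128 by default,
backed by scikit-learn's MLPRegressor with the bottleneck activations read
off the fitted weights). Before encoding, the pipeline zeroes the fused
matrix's diagonal and rescales the profile to unit maximum
(`sae_input_profile`): the unit diagonal is constant by construction while
the off-diagonal diffusion weights are ~0.02, so a raw squared-error
objective would spend nearly all capacity reconstructing the diagonal —
empirically this choice is worth ~0.13 held-out AUC at the reduction stage.

The codes are standardised per column twice — z-score with the population
σ, and robust `(x − median)/IQR` with linearly interpolated quantiles — and
the two are averaged; degenerate columns (σ = 0 or IQR = 0) contribute 0.
Pseudogene and miRNA blocks are standardised separately (their auto-encoders
are trained separately; the two sets have different sizes) and stacked,
pseudogene rows first, into the node feature matrix X.

## Graph auto-encoder

The bipartite adjacency is the symmetric block matrix
`A = [[0, PMA], [PMAᵀ, 0]]`. The encoder is a two-layer GCN

    Z = Ã · ReLU(Ã X W0) · W1,   Ã = D̂^{−1/2}(A + I)D̂^{−1/2},

with hidden sizes (64, 32). Self-loops are added before normalisation: the
plain symmetric normalisation is undefined for isolated nodes and would
never mix a node's own features into its embedding. The inner-product
decoder `σ(Z Zᵀ)` is used only to form the training loss — the mean binary
cross-entropy over all adjacency entries, with predictions clamped to
[1e-15, 1 − 1e-15] and a positive-class weight defaulting to
#zeros/#ones of A (the graph is sparse; weight 1 recovers the unweighted
form). Training is full-batch Adam, learning rate 0.001, 8,000 epochs by
default, Glorot-uniform seed-controlled initialisation, implemented in
numpy with hand-derived gradients; a non-finite loss aborts with a
diagnostic. Prediction never uses the decoder: the 32-dim embeddings go to
the classifier.

## Pair classification

A (pseudogene, miRNA) pair is the concatenation `[z_p, z_m]` (64 dims),
pseudogene half first — concatenation rather than a symmetric combination
because the relation is directed by role. The classifier is XGBoost
(binary logistic objective, 100 trees, depth 6, learning rate 0.3, L2 leaf
regularisation 1.0, single-threaded, seeded). Scores are used directly for
ranking; confusion-matrix metrics threshold at 0.5. Ranking ties are broken
lexicographically by miRNA id, so rankings are invariant to candidate
order.

## Evaluation protocols

**Cross-validation.** Negatives are drawn once per experiment, uniformly
without replacement from the zero cells of the association matrix, at
`neg_ratio` × the positive count, then split alongside the positives by
stratified k-fold (k = 5). Metrics: accuracy, sensitivity, specificity,
precision, MCC (zero denominators reported as 0 with a warning), ROC AUC,
and AUPR (average-precision step integration).

**Leakage control.** For every fold the GIP kernel, zero-filling, fusion,
auto-encoder, standardisation, and the GAE adjacency are all rebuilt from
training-fold positives only; test positives appear nowhere in the
structures that produce their features. (The association-free
Jaccard/cosine/Pearson views are computed once.) An unmasked mode
(`mask_test_edges=False`) embeds on the full graph for comparison.

**Case study.** Leave-pseudogene-out: every association involving a
holdout pseudogene is removed from training (including sampled negatives in
holdout rows), the model is trained once, and all miRNAs are ranked per
holdout. A paired-input audit in the test suite verifies that deleting a
holdout's own associations from the input leaves its ranking unchanged.

## Synthetic benchmark

The generator plants one latent vector per node and derives all observable
layers from it. Latents are cluster archetypes — a unit basis vector in
`latent_dim` = 8 dimensions plus isotropic noise (sd 0.4) — emulating the
modularity of real ceRNA data, where miRNA families share target sets and
pseudogenes form co-expressed modules. Expression is a softplus-mapped
linear readout of the latent (noise sd 0.1, 20 tissues); sequences are 60-nt
strings assembled from 3-mers drawn from a mixture of a uniform background
and 8 designated motif 3-mers weighted by the node's latent
(`motif_strength` = 0.8 mixes the two); edges are Bernoulli with
probability `σ(4·u_i·v_j + b)`, the offset calibrated so the expected edge
count is 500 over a 120 × 60 grid (~7% density, comparable to the real
network's scale at desk size; `full_scale()` gives 444 × 173 / 1,884).
A fraction `edge_noise` = 0.05 of realised edges is rewired to uniformly
random empty cells, preserving the calibrated count while making 5% of
edges pure noise.

The null control (`decouple_edges=True`, `motif_strength=0`) makes edges
i.i.d. Bernoulli at the target density: neither the attributes nor the
graph itself carry structure, so cross-validated AUC sits at chance. Note
that a graph drawn from *independent but structured* latents would not be a
null — its internal structure is learnable from training folds by the graph
stage alone.

What passing these tests shows: the pipeline recovers planted modular
structure from attribute similarity plus partial graph observation, with no
feature leakage, and reproduces the expected imbalance behaviour (AUPR
degrades as the negative ratio grows 1→10 while AUC stays within a 0.05
band). What it does not show: performance on real curated association data,
whose similarity structure, degree distribution, and noise are richer than
the cluster-archetype model; the generator also ignores real miRNA biology
(seed-site pairing, conservation) and expression count noise.

## Problem sizes and reduced budgets

Cross-validated experiments in the test suite and the acceptance script run
at the 120 × 60 fixture scale with the auto-encoder bottleneck at 32 (it
must stay below the smaller node set, 60), auto-encoder budget 200 epochs,
and GAE budget 500 epochs — chosen as the package's standard desk-scale
configuration. The full-scale dimensional check (444 × 173, default
128-dim codes and 32-dim embeddings) runs with reduced epoch budgets since
only shapes are asserted. The GAE's 8,000-epoch default mirrors the
published setup for full runs; on the dense small fixture, held-out
performance peaks far earlier, and long budgets slowly overfit the decoder
to training edges — a known trade-off of full-batch reconstruction
training on small graphs.

## Known limitations

* The GAE is full-batch and dense (O(n²) memory in node count); it targets
  networks of hundreds to a few thousand nodes, not GPU-scale graphs.
* Negative "associations" are unverified non-edges; sampled negatives may
  contain true but unobserved associations, which depresses measured
  precision on real data.
* The stacked auto-encoder bottleneck must be smaller than the node-set
  size, so very small networks need a reduced `sae_dim`.
* Expression quality control and filtering are upstream concerns: missing
  values are an error, never imputed.
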