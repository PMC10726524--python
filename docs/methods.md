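# Methods

## Model

Each T cell contributes three feature blocks. Expression input is assumed
log-normalised (and, if desired, batch-corrected) upstream; the package only
validates finiteness and reduces the panel to the top highly variable genes
(default 2000, capped at the panel size) ranked by a deterministic
dispersion score, variance/|mean| with ties broken by column index. CDR3
sequences are one-hot encoded over the 20 canonical amino acids plus an
explicit padding symbol (21 columns), left-aligned and right-padded to the
per-chain maximum length observed in the training data; longer sequences at
inference are an error, never silently truncated. V/J genes are one-hot
indicators over per-slot vocabularies built from the training data; unknown
genes at inference are an error (no "unknown" bucket).

The encoder applies: a 1024-unit dense + ReLU to RNA; a trainable
48-dimensional embedding per V/J slot (four slots concatenated); and, per
CDR3 chain, a position-wise dense map from the 21-symbol one-hot into a
16-channel continuous space followed by three stride-1, same-padding,
kernel-3 convolutions with 32/64/128 feature maps and ReLU activations,
flattened. The concatenation feeds a 512-unit hidden layer, then separate
affine heads produce μ and log σ of a 256-dimensional diagonal-Gaussian
posterior (σ = exp(log σ) for positivity). Sampling uses the
reparameterisation z = μ + σ ⊙ ε. The decoder mirrors the encoder: a
512-unit hidden layer, a dense RNA head, one dense head per V/J slot, and
per chain a dense map back to the position × 128 feature space followed by
three stride-1 convolutions down to 21 per-position logits. For stride 1
with same padding, a transposed convolution is exactly a convolution with a
flipped kernel, so the mirrored deconvolution stack is parameterised
directly as convolutions; kernel size, channel dims and feature maps are
all configurable in `ArchitectureConfig`. With `include_rna=False` the RNA
branch and head are dropped (TCR-only integration).

## Loss and training

The objective is L = α_latent·V_loss + α_gene·R_gene + α_seq·R_CDR3 +
R_RNA. V_loss is the diagonal-Gaussian KL to N(0, I), summed over latent
dimensions and averaged over the minibatch. R_RNA is the per-cell mean
squared error over genes, averaged over cells. R_gene sums the
cross-entropy of the four V/J slots; R_CDR3 sums per-position
cross-entropies over both chains including padding positions (the decoder
must learn where a sequence ends); both are averaged over cells.
Probabilities inside logs are clamped at 1e-8. Training uses Adam
(lr 0.001, β = 0.9/0.999) with batch size 256 for up to 100 epochs and an
early stop when the epoch total fails to improve by 1e-4 for 10 epochs.
All randomness (initialisation, shuffling, reparameterisation noise)
derives from a single integer seed, so traces are bit-reproducible.
Training aborts with a diagnostic naming the offending component if any
loss turns non-finite, and warns when expression magnitudes exceed 50 —
the signature of raw counts passed instead of log-normalised data, which
destabilises training.

The network and its gradients run on a small numpy reverse-mode autodiff
engine inside the package (dense, embedding and im2col convolutions reduce
to matrix products in both passes); gradient correctness is checked against
central finite differences in the test suite.

Latent extraction returns the posterior mean μ(X), never a sample, so
embeddings are deterministic given a checkpoint. Visualisation runs PCA on
the latent space followed by seeded UMAP.

## Weight selection

The three weights are dataset-dependent. The grid search trains each
candidate triple from `{1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1}`³ on a
random subsample (default 4000 cells) and maximises cell-type ASW plus
reconstruction accuracy subject to (1) ASW strictly above 0.5 — better
than random — and (2) final loss at most 115% of the grid minimum — the
model must still fit. The two accuracies are averaged by default so that
the ASW and accuracy terms have equal ranges (a switch restores plain
summation); ties break toward the lexicographically smallest triple. The
per-candidate epoch budget is reduced (configurable) relative to full
training. The values 1e-6/1e-3/1e-2 that ship as `LossWeights` defaults
were selected on a real paired blood/CSF T-cell dataset and are
dataset-specific.

For the synthetic study the package uses a modality-balance default
(α_latent = 1e-6, α_gene = 1, α_seq = 0.1): at initialisation the
unweighted terms are R_RNA ≈ 11 (set by the simulated centroid spread and
noise), R_gene ≈ 4·ln K ≈ 9 and R_CDR3 ≈ 2·L·ln 21 ≈ 97, so these weights
give each reconstruction term the same order of magnitude, rounded to the
grid's powers of ten; α_latent is kept tiny so the latent geometry is
shaped by reconstruction, as in the real-data configuration.

## Synthetic data

The generator plants the structure the model is supposed to recover: cell
types are Gaussian expression centroids (per-gene sd `type_separation`,
default 3), cells add a per-batch shift vector (sd `batch_shift`, default
1) and i.i.d. noise (sd 1); clonotypes carry identical CDR3α/β sequences
(uniform random amino acids, lengths 8–16) and V/J genes for all their
cells, with sizes skewed geometrically to mimic clonal expansion, and map
to a single cell type when `clone_type_concordance = 1`. Default scale is
600 cells × 100 genes, 3 types, 20 clonotypes, 2 batches, 2 tissues.
Defaults are sized so the planted types are clearly recoverable from raw
RNA (normalised ASW > 0.8) while leaving non-trivial within-type noise.
What the generator does **not** model: count statistics and dropout,
V(D)J recombination biology, CDR3 motif structure, antigen specificity,
realistic batch effects beyond an additive shift. Passing tests therefore
certify the algorithmic behaviour of the pipeline — not biological
realism or performance on real repertoires.

## Metrics

All distances are Euclidean. Normalised ASW rescales the mean silhouette
to [0, 1] via (s̄ + 1)/2; singleton labels score 0. bASW computes the
batch-label silhouette within each tissue, rescales per tissue, combines
tissues by cell-count weights and reports 1 − bASW (higher = better
mixing); tissues with one batch are excluded with a warning. kBET is
implemented from its description: for randomly chosen cells, a χ²
goodness-of-fit test (df = number of batches − 1) compares the batch
composition of the k-nearest neighbourhood (self included) to the global
proportions; the rejection rate at level α is reported as 1 − kBET.
Defaults k = 25, 500 tests, α = 0.05, explicit seed. Reconstruction
accuracy decodes by argmax (ties to the lowest index); CDR3 accuracy
excludes positions that are padding in the original, which would otherwise
inflate the score. Within-cluster normalised distance divides a cluster's
mean pairwise distance by the mean pairwise distance over all cells;
cluster assignments can come from any external grouping (e.g. a GLIPH2
run) as a two-column table.

## Numerical and design choices

* Multi-chain barcodes keep the highest-UMI contig per locus; ties break
  by lexicographic CDR3 then V/J, making pairing order-invariant.
* Missing or non-affirmative productivity flags drop the contig.
* Barcode matching is exact string equality; suffixes are preserved.
* Checkpoints are single `.npz` files holding parameters plus JSON
  metadata (architecture, data dimensions, HVG list), versioned.
* The acceptance study trains 60 epochs at 600 cells × 100 genes and uses
  a reduced 4-point grid for the selection demonstration; these sizes keep
  a CPU run in the minutes range while leaving all tested effects far from
  their decision thresholds.

## Known limitations

* The MSE RNA loss presumes roughly Gaussian residuals on the log scale;
  raw counts are not supported (by design — training warns).
* kBET's χ² approximation weakens when k × batch proportion < 1; the
  implementation warns and proceeds.
* The latent dimension (256) exceeds the synthetic study's intrinsic
  dimensionality by far; no pruning or disentanglement is attempted.
* Batch effects present in the expression input propagate into the latent
  space; the package measures mixing but does not correct batches itself.
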