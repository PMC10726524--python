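# tcrvae

Joint latent-space integration of paired single-cell RNA-seq and single-cell
TCR-seq data, with the evaluation metrics used to judge integration quality.

## The problem

Single-cell studies of T cells increasingly measure two modalities per cell:
the transcriptome (scRNA-seq) and the T-cell receptor (scTCR-seq) — the CDR3
amino-acid sequence and the V/J gene segments of both the α and β chains.
Cell state lives mostly in the transcriptome; antigen specificity and clonal
history live in the receptor. `tcrvae` embeds both into one latent space so
that downstream analyses (clustering, visualisation, trajectory methods,
clonotype tracking) can use a single representation that preserves cell-type
structure *and* pulls cells of the same clonotype together.

## The model

Each cell's features are encoded by three branches and fused in a
variational autoencoder:

* **RNA** — the log-normalised expression of the top highly variable genes,
  passed through a 1024-unit dense projection;
* **V/J genes** — each of the four slots (Vα, Jα, Vβ, Jβ) one-hot encoded
  and mapped through a trainable 48-dimensional embedding;
* **CDR3** — each chain one-hot encoded over a 21-symbol alphabet
  (20 amino acids + padding), mapped position-wise to a continuous channel
  space and through three convolutions with 32/64/128 feature maps.

The concatenation X passes through a 512-unit layer to a diagonal-Gaussian
posterior N(μ(X), σ(X)) on a 256-dimensional latent space; a mirrored
decoder reconstructs all modalities. The training objective is

```
L = α_latent · V_loss + α_gene · R_gene + α_seq · R_CDR3 + R_RNA
```

where `V_loss` is the KL divergence to the standard normal, `R_RNA` the
per-cell mean squared error over genes, and `R_gene` / `R_CDR3`
cross-entropies over the four gene slots and all CDR3 positions. The three
weights balance the modalities and are selected by a grid search over
`{1e-6 … 1}` that maximises cell-type ASW plus reconstruction accuracy,
subject to ASW > 0.5 and a final loss within 115% of the grid minimum.
Setting `include_rna=False` integrates the TCR features alone.

Evaluation metrics: normalised ASW (silhouette rescaled to [0, 1]), V/J and
CDR3 argmax reconstruction accuracy, tissue-weighted batch ASW reported as
1 − bASW, the kBET χ² rejection rate reported as 1 − kBET, and normalised
within-cluster pairwise distances for externally supplied TCR-similarity
clusters (e.g. GLIPH2 output).

## Worked example

```bash
tcrvae simulate --n-cells 200 --seed 2 --out sim/
tcrvae pair --contigs sim/contigs.csv --expr sim/expression.tsv \
            --meta sim/metadata.tsv --out paired/
tcrvae train --data paired/ --alpha-gene 1.0 --alpha-seq 0.1 \
             --epochs 20 --hvg 100 --seed 0 --out trained/
tcrvae embed --model trained/model.npz --data paired/ --out latent.tsv
tcrvae evaluate --embedding latent.tsv --meta sim/metadata.tsv \
                --metrics asw,basw,kbet --k 15 --n-tests 50 --out report.json
```

The train step prints one line per epoch:

```
epoch   0  v_loss=126.51151  r_rna=12.07282  r_gene=10.58551  r_cdr3=99.45937  total=32.60439
...
epoch  19  v_loss=1806.66474  r_rna=1.93531  r_gene=0.15910  r_cdr3=25.09480  total=4.60569
```

showing the reconstruction terms falling as the model learns (with
α_latent = 10⁻⁶ the KL term is essentially unconstrained and drifts up
while reconstructions improve). The evaluate step prints a JSON report:

```json
{"asw":  {"asw": 0.7154, "n": 200},
 "basw": {"basw": 0.5238, "one_minus_basw": 0.4762, "...": "..."},
 "kbet": {"rejection_rate": 0.74, "one_minus_kbet": 0.26, "k": 15, "alpha": 0.05}}
```

Here `asw` = 0.72 means the latent space separates the three simulated cell
types well above the 0.5 random-performance floor; because the simulator's
additive batch shift was left uncorrected upstream, the batch-mixing scores
are mediocre (kBET rejects 74% of neighbourhoods). A `manifest_*.json` is
written next to every output with the full configuration, seeds and input
checksums.

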