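"""The multimodal variational autoencoder and its four-part loss.

Three modality branches feed one Gaussian latent space:

* RNA: a dense projection to 1024 units (the expression input is expected
  to be normalised, log-transformed, HVG-reduced upstream);
* V/J genes: each of the four slots (V-alpha, J-alpha, V-beta, J-beta) is
  one-hot encoded and passed through its own trainable 48-dimensional
  embedding;
* CDR3: each chain's one-hot matrix goes through a position-wise dense map
  into a continuous channel space and then three stride-1 convolutions with
  32/64/128 feature maps, and is flattened.

The concatenation passes through a 512-unit hidden layer to the posterior
mean and log-sigma heads (latent dimension 256 by default); the decoder
mirrors the encoder (the stride-1 deconvolutions of the CDR3 heads are
parameterised directly as stride-1 convolutions, which span the same
function class).  The loss is

    L = a_latent * V_loss + a_gene * R_gene + a_seq * R_CDR3 + R_RNA

with V_loss the diagonal-Gaussian KL to the standard normal, R_RNA the
per-cell mean squared error over genes, and R_gene / R_CDR3 cross-entropies
over the four gene slots and all CDR3 positions (padding positions are
scored against the padding symbol).  All components are averaged over the
cells of the minibatch.  Training uses Adam with learning rate 0.001.

With ``include_rna=False`` the RNA branch and RNA head are dropped and the
model integrates the TCR features alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, concat, no_grad, softmax_cross_entropy
from .encoding import ALPHABET_SIZE, EncodedBatch, build_encoded_batch
from .errors import ConfigError, TcrVaeError
from .io import PairedDataset

_EPS = 1e-8  # clamp inside cross-entropy logs


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ArchitectureConfig:
    rna_proj_dim: int = 1024
    vj_embed_dim: int = 48
    cnn_feature_maps: tuple[int, int, int] = (32, 64, 128)
    cnn_kernel_size: int = 3
    cdr3_channel_dim: int = 16   # position-wise dense map before the CNN
    encoder_hidden: int = 512
    latent_dim: int = 256
    decoder_hidden: int = 512
    include_rna: bool = True

    def __post_init__(self):
        dims = (self.rna_proj_dim, self.vj_embed_dim, self.cnn_kernel_size,
                self.cdr3_channel_dim, self.encoder_hidden, self.latent_dim,
                self.decoder_hidden, *self.cnn_feature_maps)
        if any(d <= 0 for d in dims):
            raise ConfigError("all architecture dimensions must be positive")
        self.cnn_feature_maps = tuple(self.cnn_feature_maps)


@dataclass
class LossWeights:
    """Weights of the variational, V/J-gene and CDR3 loss terms.

    The RNA term carries an implicit weight of 1.  The defaults are values
    selected by grid search on a real paired blood/CSF T-cell dataset and
    are dataset-specific; rerun the grid search for new data.
    """

    alpha_latent: float = 1e-6
    alpha_gene: float = 1e-3
    alpha_seq: float = 1e-2

    def __post_init__(self):
        vals = (self.alpha_latent, self.alpha_gene, self.alpha_seq)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ConfigError("loss weights must be finite and non-negative")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    early_stop_patience: int = 10
    early_stop_tol: float = 1e-4


@dataclass
class LossBreakdown:
    v_loss: float
    r_rna: float
    r_gene: float
    r_cdr3: float
    total: float


@dataclass
class LatentParams:
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray


@dataclass
class ModelDims:
    """Data-dependent dimensions the architecture is instantiated for."""

    n_genes: int
    max_len_alpha: int
    max_len_beta: int
    v_alpha: int
    j_alpha: int
    v_beta: int
    j_beta: int

    @staticmethod
    def from_batch(batch: EncodedBatch) -> "ModelDims":
        return ModelDims(
            n_genes=batch.rna.shape[1],
            max_len_alpha=batch.cdr3_alpha.shape[1],
            max_len_beta=batch.cdr3_beta.shape[1],
            v_alpha=batch.v_alpha.shape[1], j_alpha=batch.j_alpha.shape[1],
            v_beta=batch.v_beta.shape[1], j_beta=batch.j_beta.shape[1])


# ---------------------------------------------------------------------------
# loss functions (public, array-based; used both in training and evaluation)


def _as_probs(scores: np.ndarray) -> np.ndarray:
    """Normalise non-negative scores to probabilities on the last axis."""
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(scores < 0):
        # treat as logits: softmax
        z = scores - scores.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=-1, keepdims=True)
    totals = scores.sum(axis=-1, keepdims=True)
    return scores / np.where(totals > 0, totals, 1.0)


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Diagonal-Gaussian KL to N(0, I): mean over cells of
    0.5 * sum_d (mu^2 + sigma^2 - 1 - ln sigma^2)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per_cell = 0.5 * np.sum(mu ** 2 + sigma ** 2 - 1.0 - np.log(sigma ** 2),
                            axis=1)
    return float(per_cell.mean())


def rna_loss(orig: np.ndarray, recon: np.ndarray) -> float:
    """Mean over cells of the per-cell mean squared error over genes."""
    orig = np.atleast_2d(np.asarray(orig, dtype=np.float64))
    recon = np.atleast_2d(np.asarray(recon, dtype=np.float64))
    if orig.shape != recon.shape:
        raise ValueError(f"shape mismatch {orig.shape} vs {recon.shape}")
    return float(((orig - recon) ** 2).mean(axis=1).mean())


def gene_loss(orig: dict[str, np.ndarray],
              recon: dict[str, np.ndarray]) -> float:
    """Cross-entropy summed over the four V/J slots, averaged over cells.

    `recon` values may be probabilities or logits; they are normalised per
    slot.  Probabilities are clamped below at 1e-8 inside the log.
    """
    n = next(iter(orig.values())).shape[0]
    per_cell = np.zeros(n)
    for slot, t in orig.items():
        p = _as_probs(recon[slot])
        if p.shape != t.shape:
            raise ValueError(f"slot {slot}: shape mismatch {p.shape} vs {t.shape}")
        per_cell += -(t * np.log(np.clip(p, _EPS, None))).sum(axis=-1)
    return float(per_cell.mean())


def cdr3_loss(orig_alpha: np.ndarray, orig_beta: np.ndarray,
              recon_alpha: np.ndarray, recon_beta: np.ndarray) -> float:
    """Cross-entropy over both chains and all positions (padding included
    as the padding class), averaged over cells."""
    per_cell = 0.0
    for t, r in ((orig_alpha, recon_alpha), (orig_beta, recon_beta)):
        t = np.asarray(t, dtype=np.float64)
        p = _as_probs(r)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
        per_cell = per_cell + (
            -(t * np.log(np.clip(p, _EPS, None))).sum(axis=-1).sum(axis=-1))
    return float(np.mean(per_cell))


def total_loss(v_loss: float, r_rna: float, r_gene: float, r_cdr3: float,
               weights: LossWeights) -> LossBreakdown:
    """Weighted sum L = a_latent*V + a_gene*R_gene + a_seq*R_CDR3 + R_RNA."""
    total = (weights.alpha_latent * v_loss + weights.alpha_gene * r_gene
             + weights.alpha_seq * r_cdr3 + r_rna)
    return LossBreakdown(v_loss=v_loss, r_rna=r_rna, r_gene=r_gene,
                         r_cdr3=r_cdr3, total=total)


# ---------------------------------------------------------------------------
# the network


class MultimodalVAE(nn.Module):
    checkpoint_extra: dict | None = None

    def __init__(self, arch: ArchitectureConfig, dims: ModelDims, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.dims = dims
        fm1, fm2, fm3 = arch.cnn_feature_maps
        k = arch.cnn_kernel_size

        concat_dim = 0
        if arch.include_rna:
            self.rna_proj = nn.Dense(dims.n_genes, arch.rna_proj_dim, rng)
            concat_dim += arch.rna_proj_dim
        for slot, size in (("v_alpha", dims.v_alpha), ("j_alpha", dims.j_alpha),
                           ("v_beta", dims.v_beta), ("j_beta", dims.j_beta)):
            setattr(self, f"emb_{slot}", nn.Embedding(size, arch.vj_embed_dim, rng))
        concat_dim += 4 * arch.vj_embed_dim
        for chain, L in (("alpha", dims.max_len_alpha), ("beta", dims.max_len_beta)):
            setattr(self, f"cdr3_embed_{chain}",
                    nn.Dense(ALPHABET_SIZE, arch.cdr3_channel_dim, rng))
            setattr(self, f"conv1_{chain}", nn.Conv1d(arch.cdr3_channel_dim, fm1, k, rng))
            setattr(self, f"conv2_{chain}", nn.Conv1d(fm1, fm2, k, rng))
            setattr(self, f"conv3_{chain}", nn.Conv1d(fm2, fm3, k, rng))
            concat_dim += L * fm3
        self.concat_dim = concat_dim

        self.enc_hidden = nn.Dense(concat_dim, arch.encoder_hidden, rng)
        self.mu_head = nn.Dense(arch.encoder_hidden, arch.latent_dim, rng)
        self.logsig_head = nn.Dense(arch.encoder_hidden, arch.latent_dim, rng)

        self.dec_hidden = nn.Dense(arch.latent_dim, arch.decoder_hidden, rng)
        if arch.include_rna:
            self.rna_head = nn.Dense(arch.decoder_hidden, dims.n_genes, rng)
        for slot, size in (("v_alpha", dims.v_alpha), ("j_alpha", dims.j_alpha),
                           ("v_beta", dims.v_beta), ("j_beta", dims.j_beta)):
            setattr(self, f"head_{slot}", nn.Dense(arch.decoder_hidden, size, rng))
        for chain, L in (("alpha", dims.max_len_alpha), ("beta", dims.max_len_beta)):
            setattr(self, f"dec_seq_{chain}", nn.Dense(arch.decoder_hidden, L * fm3, rng))
            setattr(self, f"deconv1_{chain}", nn.Conv1d(fm3, fm2, k, rng))
            setattr(self, f"deconv2_{chain}", nn.Conv1d(fm2, fm1, k, rng))
            setattr(self, f"deconv3_{chain}", nn.Conv1d(fm1, ALPHABET_SIZE, k, rng))

    # -- forward passes -------------------------------------------------------
    def _check_batch(self, batch: EncodedBatch) -> None:
        d = self.dims
        expected = {"rna": (d.n_genes,) if self.arch.include_rna else None,
                    "cdr3_alpha": (d.max_len_alpha, ALPHABET_SIZE),
                    "cdr3_beta": (d.max_len_beta, ALPHABET_SIZE),
                    "v_alpha": (d.v_alpha,), "j_alpha": (d.j_alpha,),
                    "v_beta": (d.v_beta,), "j_beta": (d.j_beta,)}
        for name, shape in expected.items():
            if shape is None:
                continue
            got = getattr(batch, name).shape[1:]
            if tuple(got) != shape:
                raise ConfigError(f"block {name!r} has shape {got}, expected {shape}")

    def _encode_chain(self, chain: str, onehot: Tensor) -> Tensor:
        h = getattr(self, f"cdr3_embed_{chain}")(onehot)
        h = getattr(self, f"conv1_{chain}")(h).relu()
        h = getattr(self, f"conv2_{chain}")(h).relu()
        h = getattr(self, f"conv3_{chain}")(h).relu()
        n, L, c = h.data.shape
        return h.reshape(n, L * c)

    def encode_t(self, batch: EncodedBatch,
                 eps: np.ndarray | None = None) -> tuple[Tensor, Tensor, Tensor]:
        """Graph-building encoder; returns (mu, logsig, z) tensors."""
        self._check_batch(batch)
        parts = []
        if self.arch.include_rna:
            parts.append(self.rna_proj(Tensor(batch.rna)).relu())
        for slot in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
            parts.append(getattr(self, f"emb_{slot}")(Tensor(getattr(batch, slot))))
        parts.append(self._encode_chain("alpha", Tensor(batch.cdr3_alpha)))
        parts.append(self._encode_chain("beta", Tensor(batch.cdr3_beta)))
        h = self.enc_hidden(concat(parts, axis=1)).relu()
        mu = self.mu_head(h)
        logsig = self.logsig_head(h)
        sigma = logsig.exp()
        if eps is None:
            z = mu
        else:
            z = mu + sigma * Tensor(eps)
        return mu, logsig, z

    def decode_t(self, z: Tensor) -> dict[str, Tensor]:
        """Graph-building decoder; returns logits/values per head."""
        h = self.dec_hidden(z).relu()
        out: dict[str, Tensor] = {}
        if self.arch.include_rna:
            out["rna"] = self.rna_head(h)
        for slot in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
            out[slot] = getattr(self, f"head_{slot}")(h)
        fm3 = self.arch.cnn_feature_maps[2]
        for chain, L in (("alpha", self.dims.max_len_alpha),
                         ("beta", self.dims.max_len_beta)):
            s = getattr(self, f"dec_seq_{chain}")(h)
            s = s.reshape(z.data.shape[0], L, fm3).relu()
            s = getattr(self, f"deconv1_{chain}")(s).relu()
            s = getattr(self, f"deconv2_{chain}")(s).relu()
            out[f"cdr3_{chain}"] = getattr(self, f"deconv3_{chain}")(s)
        return out

    # -- user-facing inference ------------------------------------------------
    def encode(self, batch: EncodedBatch,
               rng: np.random.Generator | None = None) -> LatentParams:
        """Posterior parameters for a batch; `z` is sampled only if an `rng`
        is supplied, otherwise z = mu."""
        with no_grad():
            eps = None
            if rng is not None:
                eps = rng.standard_normal(
                    (batch.n_cells, self.arch.latent_dim))
            mu, logsig, z = self.encode_t(batch, eps)
        out = LatentParams(mu=mu.data, sigma=np.exp(logsig.data), z=z.data)
        if not np.all(np.isfinite(out.mu)):
            raise TcrVaeError("non-finite activations in encoder")
        return out

    def decode(self, z: np.ndarray) -> dict[str, np.ndarray]:
        with no_grad():
            out = self.decode_t(Tensor(np.atleast_2d(z)))
        return {k: v.data for k, v in out.items()}

    def reconstruct(self, batch: EncodedBatch) -> dict[str, np.ndarray]:
        """Deterministic reconstruction through the posterior mean."""
        return self.decode(self.encode(batch).mu)

    # -- training loss --------------------------------------------------------
    def batch_loss(self, batch: EncodedBatch, weights: LossWeights,
                   eps: np.ndarray) -> tuple[Tensor, LossBreakdown]:
        n = batch.n_cells
        mu, logsig, z = self.encode_t(batch, eps)
        recon = self.decode_t(z)

        sigma2 = (logsig * 2.0).exp()
        kl = ((mu.square() + sigma2 - 1.0 - logsig * 2.0).sum() * (0.5 / n))

        gene = Tensor(0.0)
        for slot in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
            ce = softmax_cross_entropy(recon[slot], getattr(batch, slot), _EPS)
            gene = gene + ce.sum() * (1.0 / n)
        seq = Tensor(0.0)
        for chain in ("alpha", "beta"):
            ce = softmax_cross_entropy(recon[f"cdr3_{chain}"],
                                       getattr(batch, f"cdr3_{chain}"), _EPS)
            seq = seq + ce.sum() * (1.0 / n)
        if self.arch.include_rna:
            diff = recon["rna"] - Tensor(batch.rna)
            rna = diff.square().sum() * (1.0 / (n * batch.rna.shape[1]))
        else:
            rna = Tensor(0.0)

        total = (kl * weights.alpha_latent + gene * weights.alpha_gene
                 + seq * weights.alpha_seq + rna)
        breakdown = LossBreakdown(v_loss=kl.item(), r_rna=rna.item(),
                                  r_gene=gene.item(), r_cdr3=seq.item(),
                                  total=total.item())
        return total, breakdown


# ---------------------------------------------------------------------------
# training / extraction


def _prepare_batch(data: PairedDataset | EncodedBatch,
                   hvg_genes: list[str] | None) -> EncodedBatch:
    if isinstance(data, EncodedBatch):
        return data
    return build_encoded_batch(data, hvg_genes)


def train_vae(data: PairedDataset | EncodedBatch,
              arch: ArchitectureConfig = ArchitectureConfig(),
              weights: LossWeights = LossWeights(),
              cfg: TrainingConfig = TrainingConfig(),
              hvg_genes: list[str] | None = None,
              ) -> tuple[MultimodalVAE, list[LossBreakdown]]:
    """Train the VAE; fully determined by `cfg.seed`.

    Returns the trained model and one loss breakdown per epoch (the
    cell-weighted mean of the minibatch losses).  Aborts with a diagnostic
    naming the offending component if any loss turns non-finite; warns on
    extreme input magnitudes, which typically indicate raw counts were
    passed instead of log-normalised expression.
    """
    batch = _prepare_batch(data, hvg_genes)
    if batch.n_cells == 0:
        raise TcrVaeError("cannot train on an empty dataset")
    if not np.all(np.isfinite(batch.rna)):
        raise TcrVaeError("expression block contains non-finite values")
    if np.abs(batch.rna).max() > 50:
        warnings.warn("expression values have extreme magnitudes (>50); "
                      "expected log-normalised input", stacklevel=2)

    rng = np.random.default_rng(cfg.seed)
    model = MultimodalVAE(arch, ModelDims.from_batch(batch),
                          seed=int(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    trace: list[LossBreakdown] = []
    best = np.inf
    stall = 0
    n = batch.n_cells
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = np.zeros(5)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            sub = batch.subset(idx)
            eps = rng.standard_normal((len(idx), arch.latent_dim))
            opt.zero_grad()
            loss, bd = model.batch_loss(sub, weights, eps)
            parts = {"variational": bd.v_loss, "rna": bd.r_rna,
                     "gene": bd.r_gene, "cdr3": bd.r_cdr3}
            bad = [k for k, v in parts.items() if not np.isfinite(v)]
            if bad:
                raise TcrVaeError(
                    f"non-finite loss component(s) {bad} at epoch {_epoch}")
            loss.backward()
            opt.step()
            sums += len(idx) * np.array([bd.v_loss, bd.r_rna, bd.r_gene,
                                         bd.r_cdr3, bd.total])
        ep = sums / n
        trace.append(LossBreakdown(*ep))
        if best - ep[4] > cfg.early_stop_tol:
            best = ep[4]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                break
    return model, trace


def extract_latent(model: MultimodalVAE,
                   data: PairedDataset | EncodedBatch,
                   hvg_genes: list[str] | None = None) -> np.ndarray:
    """Posterior means mu(X) for every cell, in dataset order (no sampling)."""
    batch = _prepare_batch(data, hvg_genes)
    return model.encode(batch).mu


def embed_for_visualization(latent: np.ndarray, n_pcs: int = 50,
                            seed: int = 0) -> np.ndarray:
    """PCA on the latent space followed by a seeded 2-D UMAP."""
    from sklearn.decomposition import PCA

    latent = np.asarray(latent, dtype=np.float64)
    if n_pcs > latent.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds latent dimension {latent.shape[1]}")
    n_pcs = min(n_pcs, latent.shape[0] - 1, latent.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(latent)
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(pcs), dtype=np.float64)


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: MultimodalVAE, path: str | Path,
               extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + architecture + dimensions."""
    path = Path(path)
    params = {k: v.data for k, v in model.named_parameters().items()}
    meta = {"format_version": 1,
            "arch": asdict(model.arch),
            "dims": asdict(model.dims)}
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **params)


def load_model(path: str | Path) -> MultimodalVAE:
    with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arch = ArchitectureConfig(**meta["arch"])
        model = MultimodalVAE(arch, ModelDims(**meta["dims"]), seed=0)
        named = model.named_parameters()
        for k, p in named.items():
            p.data = data[k].astype(np.float64)
        model.checkpoint_extra = meta.get("extra")
    return model
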