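"""Numeric encodings of the three modalities.

RNA keeps the top highly variable genes; CDR3 sequences become one-hot
matrices over a 21-symbol alphabet (20 amino acids plus an explicit padding
symbol, sequences left-aligned and right-padded); V/J gene calls become
one-hot indicators over per-slot vocabularies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA_INDEX, CDR3_ALPHABET, PAD_SYMBOL
from .errors import AlphabetError, LengthError, VocabularyError
from .io import PairedDataset

ALPHABET_SIZE = len(CDR3_ALPHABET)  # 21


@dataclass
class EncodedBatch:
    """Model-ready blocks for a set of cells, aligned on the cell axis."""

    rna: np.ndarray          # (n, G)
    cdr3_alpha: np.ndarray   # (n, L_alpha, 21)
    cdr3_beta: np.ndarray    # (n, L_beta, 21)
    v_alpha: np.ndarray      # (n, |V_alpha|)
    j_alpha: np.ndarray
    v_beta: np.ndarray
    j_beta: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    def vj_blocks(self) -> dict[str, np.ndarray]:
        return {"v_alpha": self.v_alpha, "j_alpha": self.j_alpha,
                "v_beta": self.v_beta, "j_beta": self.j_beta}

    def subset(self, idx) -> "EncodedBatch":
        return EncodedBatch(self.rna[idx], self.cdr3_alpha[idx],
                            self.cdr3_beta[idx], self.v_alpha[idx],
                            self.j_alpha[idx], self.v_beta[idx],
                            self.j_beta[idx])


def select_hvg(expr: pd.DataFrame | np.ndarray, n_genes: int,
               gene_names: list[str] | None = None
               ) -> tuple[np.ndarray, list[str]]:
    """Keep the `n_genes` genes with the highest dispersion (variance/mean).

    The score is var/|mean| with zero-mean genes ranked by variance alone;
    ties break toward the lower column index, so selection is deterministic.
    Returns the reduced matrix (cell order unchanged) and retained labels.
    """
    if isinstance(expr, pd.DataFrame):
        gene_names = [str(g) for g in expr.columns]
        X = expr.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(expr, dtype=np.float64)
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
    if n_genes > X.shape[1]:
        raise ValueError(f"requested {n_genes} genes but matrix has {X.shape[1]}")
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(np.abs(mean) > 1e-12, var / np.abs(mean), var)
    # stable argsort on (-score, index) keeps ties deterministic
    order = np.lexsort((np.arange(len(score)), -score))
    keep = np.sort(order[:n_genes])
    return X[:, keep], [gene_names[i] for i in keep]


def encode_cdr3(seq: str, max_len: int) -> np.ndarray:
    """One-hot a CDR3 sequence into (max_len, 21), right-padded.

    Over-length sequences raise rather than truncate; unknown letters raise.
    """
    if len(seq) == 0:
        raise AlphabetError("empty CDR3 sequence")
    if len(seq) > max_len:
        raise LengthError(f"CDR3 {seq!r} longer than max_len={max_len}")
    out = np.zeros((max_len, ALPHABET_SIZE))
    for i, aa in enumerate(seq):
        if aa not in AA_INDEX or aa == PAD_SYMBOL:
            raise AlphabetError(f"unknown amino-acid letter {aa!r} in {seq!r}")
        out[i, AA_INDEX[aa]] = 1.0
    out[len(seq):, AA_INDEX[PAD_SYMBOL]] = 1.0
    return out


def decode_cdr3(mat: np.ndarray) -> str:
    """Inverse of :func:`encode_cdr3` via per-row argmax, stopping at padding."""
    letters = []
    for row in np.asarray(mat):
        sym = CDR3_ALPHABET[int(np.argmax(row))]
        if sym == PAD_SYMBOL:
            break
        letters.append(sym)
    return "".join(letters)


def encode_vj(gene: str, vocab: list[str]) -> np.ndarray:
    """One-hot indicator of `gene` within `vocab`."""
    try:
        idx = vocab.index(gene)
    except ValueError:
        raise VocabularyError(f"gene {gene!r} not in vocabulary of size {len(vocab)}")
    out = np.zeros(len(vocab))
    out[idx] = 1.0
    return out


def decode_vj(indicator: np.ndarray, vocab: list[str]) -> str:
    return vocab[int(np.argmax(indicator))]


def build_encoded_batch(ds: PairedDataset,
                        hvg_genes: list[str] | None = None) -> EncodedBatch:
    """Encode every cell of `ds` into aligned numeric blocks.

    If `hvg_genes` is given, the RNA block is restricted to those genes (in
    that order); otherwise the full panel is used.
    """
    rna = ds.rna_matrix
    if hvg_genes is not None:
        index = {g: i for i, g in enumerate(ds.gene_names)}
        missing = [g for g in hvg_genes if g not in index]
        if missing:
            raise VocabularyError(f"genes not in dataset panel: {missing[:5]}")
        rna = rna[:, [index[g] for g in hvg_genes]]

    n = len(ds)
    cdr3_a = np.zeros((n, ds.max_cdr3_len_alpha, ALPHABET_SIZE))
    cdr3_b = np.zeros((n, ds.max_cdr3_len_beta, ALPHABET_SIZE))
    v_a = np.zeros((n, len(ds.v_vocab_alpha)))
    j_a = np.zeros((n, len(ds.j_vocab_alpha)))
    v_b = np.zeros((n, len(ds.v_vocab_beta)))
    j_b = np.zeros((n, len(ds.j_vocab_beta)))
    for i, cell in enumerate(ds.cells):
        cdr3_a[i] = encode_cdr3(cell.alpha.cdr3_aa, ds.max_cdr3_len_alpha)
        cdr3_b[i] = encode_cdr3(cell.beta.cdr3_aa, ds.max_cdr3_len_beta)
        v_a[i] = encode_vj(cell.alpha.v_gene, ds.v_vocab_alpha)
        j_a[i] = encode_vj(cell.alpha.j_gene, ds.j_vocab_alpha)
        v_b[i] = encode_vj(cell.beta.v_gene, ds.v_vocab_beta)
        j_b[i] = encode_vj(cell.beta.j_gene, ds.j_vocab_beta)
    return EncodedBatch(rna=rna, cdr3_alpha=cdr3_a, cdr3_beta=cdr3_b,
                        v_alpha=v_a, j_alpha=j_a, v_beta=v_b, j_beta=j_b)


def save_encoded_batch(batch: EncodedBatch, path: str | Path,
                       vocabularies: dict | None = None) -> None:
    """Write the blocks to an HDF5 container plus a JSON vocabulary sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rna", data=batch.rna)
        fh.create_dataset("cdr3_alpha", data=batch.cdr3_alpha)
        fh.create_dataset("cdr3_beta", data=batch.cdr3_beta)
        for name, block in batch.vj_blocks().items():
            fh.create_dataset(name, data=block)
    sidecar = {"alphabet": CDR3_ALPHABET}
    if vocabularies:
        sidecar.update(vocabularies)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_encoded_batch(path: str | Path) -> EncodedBatch:
    import h5py

    with h5py.File(path, "r") as fh:
        return EncodedBatch(rna=fh["rna"][...],
                            cdr3_alpha=fh["cdr3_alpha"][...],
                            cdr3_beta=fh["cdr3_beta"][...],
                            v_alpha=fh["v_alpha"][...],
                            j_alpha=fh["j_alpha"][...],
                            v_beta=fh["v_beta"][...],
                            j_beta=fh["j_beta"][...])
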