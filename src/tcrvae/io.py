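"""Reading, filtering and pairing of scTCR-seq contigs with expression data.

The TCR side follows the 10x Genomics ``filtered_contig_annotations.csv``
dialect: one row per assembled contig with barcode, chain, CDR3 amino-acid
sequence, V/J gene calls, a productivity flag and a UMI count.  Only
productive contigs with a complete CDR3 and gene calls are used; a cell
enters the paired dataset only if it has both an alpha and a beta chain and
an expression profile under the same barcode.

The expression side is assumed normalised and log-transformed upstream
(optionally batch-corrected); this module validates finiteness only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS
from .errors import EmptyInputError, FormatError, PairingError

_TRUTHY = {"true", "t", "yes", "1"}


@dataclass(frozen=True)
class ContigDialect:
    """Column mapping for a contig annotation table (10x names by default)."""

    barcode: str = "barcode"
    chain: str = "chain"
    cdr3: str = "cdr3"
    v_gene: str = "v_gene"
    j_gene: str = "j_gene"
    productive: str = "productive"
    umis: str = "umis"

    def required_columns(self) -> list[str]:
        return [self.barcode, self.chain, self.cdr3, self.v_gene,
                self.j_gene, self.productive, self.umis]


@dataclass(frozen=True)
class TCRChain:
    chain_id: str  # "alpha" or "beta"
    cdr3_aa: str
    v_gene: str
    j_gene: str
    umi_count: int

    def __post_init__(self):
        if self.chain_id not in ("alpha", "beta"):
            raise ValueError(f"chain_id must be alpha/beta, got {self.chain_id!r}")
        if not self.cdr3_aa or any(c not in AMINO_ACIDS for c in self.cdr3_aa):
            raise ValueError(f"invalid CDR3 sequence {self.cdr3_aa!r}")
        if self.umi_count < 0:
            raise ValueError("umi_count must be non-negative")


@dataclass
class PairedCell:
    barcode: str
    alpha: TCRChain
    beta: TCRChain
    rna: np.ndarray
    batch: str
    tissue: str
    cell_type: str | None = None
    clonotype_id: str | None = None


@dataclass
class PairedDataset:
    """Paired RNA + TCR cells with the vocabularies the encoders need."""

    cells: list[PairedCell]
    gene_names: list[str]
    v_vocab_alpha: list[str] = field(default_factory=list)
    j_vocab_alpha: list[str] = field(default_factory=list)
    v_vocab_beta: list[str] = field(default_factory=list)
    j_vocab_beta: list[str] = field(default_factory=list)
    max_cdr3_len_alpha: int = 0
    max_cdr3_len_beta: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def barcodes(self) -> list[str]:
        return [c.barcode for c in self.cells]

    @property
    def rna_matrix(self) -> np.ndarray:
        return np.vstack([c.rna for c in self.cells])

    def labels(self, which: str) -> np.ndarray:
        vals = [getattr(c, which) for c in self.cells]
        if any(v is None for v in vals):
            raise FormatError(f"metadata field {which!r} missing for some cells")
        return np.asarray(vals, dtype=object)

    def subset(self, indices) -> "PairedDataset":
        """Row subset; vocabularies and max lengths are kept as trained."""
        return PairedDataset(
            cells=[self.cells[i] for i in indices],
            gene_names=self.gene_names,
            v_vocab_alpha=self.v_vocab_alpha, j_vocab_alpha=self.j_vocab_alpha,
            v_vocab_beta=self.v_vocab_beta, j_vocab_beta=self.j_vocab_beta,
            max_cdr3_len_alpha=self.max_cdr3_len_alpha,
            max_cdr3_len_beta=self.max_cdr3_len_beta)


_CHAIN_NAMES = {"TRA": "alpha", "TRB": "beta", "alpha": "alpha", "beta": "beta"}


def read_contig_table(path: str | Path,
                      dialect: ContigDialect = ContigDialect()
                      ) -> list[tuple[str, TCRChain]]:
    """Parse a contig annotation CSV into (barcode, chain) records.

    Non-productive contigs, contigs with a missing/empty CDR3 or gene call,
    and chains other than TRA/TRB are dropped.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in dialect.required_columns() if c not in df.columns]
    if missing:
        raise FormatError(f"contig table {path} lacks required column(s): "
                          + ", ".join(missing))
    if len(df) == 0:
        raise EmptyInputError(f"contig table {path} contains no records")

    records: list[tuple[str, TCRChain]] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        productive = str(row[dialect.productive]).strip().lower() in _TRUTHY
        cdr3 = row[dialect.cdr3]
        v, j = row[dialect.v_gene], row[dialect.j_gene]
        chain_raw = str(row[dialect.chain])
        if not productive or chain_raw not in _CHAIN_NAMES:
            continue
        if pd.isna(cdr3) or str(cdr3).strip() in ("", "None", "NA"):
            continue
        if pd.isna(v) or pd.isna(j) or str(v) in ("", "None") or str(j) in ("", "None"):
            continue
        cdr3 = str(cdr3).strip()
        if any(c not in AMINO_ACIDS for c in cdr3):
            continue
        umis = row[dialect.umis]
        umi_count = int(float(umis)) if not pd.isna(umis) else 0
        records.append((str(row[dialect.barcode]),
                        TCRChain(_CHAIN_NAMES[chain_raw], cdr3,
                                 str(v), str(j), umi_count)))
    return records


def select_paired_cells(contigs: list[tuple[str, TCRChain]]
                        ) -> dict[str, tuple[TCRChain, TCRChain]]:
    """Keep barcodes carrying both chains; resolve multi-chain barcodes.

    Per locus the chain with the highest UMI count wins; ties go to the
    lexicographically smallest CDR3 (then V, then J) for determinism.
    """
    by_barcode: dict[str, dict[str, list[TCRChain]]] = {}
    for barcode, chain in contigs:
        by_barcode.setdefault(barcode, {"alpha": [], "beta": []})[
            chain.chain_id].append(chain)

    def best(chains: list[TCRChain]) -> TCRChain:
        return min(chains, key=lambda c: (-c.umi_count, c.cdr3_aa,
                                          c.v_gene, c.j_gene))

    return {bc: (best(loci["alpha"]), best(loci["beta"]))
            for bc, loci in sorted(by_barcode.items())
            if loci["alpha"] and loci["beta"]}


def pair_modalities(expr: pd.DataFrame, meta: pd.DataFrame,
                    tcr: dict[str, tuple[TCRChain, TCRChain]]
                    ) -> PairedDataset:
    """Intersect expression and TCR barcodes into one dataset.

    `expr` has barcode-labelled rows and gene-labelled columns; `meta` is
    indexed by barcode and must provide `batch` and `tissue` (optionally
    `cell_type` and `clonotype_id`).  Cell order is sorted barcodes.
    """
    for col in ("batch", "tissue"):
        if col not in meta.columns:
            raise FormatError(f"metadata lacks required column {col!r}")
    shared = sorted(set(expr.index) & set(tcr) & set(meta.index))
    if not shared:
        raise PairingError("no barcode is shared between expression, "
                           "metadata and TCR inputs")
    values = expr.loc[shared].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise FormatError("expression matrix contains non-finite values")

    cells = []
    for i, bc in enumerate(shared):
        alpha, beta = tcr[bc]
        row = meta.loc[bc]
        cells.append(PairedCell(
            barcode=bc, alpha=alpha, beta=beta, rna=values[i],
            batch=str(row["batch"]), tissue=str(row["tissue"]),
            cell_type=(str(row["cell_type"])
                       if "cell_type" in meta.columns and pd.notna(row["cell_type"])
                       else None),
            clonotype_id=(str(row["clonotype_id"])
                          if "clonotype_id" in meta.columns
                          and pd.notna(row["clonotype_id"]) else None)))

    def vocab(values_):
        return sorted(set(values_))

    return PairedDataset(
        cells=cells,
        gene_names=[str(g) for g in expr.columns],
        v_vocab_alpha=vocab(c.alpha.v_gene for c in cells),
        j_vocab_alpha=vocab(c.alpha.j_gene for c in cells),
        v_vocab_beta=vocab(c.beta.v_gene for c in cells),
        j_vocab_beta=vocab(c.beta.j_gene for c in cells),
        max_cdr3_len_alpha=max(len(c.alpha.cdr3_aa) for c in cells),
        max_cdr3_len_beta=max(len(c.beta.cdr3_aa) for c in cells))


# ---------------------------------------------------------------------------
# expression / metadata readers

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a cell-by-gene matrix: h5ad, MTX triplet, or dense delimited.

    For MTX, sidecar files `<stem>_barcodes.tsv` and `<stem>_genes.tsv`
    (one label per line) must sit next to the matrix; rows are cells.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        return pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    if suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense())
        barcodes = (path.parent / f"{path.stem}_barcodes.tsv").read_text().split()
        genes = (path.parent / f"{path.stem}_genes.tsv").read_text().split()
        return pd.DataFrame(mat, index=barcodes, columns=genes)
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return df


# ---------------------------------------------------------------------------
# on-disk layout round trip

def save_paired_dataset(ds: PairedDataset, out_dir: str | Path) -> None:
    """Write the dataset as contigs.csv + expression.tsv + metadata.tsv.

    The layout round-trips through :func:`load_paired_dataset` to identical
    vocabularies, sequences and matrices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in ds.cells:
        for chain, name in ((c.alpha, "TRA"), (c.beta, "TRB")):
            rows.append({"barcode": c.barcode, "chain": name,
                         "cdr3": chain.cdr3_aa, "v_gene": chain.v_gene,
                         "j_gene": chain.j_gene, "productive": "True",
                         "umis": chain.umi_count})
    pd.DataFrame(rows).to_csv(out / "contigs.csv", index=False)

    pd.DataFrame(ds.rna_matrix, index=ds.barcodes,
                 columns=ds.gene_names).to_csv(out / "expression.tsv", sep="\t")
    meta = pd.DataFrame({
        "batch": [c.batch for c in ds.cells],
        "tissue": [c.tissue for c in ds.cells],
        "cell_type": [c.cell_type for c in ds.cells],
        "clonotype_id": [c.clonotype_id for c in ds.cells],
    }, index=pd.Index(ds.barcodes, name="barcode"))
    meta.to_csv(out / "metadata.tsv", sep="\t")
    with open(out / "dataset.json", "w") as fh:
        json.dump({"n_cells": len(ds), "n_genes": len(ds.gene_names)}, fh)


def load_paired_dataset(in_dir: str | Path) -> PairedDataset:
    in_dir = Path(in_dir)
    contigs = read_contig_table(in_dir / "contigs.csv")
    tcr = select_paired_cells(contigs)
    expr = read_expression(in_dir / "expression.tsv")
    meta = read_metadata(in_dir / "metadata.tsv")
    return pair_modalities(expr, meta, tcr)
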