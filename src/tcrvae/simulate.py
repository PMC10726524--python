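"""Synthetic paired scRNA + scTCR datasets with planted structure.

The generator emulates the features of real paired data that the model and
metrics exercise: cell types with separated Gaussian expression centroids
(log-scale expression offsets), additive per-batch shifts, clonotypes whose
cells share identical CDR3 sequences and V/J genes, and a skewed clone-size
distribution mimicking clonal expansion.  CDR3 sequences are uniform random
amino-acid strings — no V(D)J recombination biology or motif structure is
modelled, so passing tests certify algorithmic behaviour, not biological
realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .constants import AMINO_ACIDS
from .io import PairedCell, PairedDataset, TCRChain, save_paired_dataset


@dataclass
class SimulationConfig:
    n_cells: int = 600
    n_genes: int = 100
    n_cell_types: int = 3
    n_clonotypes: int = 20
    n_batches: int = 2
    n_tissues: int = 2
    cdr3_len_range: tuple[int, int] = (8, 16)
    n_v_genes: int = 10
    n_j_genes: int = 6
    type_separation: float = 3.0   # sd of per-gene centroid offsets
    batch_shift: float = 1.0       # sd of the additive per-batch vector
    clone_type_concordance: float = 1.0
    noise_sd: float = 1.0
    clone_size_skew: float = 0.15  # geometric weight decay across clonotypes
    shared_clones_across_tissues: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_cells, self.n_genes, self.n_cell_types,
                  self.n_clonotypes, self.n_batches, self.n_tissues,
                  self.n_v_genes, self.n_j_genes)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_clonotypes > self.n_cells:
            raise ValueError("more clonotypes than cells")
        if not 0 <= self.clone_type_concordance <= 1:
            raise ValueError("clone_type_concordance must be in [0, 1]")
        lo, hi = self.cdr3_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid cdr3_len_range")


@dataclass
class GroundTruth:
    cell_type: np.ndarray       # per cell
    clonotype: np.ndarray       # per cell
    batch: np.ndarray           # per cell
    tissue: np.ndarray          # per cell
    clonotype_tcr: dict         # clonotype id -> dict of CDR3/V/J features
    type_centroids: np.ndarray  # (n_cell_types, n_genes)
    batch_vectors: np.ndarray   # (n_batches, n_genes)


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_paired_dataset(cfg: SimulationConfig = SimulationConfig()
                            ) -> tuple[PairedDataset, GroundTruth]:
    """Draw a fully paired dataset; byte-identical given (config, seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    centroids = rng.normal(0.0, cfg.type_separation,
                           size=(cfg.n_cell_types, cfg.n_genes))
    batch_vecs = rng.normal(0.0, cfg.batch_shift,
                            size=(cfg.n_batches, cfg.n_genes))

    # clonotype-level features
    clone_home_type = rng.integers(cfg.n_cell_types, size=cfg.n_clonotypes)
    clone_tcr = {}
    lo, hi = cfg.cdr3_len_range
    for c in range(cfg.n_clonotypes):
        clone_tcr[f"clone{c:03d}"] = {
            "cdr3_alpha": _random_cdr3(rng, lo, hi),
            "cdr3_beta": _random_cdr3(rng, lo, hi),
            "v_alpha": f"TRAV{rng.integers(cfg.n_v_genes) + 1}",
            "j_alpha": f"TRAJ{rng.integers(cfg.n_j_genes) + 1}",
            "v_beta": f"TRBV{rng.integers(cfg.n_v_genes) + 1}",
            "j_beta": f"TRBJ{rng.integers(cfg.n_j_genes) + 1}",
        }

    # skewed clone sizes: geometric weights, every clone seeded at least once
    weights = (1.0 - cfg.clone_size_skew) ** np.arange(cfg.n_clonotypes)
    weights /= weights.sum()
    assignment = np.empty(cfg.n_cells, dtype=int)
    assignment[:cfg.n_clonotypes] = np.arange(cfg.n_clonotypes)
    assignment[cfg.n_clonotypes:] = rng.choice(
        cfg.n_clonotypes, size=cfg.n_cells - cfg.n_clonotypes, p=weights)
    rng.shuffle(assignment)

    cell_type = np.empty(cfg.n_cells, dtype=int)
    for i, clone in enumerate(assignment):
        if rng.random() < cfg.clone_type_concordance:
            cell_type[i] = clone_home_type[clone]
        else:
            cell_type[i] = rng.integers(cfg.n_cell_types)
    batch = rng.integers(cfg.n_batches, size=cfg.n_cells)
    if cfg.shared_clones_across_tissues:
        tissue = rng.integers(cfg.n_tissues, size=cfg.n_cells)
    else:
        clone_tissue = rng.integers(cfg.n_tissues, size=cfg.n_clonotypes)
        tissue = clone_tissue[assignment]

    rna = (centroids[cell_type] + batch_vecs[batch]
           + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_cells, cfg.n_genes)))

    cells = []
    for i in range(cfg.n_cells):
        clone_id = f"clone{assignment[i]:03d}"
        tcr = clone_tcr[clone_id]
        umis = rng.integers(1, 50, size=2)
        cells.append(PairedCell(
            barcode=f"cell{i:05d}-1",
            alpha=TCRChain("alpha", tcr["cdr3_alpha"], tcr["v_alpha"],
                           tcr["j_alpha"], int(umis[0])),
            beta=TCRChain("beta", tcr["cdr3_beta"], tcr["v_beta"],
                          tcr["j_beta"], int(umis[1])),
            rna=rna[i],
            batch=f"batch{batch[i]}",
            tissue=f"tissue{tissue[i]}",
            cell_type=f"type{cell_type[i]}",
            clonotype_id=clone_id))

    def vocab(values_):
        return sorted(set(values_))

    ds = PairedDataset(
        cells=cells,
        gene_names=[f"gene{g:04d}" for g in range(cfg.n_genes)],
        v_vocab_alpha=vocab(c.alpha.v_gene for c in cells),
        j_vocab_alpha=vocab(c.alpha.j_gene for c in cells),
        v_vocab_beta=vocab(c.beta.v_gene for c in cells),
        j_vocab_beta=vocab(c.beta.j_gene for c in cells),
        max_cdr3_len_alpha=max(len(c.alpha.cdr3_aa) for c in cells),
        max_cdr3_len_beta=max(len(c.beta.cdr3_aa) for c in cells))
    truth = GroundTruth(
        cell_type=np.array([c.cell_type for c in cells], dtype=object),
        clonotype=np.array([c.clonotype_id for c in cells], dtype=object),
        batch=np.array([c.batch for c in cells], dtype=object),
        tissue=np.array([c.tissue for c in cells], dtype=object),
        clonotype_tcr=clone_tcr,
        type_centroids=centroids,
        batch_vectors=batch_vecs)
    return ds, truth


def write_fixture(ds: PairedDataset, truth: GroundTruth,
                  out_dir: str | Path, cfg: SimulationConfig | None = None
                  ) -> None:
    """Write the 10x-dialect contig table, expression matrix, metadata and
    a ground-truth JSON; round-trips through the pairing pipeline."""
    out = Path(out_dir)
    save_paired_dataset(ds, out)
    payload = {
        "clonotype_tcr": truth.clonotype_tcr,
        "per_cell": {
            "cell_type": list(truth.cell_type),
            "clonotype": list(truth.clonotype),
            "batch": list(truth.batch),
            "tissue": list(truth.tissue),
        },
    }
    if cfg is not None:
        payload["config"] = asdict(cfg)
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
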