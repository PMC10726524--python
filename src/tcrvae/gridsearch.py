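"""Grid search over the three loss weights.

Each candidate triple (a_latent, a_gene, a_seq) is trained on a random
subsample of the dataset; the objective is the latent cell-type ASW plus
the reconstruction accuracy, maximised subject to two feasibility
constraints: ASW strictly above 0.5 (better than random) and final total
loss at most 115% of the smallest final loss over the grid (the model must
still fit the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import NoFeasiblePointError
from .metrics import normalized_asw, prediction_accuracy
from .model import (ArchitectureConfig, LossWeights, TrainingConfig,
                    extract_latent, train_vae)

DEFAULT_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class GridSpec:
    values: Sequence[float] = DEFAULT_GRID
    subsample_n: int = 4000
    seed: int = 0
    asw_floor: float = 0.5
    loss_ratio_cap: float = 1.15
    average_accuracies: bool = True  # ASW + mean(vj, cdr3) vs ASW + vj + cdr3


@dataclass
class CandidateResult:
    alpha_latent: float
    alpha_gene: float
    alpha_seq: float
    asw: float
    vj_accuracy: float
    cdr3_accuracy: float
    final_loss: float
    combined_objective: float = float("nan")
    feasible: bool = False

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.alpha_latent, self.alpha_gene, self.alpha_seq)


@dataclass
class GridResult:
    table: list[CandidateResult]
    selected: CandidateResult

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.table])


def combined_objective(c: CandidateResult, spec: GridSpec) -> float:
    acc = ((c.vj_accuracy + c.cdr3_accuracy) / 2.0
           if spec.average_accuracies
           else c.vj_accuracy + c.cdr3_accuracy)
    return c.asw + acc


def apply_constraints(table: Sequence[CandidateResult],
                      spec: GridSpec) -> list[CandidateResult]:
    """Rows with asw > asw_floor (strict) and loss <= cap * min loss."""
    if not table:
        return []
    min_loss = min(c.final_loss for c in table)
    return [c for c in table
            if c.asw > spec.asw_floor
            and c.final_loss <= spec.loss_ratio_cap * min_loss]


def select_winner(table: Sequence[CandidateResult],
                  spec: GridSpec) -> GridResult:
    """Annotate the table with objectives/feasibility and pick the winner.

    Ties on the objective break toward the lexicographically smallest
    weight triple.
    """
    table = list(table)
    feasible = apply_constraints(table, spec)
    feasible_ids = {id(c) for c in feasible}
    for c in table:
        c.combined_objective = combined_objective(c, spec)
        c.feasible = id(c) in feasible_ids
    if not feasible:
        raise NoFeasiblePointError(
            "no weight triple satisfies the ASW and loss constraints",
            table=table)
    winner = min(feasible, key=lambda c: (-c.combined_objective, c.triple))
    return GridResult(table=table, selected=winner)


def run_grid_search(dataset, spec: GridSpec = GridSpec(),
                    arch: ArchitectureConfig = ArchitectureConfig(),
                    cfg: TrainingConfig = TrainingConfig(),
                    hvg_genes: list[str] | None = None,
                    trainer: Callable[[object, LossWeights], CandidateResult]
                    | None = None) -> GridResult:
    """Evaluate every triple of `spec.values` ** 3 and select the winner.

    `trainer` is injectable for testing: it maps (dataset, weights) to a
    CandidateResult.  The default trainer subsamples `spec.subsample_n`
    cells (all cells if fewer), trains the VAE, and measures latent
    cell-type ASW, reconstruction accuracy and final total loss.
    """
    rng = np.random.default_rng(spec.seed)

    if trainer is None:
        def trainer(ds, weights):  # noqa: D401 - local default
            model, trace = train_vae(ds, arch, weights, cfg, hvg_genes)
            latent = extract_latent(model, ds, hvg_genes)
            rep = normalized_asw(latent, ds.labels("cell_type"))
            from .encoding import build_encoded_batch
            batch = build_encoded_batch(ds, hvg_genes)
            acc = prediction_accuracy(batch, model.reconstruct(batch))
            return CandidateResult(
                alpha_latent=weights.alpha_latent,
                alpha_gene=weights.alpha_gene,
                alpha_seq=weights.alpha_seq,
                asw=rep.asw, vj_accuracy=acc.vj_accuracy,
                cdr3_accuracy=acc.cdr3_accuracy,
                final_loss=trace[-1].total)

    table: list[CandidateResult] = []
    for al in spec.values:
        for ag in spec.values:
            for asq in spec.values:
                sub = dataset
                if hasattr(dataset, "subset") and len(dataset) > spec.subsample_n:
                    idx = np.sort(rng.choice(len(dataset), size=spec.subsample_n,
                                             replace=False))
                    sub = dataset.subset(idx)
                table.append(trainer(sub, LossWeights(al, ag, asq)))
    return select_winner(table, spec)
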