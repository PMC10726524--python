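"""Evaluation battery for integrated embeddings.

* normalized ASW — silhouette on cell-type labels rescaled to [0, 1];
* V/J and CDR3 reconstruction accuracy (argmax decoding);
* bASW — tissue-stratified silhouette on batch labels, cell-count weighted
  and reported as 1 - bASW so that higher means better mixing;
* kBET — chi-squared test of local vs global batch composition over random
  k-neighborhoods, summarised as a rejection rate and reported as 1 - kBET;
* normalized within-cluster pairwise distances — the mean pairwise distance
  inside a cluster (e.g. a CDR3-similarity cluster from an external GLIPH2
  run) divided by the mean pairwise distance across all cells.

All distances are Euclidean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import chi2
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .errors import MetricError


@dataclass
class SilhouetteReport:
    per_cell: np.ndarray
    asw: float
    n: int


@dataclass
class AccuracyReport:
    vj_accuracy: float
    cdr3_accuracy: float


@dataclass
class BatchMixingReport:
    basw_per_tissue: dict[str, float] = field(default_factory=dict)
    n_per_tissue: dict[str, int] = field(default_factory=dict)
    basw: float = float("nan")
    one_minus_basw: float = float("nan")
    kbet_rejection: float = float("nan")
    one_minus_kbet: float = float("nan")
    k: int | None = None
    alpha: float | None = None


@dataclass
class ClusterDistanceReport:
    per_cluster: dict[str, float]
    global_mean_distance: float

    @property
    def mean_normalized_distance(self) -> float:
        return float(np.mean(list(self.per_cluster.values())))


def normalized_asw(embedding: np.ndarray, labels) -> SilhouetteReport:
    """Silhouette per cell on Euclidean distances, rescaled by (mean+1)/2.

    a(i) is the mean distance to same-label cells, b(i) the smallest mean
    distance to another label's cells; cells in singleton labels score 0.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise MetricError("normalized ASW requires at least 2 distinct labels")
    per_cell = silhouette_samples(embedding, labels, metric="euclidean")
    asw = float((per_cell.mean() + 1.0) / 2.0)
    return SilhouetteReport(per_cell=per_cell, asw=asw, n=len(labels))


def prediction_accuracy(orig, recon: dict[str, np.ndarray]) -> AccuracyReport:
    """Argmax-decoding accuracy of V/J slots and CDR3 positions.

    `orig` is an EncodedBatch; `recon` maps head names to score arrays.
    V/J accuracy pools the four slots over all cells; CDR3 accuracy pools
    both chains over all positions that are not padding in the original.
    Argmax ties resolve to the lowest index.
    """
    correct = 0
    total = 0
    for slot in ("v_alpha", "j_alpha", "v_beta", "j_beta"):
        t = np.argmax(getattr(orig, slot), axis=-1)
        p = np.argmax(recon[slot], axis=-1)
        correct += int((t == p).sum())
        total += t.size
    vj_acc = correct / total if total else float("nan")

    correct = 0
    total = 0
    pad_idx = orig.cdr3_alpha.shape[-1] - 1  # padding symbol is last
    for chain in ("alpha", "beta"):
        t_onehot = getattr(orig, f"cdr3_{chain}")
        t = np.argmax(t_onehot, axis=-1)
        p = np.argmax(recon[f"cdr3_{chain}"], axis=-1)
        mask = t != pad_idx
        correct += int((t[mask] == p[mask]).sum())
        total += int(mask.sum())
    cdr3_acc = correct / total if total else float("nan")
    return AccuracyReport(vj_accuracy=vj_acc, cdr3_accuracy=cdr3_acc)


def basw(embedding: np.ndarray, batch_labels, tissue_labels) -> BatchMixingReport:
    """Tissue-stratified batch silhouette, scaled to [0,1] per tissue by
    (ASW+1)/2, combined by cell-count weights, reported also as 1 - bASW.

    Tissues with fewer than two batches are excluded with a warning.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    batch_labels = np.asarray(batch_labels)
    tissue_labels = np.asarray(tissue_labels)
    report = BatchMixingReport()
    for tissue in np.unique(tissue_labels):
        mask = tissue_labels == tissue
        if len(np.unique(batch_labels[mask])) < 2:
            warnings.warn(f"tissue {tissue!r} has a single batch; excluded "
                          "from bASW", stacklevel=2)
            continue
        s = silhouette_samples(embedding[mask], batch_labels[mask],
                               metric="euclidean")
        report.basw_per_tissue[str(tissue)] = float((s.mean() + 1.0) / 2.0)
        report.n_per_tissue[str(tissue)] = int(mask.sum())
    if not report.basw_per_tissue:
        raise MetricError("no tissue has >= 2 batches; bASW undefined")
    n_total = sum(report.n_per_tissue.values())
    report.basw = float(sum(v * report.n_per_tissue[t] / n_total
                            for t, v in report.basw_per_tissue.items()))
    report.one_minus_basw = 1.0 - report.basw
    return report


def kbet(embedding: np.ndarray, batch_labels, k: int = 25,
         n_tests: int = 500, alpha: float = 0.05,
         seed: int = 0) -> BatchMixingReport:
    """k-nearest-neighbour batch-effect test.

    For each of `n_tests` randomly drawn cells, the batch composition of its
    k-neighborhood (the cell included) is compared to the global batch
    proportions with a chi-squared goodness-of-fit test on B-1 degrees of
    freedom.  The rejection rate is the fraction of tests with p < alpha.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    batch_labels = np.asarray(batch_labels)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cell count {n}")
    batches, codes = np.unique(batch_labels, return_inverse=True)
    if len(batches) < 2:
        raise ValueError("kBET requires at least 2 batches")
    props = np.bincount(codes, minlength=len(batches)) / n
    expected = k * props
    if np.any(expected < 1):
        warnings.warn("expected neighborhood counts < 1 for some batch; "
                      "chi-squared approximation is weak", stacklevel=2)

    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    rng = np.random.default_rng(seed)
    centers = rng.choice(n, size=min(n_tests, n), replace=n_tests > n)
    _, idx = nn.kneighbors(embedding[centers])
    rejected = 0
    df = len(batches) - 1
    for row in idx:
        observed = np.bincount(codes[row], minlength=len(batches))
        stat = float(((observed - expected) ** 2 / expected).sum())
        if chi2.sf(stat, df) < alpha:
            rejected += 1
    rate = rejected / len(centers)
    return BatchMixingReport(kbet_rejection=rate, one_minus_kbet=1.0 - rate,
                             k=k, alpha=alpha)


def normalized_cluster_distances(embedding: np.ndarray,
                                 cluster_assignments: dict[str, np.ndarray]
                                 ) -> ClusterDistanceReport:
    """Mean within-cluster pairwise distance over the global mean pairwise
    distance; singleton clusters are skipped with a warning."""
    embedding = np.asarray(embedding, dtype=np.float64)
    global_mean = float(pdist(embedding).mean())
    per_cluster: dict[str, float] = {}
    for cid, members in cluster_assignments.items():
        members = np.asarray(members)
        if len(members) < 2:
            warnings.warn(f"cluster {cid!r} has < 2 cells; skipped",
                          stacklevel=2)
            continue
        per_cluster[str(cid)] = float(
            pdist(embedding[members]).mean() / global_mean)
    return ClusterDistanceReport(per_cluster=per_cluster,
                                 global_mean_distance=global_mean)
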