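"""Evaluation metrics against exhaustive reference implementations."""

import numpy as np
import pytest

from tcrvae.encoding import EncodedBatch
from tcrvae.errors import MetricError
from tcrvae.metrics import (basw, kbet, normalized_asw,
                            normalized_cluster_distances, prediction_accuracy)


def silhouette_reference(X, labels):
    """Exhaustive O(n^2) silhouette; singleton labels score 0."""
    X = np.asarray(X, float)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


class TestNormalizedAsw:
    def test_coincident_separated_clusters_score_one(self):
        X = np.array([[0.0, 0.0]] * 3 + [[100.0, 0.0]] * 3)
        labels = ["A"] * 3 + ["B"] * 3
        assert normalized_asw(X, labels).asw == pytest.approx(1.0)

    def test_four_point_line_example(self):
        # points 0,1,10,11 with labels A,A,B,B:
        # s = (9.5/10.5, 8.5/9.5, 8.5/9.5, 9.5/10.5), mean 0.899749
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        rep = normalized_asw(X, ["A", "A", "B", "B"])
        assert rep.asw == pytest.approx(0.9498747, abs=1e-6)
        assert rep.n == 4

    def test_random_labels_score_near_half(self, rng):
        X = rng.standard_normal((500, 5))
        labels = rng.integers(3, size=500)
        assert normalized_asw(X, labels).asw == pytest.approx(0.5, abs=0.05)

    def test_single_label_rejected(self, rng):
        with pytest.raises(MetricError):
            normalized_asw(rng.standard_normal((5, 2)), ["A"] * 5)

    def test_matches_exhaustive_reference_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            X = rng.standard_normal((n, 3))
            labels = rng.integers(rng.integers(2, 5), size=n)
            rep = normalized_asw(X, labels)
            ref = silhouette_reference(X, labels)
            assert np.allclose(rep.per_cell, ref, atol=1e-10)
            assert rep.asw == pytest.approx((ref.mean() + 1) / 2, abs=1e-12)


def _batch_from(vj, cdr3_a, cdr3_b):
    n = vj["v_alpha"].shape[0]
    return EncodedBatch(rna=np.zeros((n, 1)), cdr3_alpha=cdr3_a,
                        cdr3_beta=cdr3_b, **vj)


class TestPredictionAccuracy:
    SLOTS = ("v_alpha", "j_alpha", "v_beta", "j_beta")

    def _random_batch(self, rng, n=8, K=5, L=6):
        vj = {s: np.eye(K)[rng.integers(K, size=n)] for s in self.SLOTS}
        def onehot_seq():
            seqs = np.zeros((n, L, 21))
            for i in range(n):
                length = int(rng.integers(1, L + 1))
                for p in range(L):
                    seqs[i, p, rng.integers(20) if p < length else 20] = 1
            return seqs
        return _batch_from(vj, onehot_seq(), onehot_seq())

    def test_perfect_reconstruction_scores_one(self, rng):
        b = self._random_batch(rng)
        recon = {s: getattr(b, s) for s in self.SLOTS}
        recon["cdr3_alpha"] = b.cdr3_alpha
        recon["cdr3_beta"] = b.cdr3_beta
        rep = prediction_accuracy(b, recon)
        assert rep.vj_accuracy == 1.0 and rep.cdr3_accuracy == 1.0

    def test_always_wrong_scores_zero(self, rng):
        b = self._random_batch(rng)
        recon = {s: np.roll(getattr(b, s), 1, axis=-1) for s in self.SLOTS}
        recon["cdr3_alpha"] = np.roll(b.cdr3_alpha, 1, axis=-1)
        recon["cdr3_beta"] = np.roll(b.cdr3_beta, 1, axis=-1)
        rep = prediction_accuracy(b, recon)
        assert rep.vj_accuracy == 0.0 and rep.cdr3_accuracy == 0.0

    def test_matches_exhaustive_count_with_padding_excluded(self, rng):
        b = self._random_batch(rng)
        recon = {s: rng.standard_normal(getattr(b, s).shape)
                 for s in self.SLOTS + ("cdr3_alpha", "cdr3_beta")}
        rep = prediction_accuracy(b, recon)
        good = tot = 0
        for s in self.SLOTS:
            for i in range(8):
                good += int(np.argmax(recon[s][i]) == np.argmax(getattr(b, s)[i]))
                tot += 1
        assert rep.vj_accuracy == pytest.approx(good / tot)
        good = tot = 0
        for chain in ("cdr3_alpha", "cdr3_beta"):
            t = getattr(b, chain)
            for i in range(8):
                for p in range(t.shape[1]):
                    if np.argmax(t[i, p]) == 20:  # padding in original
                        continue
                    good += int(np.argmax(recon[chain][i, p]) == np.argmax(t[i, p]))
                    tot += 1
        assert rep.cdr3_accuracy == pytest.approx(good / tot)


class TestBasw:
    def test_weighted_combination_arithmetic(self):
        # directly check Eq-level arithmetic on hand-built per-tissue scores
        from tcrvae.metrics import BatchMixingReport
        rep = BatchMixingReport(basw_per_tissue={"blood": 0.6, "CSF": 0.8},
                                n_per_tissue={"blood": 100, "CSF": 300})
        n = sum(rep.n_per_tissue.values())
        combined = sum(v * rep.n_per_tissue[t] / n
                       for t, v in rep.basw_per_tissue.items())
        assert combined == pytest.approx(0.75)
        assert 1 - combined == pytest.approx(0.25)

    def test_well_mixed_batches_score_half(self, rng):
        X = rng.standard_normal((400, 4))
        batch = rng.integers(2, size=400)
        tissue = np.array(["blood"] * 200 + ["csf"] * 200)
        rep = basw(X, batch, tissue)
        assert rep.one_minus_basw == pytest.approx(0.5, abs=0.05)
        assert rep.one_minus_basw == pytest.approx(1 - rep.basw)

    def test_separated_batches_score_near_zero(self, rng):
        X = rng.standard_normal((200, 3))
        batch = np.array([0] * 100 + [1] * 100)
        X[batch == 1] += 60.0
        tissue = np.array(["t0", "t1"] * 100)
        rep = basw(X, batch, tissue)
        assert rep.one_minus_basw < 0.05

    def test_single_batch_tissue_excluded_with_warning(self, rng):
        X = rng.standard_normal((60, 2))
        batch = np.array([0, 1] * 20 + [0] * 20)
        tissue = np.array(["both"] * 40 + ["solo"] * 20)
        with pytest.warns(UserWarning, match="solo"):
            rep = basw(X, batch, tissue)
        assert list(rep.basw_per_tissue) == ["both"]
        with pytest.raises(MetricError):
            basw(X[40:], batch[40:], tissue[40:])


class TestKbet:
    def test_iid_batches_reject_near_alpha(self, rng):
        X = rng.standard_normal((800, 6))
        batch = rng.integers(2, size=800)
        rep = kbet(X, batch, k=25, n_tests=200, alpha=0.05, seed=5)
        assert rep.kbet_rejection <= 0.10
        assert rep.one_minus_kbet == pytest.approx(1 - rep.kbet_rejection)

    def test_disjoint_batches_always_reject(self, rng):
        X = rng.standard_normal((300, 3))
        batch = np.array([0] * 150 + [1] * 150)
        X[150:] += 100.0
        rep = kbet(X, batch, k=20, n_tests=100, seed=0)
        assert rep.kbet_rejection == 1.0

    def test_rejection_monotone_in_displacement(self, rng):
        X = rng.standard_normal((600, 4))
        batch = np.array([0] * 300 + [1] * 300)
        rates = []
        for d in (0.0, 1.0, 3.0):
            Xd = X.copy()
            Xd[300:, 0] += d
            rates.append(kbet(Xd, batch, k=25, n_tests=150, seed=2).kbet_rejection)
        assert rates[0] <= rates[1] <= rates[2]

    def test_argument_errors(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.raises(ValueError):
            kbet(X, np.zeros(30), k=5)           # one batch
        with pytest.raises(ValueError):
            kbet(X, np.arange(30) % 2, k=30)      # k >= n


class TestNormalizedClusterDistances:
    def test_whole_embedding_cluster_normalizes_to_one(self, rng):
        X = rng.standard_normal((20, 3))
        rep = normalized_cluster_distances(X, {"all": np.arange(20)})
        assert rep.per_cluster["all"] == pytest.approx(1.0)

    def test_coincident_cluster_scores_zero(self, rng):
        X = rng.standard_normal((10, 2))
        X[:4] = 7.0
        rep = normalized_cluster_distances(X, {"c": np.arange(4)})
        assert rep.per_cluster["c"] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((10, 4))
        members = np.array([1, 3, 4, 8])
        rep = normalized_cluster_distances(X, {"c": members})
        dists = [np.linalg.norm(X[i] - X[j]) for a, i in enumerate(members)
                 for j in members[a + 1:]]
        alldists = [np.linalg.norm(X[i] - X[j]) for i in range(10)
                    for j in range(i + 1, 10)]
        assert rep.per_cluster["c"] == pytest.approx(
            np.mean(dists) / np.mean(alldists), rel=1e-12)

    def test_singleton_skipped_with_warning(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.warns(UserWarning, match="skipped"):
            rep = normalized_cluster_distances(X, {"s": [2], "ok": [0, 1]})
        assert "s" not in rep.per_cluster and "ok" in rep.per_cluster


def test_scores_stay_in_declared_ranges_on_random_inputs(rng):
    for _ in range(5):
        n = int(rng.integers(40, 120))
        X = rng.standard_normal((n, 3)) * rng.uniform(0.1, 10)
        labels = rng.integers(2, 4, size=n)
        rep = normalized_asw(X, labels)
        assert 0.0 <= rep.asw <= 1.0
        assert np.all(rep.per_cell >= -1) and np.all(rep.per_cell <= 1)
        kb = kbet(X, labels, k=10, n_tests=50, seed=0)
        assert 0.0 <= kb.kbet_rejection <= 1.0
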