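"""Consensus clustering: tally correctness, invariants, k selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ferroscore as fs
from ferroscore.consensus import (
    correlation_distance, prepare_values, resample_indices, _cluster_subsample,
)
from ferroscore.exceptions import ValidationError

from conftest import make_expression


def duplicate_pair_matrix():
    """Four samples forming two exact duplicate pairs, far apart."""
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, size=20)
    b = -a + rng.normal(0, 0.05, size=20)
    values = np.column_stack([a, a, b, b])
    return make_expression([f"G{i}" for i in range(20)],
                           ["a1", "a2", "b1", "b2"], values)


def brute_force_consensus(values, k, draws, base="hierarchical"):
    """Independent straight-loop tally over a given subsample stream."""
    n = values.shape[1]
    cooccur = np.zeros((n, n))
    cosample = np.zeros((n, n))
    rng = np.random.default_rng(1)  # only consulted by kmeans init
    for idx in draws:
        labels = _cluster_subsample(values[:, idx], k, base, rng)
        for ai, i in enumerate(idx):
            for aj, j in enumerate(idx):
                cosample[i, j] += 1
                if labels[ai] == labels[aj]:
                    cooccur[i, j] += 1
    consensus = np.zeros((n, n))
    mask = cosample > 0
    consensus[mask] = cooccur[mask] / cosample[mask]
    np.fill_diagonal(consensus, 1.0)
    return consensus


class TestSubsetToPanel:
    def test_restricts_and_orders(self, default_cohort):
        _, matrix, _, _ = default_cohort
        panel, _ = fs.generate_gene_universe(fs.CohortConfig())
        sub = fs.subset_to_panel(matrix, panel)
        assert sub.gene_ids == panel.symbols
        assert sub.n_samples == matrix.n_samples

    def test_absent_genes_tolerated(self, default_cohort):
        _, matrix, _, _ = default_cohort
        panel = fs.FerroptosisGeneSet(
            [("DRV0000", "driver"), ("DRV0001", "driver"),
             ("SUP0000", "suppressor"), ("GHOST1", "marker")])
        sub = fs.subset_to_panel(matrix, panel)
        assert sub.gene_ids == ["DRV0000", "DRV0001", "SUP0000"]

    def test_zero_overlap_rejected(self, default_cohort):
        _, matrix, _, _ = default_cohort
        panel = fs.FerroptosisGeneSet([("GHOST1", "driver"), ("GHOST2", "suppressor")])
        with pytest.raises(ValidationError, match="no panel genes"):
            fs.subset_to_panel(matrix, panel)

    def test_constant_row_dropped(self):
        values = np.vstack([np.random.default_rng(0).normal(size=(3, 6)),
                            np.full(6, 2.0)])
        matrix = make_expression(["G1", "G2", "G3", "FLAT"],
                                 [f"S{i}" for i in range(6)], values)
        panel = fs.FerroptosisGeneSet([("G1", "driver"), ("G2", "driver"),
                                       ("G3", "suppressor"), ("FLAT", "marker")])
        sub = fs.subset_to_panel(matrix, panel)
        assert "FLAT" not in sub.gene_ids


class TestConsensusCluster:
    def test_duplicate_pairs_perfect_consensus(self):
        matrix = duplicate_pair_matrix()
        result = fs.consensus_cluster(matrix, k_range=[2], n_resamples=40,
                                      subsample_fraction=1.0, seed=3)
        cons = result.consensus_frame(2)
        assert cons.loc["a1", "a2"] == 1.0
        assert cons.loc["b1", "b2"] == 1.0
        assert cons.loc["a1", "b1"] == 0.0
        assert result.pac[2] == 0.0
        assert result.labels["a1"] == result.labels["a2"]
        assert result.labels["a1"] != result.labels["b1"]

    def test_matches_brute_force_tally(self, small_cohort):
        _, matrix, _, _ = small_cohort
        sub = matrix.subset_genes(matrix.gene_ids[:30])
        small = fs.ExpressionMatrix(sub.gene_ids, sub.sample_ids[:8],
                                    sub.values[:, :8])
        seed = 17
        result = fs.consensus_cluster(small, k_range=[2, 3], n_resamples=50,
                                      subsample_fraction=0.8, seed=seed)
        for k in (2, 3):
            draws = resample_indices(8, 0.8, 50, seed + k)
            oracle = brute_force_consensus(prepare_values(small.values), k, draws)
            np.testing.assert_array_equal(result.consensus[k], oracle)

    def test_full_fraction_deterministic_base_gives_binary_consensus(self,
                                                                     small_cohort):
        _, matrix, _, _ = small_cohort
        sub = fs.ExpressionMatrix(matrix.gene_ids[:40], matrix.sample_ids[:10],
                                  matrix.values[:40, :10])
        result = fs.consensus_cluster(sub, k_range=[2, 3], n_resamples=10,
                                      subsample_fraction=1.0, seed=1)
        for k in (2, 3):
            values = result.consensus[k]
            assert np.isin(values, (0.0, 1.0)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        matrix = make_expression([f"G{i}" for i in range(15)],
                                 [f"S{i}" for i in range(12)],
                                 rng.normal(size=(15, 12)))
        result = fs.consensus_cluster(matrix, k_range=[2, 3, 4], n_resamples=30,
                                      seed=seed)
        for k, cons in result.consensus.items():
            np.testing.assert_array_equal(cons, cons.T)
            np.testing.assert_array_equal(np.diag(cons), np.ones(12))
            assert cons.min() >= 0.0 and cons.max() <= 1.0
            co, cs = result.cooccurrence_counts[k], result.cosample_counts[k]
            observed = cs > 0
            np.testing.assert_allclose(cons[observed] * cs[observed],
                                       co[observed], atol=1e-9)
            assert 0.0 <= result.pac[k] <= 1.0
        labels = result.labels
        assert len(set(labels.values())) == result.chosen_k

    def test_determinism(self, small_cohort):
        _, matrix, _, _ = small_cohort
        sub = fs.ExpressionMatrix(matrix.gene_ids[:30], matrix.sample_ids[:10],
                                  matrix.values[:30, :10])
        r1 = fs.consensus_cluster(sub, k_range=[2, 3], n_resamples=25, seed=5)
        r2 = fs.consensus_cluster(sub, k_range=[2, 3], n_resamples=25, seed=5)
        for k in (2, 3):
            np.testing.assert_array_equal(r1.consensus[k], r2.consensus[k])
        assert r1.labels == r2.labels


class TestSelectK:
    def test_three_blob_recovery(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 4, size=(3, 25))
        cols, truth = [], []
        for c in range(3):
            for _ in range(8):
                cols.append(centers[c] + rng.normal(0, 0.3, size=25))
                truth.append(c)
        matrix = make_expression([f"G{i}" for i in range(25)],
                                 [f"S{i}" for i in range(24)],
                                 np.column_stack(cols))
        result = fs.consensus_cluster(matrix, k_range=range(2, 7),
                                      n_resamples=80, seed=11)
        assert result.chosen_k == 3
        labels = [result.labels[s] for s in matrix.sample_ids]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tie_breaks_toward_smaller_k(self):
        cons = np.full((6, 6), 0.5)
        np.fill_diagonal(cons, 1.0)
        result = fs.ConsensusResult(
            sample_ids=[f"S{i}" for i in range(6)], k_range=(2, 3, 4),
            consensus={k: cons for k in (2, 3, 4)},
            cooccurrence_counts={}, cosample_counts={}, cdf={},
            area={k: 0.5 for k in (2, 3, 4)},
            delta_area={2: 0.5, 3: 0.0, 4: 0.0},
            pac={k: 1.0 for k in (2, 3, 4)},
        )
        assert fs.select_k(result, method="pac") == 2

    def test_crisp_everywhere_falls_back_to_delta_area(self):
        crisp = np.eye(4)
        result = fs.ConsensusResult(
            sample_ids=[f"S{i}" for i in range(4)], k_range=(2, 3),
            consensus={2: crisp, 3: crisp},
            cooccurrence_counts={}, cosample_counts={}, cdf={},
            area={2: 0.3, 3: 0.3}, delta_area={2: 0.3, 3: 0.0},
            pac={2: 0.0, 3: 0.0},
        )
        assert fs.select_k(result, method="pac") == 2


class TestFinalLabels:
    def test_permutation_invariance(self, small_cohort):
        _, matrix, _, _ = small_cohort
        sub = fs.ExpressionMatrix(matrix.gene_ids[:30], matrix.sample_ids[:10],
                                  matrix.values[:30, :10])
        result = fs.consensus_cluster(sub, k_range=[2], n_resamples=40, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        shuffled = fs.ExpressionMatrix(sub.gene_ids,
                                       [sub.sample_ids[i] for i in perm],
                                       sub.values[:, perm])
        result_p = fs.consensus_cluster(shuffled, k_range=[2], n_resamples=40,
                                        seed=2)
        partition = [result.labels[s] for s in sub.sample_ids]
        partition_p = [result_p.labels[s] for s in sub.sample_ids]
        assert adjusted_rand_score(partition, partition_p) == 1.0

    def test_recovers_planted_partition(self, default_cohort):
        _, matrix, phenotypes, truth = default_cohort
        panel, _ = fs.generate_gene_universe(fs.CohortConfig())
        sub = fs.subset_to_panel(matrix, panel)
        result = fs.consensus_cluster(sub, n_resamples=100, seed=6)
        assert result.chosen_k == 2
        truth_labels = [1 if s in set(truth.case_ids) else 0
                        for s in sub.sample_ids]
        predicted = [result.labels[s] for s in sub.sample_ids]
        assert adjusted_rand_score(truth_labels, predicted) >= 0.9

    def test_unevaluated_k_rejected(self, small_cohort):
        _, matrix, _, _ = small_cohort
        sub = fs.ExpressionMatrix(matrix.gene_ids[:20], matrix.sample_ids[:8],
                                  matrix.values[:20, :8])
        result = fs.consensus_cluster(sub, k_range=[2, 3], n_resamples=20, seed=0)
        with pytest.raises(ValidationError):
            fs.final_labels(result, 7)
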