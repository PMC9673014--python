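"""Generator contracts: determinism, planted structure, identifiability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aesig.synthetic import (SyntheticConfig, gen_ae_counts,
                             gen_expression_profiles, gen_multisource_networks,
                             gen_soc_mapping, gen_tissue_and_targets)
from aesig.proximity import tissue_zscores
import networkx as nx


class TestAECounts:
    def test_shape_matches_cohort(self):
        cfg = SyntheticConfig(seed=0, n_drugs=15, n_aes=134, k_true=4)
        X, _ = gen_ae_counts(cfg)
        assert X.shape == (134, 15)

    def test_same_seed_bitwise_identical(self):
        cfg = SyntheticConfig(seed=5)
        X1, _ = gen_ae_counts(cfg)
        X2, _ = gen_ae_counts(cfg)
        assert X1.equals(X2)
        assert np.issubdtype(X1.to_numpy().dtype, np.integer)

    def test_high_scale_limit_matches_rates(self):
        # at huge count scale the empirical frequencies converge to W H
        cfg = SyntheticConfig(seed=2, n_drugs=20, n_aes=80, k_true=3,
                              count_scale=1e6)
        X, truth = gen_ae_counts(cfg)
        rates = truth.true_W.to_numpy() @ truth.true_H.to_numpy()
        freq = X.to_numpy() / X.to_numpy().sum(axis=0)
        for j in range(20):
            r = np.corrcoef(freq[:, j], rates[:, j])[0, 1]
            assert r > 0.999

    def test_signatures_identifiable(self):
        cfg = SyntheticConfig(seed=3)
        _, truth = gen_ae_counts(cfg)
        W = truth.true_W.to_numpy()
        Wn = W / np.linalg.norm(W, axis=0)
        G = Wn.T @ Wn
        off = G[~np.eye(cfg.k_true, dtype=bool)]
        assert off.max() < 0.3

    def test_truth_consistent(self):
        cfg = SyntheticConfig(seed=4)
        _, truth = gen_ae_counts(cfg)
        argmax = truth.true_H.to_numpy().argmax(axis=0) + 1
        assert (argmax == truth.true_clusters.to_numpy()).all()
        np.testing.assert_allclose(truth.true_W.sum(axis=0), 1.0, atol=1e-12)

    def test_rejects_bad_rank(self):
        with pytest.raises(ValueError):
            gen_ae_counts(SyntheticConfig(seed=0, n_drugs=5, n_aes=20,
                                          k_true=5))


class TestMultisourceNetworks:
    def test_identity_maps_noise_free_sources_agree(self):
        cfg = SyntheticConfig(seed=1, n_drugs=30, n_sources=3,
                              coverage=(1.0, 0.8, 0.8), map_noise_sd=0.0)
        nets, _ = gen_multisource_networks(cfg, identity_maps=True)
        full = nets[0].to_frame()
        for net in nets[1:]:
            sub = full.loc[net.ids, net.ids].to_numpy()
            np.testing.assert_allclose(sub, net.matrix, atol=1e-12)

    def test_coverage_counts(self):
        cfg = SyntheticConfig(seed=2, n_drugs=100, n_sources=2,
                              coverage=(1.0, 0.8))
        nets, _ = gen_multisource_networks(cfg)
        assert nets[0].n == 100
        assert nets[1].n == 80

    def test_networks_valid(self):
        cfg = SyntheticConfig(seed=3, n_drugs=25)
        nets, _ = gen_multisource_networks(cfg)
        for net in nets:
            M = net.matrix
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0 and M.max() <= 1

    def test_undercovered_source_rejected(self):
        cfg = SyntheticConfig(seed=0, n_drugs=40, n_sources=2,
                              coverage=(1.0, 0.05), latent_dim=3)
        with pytest.raises(ValueError, match="latent_dim"):
            gen_multisource_networks(cfg)


class TestExpressionProfiles:
    def test_null_effect_no_signal(self):
        cfg = SyntheticConfig(seed=5, n_drugs=40, k_true=2, effect_size=0.0,
                              n_genes=50, n_discriminant=10)
        labels = pd.Series([1] * 20 + [2] * 20,
                           index=[f"D{i}" for i in range(40)])
        prof, truth = gen_expression_profiles(cfg, labels)
        pvals = []
        for g in truth.planted_genes[(1, 2)]:
            a = prof.loc[g, labels.index[labels == 1]]
            b = prof.loc[g, labels.index[labels == 2]]
            pvals.append(stats.ttest_ind(a, b).pvalue)
        assert np.median(pvals) > 0.01

    def test_planted_gap_near_effect(self):
        cfg = SyntheticConfig(seed=6, n_drugs=40, k_true=2, effect_size=5.0,
                              n_genes=100, n_discriminant=10)
        labels = pd.Series([1] * 20 + [2] * 20,
                           index=[f"D{i}" for i in range(40)])
        prof, truth = gen_expression_profiles(cfg, labels)
        for g in truth.planted_genes[(1, 2)]:
            gap = prof.loc[g, labels.index[labels == 1]].mean() \
                - prof.loc[g, labels.index[labels == 2]].mean()
            assert abs(gap - 5.0) < 1.0

    def test_deterministic_and_disjoint(self):
        cfg = SyntheticConfig(seed=7, n_drugs=24, k_true=3)
        labels = pd.Series([1, 2, 3] * 8, index=[f"D{i}" for i in range(24)])
        p1, t1 = gen_expression_profiles(cfg, labels)
        p2, _ = gen_expression_profiles(cfg, labels)
        assert p1.equals(p2)
        sets = [set(v) for v in t1.planted_genes.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_too_many_planted_rejected(self):
        cfg = SyntheticConfig(seed=0, n_drugs=20, k_true=4, n_genes=50,
                              n_discriminant=10)
        labels = pd.Series([1, 2, 3, 4] * 5,
                           index=[f"D{i}" for i in range(20)])
        with pytest.raises(ValueError):
            gen_expression_profiles(cfg, labels)


class TestTissueAndTargets:
    def test_graph_connected(self):
        graph, _, _, _ = gen_tissue_and_targets(SyntheticConfig(seed=8))
        assert nx.is_connected(graph)

    def test_planted_block_scores_positive(self):
        cfg = SyntheticConfig(seed=9)
        _, expr, _, truth = gen_tissue_and_targets(cfg)
        Z = tissue_zscores(expr)
        for tissue, block in truth.tissue_blocks.items():
            assert (Z.loc[block, tissue] > 0).all()

    def test_targets_near_block_for_planted_drugs(self):
        cfg = SyntheticConfig(seed=10)
        graph, _, targets, truth = gen_tissue_and_targets(cfg)
        for drug, tissue in list(truth.tissue_drugs.items())[:5]:
            block = set(truth.tissue_blocks[tissue])
            hood = block | {n for b in block for n in graph.neighbors(b)}
            assert targets[drug] <= hood


class TestSOCMapping:
    def test_total_single_valued_map(self):
        cfg = SyntheticConfig(seed=11)
        X, truth = gen_ae_counts(cfg)
        mapping = gen_soc_mapping(cfg, truth)
        assert set(mapping) == set(X.index)

    def test_planted_category_has_members(self):
        cfg = SyntheticConfig(seed=12)
        _, truth = gen_ae_counts(cfg)
        mapping = gen_soc_mapping(cfg, truth)
        for v, soc in truth.enriched_soc.items():
            members = [ae for ae, c in mapping.items() if c == soc]
            assert len(members) >= 3
            assert set(truth.signature_blocks[v]) <= set(members)
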